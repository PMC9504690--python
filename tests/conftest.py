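"""Shared fixtures: hand-built pharmacophores and planted synthetic systems."""

import warnings

import numpy as np
import pytest

from qphar.pharm_core import PharmFeature, Pharmacophore, Sample
from qphar.qphar_model import QpharRegressor
from qphar.synthetic_data import gen_ligand_set, gen_library, gen_reference_system


def rigid_transform(seed: int):
    """A seeded random proper rotation + translation."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-8.0, 8.0, size=3)


@pytest.fixture
def six_feature_pharm() -> Pharmacophore:
    types = ["AR", "H", "HBA", "HBD", "PI", "NI"]
    rng = np.random.default_rng(42)
    feats = [
        PharmFeature(t, tuple(rng.uniform(0, 10, 3)), weight=float(i % 2 + 1))
        for i, t in enumerate(types)
    ]
    return Pharmacophore(name="hexa", features=feats)


@pytest.fixture(scope="session")
def planted_system():
    """One planted system (seed 1) with train/test sets and a fitted model."""
    gt = gen_reference_system(1)
    train = gen_ligand_set(gt, n=30, seed=1001)
    test = gen_ligand_set(gt, n=15, seed=1002, id_prefix="test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = QpharRegressor(random_state=1).fit(train)
    return {"gt": gt, "train": train, "test": test, "model": model}


@pytest.fixture(scope="session")
def planted_batch():
    """Twenty planted systems with fitted models, shared across test modules."""
    runs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(1, 21):
            gt = gen_reference_system(seed)
            train = gen_ligand_set(gt, n=30, seed=1000 + seed)
            model = QpharRegressor(random_state=seed).fit(train)
            runs.append({"seed": seed, "gt": gt, "train": train, "model": model})
    return runs


def site_of_model_features(gt, model):
    """Map each model feature to its nearest planted template site."""
    tmpl = gt.template.coords()
    return [
        int(np.linalg.norm(tmpl - mf.base.xyz, axis=1).argmin())
        for mf in model.model_features_
    ]
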