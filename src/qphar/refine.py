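"""Refined-pharmacophore generation from a trained QPhAR model.

The refinement algorithm turns a quantitative regression model into a
classification-optimised screening query in four steps:

1. *Importance* — impurity-based importances of the regression forest
   say how much each model feature matters for prediction.
2. *Contribution* — a signed direction per feature, obtained either
   from the model pharmacophore's per-feature activity lists (mean
   activity of contributing ligands, centered and variance-scaled) or
   from the forest itself: every internal node splits on a feature
   distance, sending smaller distances (feature present/closer) to the
   left child, so value(left) - value(right) measures whether proximity
   to that feature raises or lowers predicted activity.
3. *Negative features* — either dropped or converted to
   exclusion-volume spheres.
4. *Selection* — features ranked by contribution (optionally weighted
   by importance), the top x with non-negative rank key emitted.

Also here: the shared-feature pharmacophore baseline (features common
to the n most active aligned ligands) and the exhaustive hyperparameter
search over the 2 x 2 x 2 x 5 refinement configuration space.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pharm_core import (
    FeatureType,
    PharmFeature,
    Pharmacophore,
    Sample,
    default_tolerance,
    map_features,
    transform_pharmacophore,
)
from .qphar_model import ModelFeature, QpharRegressor, _best_conformer_by_alignment, _reference_conformer
from . import screen_metrics as sm

__all__ = [
    "ContributionVector",
    "RefinementConfig",
    "PharmacophoreRefiner",
    "feature_importances",
    "contributions_from_model",
    "contributions_from_rf",
    "process_negative_features",
    "build_refined",
    "baseline_shared",
    "grid_search",
    "default_config_space",
]

XV_RADIUS = default_tolerance(FeatureType.XV)


@dataclass
class ContributionVector:
    """Signed per-model-feature contribution.

    ``raw`` is on the activity scale; ``scaled`` is centered and
    variance-scaled (z-scored, population std) so its sign encodes the
    contribution direction.  All-equal raw values scale to all zeros.
    """

    raw: np.ndarray
    scaled: np.ndarray
    source: str  # "model" | "rf"

    @property
    def signs(self) -> np.ndarray:
        return np.sign(self.scaled)


def _center_and_scale(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    std = raw.std()  # population std
    if std == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / std


@dataclass(frozen=True)
class RefinementConfig:
    """Hyperparameters of the refinement step.

    ``num_features`` (x) is recommended in [4, 8]; smaller or larger
    values are accepted with a warning.  ``contribution_from_ml``
    selects the forest tree-traversal contribution method; otherwise
    the activity-list method is used.
    """

    weight_by_importance: bool = False
    set_exclusion_volumes: bool = False
    contribution_from_ml: bool = False
    num_features: int = 4

    def __post_init__(self):
        if not (4 <= self.num_features <= 8):
            warnings.warn(
                f"num_features={self.num_features} is outside the recommended [4, 8] interval",
                stacklevel=3,
            )


def feature_importances(model: QpharRegressor) -> np.ndarray:
    """Impurity-based importances of the fitted forest (sum to 1 if any split)."""
    model._check_fitted()
    return np.asarray(model.importances_, dtype=float)


def contributions_from_model(model: QpharRegressor) -> ContributionVector:
    """Contribution signs from the model features' activity lists.

    raw_i = mean activity of the ligands whose features merged into
    model feature i; high-activity company means positive contribution.
    """
    model._check_fitted()
    for i, mf in enumerate(model.model_features_):
        if not mf.activities:
            raise ValueError(f"model feature {i} has an empty activity list")
    raw = np.array([float(np.mean(mf.activities)) for mf in model.model_features_])
    return ContributionVector(raw=raw, scaled=_center_and_scale(raw), source="model")


def contributions_from_rf(model: QpharRegressor) -> ContributionVector:
    """Contribution signs read off the regression-tree structure.

    For every internal node splitting on feature f the signed sample
    value(left child) - value(right child) is recorded; since inputs at
    or below the threshold (smaller distance, feature closer/present)
    go left, a positive mean over all such nodes in all trees means
    proximity to f raises predicted activity.  Features never split on
    get raw contribution 0.
    """
    model._check_fitted()
    n = len(model.model_features_)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    n_internal = 0
    for tree in model.forest_.trees:
        internal = np.nonzero(tree.children_left >= 0)[0]
        n_internal += len(internal)
        for node in internal:
            f = int(tree.feature[node])
            s = tree.value[tree.children_left[node]] - tree.value[tree.children_right[node]]
            sums[f] += s
            counts[f] += 1
    if n_internal == 0:
        raise ValueError("forest has no internal nodes; contributions undefined")
    raw = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return ContributionVector(raw=raw, scaled=_center_and_scale(raw), source="rf")


def process_negative_features(
    model_features: list[ModelFeature],
    contributions: ContributionVector,
    mode: str = "drop",
) -> tuple[list[tuple[int, ModelFeature]], list[PharmFeature]]:
    """Split model features by contribution sign.

    Returns (positive, xv): positive keeps (index, feature) pairs with
    non-negative scaled contribution; with ``mode="exclusion_volume"``
    each negative feature becomes an XV sphere at the same position
    (most-negative first), with ``mode="drop"`` negatives are discarded.
    """
    if mode not in ("drop", "exclusion_volume"):
        raise ValueError(f"unknown mode {mode!r}")
    positive = [
        (i, mf) for i, mf in enumerate(model_features) if contributions.scaled[i] >= 0
    ]
    xv: list[PharmFeature] = []
    if mode == "exclusion_volume":
        neg = [i for i in range(len(model_features)) if contributions.scaled[i] < 0]
        neg.sort(key=lambda i: (contributions.scaled[i], i))  # most negative first
        xv = [
            PharmFeature(FeatureType.XV, model_features[i].base.position, XV_RADIUS)
            for i in neg
        ]
    return positive, xv


def build_refined(model: QpharRegressor, cfg: RefinementConfig) -> Pharmacophore:
    """Assemble the refined query pharmacophore from a trained model.

    Ranking key = scaled contribution, multiplied by the feature's
    importance when ``cfg.weight_by_importance``.  The top
    ``cfg.num_features`` features with non-negative key are emitted
    (fewer, with a warning, if not enough); their weights are the
    normalized importances under weighting, else 1.0.  Exclusion
    volumes replace negative features when ``cfg.set_exclusion_volumes``.
    """
    model._check_fitted()
    contrib = (
        contributions_from_rf(model) if cfg.contribution_from_ml else contributions_from_model(model)
    )
    imp = feature_importances(model)
    key = contrib.scaled * imp if cfg.weight_by_importance else contrib.scaled.copy()

    mode = "exclusion_volume" if cfg.set_exclusion_volumes else "drop"
    # negativity is judged on the ranking key (importance never flips sign,
    # so this coincides with the contribution sign under weighting)
    kept = [i for i in range(len(model.model_features_)) if key[i] >= 0]
    if not kept:
        raise ValueError("model supports no positive query: every contribution is negative")
    kept.sort(key=lambda i: (-key[i], i))
    chosen = kept[: cfg.num_features]
    if len(chosen) < cfg.num_features:
        warnings.warn(
            f"only {len(chosen)} non-negative features available "
            f"(requested {cfg.num_features})",
            stacklevel=2,
        )

    if cfg.weight_by_importance:
        w = imp[chosen]
        total = w.sum()
        weights = w / total if total > 0 else np.ones(len(chosen))
    else:
        weights = np.ones(len(chosen))

    feats = [
        PharmFeature(
            model.model_features_[i].base.ftype,
            model.model_features_[i].base.position,
            model.model_features_[i].base.tolerance,
            float(wt),
        )
        for i, wt in zip(chosen, weights)
    ]
    if cfg.set_exclusion_volumes:
        _, xv = process_negative_features(model.model_features_, contrib, mode)
        feats.extend(xv)
    return Pharmacophore(name="refined", features=feats)


class PharmacophoreRefiner:
    """sklearn-style wrapper: fit extracts the refined query from a model.

    Parameters mirror :class:`RefinementConfig`.  After ``fit`` the
    query is available as ``refined_`` and ``transform(samples)``
    returns per-sample match flags.
    """

    def __init__(
        self,
        weight_by_importance: bool = False,
        set_exclusion_volumes: bool = False,
        contribution_from_ml: bool = False,
        num_features: int = 4,
    ):
        self.weight_by_importance = weight_by_importance
        self.set_exclusion_volumes = set_exclusion_volumes
        self.contribution_from_ml = contribution_from_ml
        self.num_features = num_features

    def get_params(self, deep: bool = True) -> dict:
        return {
            "weight_by_importance": self.weight_by_importance,
            "set_exclusion_volumes": self.set_exclusion_volumes,
            "contribution_from_ml": self.contribution_from_ml,
            "num_features": self.num_features,
        }

    def set_params(self, **params) -> "PharmacophoreRefiner":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, model: QpharRegressor, y=None) -> "PharmacophoreRefiner":
        self.config_ = RefinementConfig(**self.get_params())
        self.refined_ = build_refined(model, self.config_)
        return self

    def transform(self, samples: list[Sample]) -> np.ndarray:
        if not hasattr(self, "refined_"):
            raise ValueError("refiner is not fitted")
        return np.array(sm.screen(self.refined_, samples), dtype=bool)


# ---------------------------------------------------------------------------
# shared-pharmacophore baseline


def baseline_shared(train: list[Sample], n_actives: int) -> Pharmacophore:
    """Classical shared-feature baseline query.

    The ``n_actives`` most active ligands are aligned onto the most
    active one; the output keeps exactly those reference features that
    are present (same type, within the reference tolerance) in every
    contributing ligand.
    """
    if n_actives < 2:
        raise ValueError("n_actives must be >= 2")
    labelled = sorted(
        (s for s in train if s.activity is not None),
        key=lambda s: (-s.activity, s.ligand_id),
    )
    if len(labelled) < n_actives:
        raise ValueError(f"only {len(labelled)} labelled ligands for n_actives={n_actives}")
    chosen = labelled[:n_actives]
    reference = _reference_conformer(chosen[0])
    ref_query = Pharmacophore(name="sharedref", features=reference.non_xv())

    present = np.ones(len(ref_query.features), dtype=bool)
    for s in chosen[1:]:
        ci, aln = _best_conformer_by_alignment(ref_query, s)
        moved = transform_pharmacophore(s.conformers[ci], aln.rotation, aln.translation)
        mapping = map_features(ref_query, moved)
        hit = np.zeros(len(ref_query.features), dtype=bool)
        for _, i in mapping.items():
            hit[i] = True
        present &= hit

    feats = [f for f, p in zip(ref_query.features, present) if p]
    if not feats:
        warnings.warn("no feature is shared by all selected actives; empty baseline query", stacklevel=2)
    return Pharmacophore(name=f"shared-n{n_actives}", features=feats)


# ---------------------------------------------------------------------------
# hyperparameter search


def default_config_space() -> list[RefinementConfig]:
    """The full 2 x 2 x 2 x 5 = 40 refinement configuration grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            RefinementConfig(w, xv, ml, x)
            for w, xv, ml, x in itertools.product(
                [False, True], [False, True], [False, True], range(4, 9)
            )
        ]


def _score_query(
    query: Pharmacophore,
    samples: list[Sample],
    labels: list[bool],
    beta: float,
) -> dict[str, float]:
    if not query.non_xv():
        counts = sm.ConfusionCounts(0, 0, sum(1 for l in labels if not l), sum(1 for l in labels if l))
    else:
        flags = sm.screen(query, samples)
        counts = sm.confusion(flags, labels)
    fb = sm.f_beta(counts, beta)
    fs = sm.f_specificity(counts)
    return {"f_beta": fb, "f_specificity": fs, "f_composite": sm.f_composite(fb, fs)}


def grid_search(
    train: list[Sample],
    test: list[Sample],
    model: QpharRegressor,
    config_space: list[RefinementConfig] | None = None,
    percentile: float = 20.0,
    beta: float = 0.5,
    top_k: int = 5,
) -> pd.DataFrame:
    """Exhaustive refinement-hyperparameter search with top-k validation.

    Every configuration's query is scored on the training set (actives
    = top activity percentile); rows are ranked by F_beta +
    F_Specificity descending (ties by enumeration order) and exactly
    the ``top_k`` best are additionally scored on the test set.
    Returns the full audit table, one row per configuration.
    """
    if config_space is None:
        config_space = default_config_space()
    if not config_space:
        raise ValueError("empty configuration space")
    train_labels = sm.label_actives(train, percentile)
    test_labels = sm.label_actives(test, percentile)

    rows = []
    for order_idx, cfg in enumerate(config_space):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                query = build_refined(model, cfg)
            except ValueError:
                query = Pharmacophore(name="empty", features=[])
        tr = _score_query(query, train, train_labels, beta)
        rows.append(
            {
                "order": order_idx,
                **asdict(cfg),
                "n_query_features": len(query.non_xv()),
                "n_query_xv": len(query.xv()),
                "f_beta_train": tr["f_beta"],
                "f_spec_train": tr["f_specificity"],
                "f_composite_train": tr["f_composite"],
                "f_beta_test": np.nan,
                "f_spec_test": np.nan,
                "f_composite_test": np.nan,
                "_query": query,
            }
        )

    rows.sort(key=lambda r: (-(r["f_beta_train"] + r["f_spec_train"]), r["order"]))
    for rank, row in enumerate(rows):
        row["rank_train"] = rank + 1
        if rank < top_k:
            te = _score_query(row["_query"], test, test_labels, beta)
            row["f_beta_test"] = te["f_beta"]
            row["f_spec_test"] = te["f_specificity"]
            row["f_composite_test"] = te["f_composite"]

    df = pd.DataFrame(rows)
    queries = df.pop("_query")
    df.attrs["queries"] = {int(r): q for r, q in zip(df["order"], queries)}
    return df


def baseline_search(
    train: list[Sample],
    test: list[Sample],
    n_range: range | None = None,
    percentile: float = 20.0,
    beta: float = 0.5,
) -> pd.DataFrame:
    """Sweep the shared-baseline hyperparameter n_actives (default 2..min(8, #actives))."""
    labelled = [s for s in train if s.activity is not None]
    n_act = sum(sm.label_actives(train, percentile))
    if n_range is None:
        n_range = range(2, min(8, max(2, n_act)) + 1)
    train_labels = sm.label_actives(train, percentile)
    test_labels = sm.label_actives(test, percentile)
    rows = []
    for n in n_range:
        if n > len(labelled):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            query = baseline_shared(train, n)
        tr = _score_query(query, train, train_labels, beta)
        te = _score_query(query, test, test_labels, beta)
        rows.append(
            {
                "n_actives": n,
                "n_query_features": len(query.features),
                "f_beta_train": tr["f_beta"],
                "f_spec_train": tr["f_specificity"],
                "f_composite_train": tr["f_composite"],
                "f_beta_test": te["f_beta"],
                "f_spec_test": te["f_specificity"],
                "f_composite_test": te["f_composite"],
                "_query": query,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        by=["f_composite_train", "n_actives"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    queries = df.pop("_query")
    df.attrs["queries"] = {int(n): q for n, q in zip(df["n_actives"], queries)}
    return df
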