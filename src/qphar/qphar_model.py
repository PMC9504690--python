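"""Quantitative pharmacophore activity relationship (QPhAR) regression model.

The model pharmacophore is assembled by aligning every training ligand
onto the most active one and merging same-type features within a merge
radius; each merged model feature keeps the list of activities of the
ligands that contributed to it.  A sample is featurized as the vector of
Euclidean distances between each model feature and its mapped sample
feature (a large fill constant marks unmatched features), and a random
forest regresses activity (pIC50/pKi) on these distance vectors.

Tree internals are first-class here: node arrays (split feature,
threshold, children, node value) are extracted from the fitted forest so
that predictions are reproduced by our own traversal — inputs at or
below the threshold go to the left child, above it to the right — which
makes serialized model bundles bit-reproducible and lets the refinement
module read signed feature contributions straight off the tree
structure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score

from .pharm_core import (
    Alignment,
    FeatureType,
    PharmFeature,
    Pharmacophore,
    Sample,
    align,
    default_tolerance,
    map_features,
    transform_pharmacophore,
)

__all__ = [
    "ModelFeature",
    "TreeArrays",
    "RegressionForest",
    "QpharRegressor",
    "build_model_pharmacophore",
    "fit",
    "featurize",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]

DEFAULT_FILL_DISTANCE = 100.0  # Angstrom; far beyond any matchable distance
DEFAULT_MERGE_RADIUS = 1.5  # Angstrom


@dataclass
class ModelFeature:
    """A merged model feature and the activities of its contributing ligands."""

    base: PharmFeature
    activities: list[float] = field(default_factory=list)
    _positions: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def ftype(self) -> FeatureType:
        return self.base.ftype


@dataclass
class TreeArrays:
    """Explicit node arrays of one regression tree.

    ``children_left[n] == -1`` marks a leaf.  ``value[n]`` is the mean
    training target in node ``n``.  Traversal sends inputs with
    ``x[feature[n]] <= threshold[n]`` to the left child.
    """

    feature: np.ndarray
    threshold: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    value: np.ndarray

    def predict(self, X32: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X32), dtype=np.int64)
        active = self.children_left[node] >= 0
        while np.any(active):
            idx = np.nonzero(active)[0]
            n = node[idx]
            go_left = X32[idx, self.feature[n]] <= self.threshold[n].astype(np.float32)
            node[idx] = np.where(go_left, self.children_left[n], self.children_right[n])
            active = self.children_left[node] >= 0
        return self.value[node]

    @property
    def n_internal(self) -> int:
        return int(np.sum(self.children_left >= 0))


@dataclass
class RegressionForest:
    """A forest as explicit node arrays; prediction = mean over trees."""

    trees: list[TreeArrays]
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        # scikit-learn casts inputs to float32 before threshold comparison;
        # doing the same keeps our traversal bit-identical to the library.
        X32 = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float32)
        out = np.zeros(len(X32))
        for t in self.trees:
            out += t.predict(X32)
        return out / len(self.trees)

    @classmethod
    def from_sklearn(cls, rf: RandomForestRegressor) -> "RegressionForest":
        trees = []
        for est in rf.estimators_:
            t = est.tree_
            trees.append(
                TreeArrays(
                    feature=t.feature.copy(),
                    threshold=t.threshold.copy(),
                    children_left=t.children_left.copy(),
                    children_right=t.children_right.copy(),
                    value=t.value[:, 0, 0].copy(),
                )
            )
        return cls(trees=trees, n_features=rf.n_features_in_)

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.children_left.tolist(),
                    "right": t.children_right.tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionForest":
        trees = [
            TreeArrays(
                feature=np.asarray(td["feature"], dtype=np.int64),
                threshold=np.asarray(td["threshold"], dtype=np.float64),
                children_left=np.asarray(td["left"], dtype=np.int64),
                children_right=np.asarray(td["right"], dtype=np.int64),
                value=np.asarray(td["value"], dtype=np.float64),
            )
            for td in d["trees"]
        ]
        return cls(trees=trees, n_features=int(d["n_features"]))


# ---------------------------------------------------------------------------
# model pharmacophore construction


def _best_conformer_by_alignment(ref: Pharmacophore, sample: Sample) -> tuple[int, Alignment]:
    """Conformer with highest n_mapped, then lowest rmsd, then lowest index."""
    best: tuple[int, float, int, Alignment] | None = None
    for ci, conf in enumerate(sample.conformers):
        a = align(ref, conf)
        key = (-a.n_mapped, a.rmsd, ci)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (a.n_mapped, a.rmsd, ci, a)
    assert best is not None
    return best[2], best[3]


def _reference_conformer(sample: Sample) -> Pharmacophore:
    """Most informative conformer: most non-XV features, ties by index."""
    best = max(range(len(sample.conformers)), key=lambda i: (len(sample.conformers[i].non_xv()), -i))
    return sample.conformers[best]


def build_model_pharmacophore(
    train: list[Sample],
    merge_radius: float = DEFAULT_MERGE_RADIUS,
    min_support_fraction: float = 0.1,
) -> tuple[list[ModelFeature], Pharmacophore]:
    """Merge aligned training-ligand features into model features.

    The most active ligand's reference conformer defines the frame;
    every other ligand's best-aligned conformer is transformed into it
    and its features greedily merged into same-type clusters within
    ``merge_radius`` of the running centroid.  Every ligand that
    contributes a feature to a cluster adds its activity to that model
    feature's activity list.

    A relevance filter then discards clusters supported by fewer than
    ``ceil(min_support_fraction * n_ligands)`` contributions: a feature
    seen in a single ligand carries no consensus information and only
    adds noise columns to the regression.
    """
    return _build_model_pharmacophore_impl(train, merge_radius, min_support_fraction)


def _cluster_pass(
    ligands_in_frame: list[tuple[Pharmacophore, float]],
    merge_radius: float,
    seed_features: list[PharmFeature] | None = None,
) -> list[ModelFeature]:
    """One greedy centroid-clustering pass over pre-aligned ligands."""
    clusters: list[ModelFeature] = []
    if seed_features:
        clusters = [
            ModelFeature(
                base=PharmFeature(f.ftype, f.position, f.tolerance), activities=[], _positions=[]
            )
            for f in seed_features
        ]

    def _add(feat: PharmFeature, activity: float) -> None:
        if feat.ftype == FeatureType.XV:
            return
        pos = feat.xyz
        best_i, best_d = -1, float("inf")
        for i, mf in enumerate(clusters):
            if mf.ftype != feat.ftype:
                continue
            d = float(np.linalg.norm(mf.base.xyz - pos))
            if d <= merge_radius and d < best_d:
                best_i, best_d = i, d
        if best_i < 0:
            clusters.append(
                ModelFeature(
                    base=PharmFeature(feat.ftype, tuple(pos), default_tolerance(feat.ftype)),
                    activities=[activity],
                    _positions=[pos],
                )
            )
        else:
            mf = clusters[best_i]
            mf._positions.append(pos)
            mf.activities.append(activity)
            centroid = np.mean(mf._positions, axis=0)  # activity-unweighted centroid
            mf.base = PharmFeature(mf.ftype, tuple(centroid), mf.base.tolerance)

    for conf, activity in ligands_in_frame:
        for f in conf.non_xv():
            _add(f, activity)

    # consolidation: greedy seeding can split one site into two clusters when
    # early members sit on opposite sides of it; merge closest same-type
    # centroid pairs until all pairs are farther than merge_radius apart
    while True:
        best_pair, best_d = None, merge_radius
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i].ftype != clusters[j].ftype:
                    continue
                d = float(np.linalg.norm(clusters[i].base.xyz - clusters[j].base.xyz))
                if d <= best_d:
                    best_pair, best_d = (i, j), d
        if best_pair is None:
            break
        i, j = best_pair
        a, b = clusters[i], clusters[j]
        a._positions.extend(b._positions)
        a.activities.extend(b.activities)
        if a._positions:
            centroid = np.mean(a._positions, axis=0)
            a.base = PharmFeature(a.ftype, tuple(centroid), a.base.tolerance)
        del clusters[j]
    return [mf for mf in clusters if mf.activities]


def _build_model_pharmacophore_impl(
    train: list[Sample], merge_radius: float, min_support_fraction: float
) -> tuple[list[ModelFeature], Pharmacophore]:
    if not train:
        raise ValueError("empty training set")
    labelled = [s for s in train if s.activity is not None]
    if len(labelled) < 2:
        raise ValueError("need >= 2 training samples with activities")
    acts = [s.activity for s in labelled]
    if max(acts) - min(acts) < 3.0:
        warnings.warn(
            "activity range is below 3 log units; the model may be fitting experimental noise",
            stacklevel=2,
        )

    order = sorted(labelled, key=lambda s: (-s.activity, s.ligand_id))
    ref_ligand = order[0]
    reference = _reference_conformer(ref_ligand)
    min_support = max(1, int(np.ceil(min_support_fraction * len(labelled))))

    # pass 1: anchor on the most active ligand.  Ligands sharing few
    # features with that single conformer align poorly, so the pass-1
    # clusters only rough out the site map.
    in_frame: list[tuple[Pharmacophore, float]] = [(reference, ref_ligand.activity)]
    for s in order[1:]:
        ci, aln = _best_conformer_by_alignment(reference, s)
        in_frame.append(
            (transform_pharmacophore(s.conformers[ci], aln.rotation, aln.translation), s.activity)
        )
    clusters = _cluster_pass(in_frame, merge_radius)
    clusters = [mf for mf in clusters if len(mf.activities) >= min_support]
    if not clusters:
        raise ValueError("no model feature passed the relevance filter")

    # pass 2: re-align every ligand to the merged pass-1 pharmacophore,
    # which spans all recovered sites and therefore anchors low-overlap
    # ligands far better than any single conformer can; the final
    # clusters and activity lists come from this pass.
    anchor = Pharmacophore(name="pass1", features=[mf.base for mf in clusters])
    in_frame2: list[tuple[Pharmacophore, float]] = []
    for s in order:
        ci, aln = _best_conformer_by_alignment(anchor, s)
        in_frame2.append(
            (transform_pharmacophore(s.conformers[ci], aln.rotation, aln.translation), s.activity)
        )
    clusters2 = _cluster_pass(in_frame2, merge_radius, seed_features=[mf.base for mf in clusters])
    clusters2 = [mf for mf in clusters2 if len(mf.activities) >= min_support]
    if not clusters2:
        raise ValueError("no model feature passed the relevance filter")

    return clusters2, Pharmacophore(
        name=f"ref:{ref_ligand.ligand_id}", features=list(reference.features)
    )


# ---------------------------------------------------------------------------
# the estimator


class QpharRegressor(BaseEstimator, RegressorMixin):
    """Random-forest QPhAR regressor over pharmacophore distance vectors.

    Parameters
    ----------
    merge_radius : float
        Same-type features of aligned training ligands closer than this
        (Angstrom) merge into one model feature.
    fill_distance : float
        Distance assigned to model features with no mapped sample
        feature; must exceed any matchable distance so that "larger
        distance" consistently means "feature absent".
    n_estimators, max_depth : forest size/shape, passed to scikit-learn.
    random_state : int
        Mandatory seed; training is refused without one.

    Attributes
    ----------
    model_features_ : list[ModelFeature]
    reference_frame_ : Pharmacophore
        Alignment reference (the most active ligand's conformer).
    forest_ : RegressionForest
        Extracted node arrays; all predictions go through it.
    importances_ : ndarray
        Impurity-based feature importances from the fitted forest.
    """

    def __init__(
        self,
        merge_radius: float = DEFAULT_MERGE_RADIUS,
        min_support_fraction: float = 0.1,
        fill_distance: float = DEFAULT_FILL_DISTANCE,
        n_estimators: int = 100,
        max_depth: int | None = None,
        random_state: int | None = None,
    ):
        self.merge_radius = merge_radius
        self.min_support_fraction = min_support_fraction
        self.fill_distance = fill_distance
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    # -- core API ----------------------------------------------------------

    def fit(self, samples: list[Sample], y=None) -> "QpharRegressor":
        if self.random_state is None:
            raise ValueError("random_state is mandatory for reproducible training")
        if y is not None:
            samples = [
                Sample(s.ligand_id, s.conformers, a) for s, a in zip(samples, y)
            ]
        labelled = [s for s in samples if s.activity is not None]
        targets = np.array([s.activity for s in labelled])
        if len(labelled) and np.ptp(targets) == 0:
            raise ValueError(
                "all training activities are identical; refusing to model noise"
            )
        self.model_features_, self.reference_frame_ = build_model_pharmacophore(
            labelled, self.merge_radius, self.min_support_fraction
        )
        self._model_pharm_ = Pharmacophore(
            name="model", features=[mf.base for mf in self.model_features_]
        )
        X = np.array([self._featurize_one(s) for s in labelled])
        rf = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            bootstrap=True,
            random_state=self.random_state,
        )
        rf.fit(X, targets)
        self.sklearn_forest_ = rf
        self.forest_ = RegressionForest.from_sklearn(rf)
        self.importances_ = rf.feature_importances_.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def _featurize_one(self, sample: Sample) -> np.ndarray:
        # align to the merged model pharmacophore: it spans every recovered
        # site, so low-overlap samples anchor far better than against the
        # single reference conformer
        ci, aln = _best_conformer_by_alignment(self._model_pharm_, sample)
        moved = transform_pharmacophore(sample.conformers[ci], aln.rotation, aln.translation)
        return self.distances_for_conformer(moved)

    def distances_for_conformer(self, conf_in_frame: Pharmacophore) -> np.ndarray:
        """Distance vector for a conformer already in the reference frame."""
        mapping = map_features(self._model_pharm_, conf_in_frame)
        vec = np.full(len(self.model_features_), float(self.fill_distance))
        mpos = self._model_pharm_.coords()
        cpos = conf_in_frame.coords()
        for a, i in mapping.items():
            vec[i] = float(np.linalg.norm(cpos[a] - mpos[i]))
        return vec

    def featurize(self, sample: Sample) -> np.ndarray:
        """Distance vector of the best-aligned conformer of ``sample``."""
        self._check_fitted()
        if not sample.conformers:
            raise ValueError("sample has no conformers")
        return self._featurize_one(sample)

    def aligned_best_conformer(self, sample: Sample) -> tuple[Pharmacophore, int]:
        """Best conformer rigidly placed in the model frame."""
        self._check_fitted()
        ci, aln = _best_conformer_by_alignment(self._model_pharm_, sample)
        return transform_pharmacophore(sample.conformers[ci], aln.rotation, aln.translation), ci

    def predict(self, samples) -> np.ndarray:
        self._check_fitted()
        if isinstance(samples, Sample):
            samples = [samples]
        X = np.array([self.featurize(s) for s in samples])
        return self.forest_.predict(X)

    def predict_distances(self, X: np.ndarray) -> np.ndarray:
        """Predict straight from distance vectors (grid profiling fast path)."""
        self._check_fitted()
        return self.forest_.predict(np.atleast_2d(X))

    def score_report(self, samples: list[Sample]) -> dict[str, float]:
        """R² and RMSE on labelled samples (activity units)."""
        self._check_fitted()
        labelled = [s for s in samples if s.activity is not None]
        if len(labelled) < 2:
            raise ValueError("need >= 2 labelled samples to evaluate")
        y = np.array([s.activity for s in labelled])
        yhat = self.predict(labelled)
        return {
            "r2": float(r2_score(y, yhat)),
            "rmse": float(np.sqrt(mean_squared_error(y, yhat))),
        }

    def _check_fitted(self) -> None:
        if not hasattr(self, "forest_"):
            raise ValueError("model is not fitted; call fit() first")

    # -- serialization -----------------------------------------------------

    def save(self, bundle_dir) -> None:
        """Write model_features.json, forest.json, config.json."""
        self._check_fitted()
        d = Path(bundle_dir)
        d.mkdir(parents=True, exist_ok=True)
        (d / "model_features.json").write_text(
            json.dumps(
                {
                    "reference_frame": self.reference_frame_.to_dict(),
                    "features": [
                        {
                            "type": mf.ftype.value,
                            "xyz": list(mf.base.position),
                            "tolerance": mf.base.tolerance,
                            "activities": mf.activities,
                        }
                        for mf in self.model_features_
                    ],
                },
                indent=2,
            )
        )
        (d / "forest.json").write_text(
            json.dumps(
                {"forest": self.forest_.to_dict(), "importances": self.importances_.tolist()}
            )
        )
        (d / "config.json").write_text(json.dumps(self.get_params(), indent=2) + "\n")

    @classmethod
    def load(cls, bundle_dir) -> "QpharRegressor":
        d = Path(bundle_dir)
        cfg = json.loads((d / "config.json").read_text())
        est = cls(**cfg)
        mf = json.loads((d / "model_features.json").read_text())
        est.reference_frame_ = Pharmacophore.from_dict(mf["reference_frame"])
        est.model_features_ = [
            ModelFeature(
                base=PharmFeature(rec["type"], tuple(rec["xyz"]), rec["tolerance"]),
                activities=list(rec["activities"]),
            )
            for rec in mf["features"]
        ]
        est._model_pharm_ = Pharmacophore(
            name="model", features=[m.base for m in est.model_features_]
        )
        fj = json.loads((d / "forest.json").read_text())
        est.forest_ = RegressionForest.from_dict(fj["forest"])
        est.importances_ = np.asarray(fj["importances"])
        est.n_features_in_ = est.forest_.n_features
        return est


# ---------------------------------------------------------------------------
# functional wrappers


def fit(
    train: list[Sample],
    rf_config: dict | None = None,
    seed: int | None = None,
) -> QpharRegressor:
    cfg = dict(rf_config or {})
    if seed is not None:
        cfg["random_state"] = seed
    return QpharRegressor(**cfg).fit(train)


def featurize(model: QpharRegressor, sample: Sample) -> np.ndarray:
    return model.featurize(sample)


def predict(model: QpharRegressor, sample: Sample) -> float:
    return float(model.predict([sample])[0])


def evaluate(model: QpharRegressor, test: list[Sample]) -> dict[str, float]:
    return model.score_report(test)


def save_model(model: QpharRegressor, bundle_dir) -> None:
    model.save(bundle_dir)


def load_model(bundle_dir) -> QpharRegressor:
    return QpharRegressor.load(bundle_dir)
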