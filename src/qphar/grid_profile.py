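"""3D activity profiling: favourable/unfavourable regions per feature type.

A trained QPhAR model predicts a continuous activity for any
pharmacophore.  Sweeping a hypothetical probe feature of one type over
a regular lattice around an aligned ligand and recording the change in
predicted activity relative to the unperturbed baseline yields an
activity grid: positive regions mark places where introducing a feature
of that type is expected to raise activity, negative regions where it
would lower it.  Grids are split into positive/negative fields,
optionally normalised to a unit maximum, and written as plain-text
``.kont`` files (coordinate block, title line, value block) for
visualisation alongside the ligand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pharm_core import (
    FeatureType,
    PharmFeature,
    Pharmacophore,
    Sample,
    default_tolerance,
)
from .qphar_model import QpharRegressor

__all__ = [
    "GridSpec",
    "ActivityGrid",
    "make_grid",
    "activity_grid",
    "split_and_normalize",
    "write_kont",
    "read_kont",
]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular lattice: origin, spacing (Angstrom), dims."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """Lattice points in x-fastest order, shape (n_points, 3)."""
        nx, ny, nz = self.dims
        o = np.asarray(self.origin)
        ix = np.arange(nx) * self.spacing + o[0]
        iy = np.arange(ny) * self.spacing + o[1]
        iz = np.arange(nz) * self.spacing + o[2]
        Z, Y, X = np.meshgrid(iz, iy, ix, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


@dataclass
class ActivityGrid:
    """Per-point activity deltas for one probe type.

    ``sign`` is "raw" for the signed delta field, "positive"/"negative"
    for the split fields (both store non-negative magnitudes).
    """

    spec: GridSpec
    ftype: FeatureType
    values: np.ndarray  # flat, x-fastest order
    sign: str = "raw"
    normalised: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != self.spec.n_points:
            raise ValueError("value count does not match lattice size")
        if self.sign not in ("raw", "positive", "negative"):
            raise ValueError(f"bad sign {self.sign!r}")


def make_grid(sample: Pharmacophore, spacing: float = 0.5, margin: float = 3.0) -> GridSpec:
    """Lattice covering the sample's bounding box plus a margin.

    dims = ceil((extent + 2*margin) / spacing) + 1 per axis, so even a
    point-like sample gets at least two lattice points per axis when
    margin > 0.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not sample.features:
        raise ValueError("sample pharmacophore is empty")
    coords = sample.coords()
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(math.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(float(x) for x in lo), spacing=float(spacing), dims=dims)


def activity_grid(
    model: QpharRegressor,
    sample: Sample,
    ftype: FeatureType,
    spec: GridSpec | None = None,
    spacing: float = 0.5,
    margin: float = 3.0,
) -> ActivityGrid:
    """Probe the model with a typed feature at every lattice point.

    The sample's best conformer is aligned to the model once; the probe
    is then appended at each lattice point without re-alignment (the
    probe's effect must not be conflated with a pose change) and the
    prediction difference to the unperturbed baseline recorded.  Points
    where the probe cannot map to any same-type model feature leave the
    distance vector unchanged and get a delta of exactly 0.
    """
    ftype = FeatureType(ftype)
    if ftype == FeatureType.XV:
        raise ValueError("exclusion volumes cannot be used as probes")
    model._check_fitted()
    aligned, _ = model.aligned_best_conformer(sample)
    if spec is None:
        spec = make_grid(aligned, spacing=spacing, margin=margin)

    base_vec = model.distances_for_conformer(aligned)
    baseline = float(model.predict_distances(base_vec)[0])

    pts = spec.points()
    tol = default_tolerance(ftype)
    same_type = [
        (i, mf.base.xyz, mf.base.tolerance)
        for i, mf in enumerate(model.model_features_)
        if mf.ftype == ftype
    ]
    deltas = np.zeros(len(pts))
    if not same_type:
        return ActivityGrid(spec=spec, ftype=ftype, values=deltas, sign="raw")

    centers = np.stack([c for _, c, _ in same_type])
    tols = np.array([t for _, _, t in same_type])
    # a probe farther than every same-type tolerance cannot change the
    # mapping; skip those points outright (delta exactly 0)
    reach = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=-1) <= tols[None, :]
    candidates = np.nonzero(reach.any(axis=1))[0]

    if len(candidates):
        vecs = np.empty((len(candidates), len(base_vec)))
        for row, pi in enumerate(candidates):
            probe = PharmFeature(ftype, tuple(pts[pi]), tol)
            augmented = Pharmacophore(
                name="probe", features=list(aligned.features) + [probe]
            )
            vecs[row] = model.distances_for_conformer(augmented)
        preds = model.predict_distances(vecs)
        deltas[candidates] = preds - baseline

    return ActivityGrid(spec=spec, ftype=ftype, values=deltas, sign="raw")


def split_and_normalize(
    grid: ActivityGrid, normalise: bool = False
) -> tuple[ActivityGrid, ActivityGrid]:
    """Split a raw delta grid into positive and negative magnitude fields.

    positive - negative = raw, pointwise.  With ``normalise`` each
    field is divided by its own maximum (all-zero fields stay zero).
    """
    if grid.sign != "raw":
        raise ValueError("can only split a raw grid")
    pos = np.maximum(grid.values, 0.0)
    neg = np.maximum(-grid.values, 0.0)
    if normalise:
        if pos.max() > 0:
            pos = pos / pos.max()
        if neg.max() > 0:
            neg = neg / neg.max()
    return (
        ActivityGrid(grid.spec, grid.ftype, pos, sign="positive", normalised=normalise),
        ActivityGrid(grid.spec, grid.ftype, neg, sign="negative", normalised=normalise),
    )


# ---------------------------------------------------------------------------
# .kont I/O — plain-text dialect: one fixed-width coordinate record per
# lattice point (index, x, y, z), a single title line, then one value per
# line in the same x-fastest point order.


def write_kont(grid: ActivityGrid, path, field_name: str) -> None:
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("grid contains non-finite values")
    pts = grid.spec.points()
    lines = []
    for i, (x, y, z) in enumerate(pts, start=1):
        lines.append(f"{i:8d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(str(field_name))
    for v in grid.values:
        lines.append(f"{v:10.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_kont(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a .kont file back: (points (n,3), values (n,), field name)."""
    lines = Path(path).read_text().splitlines()
    pts: list[list[float]] = []
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 4:
            try:
                pts.append([float(parts[1]), float(parts[2]), float(parts[3])])
                continue
            except ValueError:
                break
        break
    title = lines[i].strip()
    values = np.array([float(l) for l in lines[i + 1 :] if l.strip()])
    if len(values) != len(pts):
        raise ValueError(f"{path}: {len(pts)} coordinates but {len(values)} values")
    return np.asarray(pts), values, title
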