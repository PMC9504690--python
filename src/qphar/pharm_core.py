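"""Pharmacophore data model, rigid alignment, feature mapping and I/O.

A pharmacophore is an abstract 3D arrangement of typed interaction
features (aromatic, hydrophobic, H-bond donor/acceptor, positive/negative
ionizable) plus optional exclusion-volume spheres marking sterically
forbidden space.  This module provides the geometric substrate used by
the QPhAR regression model, the refinement algorithm, screening and the
activity-grid profiler: feature containers, a deterministic rigid
alignment based on correspondence seeding and Kabsch superposition,
greedy type-restricted feature mapping, query matching with exclusion
volumes, and a versioned JSON serialization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SCHEMA = "qphar-pharm/1"

__all__ = [
    "FeatureType",
    "PharmFeature",
    "Pharmacophore",
    "Sample",
    "Alignment",
    "MatchResult",
    "DEFAULT_TOLERANCES",
    "default_tolerance",
    "align",
    "map_features",
    "matches_query",
    "read_pharmacophore",
    "write_pharmacophore",
    "read_samples",
    "write_samples",
    "transform_pharmacophore",
]


class FeatureType(str, Enum):
    """The six pharmacophore probe types plus exclusion volume (XV)."""

    AR = "AR"    # aromatic
    H = "H"      # hydrophobic
    HBA = "HBA"  # H-bond acceptor
    HBD = "HBD"  # H-bond donor
    PI = "PI"    # positive ionizable
    NI = "NI"    # negative ionizable
    XV = "XV"    # exclusion volume (never a probe or regression feature)


#: Conventional ligand-based default tolerance radii in Angstrom.
DEFAULT_TOLERANCES: dict[FeatureType, float] = {
    FeatureType.AR: 1.8,
    FeatureType.H: 1.5,
    FeatureType.HBA: 1.5,
    FeatureType.HBD: 1.5,
    FeatureType.PI: 1.5,
    FeatureType.NI: 1.5,
    FeatureType.XV: 1.5,
}


def default_tolerance(ftype: FeatureType) -> float:
    return DEFAULT_TOLERANCES[FeatureType(ftype)]


@dataclass(frozen=True)
class PharmFeature:
    """A single typed spherical feature: center, tolerance radius, weight."""

    ftype: FeatureType
    position: tuple[float, float, float]
    tolerance: float = 0.0  # 0 sentinel -> type default, resolved in __post_init__
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "ftype", FeatureType(self.ftype))
        pos = tuple(float(x) for x in self.position)
        if len(pos) != 3 or not all(math.isfinite(x) for x in pos):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        tol = float(self.tolerance) if self.tolerance else default_tolerance(self.ftype)
        if tol <= 0:
            raise ValueError("tolerance must be > 0")
        object.__setattr__(self, "tolerance", tol)
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        object.__setattr__(self, "weight", float(self.weight))

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Pharmacophore:
    """A named, ordered set of pharmacophore features."""

    name: str = ""
    features: list[PharmFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def coords(self) -> np.ndarray:
        if not self.features:
            return np.zeros((0, 3))
        return np.array([f.position for f in self.features], dtype=float)

    def non_xv(self) -> list[PharmFeature]:
        return [f for f in self.features if f.ftype != FeatureType.XV]

    def xv(self) -> list[PharmFeature]:
        return [f for f in self.features if f.ftype == FeatureType.XV]

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA,
            "name": self.name,
            "features": [
                {
                    "type": f.ftype.value,
                    "xyz": list(f.position),
                    "tolerance": f.tolerance,
                    "weight": f.weight,
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pharmacophore":
        feats = []
        for i, rec in enumerate(d.get("features", [])):
            try:
                ftype = FeatureType(rec["type"])
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"feature record {i}: unknown or missing feature code {rec.get('type')!r}"
                ) from exc
            feats.append(
                PharmFeature(
                    ftype=ftype,
                    position=tuple(rec["xyz"]),
                    tolerance=float(rec.get("tolerance", 0.0)),
                    weight=float(rec.get("weight", 1.0)),
                )
            )
        return cls(name=d.get("name", ""), features=feats)


@dataclass
class Sample:
    """A ligand: one or more conformer pharmacophores plus an optional activity.

    Activities live on the pIC50/pKi scale (-log10 of molar IC50/Ki);
    library entries may carry ``activity=None``.
    """

    ligand_id: str
    conformers: list[Pharmacophore]
    activity: float | None = None

    def __post_init__(self):
        if not self.conformers:
            raise ValueError(f"sample {self.ligand_id!r} has no conformers")
        if self.activity is not None:
            self.activity = float(self.activity)
            if not math.isfinite(self.activity):
                raise ValueError(f"sample {self.ligand_id!r}: activity must be finite")

    def to_dict(self) -> dict:
        return {
            "ligand_id": self.ligand_id,
            "activity": self.activity,
            "conformers": [c.to_dict() for c in self.conformers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sample":
        return cls(
            ligand_id=d["ligand_id"],
            activity=d.get("activity"),
            conformers=[Pharmacophore.from_dict(c) for c in d["conformers"]],
        )


@dataclass
class Alignment:
    """A rigid superposition of a moving pharmacophore onto a reference.

    ``mapping`` sends moving-feature index -> reference-feature index
    (partial, injective, type-preserving).  ``rmsd`` is over mapped pairs.
    """

    rotation: np.ndarray
    translation: np.ndarray
    mapping: dict[int, int]
    rmsd: float
    n_mapped: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class MatchResult:
    matched: bool
    conformer_index: int | None = None
    rmsd: float | None = None


def identity_alignment() -> Alignment:
    return Alignment(np.eye(3), np.zeros(3), {}, 0.0, 0)


# ---------------------------------------------------------------------------
# rigid superposition


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimising ||R P + t - Q||."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _kabsch_batch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Kabsch: P, Q of shape (S, k, 3); returns (S,3,3), (S,3)."""
    pc = P.mean(axis=1, keepdims=True)
    qc = Q.mean(axis=1, keepdims=True)
    H = np.einsum("ski,skj->sij", P - pc, Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("sij,sjk->sik", Vt.transpose(0, 2, 1), U.transpose(0, 2, 1))))
    d[d == 0] = 1.0
    D = np.zeros((len(P), 3, 3))
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("sij,sjk,skl->sil", Vt.transpose(0, 2, 1), D, U.transpose(0, 2, 1))
    t = qc[:, 0, :] - np.einsum("sij,sj->si", R, pc[:, 0, :])
    return R, t


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation sending unit-ish vector a onto b."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return np.eye(3)
    a = a / na
    b = b / nb
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


# ---------------------------------------------------------------------------
# greedy type-restricted mapping


def _greedy_map(
    ref_pos: np.ndarray,
    ref_types: Sequence[FeatureType],
    ref_tol: np.ndarray,
    mov_pos: np.ndarray,
    mov_types: Sequence[FeatureType],
) -> dict[int, int]:
    """Greedy nearest-neighbour mapping mov->ref, same type, dist <= ref tol.

    Ties broken by ascending (distance, moving index, reference index);
    each feature on either side is used at most once.
    """
    cands: list[tuple[float, int, int]] = []
    for a in range(len(mov_pos)):
        for i in range(len(ref_pos)):
            if mov_types[a] != ref_types[i]:
                continue
            d = float(np.linalg.norm(mov_pos[a] - ref_pos[i]))
            if d <= ref_tol[i]:
                cands.append((d, a, i))
    cands.sort()
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    for d, a, i in cands:
        if a in mapping or i in used_ref:
            continue
        mapping[a] = i
        used_ref.add(i)
    return mapping


def map_features(ref: Pharmacophore, mov_aligned: Pharmacophore) -> dict[int, int]:
    """Map features of ``mov_aligned`` (already in the reference frame) onto ``ref``.

    Returns a partial injective dict moving-index -> reference-index,
    restricted to identical feature types and center distance no larger
    than the reference feature's tolerance.
    """
    ref_f, mov_f = ref.features, mov_aligned.features
    return _greedy_map(
        ref.coords(),
        [f.ftype for f in ref_f],
        np.array([f.tolerance for f in ref_f]) if ref_f else np.zeros(0),
        mov_aligned.coords(),
        [f.ftype for f in mov_f],
    )


# ---------------------------------------------------------------------------
# alignment search

_MAX_SEED_EVALS = 64   # greedy-evaluated Kabsch seeds per align call (documented bound)
_MAX_SEEDS = 4096      # raw correspondence triplets considered
_N_REFINE = 8          # best preliminary candidates given a rigid re-fit


def _greedy_from_mask(dist: np.ndarray, ok: np.ndarray) -> tuple[dict[int, int], float]:
    """Greedy injective assignment from a (n_mov, n_ref) admissibility mask.

    Candidates sorted by ascending (distance, moving index, reference
    index).  Returns the mapping and its RMSD (0.0 when empty).
    """
    cand = np.argwhere(ok)
    if not len(cand):
        return {}, 0.0
    d = dist[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], d))
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    sq = 0.0
    for s in order:
        a, i = int(cand[s, 0]), int(cand[s, 1])
        if a in mapping or i in used_ref:
            continue
        mapping[a] = i
        used_ref.add(i)
        sq += float(d[s]) ** 2
    if not mapping:
        return {}, 0.0
    return mapping, math.sqrt(sq / len(mapping))


def align(ref: Pharmacophore, mov: Pharmacophore, tol_scale: float = 1.0) -> Alignment:
    """Best rigid superposition of ``mov`` onto ``ref`` (XV features ignored).

    Correspondence search: type- and distance-compatible triplets of
    common-type features seed a Kabsch superposition (pairs, or a bare
    translation, when fewer than three common-type features exist); seeds
    are ranked by their correspondence RMSD, greedily mapped, and the
    most promising candidates refined by a rigid re-fit on the mapped
    pairs.  The returned alignment maximises ``n_mapped`` first and
    minimises RMSD second; deterministic for fixed inputs.  If no
    same-type feature pair exists the identity transform with an empty
    mapping is returned.
    """
    ref_f = ref.non_xv()
    mov_f = mov.non_xv()
    if not ref_f or not mov_f:
        raise ValueError("align requires non-empty pharmacophores (ignoring XV)")

    ref_pos = np.array([f.position for f in ref_f])
    mov_pos = np.array([f.position for f in mov_f])
    ref_types = [f.ftype for f in ref_f]
    mov_types = [f.ftype for f in mov_f]
    ref_tol = np.array([f.tolerance for f in ref_f]) * float(tol_scale)

    n_r, n_m = len(ref_f), len(mov_f)
    type_ok = np.array(
        [[mov_types[a] == ref_types[i] for i in range(n_r)] for a in range(n_m)], dtype=bool
    )
    if not type_ok.any():
        return identity_alignment()

    D_ref = np.linalg.norm(ref_pos[:, None, :] - ref_pos[None, :, :], axis=-1)
    D_mov = np.linalg.norm(mov_pos[:, None, :] - mov_pos[None, :, :], axis=-1)
    # pairwise correspondence compatibility C[a,b,i,j]:
    # types match per slot and |d_ref(i,j) - d_mov(a,b)| <= tol_i + tol_j
    tol_pair = ref_tol[:, None] + ref_tol[None, :]
    C = (
        type_ok[:, None, :, None]
        & type_ok[None, :, None, :]
        & (np.abs(D_ref[None, None, :, :] - D_mov[:, :, None, None]) <= tol_pair[None, None, :, :])
    )
    np.einsum("aaij->aij", C)[...] = False  # a != b
    np.einsum("abii->abi", C)[...] = False  # i != j

    seeds_P = np.zeros((0, 3, 3))
    seeds_Q = np.zeros((0, 3, 3))
    pair_seeds = False

    n_common_ref = int(np.sum(type_ok.any(axis=0)))
    n_common_mov = int(np.sum(type_ok.any(axis=1)))

    if n_common_ref >= 3 and n_common_mov >= 3 and C.any() and (n_m**3) * (n_r**3) <= 5e7:
        # triangles tri[a,b,c,i,j,k] = C[a,b,i,j] & C[b,c,j,k] & C[a,c,i,k]
        tri = (
            C[:, :, None, :, :, None]
            & C[None, :, :, None, :, :]
            & C[:, None, :, :, None, :]
        )
        idx = np.argwhere(tri)
        if len(idx):
            # each unordered correspondence set appears once with i<j<k
            idx = idx[(idx[:, 3] < idx[:, 4]) & (idx[:, 4] < idx[:, 5])]
            idx = idx[:_MAX_SEEDS]
        if len(idx):
            seeds_P = mov_pos[idx[:, :3]]
            seeds_Q = ref_pos[idx[:, 3:]]
    if not len(seeds_P):
        pidx = np.argwhere(C)
        if len(pidx):
            pidx = pidx[pidx[:, 0] < pidx[:, 1]][:1024]
        if len(pidx):
            seeds_P = mov_pos[pidx[:, :2]]
            seeds_Q = ref_pos[pidx[:, 2:]]
            pair_seeds = True

    Rs: list[np.ndarray] = [np.eye(3)]
    ts: list[np.ndarray] = [np.zeros(3)]
    # single-feature translations cover 1-feature and degenerate cases
    for a, i in np.argwhere(type_ok)[:32]:
        Rs.append(np.eye(3))
        ts.append(ref_pos[i] - mov_pos[a])

    if len(seeds_P):
        if pair_seeds:  # minimal segment rotation + centroid translation
            R = np.stack(
                [_rotation_between(p[1] - p[0], q[1] - q[0]) for p, q in zip(seeds_P, seeds_Q)]
            )
            t = seeds_Q.mean(axis=1) - np.einsum("sij,sj->si", R, seeds_P.mean(axis=1))
        else:
            R, t = _kabsch_batch(seeds_P, seeds_Q)
        moved = np.einsum("sij,skj->ski", R, seeds_P) + t[:, None, :]
        seed_rmsd = np.sqrt(np.mean(np.sum((moved - seeds_Q) ** 2, axis=-1), axis=-1))
        for s in np.argsort(seed_rmsd, kind="stable")[:_MAX_SEED_EVALS]:
            Rs.append(R[s])
            ts.append(t[s])

    Rb = np.stack(Rs)
    tb = np.stack(ts)
    moved_all = np.einsum("sij,aj->sai", Rb, mov_pos) + tb[:, None, :]
    dist_all = np.linalg.norm(moved_all[:, :, None, :] - ref_pos[None, None, :, :], axis=-1)
    ok_all = type_ok[None, :, :] & (dist_all <= ref_tol[None, None, :])

    prelim: list[tuple[int, float, int, dict[int, int]]] = []
    for s in range(len(Rb)):
        mapping, rmsd = _greedy_from_mask(dist_all[s], ok_all[s])
        if mapping:
            prelim.append((len(mapping), rmsd, s, mapping))
    if not prelim:
        return identity_alignment()
    prelim.sort(key=lambda x: (-x[0], x[1], x[2]))

    best: Alignment | None = None
    for n0, rmsd0, s, mapping0 in prelim[:_N_REFINE]:
        R, t, mapping, rmsd = Rb[s], tb[s], mapping0, rmsd0
        if n0 >= 3:  # rigid re-fit on the mapped pairs, then re-map once
            a_idx = np.fromiter(mapping0.keys(), int)
            i_idx = np.fromiter(mapping0.values(), int)
            R2, t2 = _kabsch(mov_pos[a_idx], ref_pos[i_idx])
            moved2 = mov_pos @ R2.T + t2
            d2 = np.linalg.norm(moved2[:, None, :] - ref_pos[None, :, :], axis=-1)
            m2, r2 = _greedy_from_mask(d2, type_ok & (d2 <= ref_tol[None, :]))
            if (len(m2), -r2) > (len(mapping), -rmsd):
                R, t, mapping, rmsd = R2, t2, m2, r2
        if best is None or (len(mapping), -rmsd) > (best.n_mapped, -best.rmsd):
            best = Alignment(np.asarray(R, float), np.asarray(t, float), mapping, rmsd, len(mapping))

    if best is None or best.n_mapped == 0:
        return identity_alignment()
    return best


def transform_pharmacophore(p: Pharmacophore, rotation: np.ndarray, translation: np.ndarray) -> Pharmacophore:
    """Apply a rigid transform to every feature center."""
    feats = [
        PharmFeature(
            ftype=f.ftype,
            position=tuple(rotation @ f.xyz + translation),
            tolerance=f.tolerance,
            weight=f.weight,
        )
        for f in p.features
    ]
    return Pharmacophore(name=p.name, features=feats)


def matches_query(query: Pharmacophore, target: Sample) -> MatchResult:
    """Screen one ligand against a query pharmacophore.

    A ligand matches iff some conformer, rigidly aligned to the query,
    maps every non-XV query feature and places no conformer feature
    center strictly inside any query exclusion-volume sphere.  Returns
    the best-matching conformer (lowest RMSD, ties by index).
    """
    q_main = query.non_xv()
    if not q_main:
        raise ValueError("query pharmacophore has no non-XV features")
    if not target.conformers:
        raise ValueError(f"sample {target.ligand_id!r} has no conformers")
    q = Pharmacophore(name=query.name, features=q_main)
    xv = query.xv()
    need = len(q_main)

    # cheap per-type count prefilter
    from collections import Counter

    q_counts = Counter(f.ftype for f in q_main)

    best: tuple[float, int] | None = None
    for ci, conf in enumerate(target.conformers):
        c_counts = Counter(f.ftype for f in conf.non_xv())
        if any(c_counts[t] < n for t, n in q_counts.items()):
            continue
        aln = align(q, conf)
        if aln.n_mapped < need:
            continue
        if xv:
            moved = conf.coords() @ aln.rotation.T + aln.translation
            violated = False
            for sphere in xv:
                d = np.linalg.norm(moved - sphere.xyz, axis=1)
                if np.any(d < sphere.tolerance - 1e-12):
                    violated = True
                    break
            if violated:
                continue
        if best is None or aln.rmsd < best[0] - 1e-15:
            best = (aln.rmsd, ci)
    if best is None:
        return MatchResult(False, None, None)
    return MatchResult(True, best[1], best[0])


# ---------------------------------------------------------------------------
# I/O


def write_pharmacophore(p: Pharmacophore, path) -> None:
    Path(path).write_text(json.dumps(p.to_dict(), indent=2) + "\n")


def read_pharmacophore(path, fmt: str = "json") -> Pharmacophore:
    """Read a pharmacophore from the versioned JSON schema."""
    if fmt != "json":
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed pharmacophore file {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ValueError(f"malformed pharmacophore file {path}: expected an object")
    return Pharmacophore.from_dict(d)


def write_samples(samples: Iterable[Sample], path) -> None:
    """Write a dataset as JSON-lines of sample containers."""
    with open(path, "w") as fh:
        for s in samples:
            fh.write(json.dumps(s.to_dict()) + "\n")


def read_samples(path) -> list[Sample]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                out.append(Sample.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad sample record: {exc}") from exc
    return out
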