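"""Screening, percentile labelling, confusion counts and the F-metrics.

Virtual screening is evaluated here with three related scores.  With
precision = TP/(TP+FP), recall = TP/(TP+FN) and specificity =
TN/(TN+FP):

    F_beta        = (1 + beta^2) * precision * recall
                    / (beta^2 * precision + recall)         (beta = 0.5)
    F_Specificity = precision * specificity / (precision + specificity)
    F_Composite   = (F_beta + F_Specificity) / 2

F_Specificity is deliberately implemented without a factor 2, exactly
as defined for this workflow, so its maximum is 0.5 and F_Composite's
maximum is 0.75.  A conventional harmonic-mean variant
(:func:`f_specificity_harmonic`) is provided for comparison but is not
part of the scoring pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .pharm_core import Pharmacophore, Sample, matches_query

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "ScreenReport",
    "label_actives",
    "screen",
    "confusion",
    "f_beta",
    "f_specificity",
    "f_specificity_harmonic",
    "f_composite",
    "rank_hits",
    "screen_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0


@dataclass
class ScreenReport:
    query_name: str
    flags: list[bool]
    counts: ConfusionCounts
    f_beta: float
    f_specificity: float
    f_composite: float
    ranked_hits: list[tuple[str, float]]


def label_actives(samples: list[Sample], percentile: float = 20.0) -> list[bool]:
    """Label the top activity percentile as active.

    Exactly ``ceil(percentile/100 * n)`` samples — those with the
    highest activities — are labelled active; ties at the cut are
    broken by ligand_id ascending so the count is exact.
    """
    if not samples:
        raise ValueError("empty sample list")
    for s in samples:
        if s.activity is None:
            raise ValueError(f"sample {s.ligand_id!r} has no activity")
    n_active = math.ceil(percentile / 100.0 * len(samples))
    order = sorted(range(len(samples)), key=lambda i: (-samples[i].activity, samples[i].ligand_id))
    labels = [False] * len(samples)
    for i in order[:n_active]:
        labels[i] = True
    return labels


def screen(query: Pharmacophore, library: list[Sample]) -> list[bool]:
    """Per-ligand match verdicts of the query against a library."""
    if not query.non_xv():
        raise ValueError("query pharmacophore has no non-XV features")
    return [matches_query(query, s).matched for s in library]


def confusion(flags: list[bool], labels: list[bool]) -> ConfusionCounts:
    if len(flags) != len(labels):
        raise ValueError("flags and labels differ in length")
    tp = sum(1 for f, l in zip(flags, labels) if f and l)
    fp = sum(1 for f, l in zip(flags, labels) if f and not l)
    tn = sum(1 for f, l in zip(flags, labels) if not f and not l)
    fn = sum(1 for f, l in zip(flags, labels) if not f and l)
    return ConfusionCounts(tp, fp, tn, fn)


def f_beta(counts: ConfusionCounts, beta: float = 0.5) -> float:
    """Precision/recall F-score weighted by beta (0.5 favours precision)."""
    p, r = counts.precision, counts.recall
    denom = beta * beta * p + r
    if denom == 0:
        logger.warning("degenerate F_beta (no predicted positives or no actives); scoring 0")
        return 0.0
    return (1 + beta * beta) * p * r / denom


def f_specificity(counts: ConfusionCounts) -> float:
    """precision * specificity / (precision + specificity); maximum 0.5."""
    p, s = counts.precision, counts.specificity
    if p + s == 0:
        logger.warning("degenerate F_specificity (precision and specificity both 0); scoring 0")
        return 0.0
    return p * s / (p + s)


def f_specificity_harmonic(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and specificity (NOT used in scoring)."""
    return 2.0 * f_specificity(counts)


def f_composite(f_beta_val: float, f_spec_val: float) -> float:
    """Arithmetic mean of the two scores; attainable maximum 0.75."""
    return 0.5 * (f_beta_val + f_spec_val)


def rank_hits(model, hits: list[Sample]) -> list[tuple[str, float]]:
    """Rank screening hits by predicted activity, highest first.

    Ties broken by ligand_id ascending; invariant to input order.
    """
    if not hits:
        return []
    preds = model.predict(hits)
    pairs = [(s.ligand_id, float(p)) for s, p in zip(hits, preds)]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return pairs


def screen_report(
    query: Pharmacophore,
    library: list[Sample],
    labels: list[bool] | None = None,
    model=None,
    beta: float = 0.5,
) -> ScreenReport:
    """Screen a library and assemble the full scoring/ranking report."""
    flags = screen(query, library)
    if labels is not None:
        counts = confusion(flags, labels)
    else:
        counts = ConfusionCounts(tp=sum(flags), fp=0, tn=0, fn=0)
    fb = f_beta(counts, beta)
    fs = f_specificity(counts)
    hits = [s for s, f in zip(library, flags) if f]
    ranked = rank_hits(model, hits) if model is not None and hits else []
    return ScreenReport(
        query_name=query.name,
        flags=flags,
        counts=counts,
        f_beta=fb,
        f_specificity=fs,
        f_composite=f_composite(fb, fs),
        ranked_hits=ranked,
    )
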