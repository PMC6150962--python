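"""Matching predicted complexes to a gold standard; precision/recall/F-score.

A predicted complex p matches a gold complex q when the neighborhood-affinity
score NA(p,q) = |V_p ∩ V_q|^2 / (|V_p| * |V_q|) is at least the threshold
(0.25 by convention).  Matching is many-to-many: precision is the fraction of
predicted complexes matching at least one gold complex, recall the fraction
of gold complexes matched by at least one prediction, and
F = 2PR / (P + R) their harmonic mean (0 when both are 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .ppi_io import Complex

__all__ = ["EvaluationReport", "na_score", "match_and_score"]


@dataclass
class EvaluationReport:
    n_predicted: int
    n_gold: int
    matched_pred: int
    matched_gold: int
    precision: float
    recall: float
    f_score: float
    na_threshold: float
    pair_matches: List[Tuple[int, int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_gold": self.n_gold,
            "matched_pred": self.matched_pred,
            "matched_gold": self.matched_gold,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "na_threshold": self.na_threshold,
            "pair_matches": [list(t) for t in self.pair_matches],
        }


def na_score(p: Complex, q: Complex) -> float:
    """Neighborhood affinity |p ∩ q|^2 / (|p| * |q|), symmetric, in [0,1]."""
    if len(p.members) == 0 or len(q.members) == 0:
        raise ValueError("NA score undefined for empty complexes")
    overlap = len(p.members & q.members)
    return overlap * overlap / (len(p.members) * len(q.members))


def match_and_score(predicted: Sequence[Complex], gold: Sequence[Complex],
                    na_thres: float = 0.25) -> EvaluationReport:
    """Many-to-many NA matching at ``na_thres`` (inclusive).

    Raises on an empty gold list; an empty prediction list scores P=R=F=0.
    """
    if not (0.0 < na_thres <= 1.0):
        raise ValueError("na_thres must be in (0, 1]")
    if not gold:
        raise ValueError("empty gold standard: nothing to evaluate against")
    pair_matches: List[Tuple[int, int, float]] = []
    matched_pred = set()
    matched_gold = set()
    for i, p in enumerate(predicted):
        for j, q in enumerate(gold):
            na = na_score(p, q)
            if na >= na_thres:
                pair_matches.append((i, j, na))
                matched_pred.add(i)
                matched_gold.add(j)
    n_pred = len(predicted)
    precision = len(matched_pred) / n_pred if n_pred else 0.0
    recall = len(matched_gold) / len(gold)
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvaluationReport(
        n_predicted=n_pred,
        n_gold=len(gold),
        matched_pred=len(matched_pred),
        matched_gold=len(matched_gold),
        precision=precision,
        recall=recall,
        f_score=f,
        na_threshold=na_thres,
        pair_matches=pair_matches,
    )
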