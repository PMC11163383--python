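"""Complex-catalogue evaluation: NA matching, Sn/PPV/Acc, enrichment.

Two complexes match when their neighbourhood-affinity score
``NA(p, b) = |p & b|^2 / (|p| |b|)`` reaches the threshold ``omega``
(0.25 by convention).  Precision counts matched predictions, recall counts
matched references; Sn/PPV/Acc come from the full overlap matrix.  The
enrichment p-value of a complex against a functional group is the
hypergeometric upper tail with the usual 0.01 significance cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io import ComplexSet

logger = logging.getLogger(__name__)

OMEGA_DEFAULT = 0.25
ENRICHMENT_CUTOFF = 0.01


@dataclass
class EvaluationReport:
    n_matched_predicted: int
    n_matched_reference: int
    precision: float
    recall: float
    f_score: float
    sn: float
    ppv: float
    acc: float
    omega: float
    na_matrix: np.ndarray  # (|P|, |B|)

    @property
    def composite(self) -> float:
        """F-score + Acc, the combined headline criterion."""
        return self.f_score + self.acc

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "sn": self.sn,
            "ppv": self.ppv,
            "acc": self.acc,
            "composite": self.composite,
        }


def na_score(p: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Neighbourhood affinity between two protein sets."""
    if not p or not b:
        raise ValueError("NA score is undefined for empty complexes")
    inter = len(set(p) & set(b))
    return inter * inter / (len(p) * len(b))


def precision_recall_f(
    predicted: ComplexSet, reference: ComplexSet, omega: float = OMEGA_DEFAULT
) -> tuple[float, float, float, np.ndarray]:
    """Match-based precision, recall and F-score, plus the NA matrix."""
    if len(predicted) == 0 or len(reference) == 0:
        raise ValueError("both complex sets must be nonempty")
    P = predicted.member_sets()
    B = reference.member_sets()
    na = np.array([[na_score(p, b) for b in B] for p in P])
    n_cp = int((na.max(axis=1) >= omega).sum())
    n_cb = int((na.max(axis=0) >= omega).sum())
    precision = n_cp / len(P)
    recall = n_cb / len(B)
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f, na


def sn_ppv_acc(predicted: ComplexSet, reference: ComplexSet) -> tuple[float, float, float]:
    """Clustering sensitivity, positive predictive value, geometric mean."""
    P = predicted.member_sets()
    B = reference.member_sets()
    T = np.array([[len(b & p) for p in P] for b in B])  # (|B|, |P|)
    denom_sn = sum(len(b) for b in B)
    sn = T.max(axis=1).sum() / denom_sn if denom_sn else 0.0
    denom_ppv = T.sum()
    if denom_ppv == 0:
        logger.info("no overlap between predicted and reference complexes; PPV = 0")
        ppv = 0.0
    else:
        ppv = T.max(axis=0).sum() / denom_ppv
    return float(sn), float(ppv), float(np.sqrt(sn * ppv))


def evaluate(
    predicted: ComplexSet, reference: ComplexSet, omega: float = OMEGA_DEFAULT
) -> EvaluationReport:
    precision, recall, f, na = precision_recall_f(predicted, reference, omega)
    sn, ppv, acc = sn_ppv_acc(predicted, reference)
    return EvaluationReport(
        n_matched_predicted=int((na.max(axis=1) >= omega).sum()),
        n_matched_reference=int((na.max(axis=0) >= omega).sum()),
        precision=precision,
        recall=recall,
        f_score=f,
        sn=sn,
        ppv=ppv,
        acc=acc,
        omega=omega,
        na_matrix=na,
    )


def enrichment_pvalue(
    complex_size: int, group_size: int, overlap: int, universe: int
) -> float:
    """Hypergeometric upper-tail probability of drawing >= ``overlap``
    members of a functional group of size ``group_size`` in a complex of
    ``complex_size`` proteins from a ``universe``-protein network."""
    if overlap > min(complex_size, group_size):
        raise ValueError("overlap exceeds the smaller of complex/group size")
    if group_size > universe or complex_size > universe:
        raise ValueError("group and complex must fit inside the universe")
    if overlap < 0 or complex_size < 0:
        raise ValueError("counts must be nonnegative")
    # P(X >= k) for X ~ Hypergeom(universe, group_size, complex_size)
    return float(hypergeom.sf(overlap - 1, universe, group_size, complex_size))


def mismatch_count(identified: frozenset[str] | set[str], gold: frozenset[str] | set[str]) -> int:
    """Disagreement between an identified complex and a reference complex.

    Defined as ``max(#extra, #missing)`` — the larger of the identified
    proteins absent from the reference and the reference proteins absent
    from the identification.  This convention is an inference from worked
    examples rather than a published definition; see the methods note.
    """
    if not identified or not gold:
        raise ValueError("mismatch count is undefined for empty sets")
    identified, gold = set(identified), set(gold)
    return max(len(identified - gold), len(gold - identified))
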