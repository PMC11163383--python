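"""Multiplex heterogeneous protein information network construction.

A raw PPI network is constrained by two kinds of evidence that an
interaction can physically happen: the two partners must be expressed at a
common time point of the time-course profile (temporal co-activity) or
reside in a common subcellular compartment (spatial co-location).  Retained
edges, together with RNA-protein regulatory links, form a multiplex
heterogeneous network whose layers are binary "basic spatiotemporal
interaction patterns": one layer per time point, one per compartment, and
one per time x compartment combination that is actually populated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionTable, LocalizationTable, RnaAssocTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivityProfile:
    """Per-protein expression summary and active time points.

    ``threshold`` is the protein-specific activity threshold
    ``u + k*sigma*(1 - 1/(1 + sigma^2))``: for a flat profile (sigma = 0)
    it collapses to the mean, and it approaches ``u + k*sigma`` for noisy
    profiles, so that high-variance proteins need a proportionally larger
    excursion to count as active.
    """

    protein: str
    mean: float
    sd: float
    threshold: float
    active_times: frozenset[int]  # 1-based time indices


@dataclass(frozen=True)
class EdgeAnnotation:
    co_times: frozenset[int]
    co_locations: frozenset[str]


@dataclass
class MHPIN:
    """Typed nodes plus annotated, spatiotemporally retained edges."""

    proteins: list[str]
    rnas: list[str]
    ppi_edges: dict[tuple[str, str], EdgeAnnotation]
    rna_edges: list[tuple[str, str]]  # (rna, protein)
    node_types: frozenset[str] = frozenset({"protein", "rna"})
    edge_types: frozenset[str] = frozenset(
        {"ppi_spatiotemporal", "rna_protein_association"}
    )

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def protein_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}


@dataclass
class PatternStack:
    """Ordered binary adjacency layers over the protein node set.

    Order: single-time layers ascending, single-space layers in vocabulary
    order, then populated overlap layers time-major.  Every overlap layer is
    the elementwise product of its time and space layers; all-zero layers
    are dropped.
    """

    labels: list[str]
    matrices: list[np.ndarray]
    proteins: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def M(self) -> int:
        return len(self.matrices)

    def stacked(self) -> np.ndarray:
        """(M, n, n) float array of all layers."""
        return np.stack(self.matrices).astype(float)


def active_threshold(u: float, sigma: float, k: float) -> float:
    """Protein-specific activity threshold from mean and s.d. of expression."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    return u + k * sigma * (1.0 - 1.0 / (1.0 + sigma**2))


def compute_activity(expr: ExpressionTable, k: float = 1.0) -> dict[str, ActivityProfile]:
    """Mark, for every profiled protein, the time points at which it is active.

    A point counts as active when its value is at least the threshold
    (``>=``), so a zero-variance protein is active at every time point.
    The default ``k = 1`` balances confidence in activity against network
    sparsity.
    """
    out: dict[str, ActivityProfile] = {}
    for p in expr.proteins:
        series = expr.series(p)
        u = float(series.mean())
        sd = float(series.std(ddof=0))
        thr = active_threshold(u, sd, k)
        active = frozenset(int(t) + 1 for t in np.nonzero(series >= thr)[0])
        out[p] = ActivityProfile(p, u, sd, thr, active)
    return out


def select_rna_partners(assoc: RnaAssocTable) -> list[tuple[str, str]]:
    """Keep, per protein, the RNAs scoring strictly above that protein's mean.

    The mean is taken over the scores recorded for that protein only; a
    protein with a single recorded association keeps no partner (the score
    equals its own mean).
    """
    partners: list[tuple[str, str]] = []
    for protein, grp in assoc.data.groupby("protein", sort=False):
        mean = grp["score"].mean()
        keep = grp[grp["score"] > mean]
        partners.extend((r, protein) for r in keep["rna"])
    return partners


def build_mhpin(
    edges: list[tuple[str, str]],
    activity: dict[str, ActivityProfile],
    localization: LocalizationTable,
    rna_edges: list[tuple[str, str]],
    spatiotemporal_filter: bool = True,
) -> MHPIN:
    """Assemble the heterogeneous network, filtering PPI edges.

    An edge survives iff its endpoints share at least one active time point
    or at least one compartment; survivors are annotated with both
    intersection sets.  With ``spatiotemporal_filter=False`` every edge is
    retained (annotations still computed), which is the network used by the
    no-spatiotemporal-constraint ablation.
    """
    proteins = sorted({p for e in edges for p in e})
    pset = set(proteins)
    missing = [p for p in proteins if p not in activity]
    if missing:
        logger.info("%d network proteins lack expression data", len(missing))

    retained: dict[tuple[str, str], EdgeAnnotation] = {}
    for a, b in edges:
        ta = activity[a].active_times if a in activity else frozenset()
        tb = activity[b].active_times if b in activity else frozenset()
        co_t = ta & tb
        co_s = localization.locations(a) & localization.locations(b)
        if spatiotemporal_filter and not (co_t or co_s):
            continue
        key = (a, b) if a < b else (b, a)
        retained[key] = EdgeAnnotation(co_t, co_s)
    if not retained:
        logger.warning("no PPI edges survived the spatiotemporal filter")

    rna_kept = [(r, p) for r, p in rna_edges if p in pset]
    rnas = sorted({r for r, _ in rna_kept})
    return MHPIN(proteins, rnas, retained, rna_kept)


def build_patterns(
    mhpin: MHPIN,
    T: int,
    compartments: list[str] | None = None,
) -> PatternStack:
    """Decompose the retained edges into basic spatiotemporal pattern layers."""
    proteins = mhpin.proteins
    idx = mhpin.protein_index()
    n = len(proteins)
    if compartments is None:
        seen: set[str] = set()
        for ann in mhpin.ppi_edges.values():
            seen |= ann.co_locations
        compartments = sorted(seen)

    time_labels = [f"T{t}" for t in range(1, T + 1)]
    space_labels = [f"S:{c}" for c in compartments]
    tmats = {t: np.zeros((n, n), dtype=np.uint8) for t in range(1, T + 1)}
    smats = {c: np.zeros((n, n), dtype=np.uint8) for c in compartments}
    for (a, b), ann in mhpin.ppi_edges.items():
        i, j = idx[a], idx[b]
        for t in ann.co_times:
            tmats[t][i, j] = tmats[t][j, i] = 1
        for c in ann.co_locations:
            smats[c][i, j] = smats[c][j, i] = 1

    labels: list[str] = []
    mats: list[np.ndarray] = []
    for t, lab in zip(range(1, T + 1), time_labels):
        if tmats[t].any():
            labels.append(lab)
            mats.append(tmats[t])
    for c, lab in zip(compartments, space_labels):
        if smats[c].any():
            labels.append(lab)
            mats.append(smats[c])
    for t in range(1, T + 1):
        for c in compartments:
            overlap = tmats[t] * smats[c]
            if overlap.any():
                labels.append(f"T{t}&S:{c}")
                mats.append(overlap)
    if not mats:
        logger.warning("pattern stack is empty")
    return PatternStack(labels, mats, list(proteins))


def single_layer_patterns(mhpin: MHPIN) -> PatternStack:
    """Degenerate stack with one layer holding every retained edge.

    Used by the ablation that ignores spatiotemporal interaction patterns.
    """
    idx = mhpin.protein_index()
    n = len(mhpin.proteins)
    mat = np.zeros((n, n), dtype=np.uint8)
    for a, b in mhpin.ppi_edges:
        i, j = idx[a], idx[b]
        mat[i, j] = mat[j, i] = 1
    return PatternStack(["ALL"], [mat], list(mhpin.proteins))
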