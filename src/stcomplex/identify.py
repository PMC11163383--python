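"""Embedding-guided core-attachment complex identification.

The PPI network is reweighted by cosine similarity of the learned protein
embeddings on existing edges (zero elsewhere).  Cores are maximal cliques
of size >= 3 on the positive-weight graph whose members share a common
active time point or a common compartment; overlapping candidates are
resolved greedily by density score.  Every remaining protein with an edge
into a core joins it as an attachment when its mean edge weight into the
core exceeds the adhesion threshold ``lambda``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .io import Complex, ComplexSet, LocalizationTable
from .mhpin import ActivityProfile

logger = logging.getLogger(__name__)


@dataclass
class ReweightedPIN:
    """Symmetric edge weights ``w_pq = cos(Z_p, Z_q)`` on PIN edges, else 0."""

    weights: dict[tuple[str, str], float]  # key: sorted protein pair
    adjacency: dict[str, set[str]]

    def weight(self, p: str, q: str) -> float:
        if p == q:
            return 0.0
        key = (p, q) if p < q else (q, p)
        return self.weights.get(key, 0.0)

    def neighbors(self, p: str) -> set[str]:
        return self.adjacency.get(p, set())


@dataclass
class CoreSet:
    """Extraction-ordered seed cores with density scores and an audit trail."""

    cores: list[tuple[frozenset[str], float]]
    deleted: list[frozenset[str]] = field(default_factory=list)
    updated: list[tuple[frozenset[str], frozenset[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cores)

    def __iter__(self):
        return iter(self.cores)


def reweight(embeddings: dict[str, np.ndarray], pin: list[tuple[str, str]]) -> ReweightedPIN:
    """Cosine-similarity weights on the original PIN edges."""
    missing = sorted({p for e in pin for p in e} - set(embeddings))
    if missing:
        raise ValueError(f"proteins without embeddings: {missing}")
    weights: dict[tuple[str, str], float] = {}
    adjacency: dict[str, set[str]] = {}
    for a, b in pin:
        if a == b:
            continue
        za, zb = embeddings[a], embeddings[b]
        denom = np.linalg.norm(za) * np.linalg.norm(zb)
        w = float(za @ zb / denom) if denom > 0 else 0.0
        key = (a, b) if a < b else (b, a)
        weights[key] = w
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    return ReweightedPIN(weights, adjacency)


def density_score(core: frozenset[str] | set[str], w: ReweightedPIN) -> float:
    """Sum of edge weights over unordered member pairs."""
    if len(core) < 2:
        raise ValueError("density score needs at least two members")
    return sum(w.weight(p, q) for p, q in combinations(sorted(core), 2))


def adhesion_score(p: str, core: frozenset[str] | set[str], w: ReweightedPIN) -> float:
    """Mean edge weight from ``p`` into the core."""
    if p in core:
        raise ValueError(f"{p!r} is already a core member")
    return sum(w.weight(p, q) for q in core) / len(core)


def _passes_coactivity(
    members,
    activity: dict[str, ActivityProfile] | None,
    localization: LocalizationTable | None,
) -> bool:
    """Common active-time set or common location set nonempty across members."""
    if activity is None and localization is None:
        return True
    if activity is not None:
        common_t: frozenset[int] | None = None
        for p in members:
            times = activity[p].active_times if p in activity else frozenset()
            common_t = times if common_t is None else common_t & times
            if not common_t:
                break
        if common_t:
            return True
    if localization is not None:
        common_s: frozenset[str] | None = None
        for p in members:
            locs = localization.locations(p)
            common_s = locs if common_s is None else common_s & locs
            if not common_s:
                break
        if common_s:
            return True
    return False


def _candidate_key(core: frozenset[str], w: ReweightedPIN):
    """Descending density, then larger size, then lexicographic members."""
    return (-density_score(core, w), -len(core), tuple(sorted(core)))


def mine_cores(
    w: ReweightedPIN,
    activity: dict[str, ActivityProfile] | None = None,
    localization: LocalizationTable | None = None,
) -> CoreSet:
    """Greedy density-ordered core extraction from co-active maximal cliques.

    (1) enumerate maximal cliques (size >= 3) of the positive-weight graph
    and keep those whose members share an active time or a location;
    (2) rank candidates by density score; (3) promote the best to a seed
    core; (4) prune every overlapping candidate — dropped outright when its
    non-overlapping remainder has fewer than 3 proteins (or loses the
    co-activity witness), otherwise replaced by that remainder; (5) repeat
    until no candidates remain.
    """
    G = nx.Graph()
    for (a, b), weight in w.weights.items():
        if weight > 0:
            G.add_edge(a, b)
    candidates: set[frozenset[str]] = set()
    for clique in nx.find_cliques(G) if G.number_of_nodes() else []:
        if len(clique) >= 3 and _passes_coactivity(clique, activity, localization):
            candidates.add(frozenset(clique))
    result = CoreSet(cores=[])
    if not candidates:
        logger.info("no candidate cores of size >= 3")
        return result

    while candidates:
        top = min(candidates, key=lambda c: _candidate_key(c, w))
        candidates.discard(top)
        result.cores.append((top, density_score(top, w)))
        survivors: set[frozenset[str]] = set()
        for cand in candidates:
            if not (cand & top):
                survivors.add(cand)
                continue
            remainder = cand - top
            if len(remainder) >= 3 and _passes_coactivity(
                remainder, activity, localization
            ):
                result.updated.append((cand, remainder))
                survivors.add(remainder)
            else:
                result.deleted.append(cand)
        candidates = survivors
    return result


def attach_proteins(
    cores: CoreSet, w: ReweightedPIN, lam: float
) -> ComplexSet:
    """Expand each core with high-adhesion neighbours; drop duplicate results."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    out = ComplexSet()
    seen: set[frozenset[str]] = set()
    for core, _ in cores:
        candidates = set()
        for member in core:
            candidates |= w.neighbors(member)
        candidates -= set(core)
        attachments = {
            p for p in candidates if adhesion_score(p, core, w) > lam
        }
        members = frozenset(core | attachments)
        if members in seen:
            continue
        seen.add(members)
        out.complexes.append(Complex(members, core=frozenset(core)))
    return out


def identify_complexes(
    embeddings: dict[str, np.ndarray],
    pin: list[tuple[str, str]],
    activity: dict[str, ActivityProfile] | None = None,
    localization: LocalizationTable | None = None,
    lam: float = 0.4,
) -> ComplexSet:
    """Full two-stage identification: reweight, mine cores, attach."""
    w = reweight(embeddings, pin)
    cores = mine_cores(w, activity, localization)
    return attach_proteins(cores, w, lam)
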