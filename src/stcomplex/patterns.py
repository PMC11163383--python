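"""Wide- and deep-domain weighted adjacencies from the pattern stack.

The wide-domain adjacency is a learnable convex combination of the basic
pattern layers; the deep-domain adjacency measures how similar two
proteins' per-layer degree profiles are (role similarity), via a normalised
Gram matrix of the weighted degree-profile matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mhpin import PatternStack


@dataclass
class WeightedAdjacency:
    matrix: np.ndarray  # symmetric nonnegative (n, n)
    tag: str  # "wide" or "deep"
    proteins: list[str]


def softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def wide_domain_adjacency(
    patterns: PatternStack,
    alpha: np.ndarray | None = None,
    normalized: bool = False,
) -> WeightedAdjacency:
    """Convex combination of pattern layers with softmax-normalised weights.

    ``alpha`` holds the free (pre-softmax) weights, one per retained layer;
    uniform when omitted.  With ``normalized=True`` the entries of ``alpha``
    are used directly as the combination weights (no softmax), which is
    handy for inspecting individual layers.
    """
    M = patterns.M
    if alpha is None:
        alpha = np.zeros(M)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (M,):
        raise ValueError(f"alpha must have length M={M}, got shape {alpha.shape}")
    w = alpha if normalized else softmax(alpha)
    mat = np.tensordot(w, patterns.stacked(), axes=1)
    return WeightedAdjacency(mat, "wide", list(patterns.proteins))


def degree_profile(patterns: PatternStack) -> np.ndarray:
    """(n, M) matrix of per-layer node degrees."""
    return np.stack([m.sum(axis=1) for m in patterns.matrices], axis=1).astype(float)


def deep_domain_adjacency(
    D: np.ndarray,
    epsilon: np.ndarray | None = None,
    normalized: bool = False,
) -> np.ndarray:
    """Normalised Gram matrix of the column-weighted degree profile.

    Columns of ``D`` are scaled by ``sigmoid(epsilon)``, the Gram matrix
    ``D'D'^T`` is computed, its diagonal zeroed, and the result is
    symmetrically degree-normalised (all-zero rows stay zero).  Higher
    entries mean closer structural roles across the pattern layers.  With
    ``normalized=True`` the entries of ``epsilon`` are used directly as
    column weights (no sigmoid).
    """
    D = np.asarray(D, dtype=float)
    if epsilon is None:
        epsilon = np.zeros(D.shape[1])
    eps = np.asarray(epsilon, dtype=float)
    if not normalized:
        eps = sigmoid(eps)
    if eps.shape != (D.shape[1],):
        raise ValueError("epsilon must have one entry per pattern layer")
    Dw = D * eps
    S = Dw @ Dw.T
    np.fill_diagonal(S, 0.0)
    rs = S.sum(axis=1)
    inv = np.zeros_like(rs)
    nz = rs > 0
    inv[nz] = rs[nz] ** -0.5
    return S * inv[:, None] * inv[None, :]


def deep_adjacency_from_patterns(
    patterns: PatternStack, epsilon: np.ndarray | None = None
) -> WeightedAdjacency:
    mat = deep_domain_adjacency(degree_profile(patterns), epsilon)
    return WeightedAdjacency(mat, "deep", list(patterns.proteins))


def sparsify_topk(matrix: np.ndarray, k: int = 10) -> np.ndarray:
    """Binary support of the union-symmetrised per-row top-``k`` entries.

    The dense deep-domain adjacency is pruned to each node's ``k`` strongest
    role-similarity partners; keeping the union of (i->j) and (j->i) picks
    preserves symmetry.
    """
    n = matrix.shape[0]
    support = np.zeros((n, n), dtype=bool)
    for i in range(n):
        row = matrix[i]
        nz = np.nonzero(row > 0)[0]
        if nz.size == 0:
            continue
        top = nz[np.argsort(row[nz])[::-1][:k]]
        support[i, top] = True
    support |= support.T
    np.fill_diagonal(support, False)
    return support
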