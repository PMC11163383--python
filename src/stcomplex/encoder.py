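"""Dual-view aggregator over a heterogeneous protein-RNA network.

One aggregator instance serves one interaction pattern (wide-domain or
deep-domain).  Its first-order view attends over typed one-hop neighbours
(protein neighbours from the pattern adjacency, RNA neighbours from the
bipartite association edges) with node-level then type-level attention; its
meta-path view runs a single-layer symmetric-normalised graph convolution
over the protein-protein-protein and protein-RNA-protein neighbour graphs
and fuses them with the same type-level attention machinery.  The pattern
embedding is the average of the two views.

The plain-numpy functions at the top of this module define the reference
semantics of each step and are what the unit tests exercise; the
:class:`DualViewModel` re-expresses the same computation with
autodiff tensors so the whole thing can be trained end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, constant, parameter
from .mhpin import MHPIN, PatternStack
from .patterns import deep_domain_adjacency, degree_profile, sparsify_topk

LEAKY_SLOPE = 0.2


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.exp(np.minimum(x, 0.0)) - 1.0)


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


# ---------------------------------------------------------------------------
# reference (numpy) semantics of the four aggregation steps


def node_level_attention(
    h_target: np.ndarray,
    H_neighbors: np.ndarray,
    mu: np.ndarray,
    edge_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention-weighted sum of one target's same-type neighbour features.

    Logits are ``LeakyReLU(mu^T [h_p || h_q])``; positive edge weights, when
    given, enter additively on the logits as ``log w`` so that stronger
    pattern-layer support shifts attention without leaving the softmax form.
    Returns ``(sigma(sum beta_q H_q), beta)``.  An empty neighbourhood
    yields the zero vector with empty ``beta``.
    """
    H_neighbors = np.atleast_2d(H_neighbors)
    if H_neighbors.shape[0] == 0:
        return np.zeros_like(h_target), np.zeros(0)
    logits = np.array(
        [mu @ np.concatenate([h_target, hq]) for hq in H_neighbors]
    )
    logits = np.where(logits > 0, logits, LEAKY_SLOPE * logits)
    if edge_weights is not None:
        logits = logits + np.log(np.asarray(edge_weights, dtype=float) + 1e-8)
    beta = _softmax(logits)
    return _elu(beta @ H_neighbors), beta


def type_level_attention(
    per_type: list[np.ndarray],
    mu_type: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse per-type embedding matrices with graph-global type weights.

    Each type's score is the mean over all nodes of
    ``mu^T tanh(W z + b)``; a softmax over types gives the fusion weights.
    Returns ``(fused (n, d) matrix, gamma)``.
    """
    w = np.array(
        [np.mean(np.tanh(z @ W.T + b) @ mu_type) for z in per_type]
    )
    gamma = _softmax(w)
    fused = sum(g * z for g, z in zip(gamma, per_type))
    return fused, gamma


def metapath_gcn(adjacency: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Single-layer symmetric-normalised convolution with a self term.

    ``z_p = h_p/(d_p+1) + sum_q h_q / sqrt((d_p+1)(d_q+1))`` over the
    neighbours of ``p`` in the (binary) meta-path neighbour graph.
    """
    A = (np.asarray(adjacency) > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    d = A.sum(axis=1)
    inv = 1.0 / np.sqrt(d + 1.0)
    op = A * inv[:, None] * inv[None, :]
    np.fill_diagonal(op, 1.0 / (d + 1.0))
    return op @ features


def gcn_operator(adjacency: np.ndarray) -> np.ndarray:
    """The constant (n, n) propagation matrix used by :func:`metapath_gcn`."""
    A = (np.asarray(adjacency) > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    d = A.sum(axis=1)
    inv = 1.0 / np.sqrt(d + 1.0)
    op = A * inv[:, None] * inv[None, :]
    np.fill_diagonal(op, 1.0 / (d + 1.0))
    return op


def metapath_fusion(
    per_path: list[np.ndarray],
    mu_type: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse per-meta-path embeddings; same machinery as type-level attention."""
    return type_level_attention(per_path, mu_type, W, b)


# ---------------------------------------------------------------------------
# trainable model


@dataclass
class EncoderConfig:
    feature_dim: int = 64  # h, initial learnable feature rows
    hidden_dim: int = 128  # d, embedding dimension (best-performing size)
    dropout: float = 0.3
    topk: int = 10  # deep-domain sparsification degree
    seed: int = 0


@dataclass
class ViewEmbeddings:
    """First-order view, meta-path view, and their average, for one pattern."""

    Z_stra: np.ndarray
    Z_mp: np.ndarray

    @property
    def Z_pattern(self) -> np.ndarray:
        return 0.5 * (self.Z_stra + self.Z_mp)


class _AggregatorParams:
    """All learnable tensors of one dual-view aggregator."""

    def __init__(self, rng: np.random.Generator, h: int, d: int):
        def init(*shape):
            return parameter(rng.normal(0.0, 0.1, size=shape))

        self.W_P = init(h, d)
        self.W_R = init(h, d)
        # node-level attention vectors, split into source/destination halves
        self.mu_pp = (init(d), init(d))
        self.mu_pr = (init(d), init(d))
        # type-level attention (first-order view)
        self.W_t = init(d, d)
        self.b_t = init(d)
        self.mu_type = init(d)
        # meta-path fusion attention
        self.W_m = init(d, d)
        self.b_m = init(d)
        self.mu_mp = init(d)

    def all(self) -> list[Tensor]:
        out = [self.W_P, self.W_R, self.W_t, self.b_t, self.mu_type,
               self.W_m, self.b_m, self.mu_mp]
        out += [*self.mu_pp, *self.mu_pr]
        return out


class DualViewModel:
    """Differentiable wide+deep dual-view encoder over an MHPIN.

    Holds learnable node features, the pattern weights (alpha for the
    wide-domain combination, epsilon for the deep-domain degree profile) and
    two aggregators.  ``forward()`` rebuilds both weighted adjacencies from
    the current alpha/epsilon every call, so their gradients flow through
    the attention logits.
    """

    def __init__(self, mhpin: MHPIN, patterns: PatternStack, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        nP, nR = len(mhpin.proteins), len(mhpin.rnas)
        self.nP, self.nR = nP, nR
        h, d = config.feature_dim, config.hidden_dim

        stack = patterns.stacked()  # (M, n, n)
        self.M = stack.shape[0]
        self._stack_flat = constant(stack.reshape(self.M, nP * nP))
        self._support_wide = stack.sum(axis=0) > 0  # union of layers

        # deep-domain support frozen at init (uniform epsilon)
        D = degree_profile(patterns)
        self._D = constant(D)
        dense_deep = deep_domain_adjacency(D, np.zeros(self.M))
        self._support_deep = sparsify_topk(dense_deep, config.topk)

        # bipartite RNA incidence and meta-path neighbour graphs
        B = np.zeros((nP, nR))
        pidx = mhpin.protein_index()
        ridx = {r: i for i, r in enumerate(mhpin.rnas)}
        for r, p in mhpin.rna_edges:
            B[pidx[p], ridx[r]] = 1.0
        self._B = B
        self.has_rna = B.any()
        prp = B @ B.T
        np.fill_diagonal(prp, 0.0)
        self._op_prp = constant(gcn_operator(prp))
        ppp_wide = (self._support_wide.astype(float) @ self._support_wide) > 0
        self._op_ppp_wide = constant(gcn_operator(ppp_wide))
        ppp_deep = (self._support_deep.astype(float) @ self._support_deep) > 0
        self._op_ppp_deep = constant(gcn_operator(ppp_deep))

        # learnable parameters
        self.X_P = parameter(rng.normal(0.0, 0.1, size=(nP, h)))
        self.X_R = parameter(rng.normal(0.0, 0.1, size=(max(nR, 1), h)))
        self.alpha = parameter(np.zeros(self.M))
        self.epsilon = parameter(np.zeros(self.M))
        self.agg = {
            "wide": _AggregatorParams(rng, h, d),
            "deep": _AggregatorParams(rng, h, d),
        }

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[Tensor]:
        out = [self.X_P, self.X_R, self.alpha, self.epsilon]
        for a in self.agg.values():
            out += a.all()
        return out

    # -- adjacency construction (differentiable) ---------------------------

    def wide_adjacency(self) -> Tensor:
        a = self.alpha.softmax(axis=0).reshape(1, self.M)
        return (a @ self._stack_flat).reshape(self.nP, self.nP)

    def deep_adjacency(self) -> Tensor:
        eps = self.epsilon.sigmoid()
        Dw = self._D * eps  # broadcast over columns
        S = Dw @ Dw.T
        off = constant(1.0 - np.eye(self.nP))
        S = S * off
        rs = S.sum(axis=1, keepdims=True)
        guard = constant((rs.data == 0).astype(float))
        inv = (rs + guard) ** -0.5 * constant((rs.data > 0).astype(float))
        W = S * inv * inv.reshape(1, self.nP)
        return W * constant(self._support_deep.astype(float))

    # -- forward pass ------------------------------------------------------

    def _dropout(self, H: Tensor, training: bool) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0:
            return H
        mask = (self.rng.random(H.shape) >= p) / (1.0 - p)
        return H * constant(mask)

    def _first_order(self, params, HP, HR, w_adj: Tensor, support: np.ndarray):
        """Node-level + type-level attention over the typed one-hop views."""
        # protein neighbours, weighted by the pattern adjacency
        s_src = (HP @ params.mu_pp[0].reshape(-1, 1)).reshape(self.nP, 1)
        s_dst = (HP @ params.mu_pp[1].reshape(-1, 1)).reshape(1, self.nP)
        logits = (s_src + s_dst).leaky_relu(LEAKY_SLOPE) + (
            w_adj + constant(np.full((self.nP, self.nP), 1e-8))
        ).log()
        beta = logits.masked_softmax(support)
        z_prot = (beta @ HP).elu()
        per_type = [z_prot]
        if self.has_rna:
            r_src = (HP @ params.mu_pr[0].reshape(-1, 1)).reshape(self.nP, 1)
            r_dst = (HR @ params.mu_pr[1].reshape(-1, 1)).reshape(1, -1)
            rlogits = (r_src + r_dst).leaky_relu(LEAKY_SLOPE)
            rbeta = rlogits.masked_softmax(self._B > 0)
            per_type.append((rbeta @ HR).elu())
        return self._fuse(per_type, params.mu_type, params.W_t, params.b_t)

    @staticmethod
    def _fuse(per_type: list[Tensor], mu, W, b) -> Tensor:
        scores = []
        for z in per_type:
            s = ((z @ W.T + b.reshape(1, -1)).tanh() @ mu.reshape(-1, 1)).mean()
            scores.append(s.reshape(1))
        if len(scores) == 1:
            return per_type[0]
        w = scores[0]
        for s in scores[1:]:
            w = _concat1d(w, s)
        gamma = w.softmax(axis=0)
        out = per_type[0] * gamma_entry(gamma, 0)
        for i, z in enumerate(per_type[1:], start=1):
            out = out + z * gamma_entry(gamma, i)
        return out

    def _metapath(self, params, HP, op_ppp: Tensor) -> Tensor:
        z_ppp = op_ppp @ HP
        per_path = [z_ppp]
        if self.has_rna:
            per_path.append(self._op_prp @ HP)
        return self._fuse(per_path, params.mu_mp, params.W_m, params.b_m)

    def forward(self, training: bool = False) -> dict[str, tuple[Tensor, Tensor]]:
        """Return ``{"wide": (Z_stra, Z_mp), "deep": (Z_stra, Z_mp)}``."""
        out: dict[str, tuple[Tensor, Tensor]] = {}
        adj = {"wide": self.wide_adjacency(), "deep": self.deep_adjacency()}
        support = {"wide": self._support_wide, "deep": self._support_deep}
        op_ppp = {"wide": self._op_ppp_wide, "deep": self._op_ppp_deep}
        for tag in ("wide", "deep"):
            params = self.agg[tag]
            HP = self._dropout(self.X_P @ params.W_P, training)
            HR = self._dropout(self.X_R @ params.W_R, training)
            z_stra = self._first_order(params, HP, HR, adj[tag], support[tag])
            z_mp = self._metapath(params, HP, op_ppp[tag])
            out[tag] = (z_stra, z_mp)
        return out

    def embed(self) -> dict[str, ViewEmbeddings]:
        """Evaluation-mode view embeddings as plain arrays."""
        views = self.forward(training=False)
        return {
            tag: ViewEmbeddings(z_stra.data.copy(), z_mp.data.copy())
            for tag, (z_stra, z_mp) in views.items()
        }


def _concat1d(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two 1-d tensors (used for the tiny type-score vectors)."""
    na, nb = a.shape[0], b.shape[0]
    Pa = constant(np.vstack([np.eye(na), np.zeros((nb, na))]))
    Pb = constant(np.vstack([np.zeros((na, nb)), np.eye(nb)]))
    return (Pa @ a.reshape(na, 1) + Pb @ b.reshape(nb, 1)).reshape(na + nb)


def gamma_entry(gamma: Tensor, i: int) -> Tensor:
    """Select one softmax weight as a scalar tensor."""
    e = np.zeros(gamma.shape[0])
    e[i] = 1.0
    return (gamma * constant(e)).sum()
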