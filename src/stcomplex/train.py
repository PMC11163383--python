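"""Contrastive training of the dual-view encoder.

Two InfoNCE-style objectives are optimised jointly: an inter-view loss that
aligns each protein's first-order-view and meta-path-view embeddings within
an aggregator (one term per aggregator), and an inter-pattern loss that
aligns the wide-domain and deep-domain pattern embeddings.  The positive
pair is always the same protein seen from the other side; every other
protein in the opposite side serves as a negative, and the positive is kept
in the denominator.  Similarity is cosine, scaled by a temperature.

The final representation is the average of the two pattern embeddings,
``Z = (Z_wide + Z_deep) / 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, constant
from .encoder import DualViewModel, EncoderConfig
from .mhpin import MHPIN, PatternStack

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    tau_stru: float = 0.5
    tau_pat: float = 0.5
    epochs: int = 400
    lr: float = 5e-3
    seed: int = 0
    patience: int = 50  # early stop when the loss moving average plateaus
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self) -> None:
        if self.tau_stru <= 0 or self.tau_pat <= 0:
            raise ValueError("temperatures must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainResult:
    Z: np.ndarray  # (nP, d) final embedding
    Z_wide: np.ndarray
    Z_deep: np.ndarray
    proteins: list[str]
    losses: list[float]
    config: TrainConfig

    def embedding_dict(self) -> dict[str, np.ndarray]:
        return {p: self.Z[i] for i, p in enumerate(self.proteins)}


# ---------------------------------------------------------------------------
# reference (numpy) losses


def _check_rows(Z: np.ndarray, name: str) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    norms = np.linalg.norm(Z, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{name} has zero-norm rows; cosine similarity undefined")
    return Z / norms[:, None]


def view_contrast_loss(Z_a: np.ndarray, Z_b: np.ndarray, tau: float) -> float:
    """InfoNCE loss between two views of the same node set.

    For each row ``p`` the positive is row ``p`` of the other view and the
    denominator runs over all rows of the other view (positive included).
    Zero-norm rows raise, since cosine similarity is undefined there.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    A = _check_rows(Z_a, "Z_a")
    B = _check_rows(Z_b, "Z_b")
    if A.shape != B.shape:
        raise ValueError("view matrices must have identical shapes")
    S = (A @ B.T) / tau
    row_max = S.max(axis=1, keepdims=True)
    lse = np.log(np.exp(S - row_max).sum(axis=1)) + row_max[:, 0]
    return float((lse - np.diag(S)).sum())


def pattern_contrast_loss(Z_wide: np.ndarray, Z_deep: np.ndarray, tau: float) -> float:
    """Same contract as :func:`view_contrast_loss`, across pattern embeddings."""
    return view_contrast_loss(Z_wide, Z_deep, tau)


# ---------------------------------------------------------------------------
# tensor loss and training loop


def _cosine_rows_t(Z: Tensor) -> Tensor:
    norm = ((Z * Z).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    return Z / norm


def _nce_t(Za: Tensor, Zb: Tensor, tau: float) -> Tensor:
    n = Za.shape[0]
    S = (_cosine_rows_t(Za) @ _cosine_rows_t(Zb).T) / tau
    lse = S.logsumexp_rows()
    diag = (S * constant(np.eye(n))).sum(axis=1)
    return (lse - diag).sum()


def train(mhpin: MHPIN, patterns: PatternStack, config: TrainConfig) -> TrainResult:
    """Jointly optimise encoder parameters, pattern weights and features.

    Reproducible for a fixed seed; aborts if the loss stops being finite.
    """
    enc_cfg = config.encoder
    enc_cfg = EncoderConfig(
        feature_dim=enc_cfg.feature_dim,
        hidden_dim=enc_cfg.hidden_dim,
        dropout=enc_cfg.dropout,
        topk=enc_cfg.topk,
        seed=config.seed,
    )
    model = DualViewModel(mhpin, patterns, enc_cfg)
    opt = Adam(model.parameters(), lr=config.lr)
    losses: list[float] = []
    best_avg = np.inf
    stall = 0
    for epoch in range(config.epochs):
        views = model.forward(training=True)
        zw_stra, zw_mp = views["wide"]
        zd_stra, zd_mp = views["deep"]
        z_wide = (zw_stra + zw_mp) * 0.5
        z_deep = (zd_stra + zd_mp) * 0.5
        loss = (
            _nce_t(zw_stra, zw_mp, config.tau_stru)
            + _nce_t(zd_stra, zd_mp, config.tau_stru)
            + _nce_t(z_wide, z_deep, config.tau_pat)
        )
        val = loss.item()
        if not np.isfinite(val):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={val!r}"
            )
        losses.append(val)
        opt.zero_grad()
        loss.backward()
        opt.step()

        window = np.mean(losses[-10:])
        if window < best_avg - 1e-6:
            best_avg = window
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                logger.info("early stop at epoch %d (loss plateau)", epoch)
                break

    emb = model.embed()
    Z_wide = emb["wide"].Z_pattern
    Z_deep = emb["deep"].Z_pattern
    Z = 0.5 * (Z_wide + Z_deep)
    return TrainResult(Z, Z_wide, Z_deep, list(mhpin.proteins), losses, config)
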