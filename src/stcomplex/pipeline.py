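"""End-to-end pipeline: build network, embed, identify, evaluate."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import ComplexSet, ExpressionTable, LocalizationTable, RnaAssocTable
from .metrics import EvaluationReport, evaluate
from .mhpin import (
    build_mhpin,
    build_patterns,
    compute_activity,
    select_rna_partners,
    single_layer_patterns,
)
from .identify import identify_complexes
from .train import TrainConfig, TrainResult, train

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    k: float = 1.0  # activity threshold multiplier
    lam: float = 0.4  # attachment adhesion threshold
    spatiotemporal: bool = True  # False: keep all edges, single pattern layer
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class PipelineResult:
    complexes: ComplexSet
    training: TrainResult
    n_patterns: int
    n_retained_edges: int


def run_pipeline(
    edges: list[tuple[str, str]],
    expression: ExpressionTable,
    localization: LocalizationTable,
    rna_assoc: RnaAssocTable,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full method on in-memory inputs.

    With ``config.spatiotemporal=False`` the spatiotemporal constraints are
    ablated: every input edge is kept, the pattern stack degenerates to a
    single all-edges layer, and core candidates skip the co-activity check.
    """
    config = config or PipelineConfig()
    activity = compute_activity(expression, config.k)
    rna_edges = select_rna_partners(rna_assoc)
    mhpin = build_mhpin(
        edges,
        activity,
        localization,
        rna_edges,
        spatiotemporal_filter=config.spatiotemporal,
    )
    if config.spatiotemporal:
        patterns = build_patterns(mhpin, expression.T)
    else:
        patterns = single_layer_patterns(mhpin)
    logger.info(
        "network: %d proteins, %d/%d edges retained, %d pattern layers",
        mhpin.n_proteins, len(mhpin.ppi_edges), len(edges), patterns.M,
    )
    result = train(mhpin, patterns, config.train)
    complexes = identify_complexes(
        result.embedding_dict(),
        edges,
        activity if config.spatiotemporal else None,
        localization if config.spatiotemporal else None,
        lam=config.lam,
    )
    return PipelineResult(
        complexes=complexes,
        training=result,
        n_patterns=patterns.M,
        n_retained_edges=len(mhpin.ppi_edges),
    )


def evaluate_against(
    predicted: ComplexSet, reference: ComplexSet
) -> EvaluationReport:
    return evaluate(predicted, reference)
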