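import numpy as np
import pytest

from stcomplex import (
    PipelineConfig,
    SimConfig,
    TrainConfig,
    evaluate,
    generate_benchmark,
    run_pipeline,
)
from stcomplex.encoder import EncoderConfig
from stcomplex.io import ComplexSet
from stcomplex.mhpin import build_mhpin, build_patterns, compute_activity
from stcomplex.simulate import Bundle


@pytest.fixture(scope="session")
def small_bundle() -> Bundle:
    """A 60-protein benchmark with 4 planted complexes."""
    return generate_benchmark(
        SimConfig(n_proteins=60, n_complexes=4, n_rnas=12, seed=7)
    )


@pytest.fixture(scope="session")
def small_network(small_bundle):
    """(mhpin, patterns, activity) built from the small bundle."""
    activity = compute_activity(small_bundle.expression, k=1.0)
    from stcomplex.mhpin import select_rna_partners

    rna_edges = select_rna_partners(small_bundle.rna_assoc)
    mhpin = build_mhpin(
        small_bundle.edges, activity, small_bundle.localization, rna_edges
    )
    patterns = build_patterns(mhpin, small_bundle.expression.T)
    return mhpin, patterns, activity


def random_complex_sets(rng, max_complexes=6, max_proteins=10, universe_size=15):
    """Two random toy complex catalogues over a small shared universe."""
    universe = [f"x{i}" for i in range(universe_size)]

    def one_set():
        n = rng.integers(1, max_complexes + 1)
        cs = ComplexSet()
        for _ in range(n):
            size = rng.integers(1, max_proteins + 1)
            cs.add(rng.choice(universe, size=size, replace=False).tolist())
        return cs

    return one_set(), one_set()


@pytest.fixture(scope="session")
def e2e_results():
    """Full and filter-ablated pipeline evaluations on three seeds.

    Study conditions: default benchmark (300 proteins, 20 planted
    complexes), default training configuration.
    """
    out = {}
    for seed in (42, 43, 44):
        bundle = generate_benchmark(SimConfig(seed=seed))
        out[seed] = {}
        for label, spatiotemporal in (("full", True), ("ablated", False)):
            cfg = PipelineConfig(
                spatiotemporal=spatiotemporal,
                train=TrainConfig(seed=seed),
            )
            res = run_pipeline(
                bundle.edges,
                bundle.expression,
                bundle.localization,
                bundle.rna_assoc,
                cfg,
            )
            out[seed][label] = evaluate(res.complexes, bundle.truth)
    return out
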