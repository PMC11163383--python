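"""Seeded synthetic benchmarks with planted core-attachment complexes.

The generator emulates the statistical shape of the real inputs: a yeast-
scale time-course (12 points, one elevated activity window per protein), an
11-compartment localisation table, regulator/decoy RNA association scores,
and a PPI network whose planted complexes are dense cores plus loosely
attached peripherals, on top of background noise edges.  Every complex's
members share an activity window and a home compartment, so their edges
survive the spatiotemporal filter by construction; background proteins get
their own random windows and compartments, so background edges survive
only by chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    COMPARTMENTS,
    Complex,
    ComplexSet,
    ExpressionTable,
    LocalizationTable,
    RnaAssocTable,
)


@dataclass
class SimConfig:
    n_proteins: int = 300
    n_complexes: int = 20
    core_size_min: int = 3
    core_size_max: int = 6
    attachments_min: int = 0
    attachments_max: int = 3
    p_within_core: float = 0.9
    p_background: float = 0.02
    T: int = 12
    n_compartments: int = 11
    window_length: int = 4
    baseline: float = 3.0
    amplitude: float = 2.0
    noise_sd: float = 0.3
    n_rnas: int = 60
    rnas_per_complex: int = 2
    decoy_assoc_per_protein: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_within_core, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must lie in [0, 1]")
        if self.core_size_min < 3:
            raise ValueError("cores need at least 3 proteins")
        if self.n_compartments > len(COMPARTMENTS):
            raise ValueError(f"at most {len(COMPARTMENTS)} compartments available")
        max_members = self.n_complexes * (self.core_size_max + self.attachments_max)
        if max_members > self.n_proteins:
            raise ValueError(
                "protein pool too small for the requested complexes"
            )


@dataclass
class Bundle:
    """A complete generated input set plus the planted truth."""

    edges: list[tuple[str, str]]
    expression: ExpressionTable
    localization: LocalizationTable
    rna_assoc: RnaAssocTable
    truth: ComplexSet
    config: SimConfig
    windows: dict[str, tuple[int, int]]  # protein -> [start, end) 0-based
    compartment_of: dict[str, str]  # planted home compartment per complex member


def generate_benchmark(config: SimConfig) -> Bundle:
    """Plant complexes into a noisy network; fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]
    rnas = [f"R{i:03d}" for i in range(config.n_rnas)]
    compartments = list(COMPARTMENTS[: config.n_compartments])

    pool = list(proteins)
    rng.shuffle(pool)
    truth = ComplexSet()
    edges: set[tuple[str, str]] = set()
    windows: dict[str, tuple[int, int]] = {}
    compartment_of: dict[str, str] = {}
    loc: dict[str, set[str]] = {p: set() for p in proteins}
    complex_members: list[list[str]] = []
    complex_cores: list[list[str]] = []
    complex_windows: list[tuple[int, int]] = []
    complex_compartments: list[str] = []

    def add_edge(a: str, b: str) -> None:
        edges.add((a, b) if a < b else (b, a))

    for _ in range(config.n_complexes):
        core_size = int(rng.integers(config.core_size_min, config.core_size_max + 1))
        n_attach = int(rng.integers(config.attachments_min, config.attachments_max + 1))
        members = [pool.pop() for _ in range(core_size + n_attach)]
        core, attachments = members[:core_size], members[core_size:]
        start = int(rng.integers(0, config.T - config.window_length + 1))
        window = (start, start + config.window_length)
        home = compartments[int(rng.integers(len(compartments)))]
        for p in members:
            windows[p] = window
            compartment_of[p] = home
            loc[p].add(home)
            if rng.random() < 0.3:  # occasional secondary location
                loc[p].add(compartments[int(rng.integers(len(compartments)))])
        for a, b in _pairs(core):
            if rng.random() < config.p_within_core:
                add_edge(a, b)
        half = math.ceil(core_size / 2)
        for p in attachments:
            n_links = int(rng.integers(half, core_size + 1))
            for q in rng.choice(core, size=n_links, replace=False):
                add_edge(p, str(q))
        truth.add(members, core=core)
        complex_members.append(members)
        complex_cores.append(core)
        complex_windows.append(window)
        complex_compartments.append(home)

    # background proteins: individual windows and compartments
    for p in pool:
        start = int(rng.integers(0, config.T - config.window_length + 1))
        windows[p] = (start, start + config.window_length)
        loc[p].add(compartments[int(rng.integers(len(compartments)))])
        if rng.random() < 0.3:
            loc[p].add(compartments[int(rng.integers(len(compartments)))])

    # background noise edges
    for a, b in _pairs(proteins):
        key = (a, b) if a < b else (b, a)
        if key not in edges and rng.random() < config.p_background:
            edges.add(key)

    # expression: elevated inside the window, noisy everywhere
    rows = {}
    for p in proteins:
        start, end = windows[p]
        series = np.full(config.T, config.baseline)
        series[start:end] += config.amplitude
        series += rng.normal(0.0, config.noise_sd, size=config.T)
        rows[p] = np.clip(series, 0.0, None)
    expr = ExpressionTable(
        pd.DataFrame.from_dict(rows, orient="index",
                               columns=[f"t{t}" for t in range(1, config.T + 1)])
    )

    # RNA associations: per-complex regulators score high, decoys low
    assoc_rows: list[tuple[str, str, float]] = []
    regulators = 0
    for ci, members in enumerate(complex_members):
        for _ in range(config.rnas_per_complex):
            if regulators >= config.n_rnas:
                break
            rna = rnas[regulators]
            regulators += 1
            for p in members:
                assoc_rows.append((rna, p, float(rng.uniform(0.7, 0.95))))
    decoys = rnas[regulators:]
    if decoys:
        for p in proteins:
            chosen = rng.choice(decoys, size=min(config.decoy_assoc_per_protein,
                                                 len(decoys)), replace=False)
            for rna in chosen:
                assoc_rows.append((str(rna), p, float(rng.uniform(0.05, 0.4))))
    assoc = RnaAssocTable(
        pd.DataFrame(assoc_rows, columns=["rna", "protein", "score"])
    )

    localization = LocalizationTable({p: frozenset(s) for p, s in loc.items()})
    return Bundle(
        edges=sorted(edges),
        expression=expr,
        localization=localization,
        rna_assoc=assoc,
        truth=truth,
        config=config,
        windows=windows,
        compartment_of=compartment_of,
    )


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def write_bundle(bundle: Bundle, out_dir) -> dict[str, Path]:
    """Serialise the bundle in the standard input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": out / "ppi.tsv",
        "expression": out / "expression.tsv",
        "localization": out / "localization.tsv",
        "rna_assoc": out / "rna_assoc.tsv",
        "complexes": out / "complexes.txt",
    }
    with open(paths["ppi"], "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in bundle.edges:
            fh.write(f"{a}\t{b}\n")
    df = bundle.expression.data.round(6)
    df.index.name = "protein"
    df.to_csv(paths["expression"], sep="\t")
    with open(paths["localization"], "w") as fh:
        fh.write("protein\tcompartment\n")
        for p in sorted(bundle.localization.assignments):
            for c in sorted(bundle.localization.assignments[p]):
                fh.write(f"{p}\t{c}\n")
    bundle.rna_assoc.data.round(6).to_csv(paths["rna_assoc"], sep="\t", index=False)
    with open(paths["complexes"], "w") as fh:
        for c in bundle.truth:
            fh.write(" ".join(sorted(c.members)) + "\n")
    return paths


def summarize_truth(bundle: Bundle) -> dict[str, float]:
    """Realised densities, overlap and filter-survival statistics."""
    from .mhpin import build_mhpin, compute_activity

    edges = set(bundle.edges)
    within = 0
    possible = 0
    member_sets = [set(c.core or c.members) for c in bundle.truth]
    planted = set()
    for core in member_sets:
        for a, b in _pairs(sorted(core)):
            possible += 1
            key = (a, b) if a < b else (b, a)
            if key in edges:
                within += 1
                planted.add(key)

    activity = compute_activity(bundle.expression, k=1.0)
    mhpin = build_mhpin(
        bundle.edges, activity, bundle.localization, rna_edges=[]
    )
    retained = set(mhpin.ppi_edges)
    surviving = len(planted & retained)
    all_members = [c.members for c in bundle.truth]
    overlaps = sum(
        1
        for i in range(len(all_members))
        for j in range(i + 1, len(all_members))
        if all_members[i] & all_members[j]
    )
    return {
        "n_edges": float(len(edges)),
        "within_core_density": within / possible if possible else 0.0,
        "within_core_edges": float(within),
        "core_edge_filter_survival": surviving / within if within else 0.0,
        "overall_filter_survival": len(retained) / len(edges) if edges else 0.0,
        "overlapping_complex_pairs": float(overlaps),
    }
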