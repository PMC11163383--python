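"""Readers and writers for the tabular inputs and complex catalogues.

All tables are tab-separated with a single header line.  Protein and RNA
identifiers are opaque, case-sensitive strings (yeast systematic names in
practice); no normalisation is attempted.  Complex catalogues use the
de-facto benchmark format: one complex per line, members separated by
whitespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical subcellular compartment vocabulary for budding yeast.
COMPARTMENTS = (
    "extracellular_space",
    "nucleus",
    "mitochondrion",
    "endosome",
    "vacuole",
    "peroxisome",
    "endoplasmic_reticulum",
    "golgi_apparatus",
    "cytosol",
    "cytoskeleton",
    "plasma_membrane",
)


@dataclass(frozen=True)
class Complex:
    """A protein complex: a member set with an optional core subset."""

    members: frozenset[str]
    core: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a complex must contain at least one protein")
        if self.core is not None and not self.core <= self.members:
            raise ValueError("core must be a subset of the complex members")

    def __len__(self) -> int:
        return len(self.members)


class ComplexSet:
    """Ordered collection of :class:`Complex` objects."""

    def __init__(self, complexes: list[Complex] | None = None):
        self.complexes: list[Complex] = list(complexes or [])

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def __getitem__(self, i: int) -> Complex:
        return self.complexes[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return [c.members for c in self] == [c.members for c in other]

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]

    def add(self, members, core=None) -> None:
        self.complexes.append(
            Complex(frozenset(members), frozenset(core) if core is not None else None)
        )


@dataclass
class ExpressionTable:
    """Per-protein time-course expression series, all of length ``T``."""

    data: pd.DataFrame  # index: protein, columns: t1..tT

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein IDs in expression table: {dup}")
        if self.data.shape[1] < 1:
            raise ValueError("expression table needs at least one time point")

    @property
    def T(self) -> int:
        return self.data.shape[1]

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    def series(self, protein: str) -> np.ndarray:
        return self.data.loc[protein].to_numpy(dtype=float)

    def __contains__(self, protein: str) -> bool:
        return protein in self.data.index


@dataclass
class LocalizationTable:
    """Protein -> set of subcellular compartment labels."""

    assignments: dict[str, frozenset[str]]

    def locations(self, protein: str) -> frozenset[str]:
        return self.assignments.get(protein, frozenset())

    @property
    def compartments(self) -> list[str]:
        seen = set()
        for s in self.assignments.values():
            seen |= s
        # canonical labels first in canonical order, then extras sorted
        canon = [c for c in COMPARTMENTS if c in seen]
        extra = sorted(seen - set(COMPARTMENTS))
        return canon + extra


@dataclass
class RnaAssocTable:
    """Rows of (rna, protein, score) association strengths."""

    data: pd.DataFrame  # columns: rna, protein, score

    def __post_init__(self) -> None:
        d = self.data
        if list(d.columns) != ["rna", "protein", "score"]:
            raise ValueError("RNA association table must have columns rna, protein, score")
        if d.duplicated(["rna", "protein"]).any():
            raise ValueError("duplicate (rna, protein) pairs in association table")
        if not np.isfinite(d["score"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite association scores")


@dataclass
class ParseReport:
    """Bookkeeping for rows dropped or flagged while reading inputs."""

    duplicate_edges: int = 0
    self_loops: int = 0
    flagged_proteins: list[str] = field(default_factory=list)

    def log(self) -> None:
        if self.duplicate_edges or self.self_loops:
            logger.info(
                "PPI cleanup: removed %d duplicate edges, %d self-loops",
                self.duplicate_edges,
                self.self_loops,
            )
        if self.flagged_proteins:
            logger.info(
                "%d proteins appear only in auxiliary tables", len(self.flagged_proteins)
            )


# ---------------------------------------------------------------------------
# complex catalogues


def read_complexes(path) -> ComplexSet:
    """Read a one-complex-per-line whitespace-separated catalogue.

    Duplicate members within a line are collapsed; line order is preserved.
    An empty file yields an empty :class:`ComplexSet` with a warning.
    """
    path = Path(path)
    out = ComplexSet()
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            out.add(tokens)
    if len(out) == 0:
        logger.warning("complex file %s contains no complexes", path)
    return out


def write_complexes(complexes: ComplexSet, path) -> None:
    """Write a catalogue in the same one-per-line format (members sorted)."""
    with open(path, "w") as fh:
        for c in complexes:
            fh.write(" ".join(sorted(c.members)) + "\n")


# ---------------------------------------------------------------------------
# tabular inputs


def read_ppi(path, report: ParseReport | None = None) -> list[tuple[str, str]]:
    """Read an undirected PPI edge list; drops self-loops and duplicates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["protein_a", "protein_b"]:
        raise ValueError(f"{path}: expected columns protein_a, protein_b")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}: malformed row at line {bad}")
    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    loops = dups = 0
    for a, b in df.itertuples(index=False):
        if a == b:
            loops += 1
            continue
        key = frozenset((a, b))
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        edges.append((a, b) if a < b else (b, a))
    if report is not None:
        report.duplicate_edges += dups
        report.self_loops += loops
    return edges


def read_expression(path, expected_T: int | None = None) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad_protein = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: malformed expression row for {bad_protein!r}")
    if expected_T is not None and df.shape[1] != expected_T:
        raise ValueError(
            f"{path}: expected {expected_T} time points, found {df.shape[1]}"
        )
    return ExpressionTable(df.astype(float))


def read_localization(path) -> LocalizationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["protein", "compartment"]:
        raise ValueError(f"{path}: expected columns protein, compartment")
    if df.isna().any().any() or (df["compartment"].str.len() == 0).any():
        raise ValueError(f"{path}: malformed localization row")
    table: dict[str, set[str]] = {}
    for p, c in df.itertuples(index=False):
        table.setdefault(p, set()).add(c)
    return LocalizationTable({p: frozenset(s) for p, s in table.items()})


def read_rna_assoc(path) -> RnaAssocTable:
    df = pd.read_csv(path, sep="\t", dtype={"rna": str, "protein": str, "score": float})
    if list(df.columns) != ["rna", "protein", "score"]:
        raise ValueError(f"{path}: expected columns rna, protein, score")
    if df[["rna", "protein"]].isna().any().any():
        raise ValueError(f"{path}: malformed association row")
    return RnaAssocTable(df)


def read_tables(
    ppi_path,
    expression_path,
    localization_path,
    rna_assoc_path,
    expected_T: int | None = None,
):
    """Read the four input tables and cross-check protein coverage.

    Returns ``(edges, expression, localization, rna_assoc, report)``.
    Proteins that appear only in auxiliary tables (never in the PPI network)
    are retained but flagged in the parse report.
    """
    report = ParseReport()
    edges = read_ppi(ppi_path, report)
    expr = read_expression(expression_path, expected_T)
    loc = read_localization(localization_path)
    assoc = read_rna_assoc(rna_assoc_path)

    ppi_proteins = {p for e in edges for p in e}
    aux = set(expr.proteins) | set(loc.assignments) | set(assoc.data["protein"])
    report.flagged_proteins = sorted(aux - ppi_proteins)
    report.log()
    return edges, expr, loc, assoc, report
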