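"""Clonotype identity and repertoire statistics.

A clonotype is identified at the level the field calls a "clone": the TRBV
gene *family*, the TRBJ gene *family*, and the CDR3β amino-acid sequence.
Cells or sequencing reads agreeing on all three are treated as descendants
of one ancestral V(D)J rearrangement.  This module owns that identity, the
α-chain rescue of cells whose β chain went undetected, per-clone phenotype
classification from single-cell metacluster labels, abundance-weighted
diversity and overlap measures (Shannon, Morisita-Horn), the IFNγ-capture
specificity filter used to flag microbe-reactive (bystander) clones, and
exact paired-chain lookup against a database of TCRs with known antigen
specificity.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "METACLUSTERS",
    "InvalidGeneError",
    "NonProductiveError",
    "CloneKey",
    "AlphaChain",
    "CellRecord",
    "RepertoireCounts",
    "PhenotypeCall",
    "RankEntry",
    "VdjdbRecord",
    "normalize_gene_family",
    "build_clone_key",
    "rescue_beta_by_alpha",
    "aggregate_repertoire",
    "shannon_index",
    "morisita_horn",
    "pairwise_overlap_matrix",
    "classify_clone_phenotype",
    "clone_rank_cumulative",
    "cefx_specific_clones",
    "bystander_fraction",
    "vdjdb_lookup",
]

#: the 20 proteinogenic one-letter codes; '*' (stop) and '_' (frameshift)
#: mark non-productive junctions and are rejected.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: transcriptional metaclusters of PD-1+ CD8+ T cells: A (terminally
#: differentiated), B/C (progenitor/memory-like), D (dividing), plus
#: blood-derived naive cells and cells without a label.
METACLUSTERS = ("A", "B", "C", "D", "naive", "unassigned")

_GENE_PREFIXES = ("TRAV", "TRAJ", "TRBV", "TRBJ")


class InvalidGeneError(ValueError):
    """Raised for segment names that are empty or not TRA/TRB V/J genes."""


class NonProductiveError(ValueError):
    """Raised for CDR3 sequences containing a stop ('*') or frameshift ('_')."""


def normalize_gene_family(gene: str) -> str:
    """Reduce an IMGT-style segment name to its gene family.

    The family is the name before the hyphenated member index, after
    removing any allele suffix (``*01``).  Multi-gene annotations such as
    ``TRBV20-1/TRBV20OR9-2`` use the first listed gene.

    >>> normalize_gene_family("TRBV6-2*01")
    'TRBV6'
    >>> normalize_gene_family("TRBJ2-7")
    'TRBJ2'
    """
    if not gene or not gene.strip():
        raise InvalidGeneError("empty gene name")
    first = gene.strip().split("/")[0]
    first = first.split("*")[0]
    family = first.split("-")[0].strip()
    if not family.startswith(_GENE_PREFIXES):
        raise InvalidGeneError(f"not a TRA/TRB V or J segment name: {gene!r}")
    return family


@dataclass(frozen=True, order=True)
class CloneKey:
    """Clonotype identity: TRBV family, TRBJ family, CDR3β amino acids."""

    v_family: str
    j_family: str
    cdr3_aa: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.v_family}|{self.j_family}|{self.cdr3_aa}"


def build_clone_key(v_call: str, j_call: str, cdr3_aa: str) -> CloneKey:
    """Build the family-level clonotype key from raw V/J calls and a CDR3.

    Segment names are collapsed to their families so that e.g. TRBV6-2 and
    TRBV6-3 rearrangements with the same junction compare equal.  CDR3s
    containing a stop ('*') or frameshift ('_') are non-productive and
    rejected with :class:`NonProductiveError`; callers should count, not
    crash on, such records.
    """
    if not cdr3_aa:
        raise NonProductiveError("empty CDR3 amino-acid sequence")
    if "*" in cdr3_aa or "_" in cdr3_aa:
        raise NonProductiveError(f"non-productive CDR3: {cdr3_aa!r}")
    bad = set(cdr3_aa) - AMINO_ACIDS
    if bad:
        raise NonProductiveError(
            f"CDR3 {cdr3_aa!r} contains non-amino-acid characters {sorted(bad)}"
        )
    v_family = normalize_gene_family(v_call)
    j_family = normalize_gene_family(j_call)
    if not v_family.startswith("TRBV"):
        raise InvalidGeneError(f"expected a TRBV segment, got {v_call!r}")
    if not j_family.startswith("TRBJ"):
        raise InvalidGeneError(f"expected a TRBJ segment, got {j_call!r}")
    return CloneKey(v_family, j_family, cdr3_aa)


class AlphaChain(NamedTuple):
    """One TCRα contig call; identity for rescue is (v_gene, j_gene, cdr3_nt)."""

    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str

    @property
    def identity(self) -> tuple[str, str, str]:
        return (self.v_gene, self.j_gene, self.cdr3_nt)


@dataclass(frozen=True)
class CellRecord:
    """A single cell barcode with its chain calls and annotations.

    ``beta`` is the family-level clonotype; the raw gene-level β calls are
    retained separately because database lookup requires exact genes, not
    families.  ``beta_is_rescued`` marks assignments inferred via a shared
    α chain rather than a sequenced β contig.
    """

    cell_id: str
    beta: Optional[CloneKey] = None
    alphas: tuple[AlphaChain, ...] = ()
    metacluster: str = "unassigned"
    patient: str = ""
    compartment: str = "tumor"
    beta_v_gene: Optional[str] = None
    beta_j_gene: Optional[str] = None
    beta_cdr3_aa: Optional[str] = None
    beta_is_rescued: bool = False

    def __post_init__(self) -> None:
        if self.metacluster not in METACLUSTERS:
            raise ValueError(f"unknown metacluster {self.metacluster!r}")
        if self.compartment not in ("tumor", "blood"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


def rescue_beta_by_alpha(cells: Sequence[CellRecord]) -> list[CellRecord]:
    """Assign β clonotypes to β-less cells via unambiguous shared α chains.

    A cell lacking a β chain but carrying at least one α receives clonotype
    K if and only if every cell sharing any of its α chains (exact V gene,
    J gene, and nucleotide CDR3) and carrying a *sequenced* β maps to K, and
    at least one such cell exists.  Conflicting or absent evidence leaves
    the cell unassigned.  Determined β assignments are never modified, and
    rescued assignments never serve as evidence, so the operation is
    idempotent.
    """
    evidence: dict[tuple[str, str, str], set[CloneKey]] = defaultdict(set)
    for cell in cells:
        if cell.beta is not None and not cell.beta_is_rescued:
            for alpha in cell.alphas:
                evidence[alpha.identity].add(cell.beta)

    out: list[CellRecord] = []
    for cell in cells:
        if cell.beta is not None or not cell.alphas:
            out.append(cell)
            continue
        candidates: set[CloneKey] = set()
        ambiguous = False
        for alpha in cell.alphas:
            betas = evidence.get(alpha.identity)
            if not betas:
                continue
            if len(betas) > 1:
                ambiguous = True
                break
            candidates.update(betas)
        if not ambiguous and len(candidates) == 1:
            key = next(iter(candidates))
            out.append(replace(cell, beta=key, beta_is_rescued=True))
        else:
            out.append(cell)
    return out


@dataclass
class RepertoireCounts:
    """A clone → count table for one population (sorted cells or templates)."""

    entries: dict[CloneKey, int] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for key, count in self.entries.items():
            if count < 1:
                raise ValueError(f"count for {key} must be >= 1, got {count}")

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def count(self, key: CloneKey) -> int:
        return self.entries.get(key, 0)

    def frequency(self, key: CloneKey) -> float:
        total = self.total
        return self.entries.get(key, 0) / total if total else 0.0

    def __len__(self) -> int:
        return len(self.entries)


def aggregate_repertoire(
    records: Iterable[tuple[CloneKey, int]], label: str = ""
) -> RepertoireCounts:
    """Sum positive integer weights (cells or templates) per clonotype."""
    entries: dict[CloneKey, int] = defaultdict(int)
    for key, weight in records:
        if weight < 1:
            raise ValueError(f"weights must be positive integers, got {weight}")
        entries[key] += weight
    return RepertoireCounts(dict(entries), label=label)


def shannon_index(rep: RepertoireCounts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) of clone frequencies."""
    total = rep.total
    if total < 1:
        raise ValueError("Shannon index is undefined for an empty repertoire")
    p = np.asarray(list(rep.entries.values()), dtype=float) / total
    return float(-(p * np.log(p)).sum())


def morisita_horn(x: RepertoireCounts, y: RepertoireCounts) -> float:
    """Morisita-Horn overlap between two clone-count tables.

    MH = 2 sum(x_i y_i) / ((d_x + d_y) X Y) with X = sum x_i, Y = sum y_i,
    d_x = sum x_i^2 / X^2 (Simpson concentration), analogously d_y; counts
    of clones absent from one table are zero.  Ranges from 0 (disjoint) to
    1 (identical frequency vectors).
    """
    X, Y = x.total, y.total
    if X < 1 or Y < 1:
        raise ValueError("Morisita-Horn is undefined for an empty repertoire")
    keys = set(x.entries) | set(y.entries)
    xv = np.array([x.count(k) for k in keys], dtype=float)
    yv = np.array([y.count(k) for k in keys], dtype=float)
    d_x = float((xv**2).sum()) / X**2
    d_y = float((yv**2).sum()) / Y**2
    return float(2.0 * (xv * yv).sum() / ((d_x + d_y) * X * Y))


def pairwise_overlap_matrix(reps: Sequence[RepertoireCounts]) -> np.ndarray:
    """Symmetric matrix of Morisita-Horn overlaps; diagonal 1.

    Rows/columns for empty repertoires are NaN (undefined), including the
    diagonal.
    """
    if len(reps) < 2:
        raise ValueError("need at least two repertoires")
    n = len(reps)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        if reps[i].total >= 1:
            mat[i, i] = 1.0
        for j in range(i + 1, n):
            if reps[i].total >= 1 and reps[j].total >= 1:
                mat[i, j] = mat[j, i] = morisita_horn(reps[i], reps[j])
    return mat


@dataclass(frozen=True)
class PhenotypeCall:
    """Majority phenotype of a clone over its single-cell metacluster labels."""

    clone: CloneKey
    call: str  # "AD", "BC", "ambiguous", or "unclassified"
    n_cells_A: int = 0
    n_cells_B: int = 0
    n_cells_C: int = 0
    n_cells_D: int = 0

    @property
    def n_counted(self) -> int:
        return self.n_cells_A + self.n_cells_B + self.n_cells_C + self.n_cells_D


def classify_clone_phenotype(
    clone: CloneKey, cells: Iterable[CellRecord]
) -> PhenotypeCall:
    """Classify a clone as A/D-dominant or B/C-dominant by strict cell majority.

    Only cells carrying the clone with metacluster A-D are counted; naive
    and unassigned cells are ignored.  Ties with at least one counted cell
    are ``ambiguous``; no counted cells gives ``unclassified``.
    """
    counts = {"A": 0, "B": 0, "C": 0, "D": 0}
    for cell in cells:
        if cell.beta == clone and cell.metacluster in counts:
            counts[cell.metacluster] += 1
    ad = counts["A"] + counts["D"]
    bc = counts["B"] + counts["C"]
    if ad + bc == 0:
        call = "unclassified"
    elif ad > bc:
        call = "AD"
    elif bc > ad:
        call = "BC"
    else:
        call = "ambiguous"
    return PhenotypeCall(
        clone=clone,
        call=call,
        n_cells_A=counts["A"],
        n_cells_B=counts["B"],
        n_cells_C=counts["C"],
        n_cells_D=counts["D"],
    )


class RankEntry(NamedTuple):
    clone: CloneKey
    rank: int
    frequency: float
    cumulative_frequency: float


def clone_rank_cumulative(rep: RepertoireCounts) -> list[RankEntry]:
    """Rank clones by descending abundance with cumulative frequencies.

    Ties are broken lexicographically on the clone key so the ranking is
    deterministic.  The final cumulative frequency is 1.0.
    """
    total = rep.total
    if total < 1:
        return []
    ordered = sorted(rep.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[RankEntry] = []
    running = 0
    for rank, (key, count) in enumerate(ordered, start=1):
        running += count
        out.append(RankEntry(key, rank, count / total, running / total))
    return out


def cefx_specific_clones(
    pos: RepertoireCounts,
    neg: RepertoireCounts,
    min_count: int = 2,
    min_ratio: float = 5.0,
) -> set[CloneKey]:
    """Clones specific for the stimulating (CEFX) peptide pool.

    A clone is called specific if it appears at least ``min_count`` times in
    the IFNγ+ (secreting) population and its frequency there is at least
    ``min_ratio`` times its frequency in the IFNγ- population.  Clones
    absent from the IFNγ- table have zero frequency and pass the ratio
    clause whenever the count clause holds.
    """
    if pos.total < 1:
        return set()
    neg_total = neg.total
    out: set[CloneKey] = set()
    for key, count in pos.entries.items():
        if count < min_count:
            continue
        freq_pos = count / pos.total
        freq_neg = neg.count(key) / neg_total if neg_total else 0.0
        if freq_pos >= min_ratio * freq_neg:
            out.add(key)
    return out


def bystander_fraction(
    population: Sequence[CellRecord], specific: set[CloneKey]
) -> float:
    """Percentage of cells whose clonotype is in the given specific set."""
    if not population:
        raise ValueError("bystander fraction is undefined for an empty population")
    n_specific = sum(
        1 for cell in population if cell.beta is not None and cell.beta in specific
    )
    return 100.0 * n_specific / len(population)


@dataclass(frozen=True)
class VdjdbRecord:
    """One paired-chain entry of a known-specificity TCR database."""

    cdr3_a: str
    trav: str
    traj: str
    cdr3_b: str
    trbv: str
    trbj: str
    epitope: str = ""
    species: str = ""
    complex_id: str = ""


def _strip_allele(gene: str) -> str:
    return gene.split("*")[0].strip()


def vdjdb_lookup(
    cell: CellRecord, db: Sequence[VdjdbRecord]
) -> list[VdjdbRecord]:
    """Exact paired-chain lookup against a known-specificity database.

    A match requires all six fields equal at the gene level (alleles
    stripped, families not collapsed): CDR3α, TRAV, TRAJ, CDR3β, TRBV,
    TRBJ.  Cells lacking a sequenced β chain or any α chain cannot match.
    """
    if cell.beta_cdr3_aa is None or cell.beta_v_gene is None or cell.beta_j_gene is None:
        return []
    if not cell.alphas:
        return []
    trbv = _strip_allele(cell.beta_v_gene)
    trbj = _strip_allele(cell.beta_j_gene)
    matches: list[VdjdbRecord] = []
    for rec in db:
        if rec.cdr3_b != cell.beta_cdr3_aa:
            continue
        if _strip_allele(rec.trbv) != trbv or _strip_allele(rec.trbj) != trbj:
            continue
        for alpha in cell.alphas:
            if (
                rec.cdr3_a == alpha.cdr3_aa
                and _strip_allele(rec.trav) == _strip_allele(alpha.v_gene)
                and _strip_allele(rec.traj) == _strip_allele(alpha.j_gene)
            ):
                matches.append(rec)
                break
    return matches
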