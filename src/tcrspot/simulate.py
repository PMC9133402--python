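"""Synthetic tissues, repertoires, cell tables, and barcoded reads.

Everything the pipeline consumes can be generated here with known ground
truth: a hexagonal capture-spot grid with a contiguous disc-shaped tumor
region, a Zipf-distributed clone repertoire whose clones carry an A/D
(terminally differentiated / dividing) or B/C (progenitor / memory-like)
phenotype, spot placements of clone UMIs with phenotype-dependent tumor
probability, paired FASTQ reads with configurable per-base substitution
error, matched single-cell contig and metadata tables, and IFNγ-capture
count tables with a designated microbe-specific clone set.

All generators are deterministic for a fixed seed; stage seeds are derived
from the master seed so each stage's output is reproducible independently.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .caller import SegmentReference
from .capture import SpatialCloneMatrix
from .repertoire import (
    AlphaChain,
    CellRecord,
    CloneKey,
    RepertoireCounts,
    build_clone_key,
    cefx_specific_clones,
)
from .spatial import DEFAULT_PITCH_UM, SpotGrid, hex_array_to_um

__all__ = [
    "SimulationConfig",
    "Molecule",
    "toy_segment_references",
    "generate_whitelist",
    "simulate_tissue",
    "simulate_repertoire",
    "simulate_spatial_umis",
    "emit_fastq",
    "simulate_cells",
    "simulate_cefx_tables",
]

_DNA = np.array(list("ACGT"))

# small fixed segment set: enough V/J variety to exercise family
# normalization (two TRBV6 members) and deterministic tie-breaking
TOY_V_NAMES = ("TRBV2", "TRBV6-2", "TRBV6-3", "TRBV9", "TRBV20-1", "TRBV28")
TOY_J_NAMES = ("TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-7")
TOY_TRAV_NAMES = ("TRAV1-2", "TRAV8-4", "TRAV12-1", "TRAV21", "TRAV29")
TOY_TRAJ_NAMES = ("TRAJ12", "TRAJ23", "TRAJ33", "TRAJ49")

# reverse codon table (standard code), deterministic codon order
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults describe a small but realistic slide: a 30 x 30 hexagonal spot
    array at 100 um pitch with a contiguous tumor disc covering roughly a
    quarter of the tissue, 50 clones with Zipf(1) abundances, A/D clones
    placed in tumor with probability 0.8 and B/C clones 0.2, three reads
    per molecule, and error-free sequencing unless error rates are raised.
    """

    n_rows: int = 30
    n_cols: int = 30
    pitch_um: float = DEFAULT_PITCH_UM
    tumor_center: Optional[tuple[int, int]] = None  # (array_row, array_col)
    tumor_radius_um: float = 800.0
    inflammation_ring_um: float = 200.0

    n_clones: int = 50
    zipf_exponent: float = 1.0
    p_phenotype_ad: float = 0.5
    p_tumor: dict = field(default_factory=lambda: {"AD": 0.8, "BC": 0.2})
    total_umis: int = 2000

    barcode_len: int = 16
    umi_len: int = 12
    r1_pad: int = 0
    reads_per_umi: int = 3
    err_barcode: float = 0.0
    err_umi: float = 0.0
    err_insert: float = 0.0
    primer_start: int = 40

    n_cells: int = 500
    alpha_only_fraction: float = 0.1
    phenotype_purity: float = 1.0

    n_cefx_specific: int = 10

    seed: int = 0

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible generator for one pipeline stage."""
        order = ("tissue", "repertoire", "spatial", "fastq", "cells", "cefx")
        if stage not in order:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(self.seed, spawn_key=(order.index(stage),))
        return np.random.default_rng(ss)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["tumor_center"] is not None:
            d["tumor_center"] = list(d["tumor_center"])
        return d


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_DNA[rng.integers(0, 4, n)])


def toy_segment_references(v_len: int = 220, j_len: int = 60) -> list[SegmentReference]:
    """Bundled toy TRB segment reference with valid conserved anchors.

    V segments end in the conserved cysteine codon TGT (anchor at the last
    codon); J segments begin with the FGxG phenylalanine codon TTT (anchor
    at 0).  Sequences are fixed pseudo-random so the reference is identical
    across runs and configurations.
    """
    rng = np.random.default_rng(20210607)
    refs: list[SegmentReference] = []
    for name in TOY_V_NAMES:
        seq = _random_seq(rng, v_len - 3) + "TGT"
        refs.append(SegmentReference(name, "TRB", seq, v_len - 3))
    for name in TOY_J_NAMES:
        seq = "TTT" + _random_seq(rng, j_len - 3)
        refs.append(SegmentReference(name, "TRB", seq, 0))
    return refs


def generate_whitelist(
    n: int, barcode_len: int, rng: np.random.Generator, min_distance: int = 3
) -> list[str]:
    """Random spot barcodes with pairwise Hamming distance >= min_distance.

    Rejection sampling; with 16-nt barcodes collisions below distance 3 are
    vanishingly rare, so this typically costs one pass.
    """
    codes = rng.integers(0, 4, size=(n, barcode_len))
    for _ in range(100):
        diff = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
        np.fill_diagonal(diff, barcode_len)
        bad = np.unique(np.argwhere(diff < min_distance)[:, 0])
        if bad.size == 0:
            return ["".join(_DNA[row]) for row in codes]
        codes[bad] = rng.integers(0, 4, size=(bad.size, barcode_len))
    raise RuntimeError("failed to generate a separated whitelist")


def simulate_tissue(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SpotGrid:
    """Hexagonal-offset spot grid with a disc-shaped tumor parenchyma.

    Spots within ``tumor_radius_um`` of the (spot-aligned) center are tumor
    parenchyma; a ring of ``inflammation_ring_um`` around it is labeled
    inflammation and the remainder stroma.  All spots are in tissue.
    """
    if rng is None:
        rng = config.stage_rng("tissue")
    if config.n_rows < 1 or config.n_cols < 1:
        raise ValueError("grid must have at least one row and column")
    if config.tumor_radius_um < 0:
        raise ValueError("tumor radius must be non-negative")
    rows, cols = [], []
    for r in range(config.n_rows):
        for i in range(config.n_cols):
            rows.append(r)
            cols.append(2 * i + (r % 2))
    rows = np.array(rows)
    cols = np.array(cols)
    x, y = hex_array_to_um(rows, cols, config.pitch_um)

    center = config.tumor_center
    if center is None:
        c_row = config.n_rows // 2
        center = (c_row, 2 * (config.n_cols // 2) + (c_row % 2))
    cx, cy = hex_array_to_um(np.array([center[0]]), np.array([center[1]]), config.pitch_um)
    dist = np.hypot(x - cx[0], y - cy[0])
    is_tumor = dist <= config.tumor_radius_um
    if not is_tumor.any():
        raise ValueError("tumor disc center does not coincide with any spot")
    region = np.where(
        is_tumor,
        "tumor_parenchyma",
        np.where(
            dist <= config.tumor_radius_um + config.inflammation_ring_um,
            "inflammation",
            "stroma",
        ),
    )
    barcodes = generate_whitelist(len(rows), config.barcode_len, rng)
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            "x": x,
            "y": y,
            "in_tissue": True,
            "region": region,
            "is_tumor": is_tumor,
            "array_row": rows,
            "array_col": cols,
        }
    )
    return SpotGrid(spots=df, tumor_labels=("tumor_parenchyma",))


def _random_cdr3(
    rng: np.random.Generator, interior_len: int
) -> tuple[str, str]:
    """CDR3 amino acids C...F with a matching nucleotide sequence.

    The first codon is TGT (the V anchor cysteine) and the last TTT (the J
    anchor phenylalanine) so reads built from this CDR3 align seamlessly
    into the toy reference segments.
    """
    interior_alphabet = "ADEGHIKLNPQRSTVY"  # common junction residues
    aas = "".join(
        interior_alphabet[i]
        for i in rng.integers(0, len(interior_alphabet), interior_len)
    )
    aa = "C" + aas + "F"
    codons = ["TGT"]
    for ch in aas:
        options = _CODONS[ch]
        codons.append(options[rng.integers(0, len(options))])
    codons.append("TTT")
    return aa, "".join(codons)


def simulate_repertoire(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Clone table with V/J genes, CDR3s, phenotypes, and Zipf abundances.

    Columns: clone_id, v_gene, j_gene, cdr3_aa, cdr3_nt, phenotype, weight
    (relative frequency), n_umis (planted spatial molecules, >= 1 each).
    """
    if rng is None:
        rng = config.stage_rng("repertoire")
    if config.n_clones < 1:
        raise ValueError("need at least one clone")
    ranks = np.arange(1, config.n_clones + 1, dtype=float)
    weights = ranks ** -config.zipf_exponent
    weights /= weights.sum()
    seen_keys: set[CloneKey] = set()
    records = []
    for r in range(config.n_clones):
        v = TOY_V_NAMES[rng.integers(0, len(TOY_V_NAMES))]
        j = TOY_J_NAMES[rng.integers(0, len(TOY_J_NAMES))]
        for _ in range(1000):
            aa, nt = _random_cdr3(rng, int(rng.integers(5, 12)))
            key = build_clone_key(v, j, aa)
            if key not in seen_keys:
                seen_keys.add(key)
                break
        else:  # pragma: no cover - 16^5 space, never exhausted
            raise RuntimeError("could not generate a unique CDR3")
        phenotype = "AD" if rng.random() < config.p_phenotype_ad else "BC"
        records.append(
            {
                "clone_id": f"T{r + 1:04d}",
                "v_gene": v,
                "j_gene": j,
                "cdr3_aa": aa,
                "cdr3_nt": nt,
                "phenotype": phenotype,
                "weight": weights[r],
                "n_umis": max(1, int(round(weights[r] * config.total_umis))),
            }
        )
    return pd.DataFrame(records)


class Molecule:
    """One planted molecule: a clone's UMI captured at one spot."""

    __slots__ = ("clone_id", "spot_barcode", "umi")

    def __init__(self, clone_id: str, spot_barcode: str, umi: str):
        self.clone_id = clone_id
        self.spot_barcode = spot_barcode
        self.umi = umi


def clone_table_keys(clone_table: pd.DataFrame) -> dict[str, CloneKey]:
    return {
        row.clone_id: build_clone_key(row.v_gene, row.j_gene, row.cdr3_aa)
        for row in clone_table.itertuples()
    }


def simulate_spatial_umis(
    clone_table: pd.DataFrame,
    grid: SpotGrid,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[SpatialCloneMatrix, list[Molecule]]:
    """Place each clone's UMIs on spots with phenotype-dependent tumor bias.

    Every molecule lands on a tumor spot with probability
    ``p_tumor[phenotype]`` and otherwise on a non-tumor in-tissue spot,
    uniformly within the chosen compartment.  UMI sequences are distinct
    within a (clone, spot) pair, so the returned matrix is exactly the
    deduplicated ground truth.
    """
    if rng is None:
        rng = config.stage_rng("spatial")
    tumor = sorted(grid.tumor_barcodes())
    non_tumor = sorted(grid.in_tissue_barcodes() - set(tumor))
    molecules: list[Molecule] = []
    for row in clone_table.itertuples():
        p = config.p_tumor[row.phenotype]
        if p > 0 and not tumor:
            raise ValueError("p_tumor > 0 but the grid has no tumor spots")
        if p < 1 and not non_tumor:
            raise ValueError("p_tumor < 1 but the grid has no non-tumor spots")
        used: set[tuple[str, str]] = set()
        for _ in range(row.n_umis):
            compartment = tumor if rng.random() < p else non_tumor
            spot = compartment[rng.integers(0, len(compartment))]
            while True:
                umi = _random_seq(rng, config.umi_len)
                if (spot, umi) not in used:
                    used.add((spot, umi))
                    break
            molecules.append(Molecule(row.clone_id, spot, umi))
    counts: dict[tuple[str, str], int] = {}
    for mol in molecules:
        k = (mol.clone_id, mol.spot_barcode)
        counts[k] = counts.get(k, 0) + 1
    matrix = SpatialCloneMatrix(counts=counts, clone_table=clone_table_keys(clone_table))
    return matrix, molecules


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _open_write(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def emit_fastq(
    molecules: Sequence[Molecule],
    clone_table: pd.DataFrame,
    refs: Sequence[SegmentReference],
    config: SimulationConfig,
    r1_path,
    r2_path,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, str]:
    """Write paired FASTQ for the planted molecules; returns the truth map.

    Read 1 is spot barcode + UMI (+ poly-A pad); read 2 is the clone's
    transcript: the V segment from ``primer_start`` through the planted
    CDR3 into the J segment.  Substitution errors are applied per region
    at the configured rates.  The returned dict maps every emitted read id
    to its true clone id (recorded before errors, as ground truth).
    """
    if rng is None:
        rng = config.stage_rng("fastq")
    refs_by_name = {r.name: r for r in refs}
    templates: dict[str, str] = {}
    for row in clone_table.itertuples():
        v = refs_by_name[row.v_gene]
        j = refs_by_name[row.j_gene]
        if config.primer_start >= v.anchor_offset:
            raise ValueError("primer_start must fall before the V anchor")
        templates[row.clone_id] = (
            v.seq[config.primer_start : v.anchor_offset]
            + row.cdr3_nt
            + j.seq[j.anchor_offset + 3 :]
        )
    truth: dict[str, str] = {}
    pad = "A" * config.r1_pad
    i = 0
    with _open_write(r1_path) as f1, _open_write(r2_path) as f2:
        for mol in molecules:
            template = templates[mol.clone_id]
            for _ in range(config.reads_per_umi):
                read_id = f"sim.{i:08d}"
                i += 1
                truth[read_id] = mol.clone_id
                barcode = _mutate(mol.spot_barcode, config.err_barcode, rng)
                umi = _mutate(mol.umi, config.err_umi, rng)
                r1 = barcode + umi + pad
                r2 = _mutate(template, config.err_insert, rng)
                f1.write(f"@{read_id}\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@{read_id}\n{r2}\n+\n{'I' * len(r2)}\n")
    return truth


def simulate_cells(
    clone_table: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[CellRecord], pd.DataFrame, pd.DataFrame]:
    """Single-cell table matched to the clone repertoire.

    Cells per clone follow the clone weights (at least one each).  Each
    clone carries one fixed α chain; a configurable fraction of cells is
    emitted without the β contig (rescuable through the shared α), always
    leaving at least one β-bearing cell per clone.  Metacluster labels are
    drawn from the clone's own phenotype group (A/D or B/C) with
    probability ``phenotype_purity``, else from the opposite group.

    Returns (cell records, contig table in the single-cell VDJ CSV dialect,
    cell metadata table).
    """
    if rng is None:
        rng = config.stage_rng("cells")
    groups = {"AD": ("A", "D"), "BC": ("B", "C")}
    cells: list[CellRecord] = []
    contig_rows = []
    meta_rows = []
    weights = clone_table["weight"].to_numpy()
    n_per_clone = np.maximum(1, np.round(weights * config.n_cells).astype(int))
    cell_i = 0
    for row, n in zip(clone_table.itertuples(), n_per_clone):
        alpha = AlphaChain(
            v_gene=TOY_TRAV_NAMES[rng.integers(0, len(TOY_TRAV_NAMES))],
            j_gene=TOY_TRAJ_NAMES[rng.integers(0, len(TOY_TRAJ_NAMES))],
            cdr3_aa="C"
            + "".join("ADEGILNQRSTV"[i] for i in rng.integers(0, 12, 8))
            + "F",
            cdr3_nt=_random_seq(rng, 30),
        )
        key = build_clone_key(row.v_gene, row.j_gene, row.cdr3_aa)
        own, other = groups[row.phenotype], groups["BC" if row.phenotype == "AD" else "AD"]
        for c in range(int(n)):
            cell_id = f"CELL{cell_i:06d}-1"
            cell_i += 1
            pool = own if rng.random() < config.phenotype_purity else other
            metacluster = pool[rng.integers(0, 2)]
            # cell 0 always keeps its β so the shared α is rescuable
            alpha_only = c > 0 and rng.random() < config.alpha_only_fraction
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    beta=None if alpha_only else key,
                    alphas=(alpha,),
                    metacluster=metacluster,
                    patient="sim01",
                    compartment="tumor",
                    beta_v_gene=None if alpha_only else row.v_gene,
                    beta_j_gene=None if alpha_only else row.j_gene,
                    beta_cdr3_aa=None if alpha_only else row.cdr3_aa,
                )
            )
            if not alpha_only:
                contig_rows.append(
                    {
                        "barcode": cell_id,
                        "is_cell": "True",
                        "chain": "TRB",
                        "v_gene": row.v_gene,
                        "j_gene": row.j_gene,
                        "cdr3": row.cdr3_aa,
                        "cdr3_nt": row.cdr3_nt,
                        "productive": "True",
                        "umis": int(rng.integers(1, 20)),
                    }
                )
            contig_rows.append(
                {
                    "barcode": cell_id,
                    "is_cell": "True",
                    "chain": "TRA",
                    "v_gene": alpha.v_gene,
                    "j_gene": alpha.j_gene,
                    "cdr3": alpha.cdr3_aa,
                    "cdr3_nt": alpha.cdr3_nt,
                    "productive": "True",
                    "umis": int(rng.integers(1, 20)),
                }
            )
            meta_rows.append(
                {
                    "barcode": cell_id,
                    "metacluster": metacluster,
                    "patient": "sim01",
                    "compartment": "tumor",
                }
            )
    return cells, pd.DataFrame(contig_rows), pd.DataFrame(meta_rows)


def simulate_cefx_tables(
    clone_table: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[RepertoireCounts, RepertoireCounts, set[CloneKey]]:
    """IFNγ+ / IFNγ- sorted count tables with a designated specific set.

    Designated specific clones are constructed to satisfy both clauses of
    the specificity rule (count >= 2 in IFNγ+, frequency >= 5x the IFNγ-
    frequency); every other clone is constructed to violate at least one
    clause, either by low IFNγ+ count or by a sub-threshold frequency
    ratio.  The construction is verified internally before returning.
    """
    if rng is None:
        rng = config.stage_rng("cefx")
    keys = list(clone_table_keys(clone_table).values())
    n_specific = min(config.n_cefx_specific, len(keys))
    order = rng.permutation(len(keys))
    specific = {keys[i] for i in order[:n_specific]}
    pos: dict[CloneKey, int] = {}
    neg: dict[CloneKey, int] = {}
    ratio_violators: list[CloneKey] = []
    for idx, key in enumerate(keys):
        if key in specific:
            pos[key] = int(rng.integers(2, 20))
        elif rng.random() < 0.5:
            # violate the count clause
            if rng.random() < 0.5:
                pos[key] = 1
            neg[key] = int(rng.integers(1, 30))
        else:
            # violate the ratio clause; neg count fixed below
            pos[key] = int(rng.integers(2, 10))
            ratio_violators.append(key)
            neg[key] = 1
    # iterate the ratio-violator neg counts to a fixed point: the needed
    # count depends on the totals, which depend on the counts
    for _ in range(20):
        P = sum(pos.values())
        N = sum(neg.values())
        changed = False
        for key in ratio_violators:
            needed = math.floor(pos[key] * N / (5 * P)) + 1
            if neg[key] < needed:
                neg[key] = needed
                changed = True
        if not changed:
            break
    pos_rep = RepertoireCounts({k: v for k, v in pos.items() if v > 0}, label="IFNg+")
    neg_rep = RepertoireCounts({k: v for k, v in neg.items() if v > 0}, label="IFNg-")
    recovered = cefx_specific_clones(pos_rep, neg_rep)
    if recovered != specific:  # pragma: no cover - construction guarantee
        raise RuntimeError("internal error: constructed tables violate the design")
    return pos_rep, neg_rep, specific
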