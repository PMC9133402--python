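"""Spot demultiplexing of targeted TCR reads into a clone × spot UMI matrix.

Read 1 of the targeted enrichment library carries the capture-spot barcode
followed by the unique molecular identifier (UMI); read 2 carries the TCR
transcript and is assigned to a clonotype either by an external caller's
supporting-read export or by the built-in lite caller.  This module
extracts and error-corrects the spot barcode, deduplicates molecules on
the (clone, spot, UMI) triple, and accumulates the sparse clone × spot
matrix that all downstream spatial statistics consume.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional

import pandas as pd

from .repertoire import CloneKey

__all__ = [
    "ReadPair",
    "BarcodeWhitelist",
    "CloneReadMap",
    "SpatialCloneMatrix",
    "QCReport",
    "normalize_read_id",
    "parse_read1",
    "correct_barcode",
    "load_clone_read_map",
    "build_spatial_clone_matrix",
]

_DNA = "ACGT"


class ReadPair(NamedTuple):
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str


class BarcodeWhitelist:
    """Fixed-length spot barcode whitelist supporting 1-mismatch correction."""

    def __init__(self, barcodes: Iterable[str]):
        barcodes = list(barcodes)
        if not barcodes:
            raise ValueError("empty barcode whitelist")
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise ValueError(f"whitelist barcodes have mixed lengths {sorted(lengths)}")
        self.barcode_len = lengths.pop()
        self.barcodes = frozenset(barcodes)
        if len(self.barcodes) != len(barcodes):
            raise ValueError("whitelist contains duplicate barcodes")

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)


def parse_read1(seq: str, barcode_len: int, umi_len: int) -> tuple[str, str]:
    """Slice the spot barcode and UMI off the front of a read-1 sequence.

    Trailing bases beyond barcode + UMI (poly(dT) or template) are ignored.
    Raises ValueError for reads too short to contain both.
    """
    if len(seq) < barcode_len + umi_len:
        raise ValueError(
            f"read length {len(seq)} < barcode {barcode_len} + UMI {umi_len}"
        )
    return seq[:barcode_len], seq[barcode_len : barcode_len + umi_len]


def correct_barcode(observed: str, whitelist: BarcodeWhitelist) -> Optional[str]:
    """Assign an observed barcode to a whitelist entry, allowing one mismatch.

    Exact members map to themselves.  Otherwise the barcode is assigned to
    the unique whitelist entry at Hamming distance 1, if any; ambiguity (two
    or more 1-neighbors) or greater distance returns None.  'N' mismatches
    every base, so a single 'N' behaves like one substitution.
    """
    if len(observed) != whitelist.barcode_len:
        raise ValueError(
            f"barcode length {len(observed)} != whitelist length {whitelist.barcode_len}"
        )
    if observed in whitelist:
        return observed
    hit: Optional[str] = None
    for i, base in enumerate(observed):
        prefix, suffix = observed[:i], observed[i + 1 :]
        for sub in _DNA:
            if sub == base:
                continue
            candidate = prefix + sub + suffix
            if candidate in whitelist:
                if hit is not None and hit != candidate:
                    return None
                hit = candidate
    return hit


def normalize_read_id(read_id: str) -> str:
    """Strip whitespace comments and /1, /2 mate suffixes from a read id."""
    rid = read_id.split()[0] if read_id.split() else read_id
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


@dataclass
class CloneReadMap:
    """Read id → clone id map from a caller's supporting-read export."""

    mapping: dict[str, str] = field(default_factory=dict)
    n_conflicts: int = 0

    def get(self, read_id: str) -> Optional[str]:
        return self.mapping.get(normalize_read_id(read_id))

    def __len__(self) -> int:
        return len(self.mapping)


def load_clone_read_map(
    path, read_col: str = "read_id", clone_col: str = "clone_id"
) -> CloneReadMap:
    """Load a TSV mapping supporting reads to clone ids.

    Duplicate read ids with the same clone collapse; a read id listed under
    two different clones is unsafe evidence and is dropped entirely (counted
    in ``n_conflicts``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (read_col, clone_col):
        if col not in df.columns:
            raise ValueError(f"clone read map {path} is missing column {col!r}")
    mapping: dict[str, str] = {}
    conflicted: set[str] = set()
    for rid, clone in zip(df[read_col], df[clone_col]):
        rid = normalize_read_id(str(rid))
        if rid in conflicted:
            continue
        prev = mapping.get(rid)
        if prev is None:
            mapping[rid] = str(clone)
        elif prev != clone:
            del mapping[rid]
            conflicted.add(rid)
    return CloneReadMap(mapping=mapping, n_conflicts=len(conflicted))


@dataclass
class QCReport:
    """Read-fate tallies from matrix construction."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def assignment_rate(self) -> float:
        total = self.total_reads
        return self.counts["assigned"] / total if total else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"fate": fate, "reads": n}
            for fate, n in sorted(self.counts.items())
        ]
        rows.append({"fate": "total", "reads": self.total_reads})
        df = pd.DataFrame(rows, columns=["fate", "reads"])
        df["fraction"] = df["reads"] / max(self.total_reads, 1)
        return df


@dataclass
class SpatialCloneMatrix:
    """Sparse clone × spot table of deduplicated UMI counts.

    ``counts`` maps (clone_id, spot_barcode) to the number of distinct UMI
    sequences observed there; ``clone_table`` carries each clone's
    family-level identity when known.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    clone_table: dict[str, CloneKey] = field(default_factory=dict)

    @property
    def total_umis(self) -> int:
        return sum(self.counts.values())

    def clone_ids(self) -> list[str]:
        return sorted({clone for clone, _ in self.counts})

    def spot_barcodes(self) -> list[str]:
        return sorted({spot for _, spot in self.counts})

    def clone_total(self, clone_id: str) -> int:
        return sum(n for (c, _), n in self.counts.items() if c == clone_id)

    def clone_spots(self, clone_id: str) -> dict[str, int]:
        return {s: n for (c, s), n in self.counts.items() if c == clone_id}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"clone_id": c, "spot_barcode": s, "umi_count": n}
            for (c, s), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["clone_id", "spot_barcode", "umi_count"])


def build_spatial_clone_matrix(
    pairs: Iterable[ReadPair],
    clone_map: CloneReadMap | Mapping[str, str],
    whitelist: BarcodeWhitelist,
    umi_len: int = 12,
    clone_table: Optional[Mapping[str, CloneKey]] = None,
) -> tuple[SpatialCloneMatrix, QCReport]:
    """Demultiplex read pairs into the deduplicated clone × spot UMI matrix.

    Each read with a clone assignment and a correctable spot barcode
    contributes its (clone, spot, UMI) triple; identical triples (PCR
    duplicates) collapse, and the UMI count per (clone, spot) is the number
    of distinct UMI sequences.  Every read is tallied under exactly one
    fate: assigned, no_clone, too_short, barcode_unassigned.
    """
    if isinstance(clone_map, Mapping):
        clone_map = CloneReadMap(mapping=dict(clone_map))
    barcode_len = whitelist.barcode_len
    qc = QCReport()
    triples: set[tuple[str, str, str]] = set()
    for pair in pairs:
        clone = clone_map.get(pair.read_id)
        if clone is None:
            qc.counts["no_clone"] += 1
            continue
        try:
            barcode, umi = parse_read1(pair.r1_seq, barcode_len, umi_len)
        except ValueError:
            qc.counts["too_short"] += 1
            continue
        spot = correct_barcode(barcode, whitelist)
        if spot is None:
            qc.counts["barcode_unassigned"] += 1
            continue
        qc.counts["assigned"] += 1
        triples.add((clone, spot, umi))

    counts: Counter = Counter()
    for clone, spot, _ in triples:
        counts[(clone, spot)] += 1
    matrix = SpatialCloneMatrix(
        counts=dict(counts),
        clone_table=dict(clone_table) if clone_table else {},
    )
    return matrix, qc
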