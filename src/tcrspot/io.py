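"""Readers and writers for the formats the pipeline touches.

FASTQ (optionally gzipped) paired reads, spot whitelists, the spatial
platform's tissue-positions CSV dialect, region-annotation CSVs,
single-cell VDJ contig CSVs, immunoSEQ-style bulk TCRβ TSVs, VDJdb-style
specificity TSVs, supporting-read exports, and the package's own TSV/MTX
outputs.  All writers emit headered, tab-delimited UTF-8; all readers
raise errors naming the missing column on malformed headers.
"""

from __future__ import annotations

import gzip
import re
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy.io import mmwrite
from scipy.sparse import coo_matrix

from .capture import BarcodeWhitelist, QCReport, ReadPair, SpatialCloneMatrix, normalize_read_id
from .repertoire import (
    AlphaChain,
    CellRecord,
    CloneKey,
    NonProductiveError,
    RepertoireCounts,
    VdjdbRecord,
    aggregate_repertoire,
    build_clone_key,
)

__all__ = [
    "open_maybe_gzip",
    "iter_read_pairs",
    "read_whitelist",
    "read_tissue_positions",
    "read_regions",
    "read_cell_meta",
    "read_10x_contigs",
    "adaptive_to_imgt",
    "read_adaptive_tsv",
    "read_vdjdb_tsv",
    "write_matrix",
    "write_matrix_mtx",
    "write_qc",
    "write_clone_table",
    "write_read_map",
    "write_whitelist",
    "write_tissue_positions",
    "write_regions",
    "write_adaptive_tsv",
]

_POSITIONS_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def open_maybe_gzip(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_read_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream paired FASTQ files; mates must be in corresponding order."""
    with open_maybe_gzip(r1_path) as f1, open_maybe_gzip(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for (id1, seq1, qual1), (id2, seq2, _) in zip(it1, it2, strict=True):
            if normalize_read_id(id1) != normalize_read_id(id2):
                raise ValueError(
                    f"mate order mismatch: {id1!r} in R1 vs {id2!r} in R2"
                )
            yield ReadPair(id1, seq1.upper(), qual1, seq2.upper())


def read_whitelist(path) -> BarcodeWhitelist:
    """One barcode per line, or the first column of a positions-style CSV."""
    barcodes = []
    with open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("barcode"):
                continue
            barcodes.append(line.split(",")[0])
    return BarcodeWhitelist(barcodes)


def read_tissue_positions(path) -> pd.DataFrame:
    """Tissue-positions table, headered or headerless six-column dialect."""
    with open_maybe_gzip(path) as fh:
        first = fh.readline()
    header = 0 if first.lower().startswith("barcode") else None
    df = pd.read_csv(path, header=header)
    if header is None:
        if df.shape[1] != len(_POSITIONS_COLUMNS):
            raise ValueError(
                f"headerless positions file must have {len(_POSITIONS_COLUMNS)} "
                f"columns, found {df.shape[1]}"
            )
        df.columns = _POSITIONS_COLUMNS
    for col in ("barcode", "in_tissue", "array_row", "array_col"):
        if col not in df.columns:
            raise ValueError(f"tissue positions file is missing column {col!r}")
    return df


def read_regions(path) -> dict[str, str]:
    """Region-annotation CSV: barcode, region."""
    df = pd.read_csv(path)
    for col in ("barcode", "region"):
        if col not in df.columns:
            raise ValueError(f"region annotation file is missing column {col!r}")
    return dict(zip(df["barcode"].astype(str), df["region"].astype(str)))


def read_cell_meta(path) -> pd.DataFrame:
    """Per-cell metadata CSV: barcode, metacluster, and optional patient/compartment."""
    df = pd.read_csv(path)
    for col in ("barcode", "metacluster"):
        if col not in df.columns:
            raise ValueError(f"cell metadata file is missing column {col!r}")
    return df


def _truthy(value) -> bool:
    return str(value).strip().lower() in ("true", "t", "1", "yes")


def read_10x_contigs(path, meta: Optional[pd.DataFrame] = None) -> list[CellRecord]:
    """Cell records from a single-cell VDJ contig annotation CSV.

    Uses barcode, chain, v_gene, j_gene, cdr3, cdr3_nt, productive, and
    (when present) is_cell and umis.  Non-cell and non-productive contigs
    are dropped; the β contig with the most UMIs represents the cell;
    non-productive β junctions leave the cell β-less (rescuable).
    """
    df = pd.read_csv(path, dtype=str)
    required = ("barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "productive")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"contig file is missing column {col!r}")
    if "is_cell" in df.columns:
        df = df[df["is_cell"].map(_truthy)]
    df = df[df["productive"].map(_truthy)]
    meta_by_barcode: dict[str, dict] = {}
    if meta is not None:
        meta_by_barcode = {
            str(row["barcode"]): row for _, row in meta.iterrows()
        }
    cells: list[CellRecord] = []
    for barcode, group in df.groupby("barcode", sort=True):
        betas = group[group["chain"] == "TRB"]
        if "umis" in betas.columns and len(betas) > 1:
            betas = betas.assign(_umis=betas["umis"].astype(float)).sort_values(
                "_umis", ascending=False
            )
        beta_key = None
        beta_v = beta_j = beta_cdr3 = None
        for _, row in betas.iterrows():
            try:
                beta_key = build_clone_key(row["v_gene"], row["j_gene"], row["cdr3"])
            except (NonProductiveError, ValueError):
                continue
            beta_v, beta_j, beta_cdr3 = row["v_gene"], row["j_gene"], row["cdr3"]
            break
        alphas = tuple(
            AlphaChain(row["v_gene"], row["j_gene"], row["cdr3"], row["cdr3_nt"])
            for _, row in group[group["chain"] == "TRA"].iterrows()
        )
        if beta_key is None and not alphas:
            continue
        m = meta_by_barcode.get(str(barcode), {})
        cells.append(
            CellRecord(
                cell_id=str(barcode),
                beta=beta_key,
                alphas=alphas,
                metacluster=str(m.get("metacluster", "unassigned")),
                patient=str(m.get("patient", "")),
                compartment=str(m.get("compartment", "tumor")),
                beta_v_gene=beta_v,
                beta_j_gene=beta_j,
                beta_cdr3_aa=beta_cdr3,
            )
        )
    return cells


def adaptive_to_imgt(name: str) -> str:
    """Convert immunoSEQ-style segment names (TCRBV06-01) to IMGT style.

    IMGT-style names pass through unchanged.
    """
    s = name.strip()
    if s.startswith("TCR"):
        s = "TR" + s[3:]
    # strip zero padding after the segment letter and after hyphens
    s = re.sub(r"(?<=[VJ])0+(\d)", r"\1", s)
    s = re.sub(r"-0+(\d)", r"-\1", s)
    return s


def read_adaptive_tsv(path, label: str = "") -> RepertoireCounts:
    """Bulk TCRβ repertoire from an immunoSEQ-like TSV.

    Accepts either naming convention per column: amino_acid or
    cdr3_amino_acid; v_family or v_gene; j_family or j_gene; templates or
    count.  Rows with unresolved genes or non-productive CDR3s are skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)

    def pick(*names: str) -> str:
        for n in names:
            if n in df.columns:
                return n
        raise ValueError(
            f"bulk TCR file is missing a column named one of {names}"
        )

    aa_col = pick("amino_acid", "cdr3_amino_acid")
    v_col = pick("v_family", "v_gene")
    j_col = pick("j_family", "j_gene")
    n_col = pick("templates", "count")
    records: list[tuple[CloneKey, int]] = []
    for _, row in df.iterrows():
        count = int(float(row[n_col]))
        if count < 1:
            continue
        try:
            key = build_clone_key(
                adaptive_to_imgt(str(row[v_col])),
                adaptive_to_imgt(str(row[j_col])),
                str(row[aa_col]),
            )
        except (NonProductiveError, ValueError):
            continue
        records.append((key, count))
    return aggregate_repertoire(records, label=label or str(path))


def read_vdjdb_tsv(path) -> list[VdjdbRecord]:
    """Paired-chain records from a VDJdb-style TSV.

    α and β rows sharing a non-zero complex.id are paired; unpaired rows
    are skipped (the lookup requires both chains).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("complex.id", "gene", "cdr3", "v.segm", "j.segm"):
        if col not in df.columns:
            raise ValueError(f"VDJdb file is missing column {col!r}")
    out: list[VdjdbRecord] = []
    for complex_id, group in df.groupby("complex.id", sort=True):
        if str(complex_id) == "0":
            continue
        tra = group[group["gene"] == "TRA"]
        trb = group[group["gene"] == "TRB"]
        if len(tra) != 1 or len(trb) != 1:
            continue
        a = tra.iloc[0]
        b = trb.iloc[0]
        out.append(
            VdjdbRecord(
                cdr3_a=a["cdr3"],
                trav=a["v.segm"],
                traj=a["j.segm"],
                cdr3_b=b["cdr3"],
                trbv=b["v.segm"],
                trbj=b["j.segm"],
                epitope=str(b.get("antigen.epitope", "")),
                species=str(b.get("antigen.species", "")),
                complex_id=str(complex_id),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers


def write_matrix(matrix: SpatialCloneMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index=False)


def read_matrix(path, clone_table: Optional[dict[str, CloneKey]] = None) -> SpatialCloneMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "spot_barcode": str})
    for col in ("clone_id", "spot_barcode", "umi_count"):
        if col not in df.columns:
            raise ValueError(f"matrix file is missing column {col!r}")
    counts = {
        (row.clone_id, row.spot_barcode): int(row.umi_count)
        for row in df.itertuples()
    }
    return SpatialCloneMatrix(counts=counts, clone_table=clone_table or {})


def write_matrix_mtx(matrix: SpatialCloneMatrix, prefix) -> None:
    """Sparse matrix-market export with row (clone) and column (spot) indices."""
    clones = matrix.clone_ids()
    spots = matrix.spot_barcodes()
    ci = {c: i for i, c in enumerate(clones)}
    si = {s: i for i, s in enumerate(spots)}
    rows, cols, data = [], [], []
    for (c, s), n in sorted(matrix.counts.items()):
        rows.append(ci[c])
        cols.append(si[s])
        data.append(n)
    mat = coo_matrix(
        (data, (rows, cols)), shape=(len(clones), len(spots)), dtype=np.int64
    )
    prefix = str(prefix)
    mmwrite(prefix + ".mtx", mat)
    pd.Series(clones, name="clone_id").to_csv(
        prefix + ".rows.tsv", sep="\t", index=False
    )
    pd.Series(spots, name="spot_barcode").to_csv(
        prefix + ".cols.tsv", sep="\t", index=False
    )


def write_qc(qc: QCReport, path) -> None:
    qc.to_dataframe().to_csv(path, sep="\t", index=False)


def write_clone_table(clones, path) -> None:
    """Clone table TSV from CloneRecord objects or (clone_id, CloneKey) pairs."""
    rows = []
    for clone in clones:
        if hasattr(clone, "key"):
            rows.append(
                {
                    "clone_id": clone.clone_id,
                    "v_gene": clone.v_gene,
                    "j_gene": clone.j_gene,
                    "v_family": clone.key.v_family,
                    "j_family": clone.key.j_family,
                    "cdr3_nt": clone.cdr3_nt,
                    "cdr3_aa": clone.cdr3_aa,
                    "read_count": clone.read_count,
                }
            )
        else:
            clone_id, key = clone
            rows.append(
                {
                    "clone_id": clone_id,
                    "v_family": key.v_family,
                    "j_family": key.j_family,
                    "cdr3_aa": key.cdr3_aa,
                }
            )
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["clone_id", "v_family", "j_family", "cdr3_aa"])
    df.to_csv(path, sep="\t", index=False)


def read_clone_table(path) -> dict[str, CloneKey]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    v_col = "v_family" if "v_family" in df.columns else "v_gene"
    j_col = "j_family" if "j_family" in df.columns else "j_gene"
    for col in ("clone_id", v_col, j_col, "cdr3_aa"):
        if col not in df.columns:
            raise ValueError(f"clone table is missing column {col!r}")
    return {
        row["clone_id"]: build_clone_key(row[v_col], row[j_col], row["cdr3_aa"])
        for _, row in df.iterrows()
    }


def write_read_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame(
        {"read_id": list(mapping), "clone_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def write_whitelist(barcodes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for b in barcodes:
            fh.write(b + "\n")


def write_tissue_positions(grid, path) -> None:
    """Emit the grid in the tissue-positions CSV dialect (headered)."""
    df = grid.spots
    out = pd.DataFrame(
        {
            "barcode": df["barcode"],
            "in_tissue": df["in_tissue"].astype(int),
            "array_row": df.get("array_row", pd.Series(0, index=df.index)),
            "array_col": df.get("array_col", pd.Series(0, index=df.index)),
            "pxl_row_in_fullres": df["y"],
            "pxl_col_in_fullres": df["x"],
        }
    )
    out.to_csv(path, index=False)


def write_regions(grid, path) -> None:
    grid.spots[["barcode", "region"]].to_csv(path, index=False)


def read_segment_references(fasta_path, anchors_path) -> list:
    """Reference segments from FASTA plus a sidecar anchors TSV (name, anchor_offset, chain)."""
    from Bio import SeqIO

    from .caller import SegmentReference

    anchors = pd.read_csv(anchors_path, sep="\t", dtype=str)
    for col in ("name", "anchor_offset"):
        if col not in anchors.columns:
            raise ValueError(f"anchors file is missing column {col!r}")
    meta = {
        row["name"]: (int(row["anchor_offset"]), str(row.get("chain", "TRB")))
        for _, row in anchors.iterrows()
    }
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta:
            raise ValueError(f"segment {rec.id!r} has no anchor annotation")
        offset, chain = meta[rec.id]
        refs.append(SegmentReference(rec.id, chain, str(rec.seq).upper(), offset))
    return refs


def write_segment_references(refs, fasta_path, anchors_path) -> None:
    with open(fasta_path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n{ref.seq}\n")
    pd.DataFrame(
        [
            {"name": r.name, "anchor_offset": r.anchor_offset, "chain": r.chain}
            for r in refs
        ]
    ).to_csv(anchors_path, sep="\t", index=False)


def write_adaptive_tsv(rep: RepertoireCounts, path) -> None:
    rows = [
        {
            "cdr3_amino_acid": key.cdr3_aa,
            "v_family": key.v_family,
            "j_family": key.j_family,
            "templates": count,
        }
        for key, count in sorted(rep.entries.items())
    ]
    pd.DataFrame(
        rows, columns=["cdr3_amino_acid", "v_family", "j_family", "templates"]
    ).to_csv(path, sep="\t", index=False)
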