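"""Stage compositions: extract, link, stats, repertoire.

These are the library-level entry points behind the CLI subcommands.  Each
takes in-memory objects (or paths where streaming matters), returns plain
DataFrames/objects, and performs no I/O beyond reading the FASTQ streams,
so they are directly testable and reusable.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .caller import SegmentReference, call_clones_from_fastq
from .capture import (
    BarcodeWhitelist,
    CloneReadMap,
    QCReport,
    SpatialCloneMatrix,
    build_spatial_clone_matrix,
)
from .repertoire import (
    CellRecord,
    CloneKey,
    PhenotypeCall,
    RepertoireCounts,
    aggregate_repertoire,
    bystander_fraction,
    cefx_specific_clones,
    classify_clone_phenotype,
    clone_rank_cumulative,
    morisita_horn,
    pairwise_overlap_matrix,
    rescue_beta_by_alpha,
    shannon_index,
)
from .spatial import (
    SpotGrid,
    clone_spatial_summary,
    distances_to_tumor_border,
    expand_distance_sample,
    expanded_clone_localization,
    ks_two_sample,
    mann_whitney_u,
    region_umi_distribution,
)

__all__ = ["run_extract", "run_link", "run_stats", "run_repertoire"]


def run_extract(
    r1_path,
    r2_path,
    whitelist: BarcodeWhitelist,
    read_map: Optional[CloneReadMap] = None,
    clone_table: Optional[Mapping[str, CloneKey]] = None,
    refs: Optional[Sequence[SegmentReference]] = None,
    umi_len: int = 12,
):
    """Paired FASTQ → deduplicated clone × spot UMI matrix.

    Clone assignments come from an external caller's supporting-read export
    (``read_map``) when given; otherwise the built-in lite caller annotates
    read 2 against ``refs``.  Returns (matrix, qc_report, clone_records)
    where clone_records is None for the external-export path.
    """
    clone_records = None
    if read_map is None:
        if refs is None:
            raise ValueError("either a read map or reference segments are required")

        def r2_stream():
            for pair in tio.iter_read_pairs(r1_path, r2_path):
                yield pair.read_id, pair.r2_seq

        clone_records, mapping, _dropped = call_clones_from_fastq(r2_stream(), refs)
        read_map = CloneReadMap(mapping=mapping)
        clone_table = {c.clone_id: c.key for c in clone_records}
    matrix, qc = build_spatial_clone_matrix(
        tio.iter_read_pairs(r1_path, r2_path),
        read_map,
        whitelist,
        umi_len=umi_len,
        clone_table=clone_table,
    )
    return matrix, qc, clone_records


def run_link(
    matrix: SpatialCloneMatrix, cells: Sequence[CellRecord]
) -> pd.DataFrame:
    """Join spatial clones to single-cell clones and classify phenotypes.

    Cells are α-rescued first; spatial and cell clones match on the
    family-level clone key.  Returns one row per spatial clone with its
    key fields, per-metacluster cell counts, and the A/D-vs-B/C call
    (``unclassified`` for spatial-only clones).
    """
    rescued = rescue_beta_by_alpha(cells)
    by_key: dict[CloneKey, list[CellRecord]] = defaultdict(list)
    for cell in rescued:
        if cell.beta is not None:
            by_key[cell.beta].append(cell)
    rows = []
    for clone_id in matrix.clone_ids():
        key = matrix.clone_table.get(clone_id)
        if key is None:
            continue
        call = classify_clone_phenotype(key, by_key.get(key, []))
        rows.append(
            {
                "clone_id": clone_id,
                "v_family": key.v_family,
                "j_family": key.j_family,
                "cdr3_aa": key.cdr3_aa,
                "phenotype": call.call,
                "n_cells_A": call.n_cells_A,
                "n_cells_B": call.n_cells_B,
                "n_cells_C": call.n_cells_C,
                "n_cells_D": call.n_cells_D,
                "spatial_umis": matrix.clone_total(clone_id),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id",
            "v_family",
            "j_family",
            "cdr3_aa",
            "phenotype",
            "n_cells_A",
            "n_cells_B",
            "n_cells_C",
            "n_cells_D",
            "spatial_umis",
        ],
    )


def run_stats(
    matrix: SpatialCloneMatrix,
    phenotypes: Mapping[str, str],
    grid: SpotGrid,
    top_n: Optional[int] = None,
    min_umis: Optional[int] = None,
    spot_totals: Optional[Mapping[str, int]] = None,
) -> dict:
    """Spatial statistics bundle for classified clones.

    Computes per-clone localization summaries, region-resolved UMI
    distributions per phenotype group, distance ECDFs, the KS test on
    AD-vs-BC UMI distance samples, the Mann-Whitney test on per-clone
    tumor fractions, and the expanded-clone localization table.  Tests
    are skipped (with a reason) when fewer than two groups have data.
    """
    border = distances_to_tumor_border(grid)
    summaries = []
    for clone_id in matrix.clone_ids():
        s = clone_spatial_summary(
            clone_id,
            matrix,
            grid,
            phenotype=phenotypes.get(clone_id, "unclassified"),
            border_distances=border,
        )
        summaries.append(
            {
                "clone_id": s.clone_id,
                "phenotype": s.phenotype,
                "total_umis": s.total_umis,
                "umis_in_tumor": s.umis_in_tumor,
                "tumor_fraction": s.tumor_fraction,
            }
        )
    summary_df = pd.DataFrame(summaries)

    region_df = region_umi_distribution(phenotypes, matrix, grid)

    groups = {"AD": [], "BC": []}
    for clone_id, phen in phenotypes.items():
        if phen in groups:
            groups[phen].append(clone_id)

    ecdfs = {}
    for phen, clone_ids in groups.items():
        sample = expand_distance_sample(clone_ids, matrix, grid, border)
        if sample.size:
            values, counts = np.unique(sample, return_counts=True)
            ecdfs[phen] = pd.DataFrame(
                {
                    "phenotype": phen,
                    "distance_um": values,
                    "cumulative_fraction": np.cumsum(counts) / sample.size,
                }
            )
    ecdf_df = (
        pd.concat(ecdfs.values(), ignore_index=True)
        if ecdfs
        else pd.DataFrame(columns=["phenotype", "distance_um", "cumulative_fraction"])
    )

    tests = []
    ad_sample = expand_distance_sample(groups["AD"], matrix, grid, border)
    bc_sample = expand_distance_sample(groups["BC"], matrix, grid, border)
    if ad_sample.size and bc_sample.size:
        d, p = ks_two_sample(ad_sample, bc_sample)
        tests.append(
            {
                "test": "ks_distance_AD_vs_BC",
                "statistic": d,
                "p_value": p,
                "n_AD": ad_sample.size,
                "n_BC": bc_sample.size,
            }
        )
    fractions = {
        phen: summary_df.loc[
            (summary_df["phenotype"] == phen) & summary_df["tumor_fraction"].notna(),
            "tumor_fraction",
        ].to_numpy()
        for phen in ("AD", "BC")
    }
    if fractions["AD"].size and fractions["BC"].size:
        u, p = mann_whitney_u(fractions["AD"], fractions["BC"])
        tests.append(
            {
                "test": "mannwhitney_tumor_fraction_AD_vs_BC",
                "statistic": u,
                "p_value": p,
                "n_AD": fractions["AD"].size,
                "n_BC": fractions["BC"].size,
            }
        )
    tests_df = pd.DataFrame(
        tests, columns=["test", "statistic", "p_value", "n_AD", "n_BC"]
    )

    expanded_df = expanded_clone_localization(
        matrix, phenotypes, grid, top_n=top_n, min_umis=min_umis, spot_totals=spot_totals
    )
    return {
        "summary": summary_df,
        "region_distribution": region_df,
        "ecdf": ecdf_df,
        "tests": tests_df,
        "expanded": expanded_df,
    }


def run_repertoire(
    populations: Mapping[str, Sequence[CellRecord]] = (),
    bulk: Mapping[str, RepertoireCounts] = (),
    cefx_pos: Optional[RepertoireCounts] = None,
    cefx_neg: Optional[RepertoireCounts] = None,
    min_population: int = 10,
) -> dict:
    """Diversity / overlap / specificity bundle.

    ``populations`` maps a label (e.g. a metacluster) to its cells;
    ``bulk`` maps labels to bulk count tables.  Shannon indices and the
    pairwise Morisita-Horn matrix cover both; when IFNγ+/IFNγ- tables are
    given the specific clone set and per-population bystander fractions
    are included.
    """
    reps: dict[str, RepertoireCounts] = {}
    for label, cells in dict(populations).items():
        rescued = rescue_beta_by_alpha(list(cells))
        records = [(c.beta, 1) for c in rescued if c.beta is not None]
        reps[label] = aggregate_repertoire(records, label=label)
    reps.update(dict(bulk))

    rows = []
    for label, rep in reps.items():
        rows.append(
            {
                "population": label,
                "n_clones": len(rep),
                "total": rep.total,
                "shannon": shannon_index(rep) if rep.total else float("nan"),
                "flagged_small": rep.total < min_population,
            }
        )
    diversity_df = pd.DataFrame(rows)

    labels = list(reps)
    if len(labels) >= 2:
        mh = pairwise_overlap_matrix([reps[l] for l in labels])
        overlap_df = pd.DataFrame(mh, index=labels, columns=labels)
    else:
        overlap_df = pd.DataFrame(index=labels, columns=labels, dtype=float)

    rank_tables = {
        label: pd.DataFrame(
            [
                {
                    "rank": e.rank,
                    "v_family": e.clone.v_family,
                    "j_family": e.clone.j_family,
                    "cdr3_aa": e.clone.cdr3_aa,
                    "frequency": e.frequency,
                    "cumulative_frequency": e.cumulative_frequency,
                }
                for e in clone_rank_cumulative(rep)
            ]
        )
        for label, rep in reps.items()
    }

    out = {
        "diversity": diversity_df,
        "overlap": overlap_df,
        "rank_cumulative": rank_tables,
    }
    if cefx_pos is not None and cefx_neg is not None:
        specific = cefx_specific_clones(cefx_pos, cefx_neg)
        out["cefx_specific"] = sorted(specific)
        bystander_rows = []
        for label, cells in dict(populations).items():
            cells = list(cells)
            if cells:
                bystander_rows.append(
                    {
                        "population": label,
                        "bystander_pct": bystander_fraction(
                            rescue_beta_by_alpha(cells), specific
                        ),
                    }
                )
        out["bystander"] = pd.DataFrame(bystander_rows)
    return out
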