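"""Spatial localization statistics linking clone phenotype to tissue position.

The capture-spot grid carries coordinates (micrometers, derived from the
hexagonal array layout and a configurable center-to-center pitch), an
in-tissue flag, and a region label per spot; a configurable subset of
region labels constitutes the tumor parenchyma.  On top of the clone × spot
UMI matrix this module computes per-clone tumor fractions, region-resolved
UMI distributions by phenotype group, distance-to-tumor-border ECDFs, and
the two nonparametric group comparisons used throughout: the two-sample
Kolmogorov-Smirnov test on UMI-weighted distance samples and the
Mann-Whitney U test on per-clone tumor fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .capture import SpatialCloneMatrix

__all__ = [
    "DEFAULT_PITCH_UM",
    "SpotGrid",
    "CloneSpatialSummary",
    "distance_to_tumor_border",
    "distances_to_tumor_border",
    "clone_tumor_fraction",
    "clone_spatial_summary",
    "region_umi_distribution",
    "distance_ecdf",
    "ks_two_sample",
    "mann_whitney_u",
    "overall_umi_tumor_fraction",
    "filter_detected_genes",
    "expanded_clone_localization",
]

#: center-to-center spacing of adjacent capture spots, micrometers
DEFAULT_PITCH_UM = 100.0


def hex_array_to_um(
    array_row: np.ndarray, array_col: np.ndarray, pitch_um: float = DEFAULT_PITCH_UM
) -> tuple[np.ndarray, np.ndarray]:
    """Convert hexagonal-offset array indices to micrometer coordinates.

    Columns advance by half a pitch (odd rows use odd column indices), rows
    by pitch * sqrt(3)/2, so all six neighbors of a spot lie one pitch away.
    """
    x = np.asarray(array_col, dtype=float) * pitch_um / 2.0
    y = np.asarray(array_row, dtype=float) * pitch_um * math.sqrt(3.0) / 2.0
    return x, y


@dataclass
class SpotGrid:
    """Capture-spot coordinates, tissue flags, and region annotations.

    ``spots`` columns: barcode, x, y (micrometers), in_tissue (bool),
    region (str), is_tumor (bool).  Tumor spots are by definition
    in-tissue.
    """

    spots: pd.DataFrame
    tumor_labels: tuple[str, ...] = ("tumor_parenchyma",)

    def __post_init__(self) -> None:
        required = {"barcode", "x", "y", "in_tissue", "region", "is_tumor"}
        missing = required - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns {sorted(missing)}")
        if self.spots["barcode"].duplicated().any():
            raise ValueError("duplicate spot barcodes")
        if (self.spots["is_tumor"] & ~self.spots["in_tissue"]).any():
            raise ValueError("tumor spots must be in tissue")
        self.spots = self.spots.reset_index(drop=True)
        self._index = {b: i for i, b in enumerate(self.spots["barcode"])}

    @classmethod
    def from_positions(
        cls,
        positions: pd.DataFrame,
        regions: Mapping[str, str],
        tumor_labels: Iterable[str] = ("tumor_parenchyma",),
        pitch_um: float = DEFAULT_PITCH_UM,
    ) -> "SpotGrid":
        """Build a grid from a tissue-positions table plus region annotations.

        ``positions`` uses the spatial platform's dialect: barcode,
        in_tissue, array_row, array_col (pixel columns are ignored here;
        distances use array geometry and the pitch).  ``regions`` maps spot
        barcode to region label; unannotated in-tissue spots get
        "unannotated".
        """
        tumor_labels = tuple(tumor_labels)
        x, y = hex_array_to_um(
            positions["array_row"].to_numpy(), positions["array_col"].to_numpy(), pitch_um
        )
        region = positions["barcode"].map(
            lambda b: regions.get(b, "unannotated")
        )
        in_tissue = positions["in_tissue"].astype(bool).to_numpy()
        df = pd.DataFrame(
            {
                "barcode": positions["barcode"].astype(str).to_numpy(),
                "x": x,
                "y": y,
                "in_tissue": in_tissue,
                "region": region.to_numpy(),
                "is_tumor": np.array(
                    [r in tumor_labels for r in region], dtype=bool
                )
                & in_tissue,
            }
        )
        return cls(spots=df, tumor_labels=tumor_labels)

    def __len__(self) -> int:
        return len(self.spots)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def spot(self, barcode: str) -> pd.Series:
        return self.spots.iloc[self._index[barcode]]

    def in_tissue_barcodes(self) -> set[str]:
        return set(self.spots.loc[self.spots["in_tissue"], "barcode"])

    def tumor_barcodes(self) -> set[str]:
        return set(self.spots.loc[self.spots["is_tumor"], "barcode"])

    @property
    def n_tumor(self) -> int:
        return int(self.spots["is_tumor"].sum())


def distances_to_tumor_border(grid: SpotGrid) -> pd.Series:
    """Distance from every spot to the nearest tumor spot (tumor spots: 0).

    The tumor border is implicit: distance is min Euclidean distance
    between spot centers, so non-tumor spots adjacent to the tumor score
    one pitch, not zero.
    """
    tumor = grid.spots.loc[grid.spots["is_tumor"], ["x", "y"]].to_numpy()
    if len(tumor) == 0:
        raise ValueError("grid has no tumor spots; border distance undefined")
    tree = cKDTree(tumor)
    d, _ = tree.query(grid.spots[["x", "y"]].to_numpy())
    return pd.Series(d, index=grid.spots["barcode"].to_numpy(), name="distance_um")


def distance_to_tumor_border(barcode: str, grid: SpotGrid) -> float:
    """Single-spot convenience wrapper around :func:`distances_to_tumor_border`."""
    return float(distances_to_tumor_border(grid)[barcode])


def clone_tumor_fraction(
    clone_id: str, matrix: SpatialCloneMatrix, grid: SpotGrid
) -> float:
    """Percentage of a clone's in-tissue UMIs located on tumor spots.

    Returns NaN (undefined; excluded downstream) for clones with zero
    in-tissue UMIs.
    """
    in_tissue = grid.in_tissue_barcodes()
    tumor = grid.tumor_barcodes()
    total = 0
    n_tumor = 0
    for spot, n in matrix.clone_spots(clone_id).items():
        if spot not in in_tissue:
            continue
        total += n
        if spot in tumor:
            n_tumor += n
    if total == 0:
        return float("nan")
    return 100.0 * n_tumor / total


@dataclass(frozen=True)
class CloneSpatialSummary:
    clone_id: str
    phenotype: str
    total_umis: int
    umis_in_tumor: int
    tumor_fraction: float  # percent, NaN when no in-tissue UMIs
    distances_um: tuple[float, ...]  # one entry per UMI at a non-tumor in-tissue spot


def clone_spatial_summary(
    clone_id: str,
    matrix: SpatialCloneMatrix,
    grid: SpotGrid,
    phenotype: str = "unclassified",
    border_distances: Optional[pd.Series] = None,
) -> CloneSpatialSummary:
    """Per-clone localization summary: tumor fraction and border distances."""
    if border_distances is None:
        border_distances = distances_to_tumor_border(grid)
    in_tissue = grid.in_tissue_barcodes()
    tumor = grid.tumor_barcodes()
    total = 0
    n_tumor = 0
    distances: list[float] = []
    for spot, n in sorted(matrix.clone_spots(clone_id).items()):
        if spot not in in_tissue:
            continue
        total += n
        if spot in tumor:
            n_tumor += n
        else:
            distances.extend([float(border_distances[spot])] * n)
    frac = 100.0 * n_tumor / total if total else float("nan")
    return CloneSpatialSummary(
        clone_id=clone_id,
        phenotype=phenotype,
        total_umis=total,
        umis_in_tumor=n_tumor,
        tumor_fraction=frac,
        distances_um=tuple(distances),
    )


def region_umi_distribution(
    phenotypes: Mapping[str, str],
    matrix: SpatialCloneMatrix,
    grid: SpotGrid,
) -> pd.DataFrame:
    """Per phenotype group, the percentage of UMIs in each tissue region.

    ``phenotypes`` maps clone id to its group ("AD", "BC", ...).  Rows are
    groups, columns regions; every row sums to 100.  Groups with no
    in-tissue UMIs are omitted.
    """
    region_of = dict(
        zip(grid.spots["barcode"], grid.spots["region"])
    )
    in_tissue = grid.in_tissue_barcodes()
    tallies: dict[str, dict[str, int]] = {}
    for (clone, spot), n in matrix.counts.items():
        group = phenotypes.get(clone)
        if group is None or spot not in in_tissue:
            continue
        tallies.setdefault(group, {})
        region = region_of[spot]
        tallies[group][region] = tallies[group].get(region, 0) + n
    rows = {}
    for group, per_region in sorted(tallies.items()):
        total = sum(per_region.values())
        if total == 0:
            continue
        rows[group] = {r: 100.0 * n / total for r, n in per_region.items()}
    return pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)


def distance_ecdf(
    clone_ids: Iterable[str],
    matrix: SpatialCloneMatrix,
    grid: SpotGrid,
    border_distances: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """UMI-weighted ECDF of distance to the tumor border, outside the tumor.

    Each UMI at a non-tumor in-tissue spot contributes one observation at
    its spot's distance.  Returns columns (distance_um, cumulative_fraction);
    the ECDF is right-continuous and reaches 1 at the largest distance.
    """
    sample = expand_distance_sample(clone_ids, matrix, grid, border_distances)
    if sample.size == 0:
        raise ValueError("no UMIs outside the tumor parenchyma; ECDF undefined")
    values, counts = np.unique(sample, return_counts=True)
    cum = np.cumsum(counts) / sample.size
    return pd.DataFrame({"distance_um": values, "cumulative_fraction": cum})


def expand_distance_sample(
    clone_ids: Iterable[str],
    matrix: SpatialCloneMatrix,
    grid: SpotGrid,
    border_distances: Optional[pd.Series] = None,
) -> np.ndarray:
    """Per-UMI distance observations for the given clones (non-tumor spots only)."""
    if border_distances is None:
        border_distances = distances_to_tumor_border(grid)
    in_tissue = grid.in_tissue_barcodes()
    tumor = grid.tumor_barcodes()
    clones = set(clone_ids)
    out: list[float] = []
    for (clone, spot), n in sorted(matrix.counts.items()):
        if clone not in clones or spot not in in_tissue or spot in tumor:
            continue
        out.extend([float(border_distances[spot])] * n)
    return np.asarray(out, dtype=float)


def ks_two_sample(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on UMI-expanded distance samples.

    D is the supremum ECDF difference.  The p-value uses the asymptotic
    two-sample distribution, switching to the exact computation when both
    expanded sample sizes are at most ``exact_max_n``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n) else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U on per-clone tumor fractions, AD vs BC.

    U counts pairs with x_i > y_j plus half the ties; the two-sided p-value
    uses the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires two non-empty groups")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def overall_umi_tumor_fraction(
    spot_totals: Mapping[str, int], grid: SpotGrid
) -> float:
    """Percentage of all gene-expression UMIs on tumor spots (reference line)."""
    in_tissue = grid.in_tissue_barcodes()
    tumor = grid.tumor_barcodes()
    total = sum(n for s, n in spot_totals.items() if s in in_tissue)
    if total == 0:
        raise ValueError("zero total UMIs over in-tissue spots")
    in_tumor = sum(n for s, n in spot_totals.items() if s in tumor)
    return 100.0 * in_tumor / total


def filter_detected_genes(
    gene_counts: Mapping[str, tuple[int, int]],
    min_total: int = 10,
    min_spots: int = 3,
) -> set[str]:
    """Genes above the detection limit: >= 10 total counts in >= 3 spots.

    ``gene_counts`` maps gene to (total count, number of expressing spots).
    """
    return {
        gene
        for gene, (total, n_spots) in gene_counts.items()
        if total >= min_total and n_spots >= min_spots
    }


def expanded_clone_localization(
    matrix: SpatialCloneMatrix,
    phenotypes: Mapping[str, str],
    grid: SpotGrid,
    top_n: Optional[int] = None,
    min_umis: Optional[int] = None,
    spot_totals: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Tumor localization of the most expanded clones.

    Clones are ranked by total in-tissue spatial UMIs (rank 1 = most
    expanded, ties lexicographic on clone id), restricted by ``top_n``
    and/or ``min_umis``.  When per-spot gene-expression totals are given,
    the overall tumor fraction reference value is attached as
    ``df.attrs['overall_tumor_fraction']``.
    """
    in_tissue = grid.in_tissue_barcodes()
    totals: dict[str, int] = {}
    for (clone, spot), n in matrix.counts.items():
        if spot in in_tissue:
            totals[clone] = totals.get(clone, 0) + n
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if min_umis is not None:
        ordered = [(c, n) for c, n in ordered if n >= min_umis]
    if top_n is not None:
        ordered = ordered[:top_n]
    rows = []
    for rank, (clone, n) in enumerate(ordered, start=1):
        rows.append(
            {
                "rank": rank,
                "clone_id": clone,
                "phenotype": phenotypes.get(clone, "unclassified"),
                "total_umis": n,
                "tumor_fraction": clone_tumor_fraction(clone, matrix, grid),
            }
        )
    df = pd.DataFrame(
        rows, columns=["rank", "clone_id", "phenotype", "total_umis", "tumor_fraction"]
    )
    if spot_totals is not None:
        df.attrs["overall_tumor_fraction"] = overall_umi_tumor_fraction(
            spot_totals, grid
        )
    return df
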