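"""Adaptive-introgression candidates: intersect top-percentile
introgression windows with Fst outliers and gene annotation.

All intervals are half-open [start, end): an outlier at a window's start
coordinate is contained, one at its end coordinate is not. Overlapping or
boundary-sharing windows on a chromosome merge into maximal continuous
regions. A gene is a candidate only when it overlaps a merged region AND
contains at least one retained Fst outlier — overlap with the window
alone is not enough (a relaxed mode reports window-only overlaps with
the distance to the nearest outlier instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MergedRegion",
    "intersect_outliers_windows",
    "merge_windows",
    "genes_in_candidates",
]


@dataclass
class MergedRegion:
    chrom: str
    start: int
    end: int
    source_windows: list[int] = field(default_factory=list)
    n_outliers_contained: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start


def intersect_outliers_windows(
    windows: pd.DataFrame, outliers: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windows containing >= 1 outlier position, and the outliers
    annotated with their containing window index.

    ``windows`` needs columns chrom/start/end (half-open);
    ``outliers`` needs chrom/pos. Returns (retained windows, contained
    outliers with a ``window_index`` column referring to the retained
    windows' original index).
    """
    win = windows.reset_index(drop=True)
    hits: list[tuple[int, int]] = []  # (outlier row, window row)
    for wi, w in win.iterrows():
        inside = (
            (outliers["chrom"] == w["chrom"])
            & (outliers["pos"] >= w["start"])
            & (outliers["pos"] < w["end"])
        )
        hits.extend((oi, wi) for oi in outliers.index[inside])
    if not hits:
        empty = outliers.iloc[0:0].copy()
        empty["window_index"] = pd.Series(dtype=int)
        return win.iloc[0:0].copy(), empty
    hit_df = pd.DataFrame(hits, columns=["outlier_index", "window_index"])
    kept_windows = win.loc[sorted(hit_df["window_index"].unique())].copy()
    annotated = outliers.loc[hit_df["outlier_index"]].copy()
    annotated["window_index"] = hit_df["window_index"].to_numpy()
    return kept_windows, annotated.reset_index(drop=True)


def merge_windows(windows: pd.DataFrame, gap: int = 0) -> list[MergedRegion]:
    """Merge overlapping or boundary-adjacent windows per chromosome into
    maximal continuous regions (``gap`` allows merging across small
    gaps; 0 means only touching or overlapping windows merge)."""
    regions: list[MergedRegion] = []
    win = windows.reset_index()
    for chrom in dict.fromkeys(win["chrom"]):
        sub = win[win["chrom"] == chrom].sort_values(["start", "end"])
        current: MergedRegion | None = None
        for _, row in sub.iterrows():
            if current is not None and row["start"] <= current.end + gap:
                current.end = max(current.end, int(row["end"]))
                current.source_windows.append(int(row["index"]))
            else:
                if current is not None:
                    regions.append(current)
                current = MergedRegion(
                    chrom=chrom,
                    start=int(row["start"]),
                    end=int(row["end"]),
                    source_windows=[int(row["index"])],
                )
        if current is not None:
            regions.append(current)
    return regions


def genes_in_candidates(
    regions: list[MergedRegion],
    outliers: pd.DataFrame,
    genes: pd.DataFrame,
    gene_in_window_only: bool = False,
) -> pd.DataFrame:
    """Per-chromosome candidate report plus gene lists.

    A gene counts when it overlaps a merged region and (unless
    ``gene_in_window_only``) also contains at least one retained outlier
    position. The report has one row per chromosome with the number of
    source windows, total merged span, number of contained outliers,
    number of candidate protein-coding genes and their ids, plus the
    signed distance from each region to its nearest gene when no gene
    qualifies (negative = gene upstream of the region start).
    """

    def overlaps(a_start, a_end, b_start, b_end) -> bool:
        return a_start < b_end and b_start < a_end

    # an outlier annotated against several overlapping windows is still a
    # single genomic position
    outliers = outliers.drop_duplicates(subset=["chrom", "pos"])

    for region in regions:
        inside = (
            (outliers["chrom"] == region.chrom)
            & (outliers["pos"] >= region.start)
            & (outliers["pos"] < region.end)
        )
        region.n_outliers_contained = int(inside.sum())

    rows = []
    for chrom in dict.fromkeys(r.chrom for r in regions):
        chrom_regions = [r for r in regions if r.chrom == chrom]
        chrom_outliers = outliers[outliers["chrom"] == chrom]
        chrom_genes = genes[genes["chrom"] == chrom]
        candidate_ids: list[str] = []
        nearest: tuple[str, int] | None = None
        for _, gene in chrom_genes.iterrows():
            in_region = any(
                overlaps(gene["start"], gene["end"], r.start, r.end)
                for r in chrom_regions
            )
            if not in_region:
                continue
            has_outlier = (
                (chrom_outliers["pos"] >= gene["start"])
                & (chrom_outliers["pos"] < gene["end"])
            ).any()
            if gene_in_window_only or has_outlier:
                candidate_ids.append(gene["gene_id"])
        if not candidate_ids and len(chrom_genes):
            # nearest-gene annotation for the zero-gene case
            best_d = None
            for _, gene in chrom_genes.iterrows():
                for r in chrom_regions:
                    if overlaps(gene["start"], gene["end"], r.start, r.end):
                        d = 0
                    elif gene["end"] <= r.start:
                        d = int(gene["end"] - r.start)  # negative: upstream
                    else:
                        d = int(gene["start"] - r.end)
                    if best_d is None or abs(d) < abs(best_d[1]):
                        best_d = (gene["gene_id"], d)
            nearest = best_d
        rows.append(
            {
                "chrom": chrom,
                "n_windows": sum(len(r.source_windows) for r in chrom_regions),
                "total_span": sum(r.span for r in chrom_regions),
                "n_fst_outliers": int(
                    sum(r.n_outliers_contained for r in chrom_regions)
                ),
                "n_genes": len(candidate_ids),
                "gene_ids": ",".join(candidate_ids),
                "nearest_gene": nearest[0] if nearest else "",
                "nearest_gene_distance": nearest[1] if nearest else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "n_windows", "total_span", "n_fst_outliers",
            "n_genes", "gene_ids", "nearest_gene", "nearest_gene_distance",
        ],
    )
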