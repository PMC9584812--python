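"""Windowed nucleotide diversity and per-site two-population Fst.

Nucleotide diversity uses the unbiased per-site estimator
pi_i = 2 * n_ref * n_alt / (n * (n - 1)) over called allele counts,
summed within fixed-span windows (default 100 kb, anchored at 0,
non-overlapping) and divided by the window span in bp; the population
summary is the mean over windows. Fst uses the Weir-Cockerham (1984)
single-site variance-components estimator a / (a + b + c) by default
(the convention of the VCF toolkits), with a Hudson-estimator mode for
robustness comparisons; negative estimates are reported as-is and only
undefined values are excluded from percentile ranking.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PopulationMap
from .window_scan import nearest_rank_threshold

__all__ = ["windowed_pi", "per_site_fst", "fst_outliers"]


def windowed_pi(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    population: str,
    window_bp: int = 100_000,
) -> tuple[pd.DataFrame, float]:
    """Per-window nucleotide diversity for one population and its mean.

    Windows tile each chromosome from position 0; the trailing partial
    window keeps its true span as denominator. Chromosome lengths come
    from the matrix's contig table (falling back to the last variant
    position). Sites with fewer than 2 called alleles are skipped;
    windows without variants have pi = 0.
    """
    idx = gm.sample_index(pm.samples_in(population))
    d = gm.dosage[idx]
    called = np.isfinite(d)
    n = 2.0 * called.sum(axis=0)
    alt = np.where(called, d, 0.0).sum(axis=0)
    ref = n - alt
    ok = n >= 2
    pi_site = np.zeros(gm.n_sites)
    pi_site[ok] = 2.0 * ref[ok] * alt[ok] / (n[ok] * (n[ok] - 1.0))

    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    rows = []
    for chrom in dict.fromkeys(chroms):
        in_chrom = chroms == chrom
        length = gm.contig_lengths.get(chrom)
        if length is None:
            length = int(pos[in_chrom].max()) + 1 if in_chrom.any() else window_bp
        n_windows = max(1, -(-length // window_bp))
        sums = np.zeros(n_windows)
        win_of_site = pos[in_chrom] // window_bp
        np.add.at(sums, win_of_site, pi_site[in_chrom])
        for w in range(n_windows):
            start = w * window_bp
            end = min(start + window_bp, length)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "pi": sums[w] / (end - start),
                }
            )
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "pi"])
    return windows, float(windows["pi"].mean())


def _pop_counts(gm: GenotypeMatrix, pm: PopulationMap, pop: str):
    d = gm.dosage[gm.sample_index(pm.samples_in(pop))]
    called = np.isfinite(d)
    n_dip = called.sum(axis=0).astype(float)  # called diploids
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_dip > 0, np.where(called, d, 0.0).sum(axis=0) / (2 * n_dip), np.nan)
        h = np.where(n_dip > 0, np.where(called, d == 1.0, False).sum(axis=0) / n_dip, np.nan)
    return n_dip, p, h


def per_site_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    pop_a: str,
    pop_b: str,
    method: str = "wc",
) -> pd.DataFrame:
    """Per-site Fst between two populations.

    ``wc`` is the Weir-Cockerham estimator with variance components
    a (among populations), b (among individuals within populations) and
    c (within individuals, from observed heterozygosity); ``hudson`` is
    the Hudson/Bhatia estimator from allele counts. Sites where the
    estimator is undefined (monomorphic overall, or a population with
    fewer than the required calls) carry NaN.
    """
    if method not in ("wc", "hudson"):
        raise ValueError("method must be 'wc' or 'hudson'")
    for pop in (pop_a, pop_b):
        if len(pm.samples_in(pop)) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 samples")
    na, p_a, h_a = _pop_counts(gm, pm, pop_a)
    nb, p_b, h_b = _pop_counts(gm, pm, pop_b)

    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "wc":
            r = 2.0
            n_bar = (na + nb) / r
            p_bar = (na * p_a + nb * p_b) / (r * n_bar)
            s2 = (na * (p_a - p_bar) ** 2 + nb * (p_b - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = (na * h_a + nb * h_b) / (r * n_bar)
            nc = (r * n_bar - (na**2 + nb**2) / (r * n_bar)) / (r - 1)
            a = (n_bar / nc) * (
                s2
                - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - s2 * (r - 1) / r
                - h_bar * (2 * n_bar - 1) / (4 * n_bar)
            )
            c = h_bar / 2.0
            denom = a + b + c
            fst = np.where(denom != 0, a / denom, np.nan)
            fst = np.where((na >= 1) & (nb >= 1) & (n_bar > 1), fst, np.nan)
        else:
            ca, cb = 2 * na, 2 * nb  # allele counts
            num = (
                (p_a - p_b) ** 2
                - p_a * (1 - p_a) / (ca - 1)
                - p_b * (1 - p_b) / (cb - 1)
            )
            den = p_a * (1 - p_b) + p_b * (1 - p_a)
            fst = np.where((den != 0) & (ca > 1) & (cb > 1), num / den, np.nan)

    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"].to_numpy(),
            "pos": gm.sites["pos"].to_numpy(),
            "fst": fst,
        }
    )


def fst_outliers(records: pd.DataFrame, pct: float = 1.0) -> pd.DataFrame:
    """Sites whose defined Fst reaches the nearest-rank (100 - pct)th
    percentile threshold (ties at the threshold all included)."""
    vals = records["fst"].to_numpy(dtype=float)
    thr = nearest_rank_threshold(vals, pct)
    keep = np.isfinite(vals) & (vals >= thr)
    return records[keep].reset_index(drop=True)
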