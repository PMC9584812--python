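"""Sliding-window admixture statistics (D, f_d, f_dM, d_f) in SNP-count
windows, with top-percentile window selection.

Windows are tiled per chromosome by SNP index (default 1,000 usable SNPs,
step 500, i.e. 50% overlap); the final partial window is dropped. Per
site, with trio frequencies (p1, p2, p3) and outgroup pO:

    S_i     = ABBA_i - BABA_i                       (the D numerator)
    f_d     = sum(S) / sum(S with the donor frequency
              p_D = max(p2, p3) substituted for both P2 and P3)
    f_dM    = like f_d but the denominator switches to the P1 side
              (donor max(p1, p3)) whenever p1 > p2, with matching sign,
              so P3-P1 sharing yields negative values and the statistic
              is antisymmetric under P1 <-> P2 and bounded in [-1, 1]
    d_f     = sum(S) / sum(ABBA + BABA with the donor substitution), the
              distance-fraction form reported alongside the others

Window genomic span is [first SNP position, last SNP position + 1) in
half-open coordinates; selection downstream uses f_dM, with d_f reported
but never used for ranking.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import FrequencyTable

__all__ = ["scan_windows", "top_percentile_windows", "nearest_rank_threshold"]


def _site_components(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, po: np.ndarray
) -> dict[str, np.ndarray]:
    w = 1.0 - po
    abba = (1.0 - p1) * p2 * p3 * w
    baba = p1 * (1.0 - p2) * p3 * w
    pd23 = np.maximum(p2, p3)
    fd_den = ((1.0 - p1) * pd23 * pd23 - p1 * (1.0 - pd23) * pd23) * w
    pd13 = np.maximum(p1, p3)
    fdm_alt = (pd13 * (1.0 - p2) * pd13 - (1.0 - pd13) * p2 * pd13) * w
    fdm_den = np.where(p2 >= p1, fd_den, fdm_alt)
    df_den = ((1.0 - p1) * pd23 * pd23 + p1 * (1.0 - pd23) * pd23) * w
    return {
        "abba": abba,
        "baba": baba,
        "fd_den": fd_den,
        "fdm_den": fdm_den,
        "df_den": df_den,
    }


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0.0 else np.nan


def scan_windows(
    freqs: FrequencyTable,
    trio: Sequence[str],
    outgroup: str,
    window_snps: int = 1000,
    step_snps: int = 500,
) -> pd.DataFrame:
    """Windowed D, f_d, f_dM and d_f along the genome.

    ``freqs`` must carry its site table (chrom/pos) so windows can report
    genomic spans. Only sites usable for all four groups enter windows;
    a window with a zero denominator records NaN for that statistic but
    is retained.
    """
    if window_snps < 1 or step_snps < 1:
        raise ValueError("window_snps and step_snps must be >= 1")
    if freqs.sites is None:
        raise ValueError("FrequencyTable lacks a site table (chrom/pos)")
    usable = freqs.usable([*trio, outgroup])
    p1, p2, p3, po = (freqs.freqs[g][usable] for g in (*trio, outgroup))
    comp = _site_components(p1, p2, p3, po)
    chroms = freqs.sites["chrom"].to_numpy()[usable]
    pos = freqs.sites["pos"].to_numpy()[usable]

    rows = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx) - window_snps + 1, step_snps):
            block = idx[start : start + window_snps]
            s = comp["abba"][block].sum() - comp["baba"][block].sum()
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[block[0]]),
                    "end": int(pos[block[-1]]) + 1,
                    "n_snps": len(block),
                    "D": _safe_ratio(
                        s, comp["abba"][block].sum() + comp["baba"][block].sum()
                    ),
                    "f_d": _safe_ratio(s, comp["fd_den"][block].sum()),
                    "f_dM": _safe_ratio(s, comp["fdm_den"][block].sum()),
                    "d_f": _safe_ratio(s, comp["df_den"][block].sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "D", "f_d", "f_dM", "d_f"]
    )


def nearest_rank_threshold(values: np.ndarray, pct: float) -> float:
    """Value at the nearest-rank (100 - pct)th percentile of the defined
    values (the smallest value of the top pct%)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no defined values to rank")
    return float(np.percentile(vals, 100.0 - pct, method="higher"))


def top_percentile_windows(
    stats: pd.DataFrame,
    statistic: str = "f_dM",
    pct: float = 1.0,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Windows whose ``statistic`` reaches the top ``pct`` percent
    (nearest-rank threshold, ties included), optionally restricted to
    positive values. Windows with an undefined statistic never qualify."""
    if len(stats) == 0:
        raise ValueError("empty window table")
    vals = stats[statistic].to_numpy(dtype=float)
    thr = nearest_rank_threshold(vals, pct)
    keep = np.isfinite(vals) & (vals >= thr)
    if positive_only:
        keep &= vals > 0.0
    return stats[keep].reset_index(drop=True)
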