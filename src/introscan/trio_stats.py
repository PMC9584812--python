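"""Genome-wide ABBA-BABA statistics for population trios.

For an oriented trio (P1, P2, P3) with outgroup O, each usable biallelic
site contributes frequency-weighted pattern masses

    ABBA_i = (1 - p1) * p2 * p3 * (1 - pO)
    BABA_i = p1 * (1 - p2) * p3 * (1 - pO)

and Patterson's D = sum(ABBA - BABA) / sum(ABBA + BABA). Significance
comes from a delete-one block jackknife over contiguous site blocks
(default 20), which is robust to local linkage; the admixture fraction is
summarized by the f4-ratio with the donor population split in half.

Sites where the outgroup is polymorphic are kept with the (1 - pO)
weighting by default; ``polarize_drop`` instead drops them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import FrequencyTable, GenotypeMatrix, PopulationMap, dosage_frequency

__all__ = [
    "TrioResult",
    "DStatUndefinedError",
    "population_frequencies",
    "d_statistic",
    "f4_ratio",
    "dtrios_all",
]


class DStatUndefinedError(ValueError):
    """Raised when sum(ABBA + BABA) is zero and D is undefined."""


@dataclass
class TrioResult:
    """One oriented trio's genome-wide result (one output table row)."""

    p1: str
    p2: str
    p3: str
    d: float
    z: float
    p: float
    abba: float
    baba: float
    n_sites: int
    n_blocks: int
    se: float
    f4_ratio: float = np.nan
    zero_variance: bool = False


def population_frequencies(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    populations: Sequence[str] | None = None,
) -> FrequencyTable:
    """Alt-allele frequency per population per site from non-missing calls.

    A site's frequency for a population is NaN when no allele in that
    population is called there (the site is then unusable for any
    statistic that requires the population).
    """
    pops = list(populations) if populations is not None else pm.populations
    freqs: dict[str, np.ndarray] = {}
    n_called: dict[str, np.ndarray] = {}
    for pop in pops:
        idx = gm.sample_index(pm.samples_in(pop))
        freqs[pop], n_called[pop] = dosage_frequency(gm.dosage[idx])
    return FrequencyTable(freqs=freqs, sites=gm.sites, n_called=n_called)


def _pattern_sums(
    freqs: FrequencyTable,
    trio: Sequence[str],
    outgroup: str,
    polarize_drop: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    p1 = freqs.freqs[trio[0]]
    p2 = freqs.freqs[trio[1]]
    p3 = freqs.freqs[trio[2]]
    po = freqs.freqs[outgroup]
    usable = freqs.usable([*trio, outgroup])
    if polarize_drop:
        usable = usable & (po == 0.0)
    p1, p2, p3, po = (v[usable] for v in (p1, p2, p3, po))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - po)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - po)
    return abba, baba


def _jackknife_ratio(
    num: np.ndarray, den: np.ndarray, n_blocks: int
) -> tuple[float, float]:
    """Delete-one block jackknife SE and Z denominator for a ratio
    statistic sum(num)/sum(den) over contiguous blocks."""
    blocks = np.array_split(np.arange(len(num)), n_blocks)
    tot_num, tot_den = num.sum(), den.sum()
    d_jack = np.array(
        [
            (tot_num - num[b].sum()) / (tot_den - den[b].sum())
            for b in blocks
            if (tot_den - den[b].sum()) != 0
        ]
    )
    g = len(d_jack)
    if g < 2:
        return np.nan, 0.0
    se = np.sqrt((g - 1) / g * np.sum((d_jack - d_jack.mean()) ** 2))
    return float(se), g


def d_statistic(
    freqs: FrequencyTable,
    trio: Sequence[str],
    outgroup: str,
    n_blocks: int = 20,
    orient: bool = True,
    polarize_drop: bool = False,
) -> TrioResult:
    """Patterson's D with block-jackknife Z and one-tailed p.

    With ``orient`` (the reporting convention) P1 and P2 are swapped if
    needed so D >= 0; the p-value is one-tailed against D = 0. A zero
    jackknife variance is flagged (``zero_variance``) and yields no Z.
    """
    p1l, p2l, p3l = trio
    abba, baba = _pattern_sums(freqs, trio, outgroup, polarize_drop)
    denom = abba.sum() + baba.sum()
    if denom == 0.0:
        raise DStatUndefinedError(
            f"D undefined for trio ({p1l},{p2l},{p3l}): sum(ABBA+BABA) = 0"
        )
    d = (abba.sum() - baba.sum()) / denom
    if orient and d < 0:
        p1l, p2l = p2l, p1l
        abba, baba = baba, abba
        d = -d
    se, g = _jackknife_ratio(abba - baba, abba + baba, n_blocks)
    if not np.isfinite(se) or se == 0.0:
        return TrioResult(
            p1=p1l, p2=p2l, p3=p3l, d=float(d), z=np.nan, p=np.nan,
            abba=float(abba.sum()), baba=float(baba.sum()),
            n_sites=len(abba), n_blocks=n_blocks, se=float(se) if np.isfinite(se) else np.nan,
            zero_variance=True,
        )
    z = d / se
    p = float(sps.norm.sf(z))
    return TrioResult(
        p1=p1l, p2=p2l, p3=p3l, d=float(d), z=float(z), p=p,
        abba=float(abba.sum()), baba=float(baba.sum()),
        n_sites=len(abba), n_blocks=n_blocks, se=se,
    )


def _f4(pa, pb, pc, pd_, usable) -> float:
    m = usable
    return float(np.sum((pa[m] - pb[m]) * (pc[m] - pd_[m])))


def f4_ratio(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    trio: Sequence[str],
    outgroup: str,
    seed: int = 0,
) -> float:
    """Admixture-fraction estimate f4(P1,P2;P3a,O) / f4(P1,P3b;P3a,O).

    P3 is split in half at random (seeded) into the reference panel P3a
    and the proxy P3b. The ratio estimates the fraction of P2 ancestry
    derived from the P3 lineage; it can exceed 1 when the assumed
    population tree is violated.
    """
    p1l, p2l, p3l = trio
    p3_samples = pm.samples_in(p3l)
    if len(p3_samples) < 2:
        raise ValueError(f"f4-ratio needs >= 2 samples in P3 ({p3l!r})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(p3_samples))
    half = len(p3_samples) // 2
    p3a = [p3_samples[i] for i in perm[:half]]
    p3b = [p3_samples[i] for i in perm[half:]]

    def freq_of(sample_ids):
        f, _ = dosage_frequency(gm.dosage[gm.sample_index(sample_ids)])
        return f

    fp1 = freq_of(pm.samples_in(p1l))
    fp2 = freq_of(pm.samples_in(p2l))
    fpa = freq_of(p3a)
    fpb = freq_of(p3b)
    fo = freq_of(pm.samples_in(outgroup))
    usable = np.isfinite(fp1) & np.isfinite(fp2) & np.isfinite(fpa) & np.isfinite(fpb) & np.isfinite(fo)
    num = _f4(fp1, fp2, fpa, fo, usable)
    den = _f4(fp1, fpb, fpa, fo, usable)
    if den == 0.0:
        return np.nan
    return num / den


def dtrios_all(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    outgroup: str,
    n_blocks: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """D, Z, p and f4-ratio for every unordered trio of non-outgroup
    populations, oriented so D >= 0.

    Without a guide tree, P3 for each trio is chosen by the BBAA rule:
    the pair sharing the most derived alleles (largest BBAA mass) is
    treated as the sister pair (P1, P2). Rows are sorted by D descending.
    """
    pops = [p for p in pm.populations if p != outgroup]
    if len(pops) < 3:
        raise ValueError("need at least 3 non-outgroup populations")
    freqs = population_frequencies(gm, pm)

    def bbaa(a: str, b: str, c: str) -> float:
        pa, pb, pc = freqs.freqs[a], freqs.freqs[b], freqs.freqs[c]
        po = freqs.freqs[outgroup]
        m = freqs.usable([a, b, c, outgroup])
        return float(np.sum(pa[m] * pb[m] * (1 - pc[m]) * (1 - po[m])))

    rows = []
    for a, b, c in combinations(pops, 3):
        arrangements = [((a, b), c), ((a, c), b), ((b, c), a)]
        (s1, s2), p3 = max(arrangements, key=lambda arr: bbaa(arr[0][0], arr[0][1], arr[1]))
        res = d_statistic(freqs, (s1, s2, p3), outgroup, n_blocks=n_blocks)
        res.f4_ratio = f4_ratio(gm, pm, (res.p1, res.p2, res.p3), outgroup, seed=seed)
        rows.append(res)
    rows.sort(key=lambda r: -r.d)
    return pd.DataFrame(
        {
            "P1": [r.p1 for r in rows],
            "P2": [r.p2 for r in rows],
            "P3": [r.p3 for r in rows],
            "D": [r.d for r in rows],
            "Z": [r.z for r in rows],
            "p": [r.p for r in rows],
            "f4_ratio": [r.f4_ratio for r in rows],
            "ABBA": [r.abba for r in rows],
            "BABA": [r.baba for r in rows],
            "n_sites": [r.n_sites for r in rows],
        }
    )
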