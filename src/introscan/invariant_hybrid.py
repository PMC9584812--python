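"""Invariant-based hybridization detection with admixture-fraction (gamma)
estimation, at population and individual level.

For an ordered quartet (outgroup O, P1, putative hybrid H, P2) each usable
biallelic site contributes a probability mass to each of the 16
ancestral/derived site patterns, computed from the groups' allele
frequencies: the mass of pattern (sO, s1, sH, s2) is the product over the
four groups of the derived-allele frequency (if the group is derived in
the pattern) or one minus it. Summed over sites, the three discordant
patterns

    AABB: O,P1 ancestral; H,P2 derived
    ABAB: P1,P2 derived;  O,H ancestral
    ABBA: P1,H derived;   O,P2 ancestral

carry the hybridization signal. Writing x = f(AABB) - f(ABAB) and
y = f(ABBA) - f(ABAB) (proportions of usable sites), drift on the
parental branches makes both invariant differences proportional to the
parental-branch allele-frequency variance, with weights gamma and
1 - gamma: a hybrid whose allele copies derive from P2 with probability
gamma gives E[x] = gamma * v and E[y] = (1 - gamma) * v. Hence

    gamma_hat = x / (x + y)

and the test of no hybridization (gamma = 0, i.e. x = 0) uses the ratio
T = x / y with a delta-method normal approximation under multinomial
sampling of site patterns, exactly the invariant-ratio construction of
the hybrid-speciation coalescent test. Swapping P1 and P2 exchanges x and
y, so gamma_hat maps to 1 - gamma_hat by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GenotypeMatrix, PopulationMap, dosage_frequency

__all__ = [
    "QuartetPatternCounts",
    "HybridTestResult",
    "quartet_patterns",
    "hybrid_test",
    "individual_tests",
    "full_search",
]

# pattern index: bit 3 = outgroup, bit 2 = P1, bit 1 = H, bit 0 = P2
# (bit set = derived allele)
AABB = 0b0011
ABAB = 0b0101
ABBA = 0b0110


@dataclass
class QuartetPatternCounts:
    """Frequency-weighted site-pattern masses for one ordered quartet.

    ``mass[k]`` is the summed probability mass of pattern ``k`` (bit
    encoding above); masses are non-negative and sum to ``n_sites``
    exactly (each site distributes unit mass over the 16 patterns).
    """

    outgroup: str
    p1: str
    hybrid: str
    p2: str
    mass: np.ndarray  # shape (16,)
    n_sites: int

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (16,):
            raise ValueError("pattern mass vector must have length 16")
        if (self.mass < -1e-12).any():
            raise ValueError("pattern masses must be non-negative")


@dataclass
class HybridTestResult:
    """Invariant hybrid test outcome for (P1, hybrid, P2)."""

    p1: str
    hybrid: str
    p2: str
    z: float
    p: float
    gamma: float
    n_sites: int
    low_confidence: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.gamma)


def _pattern_masses(
    fo: np.ndarray, f1: np.ndarray, fh: np.ndarray, f2: np.ndarray
) -> tuple[np.ndarray, int]:
    usable = (
        np.isfinite(fo) & np.isfinite(f1) & np.isfinite(fh) & np.isfinite(f2)
    )
    fo, f1, fh, f2 = (v[usable] for v in (fo, f1, fh, f2))
    mass = np.empty(16)
    for k in range(16):
        terms = [
            fo if k & 0b1000 else 1.0 - fo,
            f1 if k & 0b0100 else 1.0 - f1,
            fh if k & 0b0010 else 1.0 - fh,
            f2 if k & 0b0001 else 1.0 - f2,
        ]
        mass[k] = np.sum(terms[0] * terms[1] * terms[2] * terms[3])
    return mass, int(usable.sum())


def quartet_patterns(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    order: Sequence[str],
    hybrid_sample: str | None = None,
) -> QuartetPatternCounts:
    """Accumulate site-pattern masses for the ordered quartet
    ``order = (outgroup, P1, hybrid, P2)``.

    With ``hybrid_sample`` the hybrid slot is a single individual (its
    frequency is dosage/2) rather than a population; ``order[2]`` then
    only labels the output.
    """
    og, p1, hyb, p2 = order

    def pop_freq(pop: str) -> np.ndarray:
        idx = gm.sample_index(pm.samples_in(pop))
        return dosage_frequency(gm.dosage[idx])[0]

    if hybrid_sample is not None:
        row = gm.sample_index([hybrid_sample])[0]
        fh = gm.dosage[row] / 2.0
        if not np.isfinite(fh).any():
            raise ValueError(
                f"individual {hybrid_sample!r} has no called genotypes"
            )
        hyb_label = hybrid_sample
    else:
        fh = pop_freq(hyb)
        hyb_label = hyb
    mass, n = _pattern_masses(pop_freq(og), pop_freq(p1), fh, pop_freq(p2))
    if n == 0:
        raise ValueError(f"no usable sites for quartet ({og},{p1},{hyb_label},{p2})")
    return QuartetPatternCounts(
        outgroup=og, p1=p1, hybrid=hyb_label, p2=p2, mass=mass, n_sites=n
    )


def hybrid_test(counts: QuartetPatternCounts) -> HybridTestResult:
    """Z-score, one-tailed p and gamma estimate from pattern masses.

    Undefined configurations (non-positive invariant denominator) are
    returned with NaN statistics and are never filtered in downstream.
    """
    n = counts.n_sites
    f = counts.mass / n
    fa, fb, fc = f[AABB], f[ABAB], f[ABBA]
    x = fa - fb
    y = fc - fb
    if x + y == 0.0 or y <= 0.0:
        return HybridTestResult(
            p1=counts.p1, hybrid=counts.hybrid, p2=counts.p2,
            z=np.nan, p=np.nan, gamma=np.nan, n_sites=n,
        )
    gamma = x / (x + y)
    t = x / y
    # multinomial covariance of the pattern proportions, delta method on x/y
    var_x = (fa + fb - (fa - fb) ** 2) / n
    var_y = (fc + fb - (fc - fb) ** 2) / n
    cov_xy = (fb - fb**2 + fa * fb + fb * fc - fa * fc) / n
    var_t = (var_x / y**2) + (x**2 * var_y / y**4) - (2 * x * cov_xy / y**3)
    if var_t <= 0.0:
        z = np.nan
        p = np.nan
    else:
        z = t / np.sqrt(var_t)
        p = float(sps.norm.sf(z))
    return HybridTestResult(
        p1=counts.p1, hybrid=counts.hybrid, p2=counts.p2,
        z=float(z), p=p, gamma=float(gamma), n_sites=n,
    )


def individual_tests(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    trio: Sequence[str],
    outgroup: str,
    min_callable_fraction: float = 0.5,
) -> list[HybridTestResult]:
    """Test every individual of the putative-hybrid population one at a
    time against the parental populations' pattern masses.

    An individual with no called genotypes raises; one callable at fewer
    than ``min_callable_fraction`` of the parental-usable sites is
    reported with ``low_confidence``.
    """
    p1, hyb_pop, p2 = trio

    def pop_freq(pop: str) -> np.ndarray:
        idx = gm.sample_index(pm.samples_in(pop))
        return dosage_frequency(gm.dosage[idx])[0]

    parental_usable = (
        np.isfinite(pop_freq(outgroup))
        & np.isfinite(pop_freq(p1))
        & np.isfinite(pop_freq(p2))
    )
    n_parental = int(parental_usable.sum())
    results = []
    for sample in pm.samples_in(hyb_pop):
        counts = quartet_patterns(
            gm, pm, (outgroup, p1, hyb_pop, p2), hybrid_sample=sample
        )
        res = hybrid_test(counts)
        if n_parental > 0 and counts.n_sites / n_parental < min_callable_fraction:
            res.low_confidence = True
        results.append(res)
    return results


def full_search(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    outgroup: str,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    filtered: bool = True,
) -> pd.DataFrame:
    """Test every directed (P1, hybrid, P2) arrangement of non-outgroup
    populations.

    Each unordered trio is tested with each member in the hybrid role
    (P1/P2 order is symmetric: it only reflects gamma about 1/2), giving
    3 * C(k, 3) arrangements for k candidate populations. ``correction``
    is ``"bonferroni"`` across all arrangements or ``"none"`` (raw p).
    With ``filtered`` (the reporting convention) only significant
    arrangements with 0 < gamma < 1 are returned, sorted by p then Z
    descending; otherwise the full annotated table is returned.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    pops = [p for p in pm.populations if p != outgroup]
    if len(pops) < 3:
        raise ValueError("need at least 3 candidate populations")
    results = []
    for a, b, c in combinations(pops, 3):
        for hyb in (a, b, c):
            par = [p for p in (a, b, c) if p != hyb]
            counts = quartet_patterns(gm, pm, (outgroup, par[0], hyb, par[1]))
            results.append(hybrid_test(counts))
    m = len(results)
    threshold = alpha / m if correction == "bonferroni" else alpha
    df = pd.DataFrame(
        {
            "P1": [r.p1 for r in results],
            "Hybrid": [r.hybrid for r in results],
            "P2": [r.p2 for r in results],
            "Z": [r.z for r in results],
            "p": [r.p for r in results],
            "gamma": [r.gamma for r in results],
            "n_sites": [r.n_sites for r in results],
        }
    )
    df["significant"] = np.isfinite(df["p"]) & (df["p"] < threshold)
    df["filtered_in"] = (
        df["significant"] & (df["gamma"] > 0.0) & (df["gamma"] < 1.0)
    )
    df = df.sort_values(["p", "Z"], ascending=[True, False]).reset_index(drop=True)
    if filtered:
        return df[df["filtered_in"]].reset_index(drop=True)
    return df
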