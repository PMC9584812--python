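"""Ancestry-diagnostic fixed-difference sites and the hybrid index.

A site is diagnostic between two parental panels when every panel-A
sample is called and homozygous for one allele, every panel-B sample is
called and homozygous for the other allele, the site is a biallelic SNP
and QUAL passes (default >= 30). Each target sample is then scored by the
fraction of its allele copies at called diagnostic sites that match the
panel-A allele (a heterozygote contributes one copy of each), which is
the unbiased estimator of the genomic ancestry fraction; per-sample
indices can be averaged by geographic region, and the diagnostic set's
error rate is estimated on a validation panel of presumed-pure samples
as discordant allele copies over total called copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "DiagnosticSiteSet",
    "HybridIndexResult",
    "FdrEstimate",
    "find_diagnostic_sites",
    "hybrid_index",
    "aggregate_by_region",
    "estimate_fdr",
]


@dataclass
class DiagnosticSiteSet:
    """Fixed-difference diagnostic sites with provenance.

    ``table`` has columns ``chrom, pos, ref, alt, alleleA, alleleB,
    dosageA`` where ``dosageA`` is the alt-dosage (0 or 2) of a panel-A
    homozygote — the panel-A allele need not be REF.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.table) and (self.table["alleleA"] == self.table["alleleB"]).any():
            raise ValueError("diagnostic site with identical panel alleles")

    def __len__(self) -> int:
        return len(self.table)

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out["pos"] = out["pos"] + 1  # 1-based on output
        out.to_csv(path, sep="\t", index=False)


@dataclass
class HybridIndexResult:
    sample: str
    n_sites_called: int
    frac_a: float

    @property
    def frac_b(self) -> float:
        return 1.0 - self.frac_a


@dataclass
class FdrEstimate:
    total_calls: int
    discordant_calls: int

    @property
    def rate(self) -> float:
        return self.discordant_calls / self.total_calls


def find_diagnostic_sites(
    gm: GenotypeMatrix,
    panel_a_ids: Sequence[str],
    panel_b_ids: Sequence[str],
    min_qual: float = 30.0,
) -> DiagnosticSiteSet:
    """Sites fixed for opposite alleles in the two panels.

    Requires a complete call in every panel sample; QUAL below
    ``min_qual`` or a non-biallelic-SNP flag disqualifies the site.
    """
    overlap = set(panel_a_ids) & set(panel_b_ids)
    if overlap:
        raise ValueError(f"panels overlap: {sorted(overlap)}")
    if not panel_a_ids or not panel_b_ids:
        raise ValueError("both panels must be non-empty")
    da = gm.dosage[gm.sample_index(panel_a_ids)]
    db = gm.dosage[gm.sample_index(panel_b_ids)]
    a_hom_ref = (da == 0.0).all(axis=0)
    a_hom_alt = (da == 2.0).all(axis=0)
    b_hom_ref = (db == 0.0).all(axis=0)
    b_hom_alt = (db == 2.0).all(axis=0)
    qual_ok = np.nan_to_num(gm.sites["qual"].to_numpy(dtype=float), nan=0.0) >= min_qual
    biallelic = gm.sites["is_biallelic_snp"].to_numpy(dtype=bool)
    fixed_diff = (a_hom_ref & b_hom_alt) | (a_hom_alt & b_hom_ref)
    keep = fixed_diff & qual_ok & biallelic
    sub = gm.sites.loc[keep, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    a_is_alt = a_hom_alt[keep]
    sub["alleleA"] = np.where(a_is_alt, sub["alt"], sub["ref"])
    sub["alleleB"] = np.where(a_is_alt, sub["ref"], sub["alt"])
    sub["dosageA"] = np.where(a_is_alt, 2.0, 0.0)
    return DiagnosticSiteSet(
        table=sub,
        provenance={
            "panel_a": list(panel_a_ids),
            "panel_b": list(panel_b_ids),
            "min_qual": min_qual,
        },
    )


def _match_sites(gm: GenotypeMatrix, sites: DiagnosticSiteSet) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the matrix sites corresponding to the diagnostic set,
    plus the matched rows of the diagnostic table (by chrom, pos)."""
    key = gm.sites.reset_index()[["index", "chrom", "pos"]]
    merged = sites.table.merge(key, on=["chrom", "pos"], how="inner")
    return merged["index"].to_numpy(), merged["dosageA"].to_numpy()


def hybrid_index(
    gm: GenotypeMatrix,
    sites: DiagnosticSiteSet,
    sample: str,
    per_genotype: bool = False,
) -> HybridIndexResult:
    """Fraction of a sample's allele copies matching the panel-A allele.

    Missing diagnostic sites are excluded from numerator and denominator;
    zero called diagnostic sites is an error, never silently 0.0. With
    ``per_genotype`` heterozygous calls are excluded and the fraction is
    taken over homozygous calls only.
    """
    idx, dos_a = _match_sites(gm, sites)
    row = gm.sample_index([sample])[0]
    d = gm.dosage[row, idx]
    called = np.isfinite(d)
    if called.sum() == 0:
        raise ValueError(
            f"sample {sample!r}: no called genotypes at diagnostic sites"
        )
    d, dos_a = d[called], dos_a[called]
    copies_a = np.where(dos_a == 2.0, d, 2.0 - d)
    if per_genotype:
        hom = (copies_a == 0.0) | (copies_a == 2.0)
        if hom.sum() == 0:
            raise ValueError(f"sample {sample!r}: no homozygous diagnostic calls")
        frac = float((copies_a[hom] == 2.0).mean())
        return HybridIndexResult(sample=sample, n_sites_called=int(hom.sum()), frac_a=frac)
    frac = float(copies_a.sum() / (2.0 * called.sum()))
    return HybridIndexResult(sample=sample, n_sites_called=int(called.sum()), frac_a=frac)


def aggregate_by_region(
    results: Sequence[HybridIndexResult] | pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Unweighted per-region mean of fracA/fracB with sample counts.

    ``metadata`` maps ``sample`` to ``region``; samples without a region
    are excluded with a warning.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            {
                "sample": [r.sample for r in results],
                "frac_a": [r.frac_a for r in results],
            }
        )
    regions = dict(zip(metadata["sample"], metadata["region"]))
    missing = [s for s in results["sample"] if not regions.get(s)]
    if missing:
        warnings.warn(
            f"samples without region excluded: {sorted(missing)}", stacklevel=2
        )
    df = results[~results["sample"].isin(missing)].copy()
    df["region"] = df["sample"].map(regions)
    out = (
        df.groupby("region", sort=True)
        .agg(n_samples=("sample", "size"), mean_frac_a=("frac_a", "mean"))
        .reset_index()
    )
    out["mean_frac_b"] = 1.0 - out["mean_frac_a"]
    return out


def estimate_fdr(
    validation: GenotypeMatrix,
    sites: DiagnosticSiteSet,
    expected_panel: str = "A",
) -> FdrEstimate:
    """Discordance rate of a presumed-pure validation panel at the
    diagnostic sites, counted in allele copies (matching the hybrid-index
    units)."""
    if expected_panel not in ("A", "B"):
        raise ValueError("expected_panel must be 'A' or 'B'")
    idx, dos_a = _match_sites(validation, sites)
    expected = dos_a if expected_panel == "A" else 2.0 - dos_a
    d = validation.dosage[:, idx]
    called = np.isfinite(d)
    total = int(2 * called.sum())
    if total == 0:
        raise ValueError("no called genotypes at diagnostic sites")
    diff = np.abs(d - expected[np.newaxis, :])
    discordant = int(np.nansum(np.where(called, diff, 0.0)))
    return FdrEstimate(total_calls=total, discordant_calls=discordant)
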