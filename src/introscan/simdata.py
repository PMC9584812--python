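"""Synthetic admixed-population genotype simulator with known truth.

Population allele frequencies follow the Balding–Nichols drift model on
the fixed population tree ``((P1,P2),P3),Outgroup``: each branch draws a
child frequency from a Beta distribution with mean equal to the parent
frequency and variance ``p(1-p)F``, where ``F`` is the branch's drift
coefficient. Diploid genotypes are then binomial draws from the population
frequency at independent sites; an admixed individual draws the ancestry
of each allele copy from Bernoulli(gamma) (P2 with probability gamma,
else P1) and then the allele from the donor population's frequency, so the
expected alt dosage is ``2(gamma*p2 + (1-gamma)*p1)`` at every site.

The outgroup is fixed for the ancestral allele by default, which makes
"derived" unambiguous for polarized statistics; a drifting-outgroup option
exists for robustness experiments. Optional P3->P2 gene flow replaces a
configurable fraction of loci (scattered or one contiguous segment) so
that window scans and trio statistics can be exercised against a known
introgressed truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FrequencyTable, GenotypeMatrix, PopulationMap

__all__ = [
    "SimulationConfig",
    "draw_population_frequencies",
    "simulate_genotypes",
    "simulate_dataset",
    "write_simulated_vcf",
    "write_population_map",
    "write_truth_table",
]

#: branch labels of the fixed population tree; "P12" is the internal branch
#: leading to the (P1, P2) ancestor.
BRANCHES = ("P1", "P2", "P3", "P12", "OUT")

_LAWS = {"uniform", "beta", "gamma", "constant"}


def _draw_law(law: tuple, rng: np.random.Generator, size: int) -> np.ndarray:
    name, *params = law
    if name == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size)
    if name == "beta":
        a, b = params
        return rng.beta(a, b, size)
    if name == "gamma":
        shape, scale = params
        return rng.gamma(shape, scale, size)
    if name == "constant":
        return np.full(size, float(params[0]))
    raise ValueError(f"unknown law {name!r}; expected one of {sorted(_LAWS)}")


def _law_support(law: tuple) -> tuple[float, float]:
    name, *params = law
    if name == "uniform":
        return params[0], params[1]
    if name == "beta":
        return 0.0, 1.0
    if name == "gamma":
        return 0.0, math.inf
    if name == "constant":
        return params[0], params[0]
    raise ValueError(f"unknown law {name!r}")


@dataclass
class SimulationConfig:
    """Full description of one synthetic dataset; the seed determines it.

    Defaults mirror the study design the package is exercised against:
    moderately diverged parental populations (terminal drift F = 0.1, a
    shared internal branch F = 0.05), an outgroup fixed ancestral, QUAL
    scores with a realistic spread (Gamma, mean 60, ~14% below 30 so the
    quality filter has work to do), and no gene flow unless asked for.
    """

    n_sites: int = 50_000
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"P1": 8, "P2": 8, "P3": 8, "OUT": 2}
    )
    drift: dict[str, float] = field(
        default_factory=lambda: {"P1": 0.1, "P2": 0.1, "P3": 0.1, "P12": 0.05, "OUT": 0.0}
    )
    gamma_per_individual: dict[str, float] = field(default_factory=dict)
    hybrid_parents: tuple[str, str] = ("P1", "P2")
    geneflow_rate: float = 0.0
    geneflow_strength: float = 1.0
    geneflow_contiguous: bool = False
    geneflow_source: str = "P3"
    geneflow_target: str = "P2"
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    qual_law: tuple = ("gamma", 4.0, 15.0)
    missing_rate: float = 0.0
    region_labels: dict[str, str] = field(default_factory=dict)
    outgroup_pop: str = "OUT"
    outgroup_drifts: bool = False
    n_chroms: int = 1
    site_spacing_bp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")
        for pop, n in self.pop_sizes.items():
            if n < 1:
                raise ValueError(f"pop_sizes[{pop!r}] must be >= 1")
        for branch, f in self.drift.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"drift F for {branch!r} must be in [0, 1)")
        for sample, g in self.gamma_per_individual.items():
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"gamma for {sample!r} must be in [0, 1]")
        if not 0.0 <= self.geneflow_rate <= 1.0:
            raise ValueError("geneflow_rate must be in [0, 1]")
        if not 0.0 <= self.geneflow_strength <= 1.0:
            raise ValueError("geneflow_strength must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = _law_support(self.ancestral_freq_law)
        if lo < 0.0 or hi > 1.0:
            raise ValueError("ancestral_freq_law must have support within (0, 1)")

    @property
    def sample_ids(self) -> list[str]:
        """Deterministic sample naming: ``<pop>_<i>`` with i from 1."""
        out = []
        for pop, n in self.pop_sizes.items():
            out.extend(f"{pop}_{i + 1}" for i in range(n))
        return out


def _balding_nichols(
    parent: np.ndarray, f: float, rng: np.random.Generator
) -> np.ndarray:
    """One Balding–Nichols drift step: Beta(mean=parent, var=p(1-p)F)."""
    if f == 0.0:
        return parent.copy()
    out = parent.copy()
    interior = (parent > 0.0) & (parent < 1.0)
    p = parent[interior]
    scale = (1.0 - f) / f
    out[interior] = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(out, 0.0, 1.0)


def _site_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_sites
    per_chrom = [len(block) for block in np.array_split(np.arange(n), config.n_chroms)]
    chroms, pos = [], []
    for c, count in enumerate(per_chrom, start=1):
        chroms.extend([f"chr{c}"] * count)
        pos.extend(config.site_spacing_bp * np.arange(count))
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=object),
            "pos": np.asarray(pos, dtype=int),
            "ref": bases[ref_idx] if n else np.array([], dtype=object),
            "alt": bases[alt_idx] if n else np.array([], dtype=object),
            "qual": np.nan,
            "is_biallelic_snp": True,
        }
    )


def draw_population_frequencies(config: SimulationConfig) -> FrequencyTable:
    """Draw per-site population allele frequencies under the drift model.

    Returns a :class:`FrequencyTable` for P1, P2, P3 and the outgroup;
    the outgroup frequency is 0 everywhere (ancestral) unless
    ``outgroup_drifts`` is set. The table's site frame carries an
    ``introgressed`` truth column marking loci where P3->P2 gene flow was
    applied.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    ancestral = _draw_law(config.ancestral_freq_law, rng, n)
    f = {b: config.drift.get(b, 0.0) for b in BRANCHES}
    p12 = _balding_nichols(ancestral, f["P12"], rng)
    freqs = {
        "P1": _balding_nichols(p12, f["P1"], rng),
        "P2": _balding_nichols(p12, f["P2"], rng),
        "P3": _balding_nichols(ancestral, f["P3"], rng),
    }
    if config.outgroup_drifts:
        freqs[config.outgroup_pop] = _balding_nichols(ancestral, f["OUT"], rng)
    else:
        freqs[config.outgroup_pop] = np.zeros(n)
    # any further configured population is an independent lineage off the
    # root (its own terminal branch, default F = 0.1)
    extras = sorted(
        p
        for p in config.pop_sizes
        if p not in ("P1", "P2", "P3", config.outgroup_pop)
    )
    for pop in extras:
        freqs[pop] = _balding_nichols(
            ancestral, config.drift.get(pop, 0.1), rng
        )

    introgressed = np.zeros(n, dtype=bool)
    n_flow = int(round(config.geneflow_rate * n))
    if n_flow > 0:
        if config.geneflow_contiguous:
            start = int(rng.integers(0, n - n_flow + 1))
            introgressed[start : start + n_flow] = True
        else:
            introgressed[rng.choice(n, size=n_flow, replace=False)] = True
        s = config.geneflow_strength
        src = freqs[config.geneflow_source]
        tgt = freqs[config.geneflow_target]
        freqs[config.geneflow_target] = np.where(
            introgressed, (1.0 - s) * tgt + s * src, tgt
        )

    sites = _site_table(config, rng)
    sites["introgressed"] = introgressed
    sites["ancestral_freq"] = ancestral
    return FrequencyTable(freqs=freqs, sites=sites)


def simulate_genotypes(
    freqs: FrequencyTable, config: SimulationConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw diploid genotypes for every configured sample.

    Pure individuals draw two allele copies Bernoulli(p_pop) per site;
    a sample listed in ``gamma_per_individual`` is a hybrid between the
    two ``hybrid_parents`` populations. The outgroup is homozygous
    ancestral throughout (unless the outgroup drifts). Returns the
    genotype matrix and a truth table with one row per sample (true
    gamma, maternal lineage, region).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_sites
    pa, pb = config.hybrid_parents
    samples = config.sample_ids
    unknown = set(config.gamma_per_individual) - set(samples)
    if unknown:
        raise KeyError(f"gamma entries for unknown sample ids: {sorted(unknown)}")
    dosage = np.empty((len(samples), n))
    truth_rows = []
    for row, sample in enumerate(samples):
        pop = sample.rsplit("_", 1)[0]
        if sample in config.gamma_per_individual:
            g = config.gamma_per_individual[sample]
            p1, p2 = freqs.freqs[pa], freqs.freqs[pb]
            copies = np.zeros(n)
            for _ in range(2):
                from_p2 = rng.random(n) < g
                donor_p = np.where(from_p2, p2, p1)
                copies += rng.random(n) < donor_p
            dosage[row] = copies
            maternal = pb if rng.random() < g else pa
            truth_rows.append((sample, g, maternal))
        else:
            if pop not in freqs.freqs:
                raise KeyError(
                    f"sample {sample!r}: population {pop!r} has no simulated "
                    "frequencies and no gamma entry"
                )
            p = freqs.freqs[pop]
            dosage[row] = rng.binomial(2, p)
            gamma_truth = {pa: 0.0, pb: 1.0}.get(pop, np.nan)
            truth_rows.append((sample, gamma_truth, pop))

    sites = (
        freqs.sites.copy()
        if freqs.sites is not None
        else _site_table(config, np.random.default_rng(config.seed))
    )
    sites["qual"] = _draw_law(config.qual_law, rng, n)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    contig_lengths = {
        chrom: int(grp["pos"].max()) + config.site_spacing_bp
        for chrom, grp in sites.groupby("chrom", sort=False)
    }
    gm = GenotypeMatrix(
        samples=samples, sites=sites, dosage=dosage, contig_lengths=contig_lengths
    )
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "true_gamma", "maternal_lineage"]
    )
    truth["region"] = [config.region_labels.get(s, "") for s in truth["sample"]]
    return gm, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, PopulationMap]:
    """Convenience wrapper: frequencies + genotypes + population map."""
    freqs = draw_population_frequencies(config)
    gm, truth = simulate_genotypes(freqs, config)
    assignments = {s: s.rsplit("_", 1)[0] for s in gm.samples}
    roles = {config.outgroup_pop: "outgroup"}
    pm = PopulationMap(assignments=assignments, roles=roles)
    return gm, truth, pm


def _format_gt(d: float) -> str:
    if np.isnan(d):
        return "./."
    return {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[d]


def write_simulated_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal standards-conformant VCF 4.2 file.

    GT is the only FORMAT field; QUAL is written per site ('.' when
    unknown); internal 0-based positions become 1-based on output.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan-simdata\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = gm.contig_lengths or {
            c: int(g["pos"].max()) + 1 for c, g in gm.sites.groupby("chrom", sort=False)
        }
        for chrom in dict.fromkeys(list(gm.sites["chrom"]) + list(contigs)):
            length = contigs.get(chrom)
            if length is None:
                sub = gm.sites.loc[gm.sites["chrom"] == chrom, "pos"]
                length = int(sub.max()) + 1 if len(sub) else 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        quals = gm.sites["qual"].to_numpy()
        for j in range(gm.n_sites):
            site = gm.sites.iloc[j]
            qual = "." if np.isnan(quals[j]) else f"{quals[j]:.2f}"
            gts = "\t".join(_format_gt(gm.dosage[i, j]) for i in range(gm.n_samples))
            fh.write(
                f"{site['chrom']}\t{int(site['pos']) + 1}\t.\t{site['ref']}\t"
                f"{site['alt']}\t{qual}\t.\t.\tGT\t{gts}\n"
            )


def write_population_map(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\trole\n")
        for sample, pop in pm.assignments.items():
            fh.write(f"{sample}\t{pop}\t{pm.roles.get(pop, '')}\n")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
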