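"""Shared fixtures and small builders for the test suite.

All genotype fixtures are generated programmatically; nothing is read
from disk except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introscan.containers import GenotypeMatrix, PopulationMap
from introscan.simdata import SimulationConfig, simulate_dataset


def make_gm(
    dosage,
    samples=None,
    chrom="chr1",
    pos=None,
    qual=50.0,
    ref="A",
    alt="T",
    contig_lengths=None,
) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix from a dosage array (samples x sites)."""
    dosage = np.asarray(dosage, dtype=float)
    n_samples, n_sites = dosage.shape
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    if pos is None:
        pos = np.arange(n_sites) * 100
    chroms = [chrom] * n_sites if isinstance(chrom, str) else list(chrom)
    quals = np.full(n_sites, qual, dtype=float) if np.isscalar(qual) else np.asarray(qual, dtype=float)
    refs = [ref] * n_sites if isinstance(ref, str) else list(ref)
    alts = [alt] * n_sites if isinstance(alt, str) else list(alt)
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(pos, dtype=int),
            "ref": refs,
            "alt": alts,
            "qual": quals,
            "is_biallelic_snp": True,
        }
    )
    return GenotypeMatrix(
        samples=list(samples),
        sites=sites,
        dosage=dosage,
        contig_lengths=contig_lengths or {},
    )


@pytest.fixture(scope="session")
def hybrid_dataset():
    """50k-site dataset with a 4-member putative-hybrid group of two F1s
    and two pure-P1 individuals (the worked-example design)."""
    cfg = SimulationConfig(
        n_sites=50_000,
        pop_sizes={"P1": 8, "P2": 8, "HYB": 4, "OUT": 2},
        gamma_per_individual={
            "HYB_1": 0.5, "HYB_2": 0.5, "HYB_3": 0.0, "HYB_4": 0.0,
        },
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No gene flow, no hybrids: every polarized statistic is null."""
    cfg = SimulationConfig(n_sites=20_000, seed=12)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def geneflow_dataset():
    """P3 -> P2 gene flow at 20% of loci, plus an unadmixed P4 lineage."""
    cfg = SimulationConfig(
        n_sites=20_000,
        pop_sizes={"P1": 6, "P2": 6, "P3": 6, "P4": 6, "OUT": 2},
        drift={"P1": 0.1, "P2": 0.1, "P3": 0.1, "P4": 0.1, "P12": 0.05},
        geneflow_rate=0.2,
        seed=13,
    )
    return simulate_dataset(cfg)
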