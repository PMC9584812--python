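"""Simulate gene flow between two diverged populations and detect it with
genome-wide ABBA-BABA statistics.

Two sister populations (P1, P2) diverge from a third (P3) under
Balding-Nichols drift; 20% of loci in P2 are then replaced with P3-derived
variation. The D statistic contrasts the two discordant site-pattern
classes: a positive D with a large jackknife Z means P2 shares more
derived alleles with P3 than P1 does, and the f4-ratio estimates the
admixture fraction.
"""

from introscan.simdata import SimulationConfig, simulate_dataset
from introscan.trio_stats import dtrios_all

cfg = SimulationConfig(n_sites=50_000, geneflow_rate=0.2, seed=1)
gm, truth, pm = simulate_dataset(cfg)

table = dtrios_all(gm, pm, outgroup="OUT", seed=1)
print(table[["P1", "P2", "P3", "D", "Z", "p", "f4_ratio"]].to_string(index=False))
print()
print(
    "D > 0 with |Z| >> 3 flags excess P2-P3 allele sharing; the f4-ratio\n"
    "is close to the simulated 0.2 fraction of introgressed loci."
)
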