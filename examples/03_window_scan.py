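"""Localize an introgressed genomic segment with a sliding-window f_dM
scan and top-percentile selection.

10% of loci, in one contiguous block, carry P3->P2 gene flow at donor
fraction 0.5. Windows of 1,000 SNPs (step 500) are scored with D, f_d,
f_dM and d_f; the top-percentile positive-f_dM windows should coincide
with the true segment.
"""

from introscan.simdata import SimulationConfig, simulate_dataset
from introscan.trio_stats import population_frequencies
from introscan.window_scan import scan_windows, top_percentile_windows

cfg = SimulationConfig(
    n_sites=50_000,
    geneflow_rate=0.1,
    geneflow_strength=0.5,
    geneflow_contiguous=True,
    seed=1,
)
gm, _, pm = simulate_dataset(cfg)
freqs = population_frequencies(gm, pm)

stats = scan_windows(freqs, ("P1", "P2", "P3"), "OUT", window_snps=1000, step_snps=500)
top = top_percentile_windows(stats, "f_dM", pct=2)

seg = gm.sites.loc[gm.sites["introgressed"], "pos"]
print(f"{len(stats)} windows scanned; true segment spans {seg.min()}-{seg.max()} bp")
print("\ntop 2% windows by f_dM:")
print(top[["chrom", "start", "end", "D", "f_d", "f_dM"]].to_string(index=False))
print(
    "\nPositive f_dM marks P2-P3 sharing; the selected windows overlap the\n"
    "simulated segment, while background windows fluctuate around zero."
)
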