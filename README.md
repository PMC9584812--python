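# introscan

Quantify genome introgression between a domesticated lineage and its wild
relative — or any pair of recently diverged populations that hybridize —
from multi-sample SNP data.

The motivating setting is a wild population (think European polecats
recolonizing from a refugium) that hybridizes with a widespread domestic
relative (feral ferrets), leaving admixed genomes whose ancestry
fractions, introgressed regions and candidate adaptively introgressed
genes need to be measured. `introscan` implements that analysis stack as
a library with a thin CLI, and ships a seeded synthetic-data generator so
every statistic can be validated against known truth.

## What it computes

For populations P1, P2 (sisters), P3 and an outgroup O, with per-site
derived-allele frequencies `p1, p2, p3, pO`:

- **Patterson's D (ABBA-BABA)** over all population trios:
  `ABBA_i = (1-p1) p2 p3 (1-pO)`, `BABA_i = p1 (1-p2) p3 (1-pO)`,
  `D = Σ(ABBA-BABA)/Σ(ABBA+BABA)`, with delete-one block-jackknife Z,
  one-tailed p, and the f4-ratio admixture fraction
  `f4(P1,P2;P3a,O)/f4(P1,P3b;P3a,O)` (P3 split in half, seeded).
- **Invariant-based hybrid tests with γ**: site-pattern masses for the
  quartet (O, P1, hybrid, P2) give invariant differences
  `x = f(AABB)-f(ABAB)` and `y = f(ABBA)-f(ABAB)`; under hybridization
  `E[x] ∝ γ` and `E[y] ∝ 1-γ`, so `γ̂ = x/(x+y)`, tested by a
  delta-method Z on `x/y`. Population-level and one-individual-at-a-time
  modes, full directed search with Bonferroni correction and the
  `0 < γ < 1` reporting filter.
- **Windowed admixture scans**: D, `f_d`, `f_dM` and `d_f` in 1,000-SNP
  windows (step 500), and top-percentile window selection (`f_dM` is the
  selection statistic; it is antisymmetric under P1↔P2 and symmetric
  about zero without introgression).
- **Diagnostic-allele hybrid index**: sites where two parental panels are
  fixed for opposite alleles (QUAL ≥ 30, biallelic); each sample scored
  by the fraction of its allele copies matching panel A, aggregated by
  region, with the diagnostic set's error rate estimated on a validation
  panel (discordant / total allele copies).
- **Diversity and differentiation**: per-bp nucleotide diversity π in
  100-kb windows; per-site Weir–Cockerham Fst with top-percentile
  outlier calling (Hudson estimator available).
- **Topology weighting**: all `(2k-5)!!` unrooted topologies for k
  groups (15 for 5), weighted per window tree by exhaustive or seeded
  Monte-Carlo one-tip-per-group subsampling; includes a neighbor-joining
  window-tree builder on allele-sharing distances.
- **Adaptive-introgression candidates**: intersect top-`f_dM` windows
  with top-Fst outliers, merge overlapping windows into continuous
  regions, and report genes that overlap both a region and an outlier.
- **Synthetic truth**: Balding–Nichols drift on the fixed tree
  `((P1,P2),P3),O`, per-individual admixture fractions γ, optional
  localized P3→P2 gene flow, QUAL scores, missingness and region labels
  — all determined by one seed.

## Worked example

`python examples/02_hybrid_gamma.py` simulates 50,000 biallelic sites for
two parental populations (8 diploids each, drift F = 0.1), an outgroup,
and a putative-hybrid group of two F1s (γ = 0.5) and two pure-P1
individuals, then runs the invariant hybrid test:

```
population gamma: 0.252  (Z = 2.89, truth 0.25)

per-individual gamma:
  HYB_1:  0.501  (truth 0.5)
  HYB_2:  0.472  (truth 0.5)
  HYB_3:  0.014  (truth 0.0)
  HYB_4:  0.033  (truth 0.0)
```

γ is the fraction of the genome contributed by the P2 parent: an F1
scores 0.5, an unadmixed individual ~0, and a group of two F1s and two
pure individuals averages 0.25 — which the population-level test
recovers. The other scripts in `examples/` walk through the D-statistic
(`01`), window scans (`03`), the diagnostic hybrid index (`04`),
topology weighting (`05`) and the end-to-end pipeline (`06`).

The same functionality is exposed as a CLI:

```bash
introscan simulate --n-sites 50000 --seed 1 --out-prefix scratch/demo \
    --pop P1=8 --pop P2=8 --pop HYB=4 --pop OUT=2 \
    --gamma HYB_1=0.5 --gamma HYB_2=0.5 --gamma HYB_3=0 --gamma HYB_4=0
introscan hyde --vcf scratch/demo.vcf --popmap scratch/demo.popmap.tsv \
    --outgroup OUT
introscan run --config config.yaml   # full pipeline
```

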