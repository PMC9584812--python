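# Methods

This note documents the models and numerical conventions behind
`introscan`, the choices made where the design was genuinely open, and
what the synthetic-data validation does and does not establish.

## Synthetic-data model

Population allele frequencies follow the Balding–Nichols model on the
fixed topology `((P1,P2),P3),Outgroup`. Per site, an ancestral frequency
`a` is drawn from a bounded law (default Uniform(0.05, 0.95), avoiding
near-fixed ancestral sites that would be uninformative for every
statistic); each branch with drift coefficient `F` draws its child
frequency from `Beta` with mean equal to the parent frequency and
variance `p(1-p)F`. Defaults: `F = 0.1` on each terminal branch,
`F = 0.05` on the internal (P1,P2) branch. No divergence scale is
implied by the study system itself, so these are calibration choices:
they put typical parental-panel allele-frequency differences around
0.15–0.25 — large enough that 50,000 independent sites give stable
D and γ estimates, small enough that fixed differences remain rare, as
in recently diverged taxa. Any additional configured population is an
independent lineage off the root (default `F = 0.1`), which keeps every
trio statistic null in the absence of gene flow.

Diploid genotypes are binomial draws from the population frequency at
independent sites. An admixed individual with fraction γ draws each
allele copy's ancestry as Bernoulli(γ) (P2 with probability γ, else P1)
and then the allele from the donor's frequency, so its expected alt
dosage is exactly `2(γ p2 + (1-γ) p1)`. The maternal lineage recorded in
the truth table is a single Bernoulli(γ) draw per individual — a stated
simplification standing in for cross direction, not a model of it. The
outgroup is fixed for the ancestral allele by default so "derived" is
unambiguous; a drifting-outgroup switch exists for robustness checks.
Optional P3→P2 gene flow replaces a fraction of loci (scattered or one
contiguous segment) with `(1-s) p2 + s p3` at donor strength `s`
(default 1). Per-site QUAL scores default to Gamma(shape 4, scale 15)
— mean 60 with ~14% of sites below 30, so the quality filter always has
realistic work to do — and missingness is i.i.d. per call.

What the generator does **not** emulate: linkage and recombination
structure (sites are independent, so block-jackknife robustness to LD is
exercised only mechanically), selection, demographic change, sequencing
or mapping error beyond i.i.d. missingness, and multi-allelic or indel
variation (the VCF writer emits biallelic SNPs; the reader flags
non-SNPs from real files). Passing tests therefore demonstrate
statistical correctness of the estimators under their own sampling
assumptions, not robustness to the full error structure of real
resequencing data.

## Site filters

Biallelic-SNP restriction, QUAL ≥ 30 (boundary inclusive; a missing
QUAL counts as 0), LD pruning, and the ascertainment filter (total alt
count ≥ 3 plus at least one hom-alt and one hom-ref call). A
multi-sample VCF has one QUAL per site, so "site quality" is that value.
LD pruning is greedy left-to-right: a site is dropped if its r²
(squared Pearson correlation of dosage vectors over pairwise-complete
calls) with any retained site less than 5 kb upstream exceeds 0.8.
Earlier positions win, making the filter deterministic and idempotent;
pairs with under two complete calls or zero variance count as r² = 0.
Missing genotypes are excluded pairwise, never imputed. Coordinates are
0-based half-open internally; VCF and GFF convert at the I/O boundary.

## Trio statistics

`D = Σ(ABBA-BABA)/Σ(ABBA+BABA)` with frequency-weighted patterns and
`(1-pO)` outgroup weighting (polymorphic-outgroup sites are kept; a
polarize-and-drop mode exists). Standard errors come from a delete-one
block jackknife over 20 contiguous equal-site blocks — a conventional
default; the estimator is insensitive to the block count well before it
approaches the site count. Reported trios are oriented so D ≥ 0 and
tested one-tailed, which matches the reporting convention but makes the
oriented p anti-conservative under the null; the type-I-error
calibration test therefore uses the unoriented statistic. Within each
unordered trio, P3 is chosen by the BBAA rule (the pair sharing the most
derived alleles is taken as sisters), the tree-free convention. The
f4-ratio splits P3 into seeded random halves (numerator
`f4(P1,P2;P3a,O)`, denominator `f4(P1,P3b;P3a,O)`); it can exceed 1 when
the assumed tree is wrong, and is reported as-is.

## Invariant hybrid test and γ

For the quartet (O, P1, H, P2), each usable site distributes unit mass
over the 16 ancestral/derived patterns as the product of per-group
derived (or ancestral) frequencies; masses sum exactly to the usable
site count. With `x = f(AABB) - f(ABAB)` and `y = f(ABBA) - f(ABAB)`,
drift on the parental branches gives `E[x] = γ·v` and `E[y] = (1-γ)·v`
(v the parental-branch frequency variance), hence `γ̂ = x/(x+y)` and a
test of `x = 0` via the ratio `T = x/y` with a delta-method normal
approximation under multinomial pattern sampling. Because each group
enters each invariant pattern exactly once, finite-panel sampling noise
cancels in expectation and γ̂ is unbiased — including for heterogeneous
hybrid groups, where it estimates the group-mean γ (two F1s plus two
pure P1s → 0.25). Swapping P1 and P2 exchanges x and y, mapping γ̂ to
1-γ̂ exactly. Degenerate configurations (y ≤ 0 or x+y = 0) are returned
as undefined, never filtered in. The treatment of pattern masses as
multinomial counts overstates their variance, so Z is conservative;
correctness is defined by recovery of known γ and agreement with an
independent least-squares mixture estimator on synthetic data, not by
bit-level equality with any external implementation. The full search
tests every directed arrangement (3·C(k,3) for k candidates) with
Bonferroni correction by default (raw-p mode available, since reporting
conventions differ) and applies the `0 < γ̂ < 1`, significance filter to
the reported table. Individuals callable at under 50% of the
parental-usable sites carry a low-confidence flag.

## Window scan

Windows are 1,000 usable SNPs with step 500 (the window size is the
field convention; the step is unstated there, so 50% overlap was chosen
and is configurable — downstream window spans are therefore not
comparable across step choices). Windows tile each chromosome by SNP
index; the final partial window is dropped; spans are
`[first SNP, last SNP + 1)`. `f_d` substitutes the donor frequency
`max(p2, p3)` for both P2 and P3 in the denominator; `f_dM` switches the
substitution to the P1 side (donor `max(p1, p3)`, matching sign) when
`p1 > p2`, making it antisymmetric under P1↔P2 and bounded in [-1, 1];
`d_f` is reported as the distance-fraction form
`Σ(ABBA-BABA) / Σ(ABBA_D + BABA_D)` with the same donor substitution,
and is never used for selection — selection uses positive `f_dM` at the
nearest-rank top percentile. Zero-denominator windows record a missing
statistic but are retained. "Top percentile" everywhere means the
nearest-rank `(100-pct)`th percentile (numpy's `higher` method) with
ties at the threshold included.

## Diagnostic index

A diagnostic site requires every panel-A sample called and homozygous
for one allele and every panel-B sample called and homozygous for the
other; the panel-A allele need not be REF. Scoring counts allele copies
(a heterozygote contributes one of two), the unbiased estimator of the
genomic ancestry fraction; a per-genotype mode (homozygous calls only)
exists because per-site genotype classing is a plausible alternative
reading. Zero called diagnostic sites in a target is an error, never a
silent 0. Region aggregation is an unweighted mean over samples with a
region label. The validation error rate is discordant over total allele
copies — the same units as the index.

## Diversity and Fst

Per-site π is `2 n_ref n_alt / (n (n-1))` over called allele counts;
windows are fixed 100-kb spans anchored at 0 per chromosome, summed π
divided by the true window span (the trailing partial window keeps its
real length), and the population summary is the unweighted mean over
windows — so the denominator is genomic span, not SNP count. Fst is the
Weir–Cockerham two-population single-site estimator from variance
components a, b, c, with observed heterozygosity entering through c;
negative estimates are reported unclamped, and only undefined sites are
excluded from percentile ranking. A Hudson-estimator mode is provided
for sensitivity checks.

## Topology weighting

Unrooted topologies on k group labels are enumerated through the
bijection with rooted trees on k-1 labels, giving `(2k-5)!!` canonical
split sets. A window tree is weighted by one-tip-per-group subsampling:
exhaustive when the number of combinations is at most 10,000 (a
runtime/exactness balance), otherwise seeded Monte-Carlo with a
configurable sample count. A combination inducing an unresolved
(polytomous) subtree contributes fractional weight split equally among
the compatible binary topologies; a discard mode was considered and
rejected because it biases weights toward well-resolved clades. The NJ
window-tree builder uses mean allele-sharing distance
(`|dosage_i - dosage_j| / 2` over shared called sites) and exists to
exercise the weighting end-to-end; it is not a substitute for
likelihood-based tree inference on real alignments.

## Candidate regions

Half-open interval logic throughout: an Fst outlier at a window's start
coordinate is contained, at its end coordinate is not. Overlapping or
boundary-touching top-`f_dM` windows merge into maximal regions
(gap tolerance 0 by default). A gene is a candidate only if it overlaps
a merged region **and** contains a retained outlier position — window
overlap alone does not qualify, which is why a region can legitimately
report zero genes with a gene just outside; the nearest gene and its
signed distance are annotated for that case, and a relaxed
window-overlap-only mode is available.

## Pipeline

One global seed is fanned out per stage as
`sha256("{seed}:{stage}") mod 2^31`, so any stage re-run in isolation
reproduces the full-run output. All intermediates are TSV with explicit
headers; the configuration and package version are recorded verbatim in
the output directory. Stages whose roles are absent (no hybrid
population, no trio) are skipped with a logged notice.

## Problem sizes and validation scope

The reference computations use 50,000 independent sites, parental panels
of 8 diploids, a 2-diploid outgroup, and 10 replicate seeds; the null
window scan uses ~100,000 sites (200 windows); calibration of the
jackknife test uses 200 replicates of 4,000 sites. At these sizes γ̂'s
replicate-to-replicate spread is ~0.02 and all headline recoveries are
comfortably inside their stated tolerances. Known limitations: no
linkage in the simulator (jackknife calibration under real LD is
untested here), the invariant test's Z is conservative by construction,
f4-ratios above 1 are possible and meaningful only as a tree-violation
signal, and absolute window counts or spans from real data depend on the
unstated step-size convention noted above.
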