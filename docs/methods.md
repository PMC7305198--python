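# Methods

`camelscan` re-implements, as a tested library, the computational core of a
three-population resequencing analysis of domestication: hard filtering of
called variants, windowed diversity and divergence statistics, gene-based
polymorphism/divergence selection tests, the population branch statistic
(PBS), a π log-ratio relaxed-selection scan, LD pruning, and coverage-based
sex-scaffold classification.  A forward Wright–Fisher simulator generates
complete synthetic inputs so that every stage can be exercised, calibrated
and benchmarked without any external data.

The three analysis cohorts are labelled **D** (a deeply diverged domestic
population, the dromedary-like cohort), **B** (a domestic population closely
related to the wild cohort, the Bactrian-like cohort) and **F** (the wild
two-humped cohort), with topology `((B, F), D)` and an outgroup genome (an
alpaca-like relative) used only to polarise fixed differences.

## Variant filtering

The cascade operates on biallelic SNPs and mirrors a conservative
resequencing workflow.  Site-level rules (all individually switchable, with
the workflow's published thresholds as defaults): site quality `QUAL < 20`;
combined depth `INFO/DP > 750` (about twice the expected coverage of a
25-genome cohort at ~15×); quality-by-depth `QD < 2`; strand bias
`FS > 60`; RMS mapping quality `MQ < 40`; rank-sum annotations
`MQRankSum < −12.5` and `ReadPosRankSum < −8`; inbreeding coefficient
`< −0.8`; SNP clusters (≥ 3 SNPs spanning ≤ 20 bases inclusively — all
members of the cluster are removed); proximity `< 10 bp` to an indel;
overlap with an annotated repeat; and location on a sex-linked scaffold.
Genotype-level rules run afterwards in a fixed order, because order changes
counts: (1) genotypes with depth outside `[4, 30]` are set missing (the
published rule "4 > DP > 30" is read as `DP < 4 OR DP > 30`; the literal
chain is unsatisfiable and the upper bound matches ~30× per individual);
(2) sites missing in more than 5 individuals are removed; (3) sites with
minor-allele count < 2 on the post-masking called alleles are removed;
(4) sites with exact Hardy–Weinberg `p < 1e-4`, pooling all individuals,
are removed.  A per-site ledger records every rule each site failed, so
`input = output + removed` always balances and cascade re-application is a
no-op (idempotence is tested).

Caveat: pooling three diverged populations in one HWE test is a Wahlund
setting — strongly differentiated sites, including between-species fixed
differences, show heterozygote deficits and can be removed at desk-scale
sample sizes.  This is faithful to the whole-cohort filter being modelled,
but analyses that need fixed differences (the gene-based tests below)
should be run with `hwe_alpha` relaxed or on the unfiltered call set; the
calibration benchmarks do the latter.

Missing INFO annotations required by an enabled rule are an error, never a
silent pass.  Variant-set QC reports the transition/transversion ratio
(transitions A↔G, C↔T); mammalian resequencing sets are expected near
2.0–2.5, and the synthetic generator draws alternate alleles with a
transition bias targeting Ts/Tv ≈ 2.54.

## Windowed statistics

Windows are 0-based half-open intervals laid on each scaffold at starts
0, step, 2·step, … while `start + size ≤ length` (trailing partial windows
dropped).  Scans use 100-kb windows with 50-kb steps; summary reports use
non-overlapping 10-kb windows.  Per window and population:

* **π** — per-site pairwise diversity `2·c_ref·c_alt / (n(n−1))` summed over
  sites and divided by the accessible length (window span by default; a
  callable-sites mask can override it, since VCF-only input cannot
  distinguish monomorphic from uncallable sequence).
* **θ_W** — segregating sites / `a_{n−1}` / accessible length, with
  `n = 2 ×` population individuals (per-site missingness is ignored here;
  sites are expected to have passed the missingness filter).
* **Tajima's D** — the standard normalised difference between π-based and
  S-based estimators with the textbook constants; `NaN` when `S = 0`.
* **per-individual heterozygosity** — heterozygous calls / accessible length.

Between populations: **D_XY** `= p_A(1−p_B) + p_B(1−p_A)` summed per site
over accessible length, and **F_ST** as the two-population Weir–Cockerham
(1984) variance-components estimator aggregated as a ratio of sums
(Σa / Σ(a+b+c)) — the coancestry family usually cited as "Reynolds" F_ST;
the named estimator has no unique published formula at window level and any
coancestry-consistent choice preserves PBS rankings.  Window F_ST is
clamped to `[0, 1−1e−9]` (negative estimates to 0, standard PBS practice)
so the Cavalli-Sforza transform `T = −ln(1 − F_ST)` stays finite.

## Selection scans

**Gene-based (homogeneity + HKA).**  For each gene (longest isoform per
gene id, 1-based closed intervals) four counts are accumulated:
A = sites polymorphic in the focal domestic population, B = polymorphic in
the wild population, C = fixed differences of focal vs both wild and the
outgroup, D = fixed differences of wild vs both focal and the outgroup.
The outgroup allele is the most common base with depth ≥ 2, ties broken by
a seeded uniform draw (tie-breaking is recorded, making scans
reproducible); a fixed pattern with an outgroup no-call is uninformative.
Requiring the outgroup to carry the non-focal allele polarises the
substitution onto the focal branch.  Genes with `A < 1` or `C < 1` are
omitted.  The homogeneity test is a two-sided Fisher exact test of
`[[A, B], [C, D]]`; the HKA-style test compares each gene's A/C (and B/D)
to the totals over all analysed genes (focal gene included, matching the
"summed across all genes analysed" convention; a flag excludes it).
Candidates require homogeneity `p < 0.05` and an HKA signal (`p < 0.05`)
on the focal side only — the wild side is operationalised as the analogous
B/D-vs-totals test being non-significant.  These p-values are ranking
scores, not calibrated significance: accurate p-values would require
demographic simulation, so candidates are priorities, not discoveries.

**Window-based.**  All quantile thresholds use linear interpolation over
eligible windows (those with ≥ 10 polymorphic sites across the cohort) and
inclusive comparisons:

* *π/D_XY percentile scan* — windows jointly in the lowest 0.5 % of focal
  π and the highest 99.5 % of D_XY to the wild population.
* *PBS scan* — `PBS_focal = (T1 + T2 − T3)/2` from the three pairwise
  transforms, windows in the top 0.5 %.  Windows with undefined F_ST are
  dropped from the ranking (counted in the result metadata), never imputed.
  The three per-branch PBS values satisfy `ΣPBS = (T1+T2+T3)/2`, which is
  asserted as an algebraic property test.
* *π log-ratio scan* — `ln π_domestic − ln π_wild` for both domestic
  populations; windows in both 99.5 % tails with wild Tajima's D ≤ −2.
  A window π of 0 is floored at `1e-5` before the logarithm.

Genes overlap a selected window when they share ≥ 1 base; genes spanning
merged window runs are reported once.

**LD pruning** uses squared Pearson correlation of dosage vectors over
pairwise-complete genotypes within 1-Mb windows; one member of each pair
with `r² > 0.5` is removed by a seeded coin flip, scanning left to right
until no violating pair remains among retained sites.  Zero-variance sites
are uncorrelated by convention.

## Exact tests

Fisher's 2×2 test, the exact conditional Hardy–Weinberg test, and the
Wilcoxon rank-sum and signed-rank tests are implemented by full
enumeration of their conditional null distributions (subset-sum dynamic
programmes for the Wilcoxon statistics), with two-sided p-values defined
as the total probability of outcomes no more probable than the observed
one (relative tie tolerance `1e-7`).  The Wilcoxon tests switch to a
normal approximation with continuity and tie corrections beyond
configurable sample sizes or in the presence of ties.  All are verified
against independent full-enumeration oracles, and their null rejection
rates are checked to be conservative.

## Sex-scaffold classification

With a male reference, X scaffolds show male:female coverage ratios near
0.5:1 and Y scaffolds near 0.5:~0.  Ratios are per-individual scaffold
depth over genome-wide mean depth; labels are invariant to rescaling any
individual's depths.  Rules (α = 0.05): **X** — one-sided exact rank-sum
test that male ratios are below female ratios, plus ≥ 20 % of the scaffold
aligning to a reference X.  **Y** — male ratios not significantly
different from 0.5 (two-sided exact signed-rank, a deliberate
non-rejection criterion, statistically weak but faithful to the rule being
modelled), female ratios significantly below 0.5, plus ≥ 20 % aligned to a
reference Y.  The whole-genome alignment fractions are inputs, not
recomputed.

The female-vs-0.5 comparison uses the exact signed-rank with the *mid-p*
convention (half weight on the observed statistic).  This is deliberate:
with four females the smallest achievable one-sided exact p is
`1/2⁴ = 0.0625`, so the plain exact test can never reach α = 0.05 and no
scaffold could ever be labelled Y at that cohort size; mid-p is a standard
remedy for the over-conservatism of discrete tests.  The male
non-rejection test keeps the plain exact form, where conservatism only
makes non-rejection easier, matching the rule's intent.

## The synthetic-data generator

A forward-time diploid Wright–Fisher simulator with discrete generations
and infinite-sites mutation on a finite sequence (positions drawn without
replacement; exhaustion is an error, never silent recycling).  Scaffolds
are simulated independently (free recombination between scaffolds) and may
have heterogeneous lengths, as scaffold-level assemblies do.

Numerical choices:

* The ancestral population is seeded from the stationary infinite-sites
  ensemble — segregating-site count Poisson with mean `a_{2N−1}·4NμL`,
  frequencies ∝ 1/i — followed by a short burn-in (N/2 generations by
  default).  This preserves the expected site-frequency spectrum, E[S] and
  E[π] (verified against Watterson's expectation in the tests) at a small
  fraction of the cost of a ≥ 10N-generation burn-in from a monomorphic
  start.  Equilibrium linkage disequilibrium is *not* reproduced at the
  seeding point; LD relevant to sweeps is generated by the post-seeding
  dynamics.
* Gametes carry at most one crossover (probability `1 − exp(−rL)`); at the
  simulated map lengths the neglected multi-crossover probability is below
  1 %.
* Sweeps are additive (fitnesses 1, 1+s/2, 1+s), injected as a single copy
  and re-injected whenever lost before reaching frequency 0.1 —
  conditioning on establishment so desk-scale runs do not waste
  replicates.
* The admixture pulse replaces the configured fraction of the destination
  population with source-population offspring at the stated generation.
* Recurring one-way gene flow from the wild population into B
  (`migration_wild_to_b`, default 0.0025 per individual per generation)
  emulates the ongoing wild/domestic hybridization documented for
  two-humped camels.  It holds the background B–F differentiation at a
  drift–migration balance (F_ST ≈ 0.2–0.3 at the default scale) — the
  regime in which branch-length scans are informative — while leaving the
  wild gene pool unaffected.

Scaled-down defaults, chosen once and fixed: N = 200 diploids everywhere,
μ = 2.5e−7 and r = 5e−8 per bp per generation, deep split 450 and recent
split 400 generations before present, sample sizes 9/7/9 echoing the
modelled cohort.  These are testing conditions, not biological claims:
time is compressed ~100-fold relative to a livestock genome, and rates are
scaled up so that 100-kb windows on sub-megabase scaffolds carry
analysis-relevant site counts (≈ 50–200 SNPs) and linkage.  Under ongoing
immigration a swept allele equilibrates near `1 − 2m/s` rather than fixing
exactly; "completed" sweeps are taken as population frequency ≥ 0.9 at
sampling.

What the generator does **not** emulate: read-level error and mapping
artefacts (the VCF INFO annotations are drawn from labelled pass/fail
mixtures purely so the filter cascade has known truth — the values have no
mechanistic meaning), genotype-calling bias, recombination-map
heterogeneity, background selection, and realistic gene structure (genes
and repeats are uniformly placed intervals).  Passing tests therefore
demonstrate correctness and calibration of the *statistics and decision
rules*, not robustness to upstream artefacts of real data.

Coverage tables use a hemizygous dosage model: relative to each
individual's genome-wide mean, autosomes at ratio 1 in both sexes, X at
0.5 in males and 1 in females, Y at 0.5 in males and a small mismapping
background (0.02) in females, with multiplicative Gaussian noise
(σ = 0.05 default).  A fast Balding–Nichols generator (ancestral
frequencies Uniform(0.05, 0.95), population frequencies Beta-distributed
with per-branch F, binomial genotypes under HWE) provides unlinked sites
for F_ST calibration; the Weir–Cockerham estimator recovers the generating
F = 0.1 within ±0.03 at 5 000 sites and 20 diploids per population.

## Benchmark problem sizes and statistical power

The calibration benchmarks use sixteen 400-kb scaffolds (≈ 112 windows of
100 kb at 50-kb steps) per neutral replicate, 20 replicates.  The
sweep-recovery benchmark places an s = 0.1 sweep, started 300 generations
ago, at the midpoint of a 150-kb scaffold alongside five 400-kb neutral
scaffolds, and asks whether a window containing the swept site is among
the PBS selections at the 99.5th percentile; replicates are conditioned on
the sweep having completed (premise of the scenario), never on scan
outcomes.  At this scale 2Ns = 40, and the per-window PBS noise floor is
genealogical — doubling the per-window site count leaves the window
standard deviation unchanged — so recovery power is ≈ 0.8, with the s = 0
false-hit rate ≈ 1/(number of windows).  Real scans at genome scale with
2Ns in the hundreds-to-thousands sit far further from this boundary; the
benchmark probes the method at the edge of its operating regime.

## Pipeline and reproducibility

One YAML config (unknown keys rejected before any computation) drives
simulate/load → sex classification → filter cascade → QC report (10-kb
diversity summaries, Ts/Tv, the SNP-sharing partition of sites by the
populations they segregate in, with between-species fixed differences as a
disjoint count) → LD pruning → window statistics → the three window scans
and the gene-based tests.  Every threshold is echoed into a manifest with
a config hash; outputs contain no timestamps, and rerunning with the same
config and seed reproduces every output byte for byte.  All randomness
(simulation, LD-prune coin flips, outgroup tie-breaks) flows from the
single configured seed.

## Known limitations

* Tajima's D and θ_W use the full population sample size, ignoring
  per-site missingness (documented approximation; sites are pre-filtered
  for missingness).
* The pooled-cohort HWE filter removes strongly differentiated sites
  (Wahlund effect) — intentional fidelity, see above.
* The homogeneity/HKA p-values are ranking scores; their null rate is
  conservative (tested) but they are not calibrated significance levels.
* The exact rank-sum path assumes no ties; ties fall back to the
  tie-corrected normal approximation even at small n.
* `VQSLOD`-style mixture-model recalibration is out of scope; the cascade
  operates on the hard annotations only.
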