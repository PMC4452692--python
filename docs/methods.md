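# Methods

This note documents the statistical procedures implemented in
`crossonc`, the assumptions behind them, the tunable parameters, and the
design choices made where the procedure admitted more than one
reasonable reading.

## Copy-number segmentation and CNA calling

**Model.** Probe-level aCGH measurements are log2 tumor/normal
hybridization ratios, modelled per chromosome as a piecewise-constant
mean plus i.i.d. Gaussian noise.  Change-points are placed by exact
dynamic programming: for each candidate number of change-points
`k ≤ max_k`, the placement minimising the residual sum of squares (RSS)
over all C(n−1, k) possibilities is found in O(k·n²) time and O(n²)
memory.  Ties in the DP resolve to the leftmost placement so results are
deterministic.

**Model selection.** `k` is chosen by minimising
`RSS(k) + penalty · k`, with the per-change-point penalty defaulting to
a modified-BIC value `2·σ̂²·log n`.  The noise scale `σ̂` is estimated
robustly from the median absolute first difference of the probe ratios
(divided by `0.6745·√2`), which is insensitive to the handful of
differences that straddle true change-points.  On noise-free input
`σ̂ = 0`, the penalty vanishes, and the smallest `k` reaching the
minimal RSS is selected, so implanted segments are recovered exactly.
`max_k` defaults to `max(20, ⌈n/20⌉)` — enough budget for many focal
events on a dense chromosome while keeping a 1,800-probe chromosome
under a second.

**Calling.** Segments are tested genome-wide: each segment's probe
ratios are compared against zero with a one-sample t-test, and
Benjamini–Hochberg is applied across all segments of the genome.  A
segment is called amplified when `q ≤ 0.01`, it has at least 3 probes,
and its mean log2 ratio is at least +0.4 (mirrored for deletions).
These three thresholds are the calling parameters of the study the
pipeline reproduces and are all configurable.  Single-probe and
zero-variance segments receive p = 1 unless their (noise-free) mean is
non-zero.  Chromosome X is excluded from testing and calling by
default — the original cohort contained one tumor hybridised against a
sex-mismatched reference — and the exclusion set is configurable.

Over-segmentation is deliberately tolerated: a spurious change-point
produces short near-zero segments that fail the q/mean/probe-count
gates, so the false-discovery proportion of *calls* stays controlled
even when the DP slightly over-fits.  Segment bp extents are reported as
`[first probe position, last probe position + 1)`.

## Gene-level status and recurrence

A gene takes the call of the segment containing its midpoint; midpoints
falling in inter-segment probe gaps use the nearer flanking segment.
Recurrence across samples is scored with a permutation analog of a
G-score: the per-gene amplification score is `Σ_samples max(0,
amplitude)` (deletion mirrored), and the null distribution comes from
independent per-sample cyclic shifts of each sample's gene-level
amplitude vector along the genomic gene order.  Cyclic shifts preserve
each sample's total amplified amplitude and the spatial autocorrelation
of its profile exactly, so the test measures co-localisation of
amplification across samples above sample-specific background — the
same inferential target as recurrence tools built on background
permutation.  Empirical p-values pool permuted scores across genes
(add-one estimator), giving resolution far below `1/n_perm`;
Benjamini–Hochberg is applied separately to the amplification and
deletion arms, and genes are recurrent at `q ≤ 0.2` by default.  A gene
may be recurrent in both arms across different samples.

## Expression classification and integration

Expression values are FPKM-scale and transformed to `log2(FPKM + 1)`
for all statistics; the pseudocount (configurable) bounds the influence
of near-zero FPKM.  Genes are pre-filtered to those with FPKM ≥ 1 in at
least one sample (both thresholds configurable, boundaries inclusive).

For each gene, the samples that are copy-neutral (diploid) in that gene
define a reference.  A sample's expression is called low/normal/high
against a Student-t **prediction interval** for one new observation,

    mean ± t_{1−α/2, n−1} · s · √(1 + 1/n),

with α = 0.05.  A plain confidence interval for the mean would flag far
more than 5% of diploid samples as outliers (its width shrinks with n);
the prediction interval is the reading under which "95%" describes the
rate at which copy-neutral samples are left unflagged, which is the
evident intent of an outlier rule.  Diploid reference samples are
classified against the leave-one-out interval to avoid self-inclusion
bias; genes with fewer than 3 diploid references are unclassifiable;
zero-variance references give a degenerate interval where only exact
equality is "normal".  The calibration of this rule is measured by
simulation (see the acceptance script): the marginal fraction of
held-out diploid draws classified "normal" is ≈ 95%.

The 3×3 concordance table cross-tabulates CNA group (deleted /
unchanged / amplified) against expression level, as percentages within
each CNA column (columns sum to 100).

Differential expression between two sample groups uses a per-gene Welch
t-test on `log2(FPKM+1)` with BH control at FDR 0.1.  A
negative-binomial count-model arm is intentionally out of scope; this
module consumes an FPKM-scale matrix, not read counts.

Group-level concordance differences are tested with a two-sample
Hotelling T² on per-gene bivariate features — each gene contributes its
(mean log2 copy ratio, mean log2 expression) pair — converted to an F
statistic via `T²·(n₁+n₂−p−1)/(p·(n₁+n₂−2))`, p = 2.  An alternative
feature construction (per-gene copy/expression correlation
coefficients) is plausible but less stable at small sample counts; it is
left as a documented extension.

## Mutation spectrum

Substitution records carry read depth and flanking reference bases.
The coverage filter keeps depths in [30, 300] inclusive — the window in
which RNA-seq-derived substitution calls are reliable (enough reads to
call, not so many as to indicate collapsed repeats).  The twelve ordered
substitutions collapse onto six pyrimidine-reference classes by reverse
complementation; transitions are C>T and T>C.  A CpG site is the
dinucleotide on either strand (C with 3′ G, or G with 5′ C); TpC is the
strand-collapsed 5′-thymine context of a mutated cytosine.  Records with
an N flank have unknown context and are excluded from context-restricted
analyses.

The virus-status comparison pools transversion/transition counts at CpG
sites across samples within each group — with as few as two
virus-positive tumors, per-sample tests would be powerless — and applies
a two-sided Fisher's exact test.  Per-sample fractions are also reported
for transparency.  The test is two-sided and no direction is hard-coded;
the per-group fractions let the user read the direction off the data.
The TpC analysis reports the per-group fraction of C-class mutations in
TpC context without a hard-coded test.

Coding consequences use the standard genetic code: stop gain is
nonsense, a preserved residue synonymous, anything else missense, with
labels formatted like `E233K`.

## Cross-species driver/passenger discrimination

A recurrently amplified region in genome A is projected through a
synteny block map into genome B by piecewise-linear, length-preserving
coordinate transfer; '−' blocks reverse within-block offsets, unmapped
gaps are reported rather than silently dropped, and the projection is
invertible on mapped bases.  Genome-B genes are assigned to exactly one
projected region by midpoint and classified amplified (`q_amp ≤ 0.2`),
deleted (`q_del ≤ 0.2`), or unchanged.  "Unchanged" means neither
recurrently amplified nor deleted; deleted genes are excluded from both
candidate sets and reported separately.  A two-sided Fisher's exact
test on the amplified/unchanged 2×2 across the two regions (one-vs-rest
with BH for more than two regions) decides discrimination: if
significant, amplified genes in the amplified region(s) are driver
candidates (DCGs) and unchanged genes in the other region(s) passenger
candidates (PCGs); otherwise both sets are empty with a status flag.
Ortholog mapping is by coordinate projection of gene midpoints; a
one-to-one ortholog table may override it.  Validation helpers compare
mutation prevalence between DCGs and PCGs (Fisher) and their
copy/expression concordance (Hotelling T²).

## Synthetic data

The generator supplies every input with known ground truth:

- **Genomes** default to 5 chromosomes × 10 Mb with one probe per
  5.5 kb on a grid jittered uniformly by ±40% of the nominal spacing
  (grid artifacts would otherwise make segmentation look better than it
  is), and non-overlapping 20 kb genes placed uniformly.  The scale is
  deliberately smaller than a mammalian genome: density and structure,
  not total length, are what the downstream statistics consume.
- **aCGH profiles** are implanted segment amplitudes plus Gaussian
  probe noise (default sd 0.2 in log2 units; array platforms do not
  publish a noise figure, so the default is chosen for testability, not
  platform fidelity).
- **Expression** is Gaussian on the log2 scale (baseline mean 5, sd
  0.5) with `coupling × copy_log2` added for designated driver genes
  and omitted for passengers, then exported on the FPKM scale.
- **Variants** draw substitution classes from a per-sample profile
  (default: C>T/G>A-dominant, transitions ≈ 74%), then pick reference
  sites matching the class, weighting CpG sites by the configured
  transversion odds multiplier and TpC sites by the TpC propensity
  multiplier.  Because the class is drawn first, observed class
  fractions follow the profile exactly up to multinomial noise, while
  the context weights realise the configured conditional odds ratios.
  Read depths are uniform in [30, 300] with a fixed 10% injected
  outside the range so the coverage filter is always exercised.
- **Synteny scenarios** split one "human" region of 398 genes across
  two "dog" chromosomes (210 vs 188 genes by default, one block
  inverted), flag all human genes amplified, and implant amplification
  (+1.0 log2) covering a configurable fraction (default 125/210) of
  region-A genes — the drivers.

What the generator does **not** emulate: tumor purity and subclonality,
GC waves and probe-specific biases, overdispersed RNA-seq counts,
linked-site mutation processes, or gene-length/expression-level
confounding of mutation detection.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its stated
model, not robustness to every artifact of real tumor data.

## Problem sizes and numerical choices

The bundled experiments use sizes chosen so the whole suite runs in a
few minutes on one CPU: the FDR experiment uses 20 replicate genomes of
5 × 10 Mb (~9,000 probes each); the calibration experiment 10,000
replicates of an 8-sample reference; the end-to-end recovery an 8 Mb
region with 80 genes and 8 tumors at 500 permutations.  Empirical
q-values use the add-one estimator so no p is ever exactly zero.
Fisher tests use the exact hypergeometric two-sided convention
(probability-mass ordering), verified in the tests against full
enumeration.  All generators and permutation tests consume explicit
integer seeds; pipeline runs derive per-stage substreams from one root
seed via `numpy.random.SeedSequence`, so a run is a pure function of
(inputs, config, seed).

## Known limitations

- The segmentation cost matrix is O(n²) memory per chromosome; fine to
  ~20k probes per chromosome, beyond which a banded or pruned DP would
  be needed.
- The recurrence null assumes genes are exchangeable along the genome
  under cyclic shift; strong chromosome-end effects are not modelled.
- The expression classifier assumes approximate normality of
  log-expression among diploid samples; heavy tails inflate the
  flagged fraction.
- Hotelling features use per-gene means; with very few samples per
  gene the copy/expression coupling estimate is noisy.
- The driver/passenger logic presumes the human-side region is
  uniformly recurrently amplified (it validates this) and that the
  synteny map is length-preserving per block.
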