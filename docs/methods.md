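# Methods

This note documents the models, the parameters that matter, the synthetic
data generator, and the numerical and design choices behind `cnkit`.

## Coverage and normalization model

The atomic observation is the number of filter-passing reads whose leftmost
aligned base falls inside a capture target ("bait"): MAPQ > 1, proper pair,
primary, non-duplicate, non-supplementary. Counting read starts (rather than
overlaps) assigns each read to exactly one bait, so a read spanning two
baits is never double-counted. Fragments are counted per mate, not per pair.

Raw counts are confounded by per-sample depth, capture efficiency and smooth
"genomic waves". Instead of modeling these explicitly, each sample is
normalized against a **dynamic reference**: the N most similar other
samples, where similarity is the sum of two ranks — Spearman correlation of
autosomal counts (computed on a fixed, hash-selected subsample of at most
20,000 baits so all pairs use the same sites) and closeness of genomic-wave
scale. Ties break by sample id, making selection invariant to input order.
The chrX dose response (|median chrX log2 ratio against opposite-sex
members|, expected ≈ 1) is recorded per reference set as a diagnostic rather
than entering the ranking objective, keeping each score component separately
inspectable. N is a deliberate cohort-wide constant (biobank-scale runs use
N = 2,000; the desk-scale studies here use 30–100) so reference-size
differences cannot bias comparisons between samples.

The log2 ratio uses a 0.5 pseudo-count in numerator and denominator and is
centered by the sample's autosomal median, so every centered row has
autosomal median 0 (enforced to 1e−9). Baits whose reference median is zero
carry no information and become NaN, excluded from centering and skipped
downstream. References are computed on raw counts; depth differences cancel
in the centering step.

Sex is classified first (2-means on the chrX/autosome coverage ratio,
rescaled so the two-X cluster centers at 1.0). Ambiguity bands are robust
and scale-free: beyond center ± max(4·MAD, 0.25) → ambiguous high/low;
within 20% of the inter-center distance of the midpoint → ambiguous mid.
Ambiguous samples are excluded from all reference pools.

### Genomic-wave score

One smoother quantifies waves everywhere: a centered 401-point running
median of the autosomal profile (span shrunk to the largest odd number ≤ n
when the profile is shorter, with a warning). The reference-selection score
divides its standard deviation by a robust probe-noise scale
(median |first difference| / √2 × 1.4826); the QC estimate divides its IQR
by 1.349 × the same noise scale. Both are scale-free and read "≈ 1" as
"wave as large as probe noise"; values above 1 flag samples whose calling
is wave-limited. Window edges use partial windows (pandas-style
`min_periods=1`), which affects at most 200 baits per chromosome end.

## CNV calling

A single 3-state HMM (loss, neutral, gain) with Gaussian emissions on
centered log2 ratios. Canonical initialization encodes diploid dosage
geometry: means log2(1/2, 2/2, 3/2) = (−1, 0, 0.585), self-transitions
0.999, π = (0.005, 0.99, 0.005), shared σ initialized from the robust SD of
the training rows (floored at 0.01).

**Training.** Baum–Welch EM per target sample over the mismatched-flavor
ratio rows of its reference members, each row an independent sequence. The
opposite-sex chrX shift guarantees a large single-copy event in every
training sequence, anchoring the non-neutral states; the main benefit of
training on many similar rows is accurate transition probabilities. The
log-likelihood is asserted non-decreasing at every iteration and training
stops at |Δll| < tol or max_iter. If the mean ordering is violated after an
M-step the states are relabeled (a likelihood-invariant permutation).

**Robust emissions.** Each state emits from
(1 − ε)·Normal(μ_s, σ_s) + ε·Cauchy(0, 2) with ε = 10⁻⁶ fixed and shared.
Pure Gaussian emissions underflow on extreme artifact baits (the scaled
recursions produce NaN), and flooring the density breaks the EM bound; the
tiny heavy-tailed component keeps every recursion strictly positive, keeps
EM exactly monotone (the M-step uses Gaussian-component responsibilities),
and stops single artifact baits from dragging component means. For ordinary
data it is Gaussian to numerical precision.

**Decoding.** Exact Viterbi per chromosome (π reused at each chromosome
start), ties toward the lower state index; forward–backward posteriors
provide per-bait confidence. Missing baits emit 1 in every state, so the
transition structure composes across gaps without a distance model. Maximal
runs of identical non-neutral states become calls with the run's outermost
bait bounds, mean ratio, and mean posterior — no outlier-tolerant merging
on top.

**Dosage-anchored decoding.** The mismatched chrX anchor sits at ±1 in log2
(2-vs-1 copies), so trained gain means land near +1 — but a single-copy gain
on a diploid background sits at +0.585, which halves gain sensitivity if
decoded naively. By default the decoding model therefore keeps the trained
transitions and σ but re-anchors the emission means at (−1, 0, 0.585)
(`anchor_means` in `call_all`). Calls are made on the matched-flavor ratios;
training uses mismatched only.

## Merging, frequencies, PCA

Calls of one type (losses and gains separately) merge into events via the
connected components of the graph joining call pairs whose reciprocal
overlap — overlap length over each interval's own length — is ≥ 0.5 in both
directions. Components are exactly the closure of "add any call sharing 50%
with a member", but order-free and deterministic. Event bounds move 80% of
the way from the innermost member bound toward the outermost (rounded to
nearest integer). Frequencies are carriers/n with binomial standard errors
√(p(1−p)/n); a sample counts once per event, and the overall frequency
counts carriers of either type whose calls reciprocally overlap the event
span. Bait-level frequencies count samples with ≥ 1 overlapping call per
bait.

Copy-number PCA is NIPALS-style power iteration with deflation (seeded
start, convergence |Δv| < 10⁻⁹, up to 10,000 iterations per component —
narrow spectral gaps converge slowly; sign fixed by making the
largest-|loading| coordinate positive), run separately on four strata:
bait-level log2 ratios and event-level carrier dosages (−1/0/+1), each split
at 1% frequency into common (≥ 1%) and rare (> 0, < 1%) variable sites.
Mixing strata lets common sites dominate the leading components, which is
why they are decomposed apart.

## Association testing

Quantitative traits are inverse-rank normalized — average ranks, offset
(rank − 0.5)/n, mapped through Φ⁻¹ — then fit by OLS per site on the
continuous dosage plus covariates (sex, age, batch indicators, 10 common +
10 rare CNV PCs; collinear columns dropped by pivoted QR). The per-site scan
residualizes the trait and all dosage columns against the covariate block
once (Frisch–Waugh), which is algebraically identical to full OLS
(cross-checked against statsmodels in the tests) and makes 100 permutation
rounds cost seconds. Binary traits use unpenalized ML logistic regression
and require ≥ 500 cases; non-convergent sites are flagged with missing p.
Zero-variance dosages are skipped. Binary traits are not rank-normalized.

Calibration: λ = median(χ²₁(1 − p)) / χ²₁⁻¹(0.5); the denominator is the
exact null median 0.45494 so that p ≡ 0.5 gives λ = 1 exactly. Thresholds:
fixed genome-wide 5×10⁻⁸, Bonferroni α/n, or Benjamini–Hochberg step-up.
Permutation nulls re-run the full linear scan on seeded reorderings of the
phenotype.

Fine mapping merges maximal runs of directly adjacent significant baits,
then merges regions sharing any gene, absorbing that gene's intervening
non-significant baits into the span; the lead bait is the minimum-p member
(ties: larger |β|, then leftmost). The output partitions the significant
set.

## SNP–CNV integration

r² is the squared Pearson correlation between the lead bait's dosage and a
SNP's allele dosage on complete cases (0, flagged, for constant vectors).
Within ±1 Mb of the lead bait, a fine-mapped region is classified by
decision order: no significant SNP nearest a region gene → CNV_only if
nothing tags the CNV (r² > 0.6), else SNP_CNV_far; significant near SNPs but
none tagging → CNV_allele; any tagging near SNP → SNP_CNV_near. "Nearest
gene" is distance to the gene interval (0 inside), ties by distance to the
lead bait then gene id.

Copy-number states at lead sites come from a 3-component univariate
Gaussian mixture (EM, percentile 10/50/90 initialization, weights floored at
10⁻⁴). Assignment is posterior argmax, clamped so no sample sits beyond the
mean of a non-assigned adjacent component; an outer component within 0.25
log2 of the middle one is not a distinct copy-number state (true adjacent
states are ≥ 0.585 apart) and its samples fold into the middle. States enter
models as one ordinal 0/1/2 term. The eight competitive models are the four
single-term fits (CN estimate, CN state, best-p SNP, best-r² SNP) and the
four pairwise CNV+SNP joint fits; a CNV term with p > 5×10⁻⁸ in a joint
model is "controlled" by the SNP.

## Synthetic cohorts

Counts are Poisson (or gamma-Poisson with var = μ + φμ²) around
depth·wave·(copy/2)·sex-factor. Waves are multiplicative: exp2 of a
per-sample sum of 3 sinusoids with random phases, periods 100–800 baits
(sub-chromosomal, GC-like scales) and amplitudes N(0, 0.03) in log2 — about
5% smooth modulation, a modest exome wave consistent with the mismatched
chrX dose response staying within ±0.1 at desk-scale reference pools.
Per-sample depth is lognormal (10% sd) around 200 reads/bait. chrX is
half-dosed in males. CNVs ride on haplotypes (allele frequency
1 − √(1 − carrier frequency)), so recurrent events include homozygous
carriers; SNPs couple to CNV haplotypes through a fixed-marginal 2×2
haplotype table that hits a target r² exactly in expectation and raises,
naming the bound r²max = f(1−g)/(g(1−f)), when infeasible. Quantitative
traits are Σβ·dosage (optionally variance-standardized) + covariate effects
+ N(0, 1); binary traits use a logistic link at a configured case fraction.
Everything is a pure function of the seed; fixture files are byte-identical
across runs.

The default cohort (200 samples × 2,000 baits) carries ~12 common
polymorphic loci with a loss bias and 3 rare loci, chosen so per-sample call
profiles resemble real exome cohorts (most samples carry several calls,
loss:gain ≈ 1.4) and cohort-level QC fences are non-degenerate.

What the generator does **not** emulate: GC-content structure (waves are
phase-random sinusoids, not sequence-driven), mappability artifacts,
batch-correlated capture differences, relatedness, linkage between CNV
loci, non-additive or U-shaped genotype–phenotype maps, and read-level
artifacts. Passing tests therefore demonstrate the statistical machinery
under the stated noise model, not robustness to every failure mode of real
capture data.

## Benchmark study sizes

The built-in studies (`cnkit.studies`) use desk-scale sizes chosen to keep
each run in minutes on one CPU while leaving the estimates stable: the null
calibration study uses 2,000 samples × 1,000 autosomal baits (+80 chrX),
reference size 50, HMM training on 12 member rows with ≤ 15 EM iterations;
call-recovery cohorts use 150 samples × 1,260 baits with six injected loci
of 3–6 baits; the dose-response comparison drops depth to 60 reads/bait,
where the loss/gain sensitivity gap is visible. GWAS in the null study tests
all 1,000 autosomal baits with the full covariate set.

## QC pass rules

Per sample: total call count inside Tukey fences (quartiles ± 3×IQR) of the
cohort distribution; rare-call proportion (calls whose event frequency,
per type, is < 1%) below the cohort upper fence; |log10((losses+1)/
(gains+1))| < 1. Samples with no calls pass with zeroed metrics and a logged
note. The fences are configuration-exposed; they are declared substitutes
for unpublished pass rules.

## Known limitations

- Copy number is **relative**: at loci where a large fraction of the
  reference carries the variant the median baseline shifts and dosage (and
  tagging r²) is attenuated — visible in the examples at a 45%-frequency
  locus. This is inherent to median-reference normalization.
- Homozygous deletions sit near log2 ≈ −8, a strong nonlinearity for the
  additive dosage model; linear tests lose power where CN-0 carriers are
  common.
- The HMM has three states: multi-copy amplifications are called "gain"
  without copy resolution; breakpoints are bait-resolution only.
- Logistic fits are plain ML (no Firth correction); rare binary traits near
  the 500-case floor can be unstable.
- No relatedness or mixed-model correction; inputs are assumed unrelated.
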