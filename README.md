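# cnkit

Copy-number estimation, CNV calling and copy-number GWAS from targeted
sequencing read depth.

`cnkit` is for statistical geneticists who want to treat copy number the way
SNP GWAS treats allele dosage: estimate a well-calibrated, continuous
copy-number dosage at every capture target (bait/exon) across a cohort, call
CNVs from it, and regress traits on it genome-wide — with the usual GWAS
diagnostics (QQ/λ, permutations, fine mapping) and a four-way classification
of whether each CNV association is discoverable or taggable by nearby SNPs.

## The method

For sample *i* with read count $c_{ib}$ at bait *b*, the dosage estimate is a
log2 ratio against a **dynamic reference** — the median count of the *N*
other samples most similar to *i* (ranked by Spearman depth correlation plus
genomic-wave-scale similarity):

$$r_{ib} = \log_2\frac{c_{ib}+1/2}{\mathrm{median}_{j\in R_i}\,c_{jb}+1/2}
\;-\; \mathrm{median}_{b'\in\text{autosomes}}(\cdot)$$

computed per reference flavor (same-sex "matched", opposite-sex
"mismatched", or "mixed"). A value of 0 means two copies, −1 a single-copy
loss, +0.585 a single-copy gain. CNVs are called per sample with a 3-state
HMM (loss / neutral / gain, Gaussian emissions), trained by Baum–Welch on
the sample's reference members' *mismatched* ratios — every training
sequence then contains the chrX single-copy shift, anchoring the non-neutral
states — and decoded by Viterbi per chromosome. Calls are merged across
samples into copy-number events (CNVEs) by iterative 50%-reciprocal-overlap
closure with an 80% inner→outer boundary adjustment and binomial carrier
frequencies. Association testing is OLS of the inverse-rank-normalized trait
(logistic regression for binary traits with ≥500 cases) on the per-bait
dosage, with sex, age, batch and 10+10 frequency-stratified copy-number PCs
as covariates; calibration is checked with the genomic inflation factor
λ = median(χ²)/0.4549 and phenotype permutations, and significant baits are
merged into gene-aware fine-mapped regions (threshold 5×10⁻⁸).

Every stage runs against a seeded synthetic cohort generator
(`cnkit.simulate`) that emulates Poisson/negative-binomial coverage,
multiplicative genomic waves, sex-dependent chrX dosage, haplotype-borne
CNVs, tagging SNPs with a target r², and additive phenotypes — with full
ground truth for benchmarking.

## Worked example

`examples/05_cn_gwas.py` simulates 800 samples × 2,000 baits with a loss
locus (15% carriers) carrying a standardized effect of 0.4 on the trait
`qt_height`, normalizes the cohort, and runs the dosage GWAS:

```
1920 baits tested, covariates: ['sex_female', 'age', 'batch_1']
genomic inflation lambda = 0.981 (well calibrated if ~1, flagged above 1.13)
strongest signals:
    site_id     beta       se            p
chr1_b00841 0.442688 0.046348 1.539421e-20
chr1_b00843 0.440120 0.046393 2.689831e-20
chr1_b00842 0.438351 0.046346 3.435892e-20
1 fine-mapped region(s) at 5e-08:
  chr1:2530000-2542120 genes=chr1_g0105 lead=chr1_b00841 p=1.54e-20 beta=0.44
(injected causal locus spans bait indices 840-844)
```

λ ≈ 0.98 says the 1,900-odd null baits are well calibrated; the single
fine-mapped region sits exactly on the injected locus, and the lead-exon
beta ≈ 0.44 recovers the planted effect per unit of log2 dosage. The other
examples (`examples/01`–`06`) walk through simulation, normalization,
calling, merging/QC and SNP–CNV integration the same way; `cnkit run
--config cfg.json --workdir out/` runs the whole chain from the shell with a
hash-checked manifest.

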