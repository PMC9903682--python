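"""Generate a seeded synthetic exome cohort and look at its ground truth.

The generator produces per-bait read counts with sample-specific genomic
waves, sex-dependent chrX dosage, haplotype-borne CNVs, tagging SNPs and
phenotypes — everything downstream stages need, with the truth recorded.
"""
import numpy as np

from cnkit.simulate import default_config, simulate_cohort

cohort = simulate_cohort(default_config(seed=7, n_samples=100))

print(f"samples: {cohort.coverage.n_samples}, baits: {cohort.coverage.n_baits}")
print(f"mean coverage per bait: {cohort.coverage.values.mean():.1f} reads")
n_female = (cohort.truth.sex == "female").sum()
print(f"sex: {n_female} female / {len(cohort.truth.sex) - n_female} male")
print(f"CNV loci: {len(cohort.config.cnvs)}; carrier frequencies "
      f"{np.round(cohort.truth.carriers.mean(axis=0), 3).tolist()}")
d = cohort.truth.copy_numbers[:, 0] - 2
r2 = np.corrcoef(d, cohort.snp_dosages[:, 0])[0, 1] ** 2
print(f"realized tagging r2 between rs_tag1 and its CNV: {r2:.3f} "
      "(target 0.9)")
# The counts are Poisson draws around depth x wave x copy/2 x sex factor, so
# carriers of the first (loss) locus should show ~half coverage there:
lo, hi = cohort.truth.cnv_bait_spans[0]
carrier = cohort.truth.carriers[:, 0]
inside = cohort.coverage.values[:, lo:hi].mean(axis=1)
print(f"mean count at the loss locus: carriers {inside[carrier].mean():.0f} "
      f"vs non-carriers {inside[~carrier].mean():.0f}")
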