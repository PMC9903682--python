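"""Self-contained benchmark studies on synthetic cohorts.

Each study generates a seeded cohort with known ground truth, runs the full
method, and reports calibration or recovery metrics: null-GWAS inflation,
phenotype-permutation false positives, CNV call precision/recall against the
injected truth, and detection power for a planted dosage effect.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import GENOME_WIDE_ALPHA, genomic_inflation, permutation_null, run_gwas
from .merge import reciprocal_overlap
from .simulate import (
    CnvSpec,
    SimulationConfig,
    TraitSpec,
    simulate_cohort,
    true_calls,
)
from .workflows import call_all, cnv_pca, covariate_matrix, merge_all, normalize

__all__ = [
    "NullStudy",
    "null_study_config",
    "run_null_gwas",
    "null_permutation_counts",
    "cnv_recovery",
    "gwas_power",
]


def null_study_config(
    seed: int, n_samples: int = 2000, autosomal_baits: int = 1000
) -> SimulationConfig:
    """Null cohort: waves and trait-independent CNVs, phenotype driven by
    covariates only (never by copy number)."""
    per_chrom = autosomal_baits // 2
    cnvs = (
        CnvSpec("chr1", per_chrom // 5, 5, "loss", 0.10),
        CnvSpec("chr2", per_chrom // 5, 6, "gain", 0.08),
        CnvSpec("chr1", (3 * per_chrom) // 5, 5, "loss", 0.008),
        CnvSpec("chr2", (3 * per_chrom) // 5, 4, "gain", 0.006),
    )
    traits = (
        TraitSpec("null_qt", "quantitative", sex_beta=0.4, age_beta=0.25,
                  batch_beta=0.2),
    )
    return SimulationConfig(
        n_samples=n_samples,
        n_autosomes=2,
        baits_per_chrom=per_chrom,
        x_baits=80,
        cnvs=cnvs,
        traits=traits,
        seed=seed,
    )


@dataclass
class NullStudy:
    lambda_inflation: float
    results: pd.DataFrame
    dosages: np.ndarray  # autosomal log2 ratios used as dosage
    trait: np.ndarray
    covariates: np.ndarray
    n_samples: int
    n_sites: int


def run_null_gwas(
    seed: int,
    n_samples: int = 2000,
    autosomal_baits: int = 1000,
    reference_n: int = 50,
    max_train_rows: int = 12,
    hmm_max_iter: int = 15,
) -> NullStudy:
    """Full normalization + calling + CNV-PC covariates + linear dosage GWAS
    on a null cohort; reports the genomic inflation factor."""
    cfg = null_study_config(seed, n_samples, autosomal_baits)
    cohort = simulate_cohort(cfg)
    norm = normalize(cohort.coverage, cohort.bait_map, reference_n=reference_n)
    calls, _ = call_all(
        norm, max_train_rows=max_train_rows, max_iter=hmm_max_iter, tol=1e-3
    )
    events, assignment, bfreq = merge_all(
        calls, cohort.bait_map, cohort.coverage.n_samples
    )
    pca = cnv_pca(norm.ratios["matched"], bfreq, events, assignment, calls,
                  k=10, seed=seed)
    covar, _ = covariate_matrix(cohort.phenotypes, pca)
    auto = cohort.bait_map.is_autosome
    dosages = norm.ratios["matched"].values[:, auto]
    trait = cohort.phenotypes["null_qt"].to_numpy()
    res = run_gwas(
        dosages,
        trait,
        "quantitative",
        covariates=covar,
        site_ids=cohort.bait_map.bait_id[auto],
    )
    lam = genomic_inflation(res["p"])
    return NullStudy(lam, res, dosages, trait, covar, n_samples, int(auto.sum()))


def null_permutation_counts(
    study: NullStudy, rounds: int = 100, seed: int = 0
) -> np.ndarray:
    """Per-round counts of sites passing 5e-08 under phenotype permutation."""
    return permutation_null(
        study.dosages,
        study.trait,
        covariates=study.covariates,
        rounds=rounds,
        seed=seed,
        threshold=GENOME_WIDE_ALPHA,
    )


# ---------------------------------------------------------------------------
# CNV recovery


def recovery_config(seed: int, n_samples: int = 150) -> SimulationConfig:
    """Cohort with injected events of >=3 baits for call benchmarking."""
    cnvs = (
        CnvSpec("chr1", 80, 5, "loss", 0.08),
        CnvSpec("chr1", 240, 4, "gain", 0.08),
        CnvSpec("chr1", 400, 3, "loss", 0.04),
        CnvSpec("chr2", 120, 3, "gain", 0.04),
        CnvSpec("chr2", 300, 6, "loss", 0.02),
        CnvSpec("chr2", 460, 5, "gain", 0.02),
    )
    return SimulationConfig(
        n_samples=n_samples,
        n_autosomes=2,
        baits_per_chrom=600,
        x_baits=60,
        cnvs=cnvs,
        seed=seed,
    )


def cnv_recovery(
    seed: int,
    n_samples: int = 150,
    reference_n: int = 40,
    max_train_rows: int = 15,
    min_ro: float = 0.5,
) -> dict:
    """Call CNVs end-to-end and score them against the injected truth at 50%
    reciprocal overlap, per sample."""
    cohort = simulate_cohort(recovery_config(seed, n_samples))
    norm = normalize(cohort.coverage, cohort.bait_map, reference_n=reference_n)
    calls, _ = call_all(norm, max_train_rows=max_train_rows, max_iter=25, tol=1e-3)
    truth = true_calls(cohort)

    def _match(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
        """For each row of a: does b hold a same-sample same-type call with
        reciprocal overlap >= min_ro?"""
        hit = np.zeros(len(a), dtype=bool)
        groups = {k: g for k, g in b.groupby(["sample_id", "chrom", "state"])}
        for i, row in a.reset_index(drop=True).iterrows():
            g = groups.get((row["sample_id"], row["chrom"], row["state"]))
            if g is None:
                continue
            for s, e in zip(g["start"], g["end"]):
                if min(reciprocal_overlap((row["start"], row["end"]), (s, e))) >= min_ro:
                    hit[i] = True
                    break
        return hit

    auto_calls = calls[calls["chrom"] != "chrX"].reset_index(drop=True)
    tp_truth = _match(truth, auto_calls)
    tp_calls = _match(auto_calls, truth)
    loss_t = truth["state"] == "loss"
    out = {
        "recall": float(tp_truth.mean()) if len(truth) else float("nan"),
        "precision": float(tp_calls.mean()) if len(auto_calls) else float("nan"),
        "recall_loss": float(tp_truth[loss_t].mean()) if loss_t.any() else float("nan"),
        "recall_gain": float(tp_truth[~loss_t].mean()) if (~loss_t).any() else float("nan"),
        "n_true": int(len(truth)),
        "n_called": int(len(auto_calls)),
    }
    return out


# ---------------------------------------------------------------------------
# Power


def power_config(seed: int, n_samples: int = 2000, beta: float = 0.1,
                 carrier_freq: float = 0.05) -> SimulationConfig:
    """One causal CNV with a standardized additive effect on one trait."""
    cnvs = (CnvSpec("chr1", 30, 4, "loss", carrier_freq),)
    traits = (
        TraitSpec("qt", "quantitative", effects=((0, beta),),
                  standardized=True, sex_beta=0.3, age_beta=0.2),
    )
    return SimulationConfig(
        n_samples=n_samples,
        n_autosomes=1,
        baits_per_chrom=80,
        x_baits=30,
        cnvs=cnvs,
        traits=traits,
        seed=seed,
    )


def gwas_power(
    seeds,
    n_samples: int = 2000,
    beta: float = 0.1,
    carrier_freq: float = 0.05,
    reference_n: int = 50,
    threshold: float = GENOME_WIDE_ALPHA,
) -> dict:
    """Fraction of replicates where the planted effect reaches genome-wide
    significance at the causal site (lead bait of the causal locus)."""
    detected = []
    causal_p = []
    for seed in seeds:
        cohort = simulate_cohort(power_config(seed, n_samples, beta, carrier_freq))
        norm = normalize(cohort.coverage, cohort.bait_map, reference_n=reference_n,
                         flavors=("matched",))
        covar, _ = covariate_matrix(cohort.phenotypes)
        auto = cohort.bait_map.is_autosome
        res = run_gwas(
            norm.ratios["matched"].values[:, auto],
            cohort.phenotypes["qt"].to_numpy(),
            "quantitative",
            covariates=covar,
            site_ids=np.flatnonzero(auto),
        )
        lo, hi = cohort.truth.cnv_bait_spans[0]
        at_locus = res[(res["site_id"] >= lo) & (res["site_id"] < hi)]
        pmin = float(at_locus["p"].min()) if len(at_locus) else 1.0
        causal_p.append(pmin)
        detected.append(pmin < threshold)
    return {
        "power": float(np.mean(detected)),
        "n_replicates": len(detected),
        "median_causal_p": float(np.median(causal_p)),
    }
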