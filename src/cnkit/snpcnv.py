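"""SNP-CNV integration: tagging r2, four-class labels, copy-number states,
and competitive joint models.

A fine-mapped CNV association is classified by whether SNP GWAS inside a
1 Mb window could have found it (significant SNPs nearest a region gene) and
whether it is taggable (any such SNP with r2 > 0.6 against the lead CNV
dosage): CNV_only, CNV_allele, SNP_CNV_near, SNP_CNV_far. At lead sites a
3-component Gaussian mixture converts continuous log2 ratios into ordinal
copy-number states, and eight competitive regressions measure how much of the
CNV signal the best SNPs absorb.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gwas import GENOME_WIDE_ALPHA, _design

__all__ = [
    "snp_cnv_r2",
    "classify_region",
    "fit_cn_states",
    "competitive_models",
    "AssociationClass",
    "CnStateFit",
    "CLASS_LABELS",
]

log = logging.getLogger(__name__)

CLASS_LABELS = ("CNV_only", "CNV_allele", "SNP_CNV_near", "SNP_CNV_far")
DEFAULT_WINDOW = 1_000_000
DEFAULT_R2_CUT = 0.6


def snp_cnv_r2(cnv_dosage, snp_dosage) -> float:
    """Squared Pearson correlation on complete cases; 0 when either vector is
    constant (logged)."""
    x = np.asarray(cnv_dosage, dtype=float)
    y = np.asarray(snp_dosage, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.var(x) == 0 or np.var(y) == 0:
        log.info("zero-variance vector in r2 computation; returning 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class AssociationClass:
    region_id: str
    label: str
    max_r2: float
    supporting_snps: list[str]


def classify_region(
    region_id: str,
    region_genes: set[str],
    snps: pd.DataFrame,
    lead_dosage: np.ndarray,
    snp_dosages: np.ndarray,
    r2_cut: float = DEFAULT_R2_CUT,
    snp_sig: float = GENOME_WIDE_ALPHA,
) -> AssociationClass:
    """Four-way label for one fine-mapped CNV region.

    ``snps`` holds the SNPs already windowed to +-1 Mb of the lead bait, with
    columns snp_id, assoc_p, nearest_gene_id; ``snp_dosages`` is the matching
    (n_samples x n_snps) dosage matrix.

    Decision rules:
      - no significant SNP nearest a region gene: CNV_only if no significant
        SNP anywhere in the window tags the CNV (r2 > cut), else SNP_CNV_far;
      - significant SNPs nearest a region gene, none tagging: CNV_allele;
      - any tagging significant SNP nearest a region gene: SNP_CNV_near.
    """
    if len(snps) == 0:
        return AssociationClass(region_id, "CNV_only", 0.0, [])
    r2 = np.array(
        [snp_cnv_r2(lead_dosage, snp_dosages[:, j]) for j in range(len(snps))]
    )
    sig = snps["assoc_p"].to_numpy() < snp_sig
    near = sig & snps["nearest_gene_id"].isin(region_genes).to_numpy()
    tagged = sig & (r2 > r2_cut)
    max_r2 = float(r2[sig].max()) if sig.any() else 0.0

    snp_ids = snps["snp_id"].to_numpy()
    if not near.any():
        if not tagged.any():
            return AssociationClass(region_id, "CNV_only", max_r2, [])
        return AssociationClass(
            region_id, "SNP_CNV_far", max_r2, list(snp_ids[tagged])
        )
    if (near & tagged).any():
        return AssociationClass(
            region_id, "SNP_CNV_near", max_r2, list(snp_ids[near & tagged])
        )
    return AssociationClass(region_id, "CNV_allele", max_r2, list(snp_ids[near]))


def nearest_gene(pos: int, genes: pd.DataFrame, lead_pos: int | None = None) -> str:
    """Gene whose interval is closest to ``pos`` (0 if inside); ties broken by
    distance to the lead position, then gene id."""
    if len(genes) == 0:
        return ""
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    dist = np.where(pos < starts, starts - pos, np.where(pos >= ends, pos - ends + 1, 0))
    lead_d = (
        np.abs((starts + ends) // 2 - lead_pos)
        if lead_pos is not None
        else np.zeros(len(genes))
    )
    order = sorted(
        range(len(genes)),
        key=lambda i: (dist[i], lead_d[i], str(genes["gene_id"].iloc[i])),
    )
    return str(genes["gene_id"].iloc[order[0]])


# ---------------------------------------------------------------------------
# Copy-number state mixture


@dataclass
class CnStateFit:
    means: np.ndarray  # ascending
    sds: np.ndarray
    weights: np.ndarray
    states: np.ndarray  # 0 low, 1 mid, 2 high per sample
    converged: bool


def fit_cn_states(
    values: np.ndarray,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_separation: float = 0.25,
) -> CnStateFit:
    """3-component univariate Gaussian mixture over lead-site log2 ratios.

    Initialized at the 10th/50th/90th percentiles. Samples are assigned their
    maximum-posterior component and then clamped so that no sample sits beyond
    the mean of a non-assigned adjacent component. An outer component whose
    mean sits within ``min_separation`` log2 units of the middle one does not
    represent a distinct copy-number state (true adjacent states are >= 0.585
    apart) and its samples are folded into the middle state.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 50:
        raise ValueError(f"need >= 50 samples to fit copy-number states, got {n}")
    mu = np.percentile(x, [10, 50, 90]).astype(float)
    if mu[0] == mu[1]:
        mu[0] -= 1e-3
    if mu[1] == mu[2]:
        mu[2] += 1e-3
    sd = np.full(3, max(np.std(x) / 2, 1e-3))
    w = np.full(3, 1 / 3)

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        resp = np.empty((n, 3))
        for k in range(3):
            resp[:, k] = w[k] * np.exp(-0.5 * ((x - mu[k]) / sd[k]) ** 2) / sd[k]
        tot = resp.sum(axis=1, keepdims=True)
        tot[tot <= 0] = 1e-300
        ll = float(np.sum(np.log(tot))) - n * 0.5 * np.log(2 * np.pi)
        resp /= tot
        nk = resp.sum(axis=0)
        w = np.maximum(nk / n, 1e-4)
        w /= w.sum()
        nk = np.maximum(nk, 1e-8)
        mu_new = resp.T @ x / nk
        var = resp.T @ (x**2) / nk - mu_new**2
        mu = mu_new
        sd = np.sqrt(np.maximum(var, 1e-6))
        order = np.argsort(mu, kind="stable")
        mu, sd, w = mu[order], sd[order], w[order]
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    if not converged:
        log.warning("copy-number state mixture hit max_iter; best fit returned")

    resp = np.empty((n, 3))
    for k in range(3):
        resp[:, k] = w[k] * np.exp(-0.5 * ((x - mu[k]) / sd[k]) ** 2) / sd[k]
    states = np.argmax(resp, axis=1)
    # clamping: never beyond the mean of a non-assigned adjacent component
    states = np.where((states < 2) & (x > mu[np.minimum(states + 1, 2)]),
                      states + 1, states)
    states = np.where((states < 2) & (x > mu[2]), 2, states)
    states = np.where((states > 0) & (x < mu[np.maximum(states - 1, 0)]),
                      states - 1, states)
    states = np.where((states > 0) & (x < mu[0]), 0, states)
    # fold outer components that are not distinct copy-number states
    if mu[1] - mu[0] < min_separation:
        states[states == 0] = 1
    if mu[2] - mu[1] < min_separation:
        states[states == 2] = 1
    return CnStateFit(mu, sd, w, states.astype(int), converged)


# ---------------------------------------------------------------------------
# Competitive models


MODEL_SPECS = {
    "cn_estimate": ("cn_estimate",),
    "cn_state": ("cn_state",),
    "max_snp": ("max_snp",),
    "max_r2_snp": ("max_r2_snp",),
    "cn_estimate+max_snp": ("cn_estimate", "max_snp"),
    "cn_state+max_snp": ("cn_state", "max_snp"),
    "cn_estimate+max_r2_snp": ("cn_estimate", "max_r2_snp"),
    "cn_state+max_r2_snp": ("cn_state", "max_r2_snp"),
}

CNV_TERMS = ("cn_estimate", "cn_state")


def competitive_models(
    cn_estimate: np.ndarray,
    cn_state: np.ndarray,
    trait: np.ndarray,
    max_snp_dosage: np.ndarray,
    max_r2_snp_dosage: np.ndarray,
    covariates=None,
    threshold: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Fit the eight competitive regressions at one lead site.

    Single-term models for the continuous copy-number estimate, the ordinal
    copy-number state (0/1/2), the most significant SNP and the best-tagging
    SNP, plus the four pairwise CNV+SNP joint models. The ``controlled`` flag
    marks CNV terms pushed above the significance threshold in a joint model.
    """
    terms = {
        "cn_estimate": np.asarray(cn_estimate, dtype=float),
        "cn_state": np.asarray(cn_state, dtype=float),
        "max_snp": np.asarray(max_snp_dosage, dtype=float),
        "max_r2_snp": np.asarray(max_r2_snp_dosage, dtype=float),
    }
    n = len(trait)
    X0 = _design(covariates, n)
    rows = []
    for model_name, used in MODEL_SPECS.items():
        X = np.column_stack([terms[t] for t in used] + [X0])
        res = sm.OLS(np.asarray(trait, dtype=float), X).fit()
        joint = len(used) == 2
        for k, t in enumerate(used):
            rows.append(
                {
                    "model": model_name,
                    "term": t,
                    "beta": float(res.params[k]),
                    "se": float(res.bse[k]),
                    "p": float(res.pvalues[k]),
                    "joint": joint,
                    "controlled": bool(
                        joint and t in CNV_TERMS and res.pvalues[k] > threshold
                    ),
                }
            )
    return pd.DataFrame(rows)
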