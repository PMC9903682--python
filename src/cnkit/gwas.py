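"""Copy-number GWAS: dosage regressions, calibration diagnostics, fine mapping.

The continuous copy-number estimate (log2 ratio, or mean ratio per merged
event) is treated as an additive dosage, exactly as allele dosage is in SNP
GWAS: ordinary least squares on inverse-rank-normalized quantitative traits,
unpenalized maximum-likelihood logistic regression for binary traits, always
with covariates. Calibration is checked with the genomic inflation factor and
phenotype-permutation nulls.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy.special import ndtri
from scipy.stats import chi2, rankdata
from scipy.stats import t as t_dist

from .baits import BaitMap

__all__ = [
    "inverse_rank_normalize",
    "run_gwas",
    "genomic_inflation",
    "significance_thresholds",
    "permutation_null",
    "fine_map",
    "FineMappedRegion",
    "GENOME_WIDE_ALPHA",
]

log = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8
CHI2_NULL_MEDIAN = chi2.ppf(0.5, 1)  # 0.4549...


def inverse_rank_normalize(values) -> np.ndarray:
    """Map values through ranks to standard normal quantiles.

    Uses average ranks for ties and the offset (rank - 0.5)/n; missing values
    are preserved as NaN. A constant vector maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    n = ok.sum()
    if n == 0:
        return out
    if n == 1:
        out[ok] = 0.0
        return out
    ranks = rankdata(v[ok], method="average")
    out[ok] = ndtri((ranks - 0.5) / n)
    return out


# ---------------------------------------------------------------------------
# Design-matrix helpers


def _design(covariates, n: int) -> np.ndarray:
    """Intercept + covariates, with collinear columns dropped (pivoted QR)."""
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    keep = piv[diag > max(X.shape) * np.finfo(float).eps * max(diag.max(), 1.0)]
    return X[:, np.sort(keep)]


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q


@dataclass
class _LinearEngine:
    """Covariate-residualized linear dosage scan (Frisch-Waugh projection).

    Residualizing the trait and every dosage column against the covariate
    block once makes each per-site OLS a one-dimensional regression, which is
    what lets a 100-round permutation scan run in seconds. Equivalent to full
    OLS with the covariates in the model (cross-checked in the test suite).
    """

    dosages: np.ndarray
    covariates: np.ndarray | None = None
    _Q: np.ndarray = field(init=False, repr=False)
    _Xr: np.ndarray = field(init=False, repr=False)
    _xx: np.ndarray = field(init=False, repr=False)
    df: int = field(init=False)

    def __post_init__(self):
        D = np.asarray(self.dosages, dtype=float)
        n = D.shape[0]
        X = _design(self.covariates, n)
        self._Q = _orthonormal_basis(X)
        self._Xr = D - self._Q @ (self._Q.T @ D)
        self._xx = np.einsum("ij,ij->j", self._Xr, self._Xr)
        self.df = n - X.shape[1] - 1

    def scan(self, trait: np.ndarray):
        """Per-site (beta, se, p) of the dosage term."""
        y = np.asarray(trait, dtype=float)
        yr = y - self._Q @ (self._Q.T @ y)
        yy = float(yr @ yr)
        xx = np.maximum(self._xx, 1e-300)
        beta = (self._Xr.T @ yr) / xx
        rss = np.maximum(yy - beta**2 * xx, 0.0)
        sigma2 = rss / self.df
        se = np.sqrt(np.maximum(sigma2 / xx, 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        p = 2.0 * t_dist.sf(np.abs(tstat), self.df)
        return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)

    @property
    def informative(self) -> np.ndarray:
        """Sites whose dosage retains variance after covariate projection."""
        scale = np.var(np.asarray(self.dosages, dtype=float), axis=0)
        return (self._xx > 1e-12) & (scale > 1e-12)


def run_gwas(
    dosages,
    trait,
    trait_type: str = "quantitative",
    covariates=None,
    site_ids=None,
    min_cases: int = 500,
    apply_irn: bool = True,
) -> pd.DataFrame:
    """Per-site association of a trait with copy-number dosage.

    Quantitative traits are inverse-rank normalized, then fit by OLS with
    covariates; binary traits by unpenalized ML logistic regression (at least
    ``min_cases`` cases required). Sites with zero dosage variance are
    skipped. Returns a table with site_id, beta, se, p, n_used.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if site_ids is None:
        site_ids = np.arange(D.shape[1])
    site_ids = np.asarray(site_ids)

    ok = np.isfinite(y)
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        ok &= np.isfinite(C).all(axis=1)
    else:
        C = None
    col_ok = np.isfinite(D).all(axis=0)
    if not col_ok.all():
        # complete-case per matrix: mean-fill is wrong for dosage, so restrict
        # rows where any retained site is missing
        ok &= np.isfinite(D).all(axis=1)
    D, y = D[ok], y[ok]
    Cm = C[ok] if C is not None else None
    n_used = int(ok.sum())

    if trait_type == "quantitative":
        yt = inverse_rank_normalize(y) if apply_irn else y
        engine = _LinearEngine(D, Cm)
        beta, se, p = engine.scan(yt)
        keep = engine.informative
    elif trait_type == "binary":
        cases = int(np.sum(y == 1))
        if cases < min_cases:
            raise ValueError(
                f"binary trait has {cases} cases; at least {min_cases} required"
            )
        X0 = _design(Cm, len(y))
        beta = np.full(D.shape[1], np.nan)
        se = np.full(D.shape[1], np.nan)
        p = np.full(D.shape[1], np.nan)
        keep = D.var(axis=0) > 1e-12
        for j in np.flatnonzero(keep):
            X = np.column_stack([D[:, j], X0])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", False):
                    raise RuntimeError("no convergence")
                beta[j], se[j] = res.params[0], res.bse[0]
                p[j] = res.pvalues[0]
            except Exception:
                log.warning("logistic fit failed to converge at site %s", site_ids[j])
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")

    out = pd.DataFrame(
        {"site_id": site_ids, "beta": beta, "se": se, "p": p, "n_used": n_used}
    )
    return out[keep].reset_index(drop=True)


def genomic_inflation(p_values) -> float:
    """Inflation factor: median association chi-square over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return float("nan")
    chis = chi2.isf(p, 1)
    return float(np.median(chis) / CHI2_NULL_MEDIAN)


def significance_thresholds(
    p_values, mode: str = "genomewide", alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Significance threshold plus the boolean significant set.

    genomewide: fixed 5e-08; bonferroni: alpha / n_tests; bh: Benjamini-
    Hochberg step-up at FDR alpha.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if mode == "genomewide":
        thr = GENOME_WIDE_ALPHA
        sig = finite & (p < thr)
    elif mode == "bonferroni":
        thr = alpha / max(finite.sum(), 1)
        sig = finite & (p < thr)
    elif mode == "bh":
        n = finite.sum()
        order = np.argsort(p[finite])
        sorted_p = p[finite][order]
        crit = alpha * (np.arange(1, n + 1)) / n
        passing = np.flatnonzero(sorted_p <= crit)
        thr = float(sorted_p[passing[-1]]) if passing.size else 0.0
        sig = finite & (p <= thr) if passing.size else np.zeros_like(finite)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(thr), sig


def permutation_null(
    dosages,
    trait,
    covariates=None,
    rounds: int = 100,
    seed: int = 0,
    threshold: float = GENOME_WIDE_ALPHA,
    apply_irn: bool = True,
) -> np.ndarray:
    """Counts of sites passing ``threshold`` in each phenotype permutation.

    The trait vector is randomly reordered each round (seeded) and the full
    linear dosage scan re-run against the unchanged dosage matrix.
    """
    if rounds <= 0:
        return np.zeros(0, dtype=int)
    D = np.asarray(dosages, dtype=float)
    y = np.asarray(trait, dtype=float)
    yt = inverse_rank_normalize(y) if apply_irn else y
    engine = _LinearEngine(D, covariates)
    keep = engine.informative
    rng = np.random.default_rng(seed)
    counts = np.zeros(rounds, dtype=int)
    for r in range(rounds):
        perm = rng.permutation(len(yt))
        _, _, p = engine.scan(yt[perm])
        counts[r] = int(np.sum(p[keep] < threshold))
    return counts


# ---------------------------------------------------------------------------
# Fine mapping


@dataclass
class FineMappedRegion:
    chrom: str
    start: int
    end: int
    member_baits: list[str]
    genes: list[str]
    lead_bait: str
    lead_p: float
    lead_beta: float


def fine_map(
    results: pd.DataFrame,
    bait_map: BaitMap,
    threshold: float = GENOME_WIDE_ALPHA,
) -> list[FineMappedRegion]:
    """Merge per-bait association signals into fine-mapped regions.

    Step 1: maximal runs of directly adjacent significant baits (no
    intervening non-significant signal) are merged. Step 2: regions sharing
    any gene are merged, absorbing that gene's intervening non-significant
    baits into the span. The lead bait is the minimum-p member (ties: larger
    |beta|, then leftmost).

    ``results`` must be aligned to bait order, one row per bait, with columns
    p and beta (optionally bait_index).
    """
    res = results.reset_index(drop=True)
    if "bait_index" in res.columns:
        bait_idx = res["bait_index"].to_numpy()
    else:
        bait_idx = np.arange(len(res))
    p = res["p"].to_numpy()
    beta = res["beta"].to_numpy()
    sig = np.isfinite(p) & (p < threshold)
    if not sig.any():
        return []

    chroms = bait_map.chrom
    # step 1: consecutive runs (consecutive bait indices on one chromosome)
    runs: list[list[int]] = []
    prev = None
    for i in np.flatnonzero(sig):
        b = bait_idx[i]
        if (
            prev is not None
            and bait_idx[prev] == b - 1
            and chroms[b] == chroms[bait_idx[prev]]
        ):
            runs[-1].append(i)
        else:
            runs.append([i])
        prev = i

    # step 2: union regions sharing any gene
    genes = bait_map.gene_id
    run_genes = [
        {g for i in run if (g := genes[bait_idx[i]]) != ""} for run in runs
    ]
    parent = list(range(len(runs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    gene_owner: dict[str, int] = {}
    for ridx, gset in enumerate(run_genes):
        for g in gset:
            if g in gene_owner:
                ra, rb = find(gene_owner[g]), find(ridx)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
            else:
                gene_owner[g] = ridx

    merged: dict[int, list[int]] = {}
    for ridx in range(len(runs)):
        merged.setdefault(find(ridx), []).append(ridx)

    regions = []
    for run_ids in merged.values():
        rows = sorted(i for r in run_ids for i in runs[r])
        gset = set().union(*(run_genes[r] for r in run_ids))
        members = [int(bait_idx[i]) for i in rows]
        # absorb intervening baits of shared genes between the outermost members
        lo, hi = min(members), max(members)
        absorbed = [
            j for j in range(lo, hi + 1)
            if j in members or (genes[j] in gset and chroms[j] == chroms[lo])
        ]
        lead_row = min(rows, key=lambda i: (p[i], -abs(beta[i]), bait_idx[i]))
        regions.append(
            FineMappedRegion(
                chrom=str(chroms[lo]),
                start=int(bait_map.start[absorbed].min()),
                end=int(bait_map.end[absorbed].max()),
                member_baits=[str(bait_map.bait_id[j]) for j in absorbed],
                genes=sorted(gset),
                lead_bait=str(bait_map.bait_id[bait_idx[lead_row]]),
                lead_p=float(p[lead_row]),
                lead_beta=float(beta[lead_row]),
            )
        )
    regions.sort(key=lambda r: (str(r.chrom), r.start))
    return regions
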