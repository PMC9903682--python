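"""Iterative PCA on copy-number values, stratified by population frequency.

Common and rare variable sites are decomposed separately: common sites carry
population structure while rare sites capture residual technical structure,
and mixing the two lets high-frequency sites dominate the leading components.
The component scores are the CNV covariates of the association models.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PcaResult", "stratify_sites", "iterative_pca", "event_dosage_matrix"]

STRATA = ("common_bait", "rare_bait", "common_event", "rare_event")


@dataclass
class PcaResult:
    stratum: str
    scores: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (n_sites, k), unit columns
    explained: np.ndarray  # variance fractions, non-increasing

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def stratify_sites(frequencies, threshold: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Split variable sites into common (freq >= threshold) and rare
    (0 < freq < threshold); invariant sites (freq == 0) are excluded."""
    f = np.asarray(frequencies, dtype=float)
    common = np.flatnonzero(f >= threshold) if threshold > 0 else np.flatnonzero(f > 0)
    rare = np.flatnonzero((f > 0) & (f < threshold))
    return common, rare


def iterative_pca(
    matrix: np.ndarray,
    k: int = 10,
    max_iter: int = 10_000,
    tol: float = 1e-9,
    seed: int = 0,
    stratum: str = "common_bait",
) -> PcaResult:
    """Top-k principal components by NIPALS-style power iteration with deflation.

    Columns are mean-centered (NaNs mean-filled) first. Each component's
    loading vector is iterated to |delta| < tol and deflated from the matrix.
    Sign convention: the largest-|loading| coordinate is positive.
    """
    X = np.array(matrix, dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_mask = ~np.isfinite(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    n, p = X.shape
    total_var = float((X**2).sum())
    k_req = min(k, n, p)
    rng = np.random.default_rng(seed)

    loadings = []
    scores = []
    explained = []
    for comp in range(k_req):
        v = rng.standard_normal(p)
        v /= np.linalg.norm(v)
        for _ in range(max_iter):
            w = X.T @ (X @ v)
            nw = np.linalg.norm(w)
            if nw <= 1e-12 * max(total_var, 1.0) or nw == 0.0:
                v = None
                break
            w /= nw
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                break
            v = w
        if v is None:
            break
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        t = X @ v
        loadings.append(v)
        scores.append(t)
        explained.append(float(t @ t) / total_var if total_var > 0 else 0.0)
        X = X - np.outer(t, v)
    if len(loadings) < k:
        warnings.warn(
            f"requested {k} components but rank supports {len(loadings)}"
        )
    if not loadings:
        return PcaResult(stratum, np.zeros((n, 0)), np.zeros((p, 0)), np.zeros(0))
    return PcaResult(
        stratum,
        np.column_stack(scores),
        np.column_stack(loadings),
        np.array(explained),
    )


def event_dosage_matrix(
    events, assignment: np.ndarray, calls, sample_ids: list[str]
) -> np.ndarray:
    """Per-sample carrier dosage at each event: -1 loss, 0 none, +1 gain."""
    calls = calls.reset_index(drop=True)
    idx = {s: i for i, s in enumerate(sample_ids)}
    out = np.zeros((len(sample_ids), len(events)))
    for eid, ev in events.reset_index(drop=True).iterrows():
        sign = -1.0 if ev["type"] == "loss" else 1.0
        for m in ev["members"]:
            sid = calls.loc[m, "sample_id"]
            if sid in idx:
                out[idx[sid], eid] = sign
    return out
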