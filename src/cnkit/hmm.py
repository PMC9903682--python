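"""Three-state HMM copy-number caller.

States are (loss, neutral, gain) with Gaussian emissions on centered log2
ratios. The model is trained per target sample by Baum-Welch EM on the
mismatched-flavor ratio rows of that sample's dynamic reference members; the
opposite-sex chrX shift guarantees every training sequence contains at least
one large single-copy event, anchoring the loss/gain emission components.
Decoding is exact Viterbi per chromosome; forward-backward posteriors provide
per-bait confidence.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baits import BaitMap

__all__ = [
    "HmmModel",
    "train_hmm",
    "viterbi",
    "posteriors",
    "segment_calls",
    "call_sample",
]

log = logging.getLogger(__name__)

LOSS, NEUTRAL, GAIN = 0, 1, 2
STATE_NAMES = ("loss", "neutral", "gain")
SIGMA_FLOOR = 0.01

try:  # optional JIT; identical semantics without it
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass
class HmmModel:
    """3-state generative model: initial probs, transitions, Gaussian emissions."""

    pi: np.ndarray = field(default_factory=lambda: np.array([0.005, 0.99, 0.005]))
    A: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.999, 0.0005, 0.0005],
             [0.0005, 0.999, 0.0005],
             [0.0005, 0.0005, 0.999]]
        )
    )
    means: np.ndarray = field(default_factory=lambda: np.array([-1.0, 0.0, 0.585]))
    sds: np.ndarray = field(default_factory=lambda: np.array([0.2, 0.2, 0.2]))

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.validate()

    def validate(self):
        if not np.allclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("initial probabilities must sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not (np.diff(self.means) > 0).all():
            raise ValueError("state means must be strictly increasing")
        if (self.sds <= 0).any():
            raise ValueError("emission sds must be positive")

    @classmethod
    def canonical(cls, sigma: float = 0.2) -> "HmmModel":
        """Diploid dosage geometry: means log2(1/2, 2/2, 3/2)."""
        return cls(sds=np.array([sigma] * 3))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "pi": self.pi.tolist(),
                "A": self.A.tolist(),
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "HmmModel":
        if hasattr(source, "read"):
            data = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(np.array(data["pi"]), np.array(data["A"]),
                   np.array(data["means"]), np.array(data["sds"]))


# ---------------------------------------------------------------------------
# Kernels (numba-compiled when available)


@njit(cache=False)
def _forward_backward_counts(B, pi, A):
    """Scaled forward-backward for one sequence of emission likelihoods B (T x 3).

    Returns (loglik, gamma (T x 3), xi_sum (3 x 3), gamma0 (3,)).
    """
    T = B.shape[0]
    S = 3
    alpha = np.zeros((T, S))
    c = np.zeros(T)
    for s in range(S):
        alpha[0, s] = pi[s] * B[0, s]
    c[0] = alpha[0].sum()
    if c[0] <= 0:
        c[0] = 1e-300
    alpha[0] /= c[0]
    for t in range(1, T):
        for j in range(S):
            acc = 0.0
            for i in range(S):
                acc += alpha[t - 1, i] * A[i, j]
            alpha[t, j] = acc * B[t, j]
        c[t] = alpha[t].sum()
        if c[t] <= 0:
            c[t] = 1e-300
        alpha[t] /= c[t]
    beta = np.zeros((T, S))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(S):
            acc = 0.0
            for j in range(S):
                acc += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        z = gamma[t].sum()
        if z > 0:
            gamma[t] /= z
    xi = np.zeros((S, S))
    for t in range(T - 1):
        for i in range(S):
            for j in range(S):
                xi[i, j] += alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    return ll, gamma, xi, gamma[0].copy()


@njit(cache=False)
def _viterbi_path(logB, logpi, logA):
    """Exact MAP path; ties broken toward the lower state index."""
    T = logB.shape[0]
    S = 3
    delta = np.zeros((T, S))
    back = np.zeros((T, S), dtype=np.int64)
    for s in range(S):
        delta[0, s] = logpi[s] + logB[0, s]
    for t in range(1, T):
        for j in range(S):
            best = delta[t - 1, 0] + logA[0, j]
            arg = 0
            for i in range(1, S):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            delta[t, j] = best + logB[t, j]
            back[t, j] = arg
    path = np.zeros(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for s in range(1, S):
        if delta[T - 1, s] > best:
            best = delta[T - 1, s]
            arg = s
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


OUTLIER_EPS = 1e-6
OUTLIER_SCALE = 2.0  # Cauchy scale of the shared heavy-tail component


def _emission_likelihoods(row: np.ndarray, model: HmmModel, parts: bool = False):
    """Per-state emission likelihoods; missing baits emit 1 in every state.

    Each state emits from (1 - eps) * Gaussian + eps * Cauchy with a tiny,
    fixed outlier weight shared across states. The heavy tail keeps the
    recursions away from zero for arbitrarily extreme ratios and stops single
    artifact baits from dragging component means during EM, while leaving
    regular emissions Gaussian to numerical precision.
    """
    x = np.asarray(row, dtype=float)
    B = np.ones((x.size, 3))
    ok = np.isfinite(x)
    xs = x[ok]
    cauchy = 1.0 / (np.pi * OUTLIER_SCALE * (1.0 + (xs / OUTLIER_SCALE) ** 2))
    G = np.zeros((x.size, 3))
    for s in range(3):
        gs = np.exp(-0.5 * ((xs - model.means[s]) / model.sds[s]) ** 2) / (
            np.sqrt(2 * np.pi) * model.sds[s]
        )
        G[ok, s] = (1.0 - OUTLIER_EPS) * gs
        B[ok, s] = G[ok, s] + OUTLIER_EPS * cauchy
    if parts:
        with np.errstate(invalid="ignore"):
            frac_g = np.where(B > 0, G / np.maximum(B, 1e-300), 0.0)
        return B, frac_g
    return B


# ---------------------------------------------------------------------------
# EM training


def _relabel_by_mean(pi, A, means, sds):
    order = np.argsort(means, kind="stable")
    if (order == np.arange(3)).all():
        return pi, A, means, sds
    return pi[order], A[np.ix_(order, order)], means[order], sds[order]


def train_hmm(
    training_rows: np.ndarray,
    init: HmmModel | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> HmmModel:
    """Baum-Welch EM over independent ratio-row sequences.

    Each row of ``training_rows`` (typically the mismatched-flavor log2 ratios
    of the target's reference members) is treated as one observation sequence.
    The log-likelihood is checked to be non-decreasing every iteration; the
    mean ordering (loss < neutral < gain) is re-imposed by state relabeling.
    """
    rows = np.atleast_2d(np.asarray(training_rows, dtype=float))
    if init is None:
        finite = rows[np.isfinite(rows)]
        sd = max(float(np.median(np.abs(finite - np.median(finite))) * 1.4826),
                 SIGMA_FLOOR) if finite.size else 0.2
        init = HmmModel.canonical(sigma=sd)
    pi, A = init.pi.copy(), init.A.copy()
    means, sds = init.means.copy(), init.sds.copy()

    prev_ll = -np.inf
    for iteration in range(max_iter):
        model = HmmModel(pi, A, means, sds)
        total_ll = 0.0
        g0 = np.zeros(3)
        xi_sum = np.zeros((3, 3))
        gsum = np.zeros(3)
        gx = np.zeros(3)
        gxx = np.zeros(3)
        gamma_last = np.zeros(3)
        for row in rows:
            B, frac_g = _emission_likelihoods(row, model, parts=True)
            ll, gamma, xi, first = _forward_backward_counts(B, pi, A)
            total_ll += ll
            g0 += first
            xi_sum += xi
            ok = np.isfinite(row)
            # Gaussian-component responsibilities for the emission M-step:
            # points claimed by the shared outlier tail carry ~zero weight
            gg = (gamma * frac_g)[ok]
            gsum += gg.sum(axis=0)
            gx += gg.T @ row[ok]
            gxx += gg.T @ (row[ok] ** 2)
            gamma_last += gamma[-1]
        if not np.isfinite(total_ll):
            raise FloatingPointError("non-finite log-likelihood during EM")
        if total_ll + 1e-8 < prev_ll:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {total_ll}"
            )
        converged = iteration > 0 and abs(total_ll - prev_ll) < tol
        prev_ll = total_ll
        if converged:
            break
        # M-step
        pi = g0 / g0.sum()
        denom = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(denom > 0, xi_sum / np.maximum(denom, 1e-300), A)
        A /= A.sum(axis=1, keepdims=True)
        nz = gsum > 1e-12
        means = np.where(nz, gx / np.maximum(gsum, 1e-12), means)
        var = np.where(nz, gxx / np.maximum(gsum, 1e-12) - means**2, sds**2)
        if (var < SIGMA_FLOOR**2).any():
            warnings.warn("degenerate emission variance floored at 0.01 sd")
        sds = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
        pi, A, means, sds = _relabel_by_mean(pi, A, means, sds)
        if (np.diff(means) <= 0).any():
            # equal means after relabeling: nudge apart to keep ordering strict
            means = means + np.array([-1e-6, 0.0, 1e-6])
    return HmmModel(pi, A, means, sds)


# ---------------------------------------------------------------------------
# Decoding


def _per_chrom(row: np.ndarray, bait_map: BaitMap | None):
    if bait_map is None:
        yield slice(0, len(row))
    else:
        yield from bait_map.chrom_slices().values()


def viterbi(row: np.ndarray, model: HmmModel, bait_map: BaitMap | None = None) -> np.ndarray:
    """Most likely state path; decoded independently per chromosome.

    Missing baits (NaN) contribute no emission term — the transition structure
    is composed across them. An all-missing row yields an empty path.
    """
    row = np.asarray(row, dtype=float)
    if not np.isfinite(row).any():
        return np.zeros(0, dtype=np.int64)
    path = np.empty(row.size, dtype=np.int64)
    logpi = np.log(np.maximum(model.pi, 1e-300))
    logA = np.log(np.maximum(model.A, 1e-300))
    for sl in _per_chrom(row, bait_map):
        B = _emission_likelihoods(row[sl], model)
        path[sl] = _viterbi_path(np.log(np.maximum(B, 1e-300)), logpi, logA)
    return path


def posteriors(row: np.ndarray, model: HmmModel, bait_map: BaitMap | None = None) -> np.ndarray:
    """Forward-backward smoothed state probabilities (rows sum to 1)."""
    row = np.asarray(row, dtype=float)
    out = np.zeros((row.size, 3))
    for sl in _per_chrom(row, bait_map):
        B = _emission_likelihoods(row[sl], model)
        _, gamma, _, _ = _forward_backward_counts(B, model.pi, model.A)
        out[sl] = gamma
    return out


def segment_calls(
    path: np.ndarray,
    post: np.ndarray,
    row: np.ndarray,
    bait_map: BaitMap,
    sample_id: str,
) -> pd.DataFrame:
    """Merge maximal runs of identical non-neutral states into CNV calls.

    Runs never cross chromosome boundaries. Bounds are the outermost bait
    bounds of the run (0-based half-open).
    """
    records = []
    chroms = bait_map.chrom
    starts = bait_map.start
    ends = bait_map.end
    row = np.asarray(row, dtype=float)
    for chrom, sl in bait_map.chrom_slices().items():
        i = sl.start
        while i < sl.stop:
            s = path[i]
            j = i
            while j < sl.stop and path[j] == s:
                j += 1
            if s != NEUTRAL:
                seg = slice(i, j)
                vals = row[seg]
                records.append(
                    {
                        "sample_id": sample_id,
                        "chrom": chrom,
                        "start": int(starts[i]),
                        "end": int(ends[j - 1]),
                        "state": STATE_NAMES[s],
                        "n_baits": j - i,
                        "mean_l2r": float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan"),
                        "mean_posterior": float(post[seg, s].mean()),
                        "first_bait": i,
                        "last_bait": j - 1,
                    }
                )
            i = j
    cols = ["sample_id", "chrom", "start", "end", "state", "n_baits",
            "mean_l2r", "mean_posterior", "first_bait", "last_bait"]
    return pd.DataFrame(records, columns=cols)


def call_sample(
    row: np.ndarray,
    model: HmmModel,
    bait_map: BaitMap,
    sample_id: str,
) -> pd.DataFrame:
    """Viterbi decode + forward-backward confidence + segmentation."""
    if not np.isfinite(np.asarray(row, dtype=float)).any():
        return segment_calls(np.full(len(row), NEUTRAL), np.zeros((len(row), 3)),
                             row, bait_map, sample_id)
    path = viterbi(row, model, bait_map)
    post = posteriors(row, model, bait_map)
    return segment_calls(path, post, row, bait_map, sample_id)
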