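"""Sex classification, dynamic reference selection, and log2-ratio normalization.

Every sample is normalized against its own *dynamic reference*: the N other
samples whose coverage profiles are most similar in overall correlation and in
genomic-wave scale. The reference median is taken over same-sex members
("matched"), opposite-sex members ("mismatched" — guaranteeing a single-copy
chrX shift, which the HMM trainer exploits), or all members ("mixed").
"""
from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from ._robust import mad, probe_noise, running_median
from .baits import BaitMap
from .matrixio import CoverageMatrix, RatioMatrix

__all__ = [
    "SexCall",
    "ReferenceSet",
    "ReferenceSelector",
    "classify_sex",
    "wave_scale",
    "select_reference",
    "select_all_references",
    "compute_log2_ratios",
]

log = logging.getLogger(__name__)

MALE, FEMALE = "male", "female"
AMBIG_LOW, AMBIG_MID, AMBIG_HIGH = "ambiguous_low", "ambiguous_mid", "ambiguous_high"
UNAMBIGUOUS = (MALE, FEMALE)


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    rel_x: float  # chrX / autosome mean-coverage ratio, scaled so females ~ 1.0
    label: str


@dataclass
class ReferenceSet:
    """The dynamic reference of one sample."""

    target: str
    members: list[str]
    member_scores: pd.DataFrame  # per member: depth_correlation, wave_similarity
    dose_response: float  # |median chrX mismatched log2 ratio|, diagnostic


# ---------------------------------------------------------------------------
# Sex classification


def classify_sex(matrix: CoverageMatrix, bait_map: BaitMap | None = None) -> list[SexCall]:
    """Classify sample sex from relative chrX coverage via 2-means clustering.

    rel_x is (mean chrX count) / (mean autosome count), rescaled so that the
    upper cluster (two X copies) centers at 1.0. Samples outside robust bands
    around the two cluster centers are labelled ambiguous and are excluded
    from reference pools downstream.
    """
    bait_map = bait_map or matrix.bait_map
    is_x = bait_map.is_x
    is_auto = bait_map.is_autosome
    if not is_x.any():
        raise ValueError("bait map contains no chrX baits; cannot classify sex")
    if not is_auto.any():
        raise ValueError("bait map contains no autosomal baits")
    vals = matrix.values.astype(float)
    rel = vals[:, is_x].mean(axis=1) / np.maximum(vals[:, is_auto].mean(axis=1), 1e-12)

    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(rel[:, None])
    centers = km.cluster_centers_.ravel()
    hi = int(np.argmax(centers))
    upper = rel[km.labels_ == hi]
    lower = rel[km.labels_ != hi]
    if lower.size == 0 or upper.size == 0 or np.isclose(centers[0], centers[1]):
        warnings.warn("single coverage cluster; assigning sex by absolute 0.75 cutoff")
        scaled = rel / max(np.median(rel), 1e-12)
        return [
            SexCall(s, float(r), FEMALE if r >= 0.75 else MALE)
            for s, r in zip(matrix.sample_ids, scaled)
        ]

    scale = np.median(upper)
    rel = rel / scale
    c_f, c_m = float(np.median(upper) / scale), float(np.median(lower) / scale)
    mad_f, mad_m = mad(upper / scale), mad(lower / scale)
    hi_cut = c_f + max(4.0 * mad_f, 0.25)
    lo_cut = c_m - max(4.0 * mad_m, 0.25)

    calls = []
    for sid, r in zip(matrix.sample_ids, rel):
        if r > hi_cut:
            label = AMBIG_HIGH
        elif r < lo_cut:
            label = AMBIG_LOW
        elif abs(abs(r - c_f) - abs(r - c_m)) < 0.2 * (c_f - c_m):
            label = AMBIG_MID
        else:
            label = FEMALE if abs(r - c_f) < abs(r - c_m) else MALE
        calls.append(SexCall(sid, float(r), label))
    return calls


def sex_calls_frame(calls: list[SexCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": [c.sample_id for c in calls],
         "rel_x": [c.rel_x for c in calls],
         "label": [c.label for c in calls]}
    )


# ---------------------------------------------------------------------------
# Wave scale


def wave_scale(values: np.ndarray, span: int = 401) -> float:
    """Low-frequency wave energy of a profile relative to probe-level noise.

    Standard deviation of the centered running median divided by the robust
    probe noise scale. ~0 for flat/white profiles, >1 when a smooth genomic
    wave dominates probe noise.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return 0.0
    rm = running_median(v, span)
    noise = probe_noise(v)
    num = float(np.std(rm))
    if noise == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return num / noise


# ---------------------------------------------------------------------------
# Reference selection


def _bait_subsample(bait_map: BaitMap, max_baits: int = 20_000) -> np.ndarray:
    """Deterministic autosomal bait subsample, chosen by hashing bait ids.

    The same subsample is used for every sample pair so correlations are
    comparable across pairs.
    """
    auto_idx = np.flatnonzero(bait_map.is_autosome)
    if auto_idx.size <= max_baits:
        return auto_idx
    digests = [
        hashlib.md5(bait_map.bait_id[i].encode()).hexdigest() for i in auto_idx
    ]
    order = np.argsort(digests, kind="stable")
    return np.sort(auto_idx[order[:max_baits]])


class ReferenceSelector:
    """Ranks candidate reference samples for each target.

    Candidates are scored by the sum of two ranks: rank of Spearman depth
    correlation with the target, and rank of (negative) absolute difference
    in genomic-wave scale. Ties are broken by sample id so the selection is
    invariant to input order.
    """

    def __init__(
        self,
        matrix: CoverageMatrix,
        sex_calls: list[SexCall],
        bait_map: BaitMap | None = None,
        qc_pass: dict[str, bool] | None = None,
        max_corr_baits: int = 20_000,
    ):
        self.matrix = matrix
        self.bait_map = bait_map or matrix.bait_map
        self.sample_ids = list(matrix.sample_ids)
        self.sex = {c.sample_id: c.label for c in sex_calls}
        self.qc_pass = qc_pass or {}
        sub = _bait_subsample(self.bait_map, max_corr_baits)
        counts = matrix.values[:, sub].astype(float)
        ranks = np.apply_along_axis(rankdata, 1, counts)
        ranks -= ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(ranks, axis=1)
        self._z = ranks / np.maximum(norms, 1e-12)[:, None]
        log_counts = np.log2(matrix.values.astype(float) + 0.5)
        auto = self.bait_map.is_autosome
        self.wave = np.array([wave_scale(row[auto]) for row in log_counts])
        self._eligible = np.array(
            [
                self.sex.get(s) in UNAMBIGUOUS and self.qc_pass.get(s, True)
                for s in self.sample_ids
            ]
        )

    def correlations(self, target_idx: int) -> np.ndarray:
        """Spearman correlation of the target with every sample."""
        return self._z @ self._z[target_idx]

    def select(self, target: str, n: int) -> ReferenceSet:
        ti = self.sample_ids.index(target)
        cand = np.flatnonzero(self._eligible)
        cand = cand[cand != ti]
        if cand.size < n:
            raise ValueError(
                f"only {cand.size} eligible reference candidates for {target!r}; "
                f"{n} requested"
            )
        corr = self.correlations(ti)[cand]
        wave_diff = np.abs(self.wave[cand] - self.wave[ti])
        score = rankdata(corr) + rankdata(-wave_diff)
        ids = np.array([self.sample_ids[i] for i in cand])
        order = np.lexsort((ids, -score))  # highest score first, ties by id
        chosen = order[:n]
        members = [str(ids[i]) for i in chosen]
        scores = pd.DataFrame(
            {
                "member": members,
                "depth_correlation": corr[chosen],
                "wave_similarity": wave_diff[chosen],
            }
        )
        dr = self._dose_response(ti, [cand[i] for i in chosen])
        return ReferenceSet(target, members, scores, dr)

    def select_all(self, n: int) -> dict[str, ReferenceSet]:
        return {s: self.select(s, n) for s in self.sample_ids}

    def _dose_response(self, target_idx: int, member_idx: list[int]) -> float:
        """|median chrX mismatched log2 ratio| of the target (diagnostic)."""
        t_label = self.sex.get(self.sample_ids[target_idx])
        opp = [
            i for i in member_idx
            if self.sex.get(self.sample_ids[i]) in UNAMBIGUOUS
            and self.sex.get(self.sample_ids[i]) != t_label
        ]
        if not opp:
            return float("nan")
        is_x = self.bait_map.is_x
        if not is_x.any():
            return float("nan")
        vals = self.matrix.values.astype(float)
        med = np.median(vals[opp], axis=0)
        ratio = np.log2((vals[target_idx] + 0.5) / (med + 0.5))
        offset = np.median(ratio[self.bait_map.is_autosome])
        return float(abs(np.median(ratio[is_x] - offset)))


def select_reference(
    target: str,
    matrix: CoverageMatrix,
    sex_calls: list[SexCall],
    n: int,
    bait_map: BaitMap | None = None,
) -> ReferenceSet:
    """Select the dynamic reference of one sample (see ReferenceSelector)."""
    return ReferenceSelector(matrix, sex_calls, bait_map).select(target, n)


def select_all_references(
    matrix: CoverageMatrix,
    sex_calls: list[SexCall],
    n: int,
    bait_map: BaitMap | None = None,
    qc_pass: dict[str, bool] | None = None,
) -> dict[str, ReferenceSet]:
    return ReferenceSelector(matrix, sex_calls, bait_map, qc_pass).select_all(n)


# ---------------------------------------------------------------------------
# Log2 ratios


def compute_log2_ratios(
    matrix: CoverageMatrix,
    reference_sets: dict[str, ReferenceSet],
    sex_calls: list[SexCall],
    flavor: str = "mixed",
    bait_map: BaitMap | None = None,
) -> RatioMatrix:
    """Log2 ratios against the flavor-restricted reference median, centered
    so the autosomal median of every sample row is zero.

    ratio = log2((count + 0.5) / (median reference count + 0.5)); a bait whose
    reference median is zero is set to NaN and excluded from centering.
    """
    bait_map = bait_map or matrix.bait_map
    sex = {c.sample_id: c.label for c in sex_calls}
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    is_auto = bait_map.is_autosome
    vals = matrix.values.astype(float)
    out = np.full_like(vals, np.nan, dtype=np.float64)
    offsets = np.zeros(matrix.n_samples)

    for sid in matrix.sample_ids:
        rs = reference_sets.get(sid)
        if rs is None:
            raise KeyError(f"no reference set for sample {sid!r}")
        t_label = sex.get(sid)
        if flavor == "matched":
            members = [m for m in rs.members if sex.get(m) == t_label]
        elif flavor == "mismatched":
            members = [
                m for m in rs.members
                if sex.get(m) in UNAMBIGUOUS and sex.get(m) != t_label
            ]
            if not members:
                raise ValueError(
                    f"sample {sid!r}: no opposite-sex reference members for "
                    "the mismatched flavor"
                )
        else:
            members = list(rs.members)
        if not members:
            raise ValueError(f"sample {sid!r}: no {flavor} reference members")
        mrows = vals[[idx[m] for m in members]]
        med = np.median(mrows, axis=0)
        i = idx[sid]
        ratio = np.log2((vals[i] + 0.5) / (med + 0.5))
        ratio[med == 0] = np.nan
        center = np.nanmedian(ratio[is_auto])
        out[i] = ratio - center
        offsets[i] = center

    return RatioMatrix(list(matrix.sample_ids), out, bait_map, flavor, offsets)
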