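"""Genomic-wave estimation on final log2 ratios and per-sample call QC.

The wave estimate is the IQR of a 401-point running median of the autosomal
log2-ratio profile, scaled by 1/(1.349 * probe noise). With that scaling a
value of 1 marks the point where the smooth wave is as large as probe-level
noise, i.e. where wave artifacts start to threaten CNV calling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._robust import iqr, probe_noise, running_median

__all__ = ["SampleQc", "genomic_wave_estimate", "sample_metrics", "cohort_qc"]

log = logging.getLogger(__name__)

NORMAL_IQR = 1.349  # IQR of a standard Gaussian


@dataclass
class SampleQc:
    sample_id: str
    wave_estimate: float
    n_calls: int
    n_loss: int
    n_gain: int
    rare_proportion: float
    loss_gain_log10: float
    qc_pass: bool


def genomic_wave_estimate(ratio_row: np.ndarray, span: int = 401) -> float:
    """Wave estimate for one sample's autosomal log2-ratio profile."""
    v = np.asarray(ratio_row, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return 0.0
    rm = running_median(v, span)
    noise = probe_noise(v)
    num = iqr(rm)
    if noise == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return num / (NORMAL_IQR * noise)


def sample_metrics(
    calls: pd.DataFrame,
    call_event_freq: np.ndarray | None,
    wave_estimate: float,
    sample_id: str,
    rare_freq: float = 0.01,
) -> SampleQc:
    """Raw QC metrics for one sample (pass/fail is decided cohort-wide).

    ``call_event_freq`` gives, for each of the sample's calls, the population
    frequency of the merged event it belongs to (loss and gain frequencies
    computed separately).
    """
    n_calls = len(calls)
    n_loss = int((calls["state"] == "loss").sum()) if n_calls else 0
    n_gain = n_calls - n_loss
    if n_calls == 0:
        log.info("sample %s has no CNV calls; QC metrics zeroed", sample_id)
        rare_prop = 0.0
    else:
        rare_prop = float(np.mean(np.asarray(call_event_freq) < rare_freq))
    lg = float(np.log10((n_loss + 1) / (n_gain + 1)))
    return SampleQc(sample_id, float(wave_estimate), n_calls, n_loss, n_gain,
                    rare_prop, lg, qc_pass=True)


def _tukey_fence(values: np.ndarray, k: float = 3.0) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])
    spread = q3 - q1
    return float(q1 - k * spread), float(q3 + k * spread)


def cohort_qc(metrics: list[SampleQc], fence: float = 3.0) -> pd.DataFrame:
    """Apply cohort-level pass rules to per-sample metrics.

    A sample passes when its total call count sits inside Tukey fences of the
    cohort distribution, its rare-call proportion is below the cohort upper
    fence, and its loss/gain log-ratio is within +-1.
    """
    n_calls = np.array([m.n_calls for m in metrics], dtype=float)
    rare = np.array([m.rare_proportion for m in metrics])
    lo_n, hi_n = _tukey_fence(n_calls, fence)
    _, hi_rare = _tukey_fence(rare, fence)
    rows = []
    for m in metrics:
        ok = (
            lo_n <= m.n_calls <= hi_n
            and m.rare_proportion < max(hi_rare, np.finfo(float).tiny)
            and abs(m.loss_gain_log10) < 1.0
        ) or m.n_calls == 0
        rows.append(
            {
                "sample_id": m.sample_id,
                "wave_estimate": m.wave_estimate,
                "n_calls": m.n_calls,
                "n_loss": m.n_loss,
                "n_gain": m.n_gain,
                "rare_proportion": m.rare_proportion,
                "loss_gain_log10": m.loss_gain_log10,
                "qc_pass": bool(ok),
            }
        )
    return pd.DataFrame(rows)
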