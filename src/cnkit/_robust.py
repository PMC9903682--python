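"""Shared robust-statistics helpers: running medians and probe-level noise.

One smoother is used everywhere a "genomic wave" is quantified so that the
reference-selection wave score and the QC wave estimate agree by construction.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

MAD_SCALE = 1.4826  # consistency constant for a Gaussian


def effective_span(n: int, span: int) -> int:
    """Largest odd span <= requested span that fits n points (>=1)."""
    if span > n:
        s = n if n % 2 == 1 else n - 1
        s = max(s, 1)
        warnings.warn(
            f"running-median span {span} exceeds {n} data points; shrunk to {s}",
            stacklevel=3,
        )
        return s
    return span


def running_median(values: np.ndarray, span: int = 401) -> np.ndarray:
    """Centered running median with partial windows at the edges.

    Accepts a 1-D vector or a 2-D (rows x positions) array; NaNs are ignored
    within each window.
    """
    values = np.asarray(values, dtype=float)
    one_d = values.ndim == 1
    mat = values[None, :] if one_d else values
    span = effective_span(mat.shape[1], span)
    df = pd.DataFrame(mat.T)
    out = df.rolling(span, center=True, min_periods=1).median().to_numpy().T
    return out[0] if one_d else out


def probe_noise(values: np.ndarray) -> float:
    """Robust probe-level noise scale: median |first difference| / sqrt(2) * 1.4826.

    Differencing removes slow structure; the sqrt(2) accounts for the variance
    of a difference of two independent probes.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(v))) / np.sqrt(2.0) * MAD_SCALE)


def iqr(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return 0.0
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 - q1)


def mad(values: np.ndarray) -> float:
    """Scaled median absolute deviation (Gaussian-consistent)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return 0.0
    return float(np.median(np.abs(v - np.median(v))) * MAD_SCALE)
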