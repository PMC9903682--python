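"""Sample x bait matrices and the CNB1 binary container.

CNB1 is a tiny random-access format: a fixed header, a sample-id block, then a
row-major payload, so a single sample's row can be read without loading the
whole cohort. Layout (little-endian):

    magic   4 bytes  b"CNB1"
    dtype   u8       0 = int32, 1 = float32, 2 = float64
    u32     n_samples
    u32     n_baits
    ids     n_samples x (u16 length + UTF-8 bytes)
    payload n_samples * n_baits values, row-major
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baits import BaitMap

__all__ = [
    "CoverageMatrix",
    "RatioMatrix",
    "MatrixFormatError",
    "write_matrix",
    "read_matrix",
    "read_sample_row",
]

MAGIC = b"CNB1"
_DTYPE_CODES = {0: np.dtype("<i4"), 1: np.dtype("<f4"), 2: np.dtype("<f8")}
_CODE_FOR = {np.dtype("int32"): 0, np.dtype("float32"): 1, np.dtype("float64"): 2}


class MatrixFormatError(IOError):
    """Bad magic, truncation, or inconsistent CNB1 header."""


@dataclass
class CoverageMatrix:
    """Per-sample, per-bait read counts (non-negative integers)."""

    sample_ids: list[str]
    values: np.ndarray  # (n_samples, n_baits) int32
    bait_map: BaitMap | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise ValueError("values must be 2-D with one row per sample")
        if self.bait_map is not None and self.values.shape[1] != len(self.bait_map):
            raise ValueError("column count does not match bait map")
        if np.issubdtype(self.values.dtype, np.integer) and (self.values < 0).any():
            raise ValueError("negative read counts")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_baits(self) -> int:
        return self.values.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


@dataclass
class RatioMatrix:
    """Centered log2 ratios for one reference flavor.

    ``offsets`` holds the per-sample autosomal-median centering shift (log2
    units) that was subtracted; NaN marks baits with an unusable reference.
    """

    sample_ids: list[str]
    values: np.ndarray  # (n_samples, n_baits) float64
    bait_map: BaitMap | None = None
    flavor: str = "mixed"
    offsets: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise ValueError("values must be 2-D with one row per sample")
        if self.flavor not in ("matched", "mismatched", "mixed"):
            raise ValueError(f"unknown flavor {self.flavor!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_baits(self) -> int:
        return self.values.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


# ---------------------------------------------------------------------------
# CNB1 I/O


def _coerce(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if np.issubdtype(values.dtype, np.integer):
        return values.astype("<i4", copy=False)
    if values.dtype == np.float32:
        return values.astype("<f4", copy=False)
    return values.astype("<f8", copy=False)


def write_matrix(matrix, path) -> None:
    """Write a CoverageMatrix/RatioMatrix (or raw ids+values) to CNB1."""
    sample_ids, values = matrix.sample_ids, matrix.values
    values = _coerce(values)
    code = _CODE_FOR[np.dtype(values.dtype.name)]
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<BII", code, values.shape[0], values.shape[1]))
        for sid in sample_ids:
            raw = sid.encode("utf-8")
            if len(raw) > 0xFFFF:
                raise ValueError(f"sample id too long: {sid[:32]}...")
            fh.write(struct.pack("<H", len(raw)))
            fh.write(raw)
        fh.write(np.ascontiguousarray(values).tobytes())


def _read_header(fh):
    head = fh.read(4)
    if head != MAGIC:
        raise MatrixFormatError(f"bad magic {head!r}; not a CNB1 file")
    code, n_samples, n_baits = struct.unpack("<BII", fh.read(9))
    if code not in _DTYPE_CODES:
        raise MatrixFormatError(f"unknown dtype code {code}")
    sample_ids = []
    for _ in range(n_samples):
        (ln,) = struct.unpack("<H", fh.read(2))
        sample_ids.append(fh.read(ln).decode("utf-8"))
    return _DTYPE_CODES[code], n_samples, n_baits, sample_ids, fh.tell()


def read_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a full CNB1 file; returns (sample_ids, values)."""
    with open(path, "rb") as fh:
        dtype, n_samples, n_baits, sample_ids, _ = _read_header(fh)
        payload = fh.read()
    expected = n_samples * n_baits * dtype.itemsize
    if len(payload) != expected:
        raise MatrixFormatError(
            f"truncated payload: {len(payload)} bytes, expected {expected}"
        )
    values = np.frombuffer(payload, dtype=dtype).reshape(n_samples, n_baits)
    return sample_ids, values.copy()


def read_sample_row(path, sample_id: str) -> np.ndarray:
    """Read one sample's row without loading the whole matrix."""
    with open(path, "rb") as fh:
        dtype, n_samples, n_baits, sample_ids, offset = _read_header(fh)
        try:
            idx = sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None
        fh.seek(offset + idx * n_baits * dtype.itemsize)
        raw = fh.read(n_baits * dtype.itemsize)
    if len(raw) != n_baits * dtype.itemsize:
        raise MatrixFormatError("truncated payload while reading row")
    return np.frombuffer(raw, dtype=dtype).copy()


# ---------------------------------------------------------------------------
# TSV interchange


def matrix_to_tsv(matrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids)
    if matrix.bait_map is not None:
        df.columns = matrix.bait_map.bait_id
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def matrix_from_tsv(path, bait_map: BaitMap | None = None):
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    values = df.to_numpy()
    ids = [str(s) for s in df.index]
    if np.issubdtype(values.dtype, np.integer):
        return CoverageMatrix(ids, values.astype(np.int32), bait_map)
    return RatioMatrix(ids, values, bait_map)
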