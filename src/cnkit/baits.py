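"""Bait (capture target) maps.

The ordered list of baits is the coordinate system for every matrix in the
toolkit: coverage, log2 ratios, HMM paths and per-bait association statistics
are all column-aligned to it. Coordinates are 0-based half-open (BED native).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BaitMap", "BaitMapError", "read_bait_map"]

_X_NAMES = {"chrx", "x"}
_Y_NAMES = {"chry", "y"}


class BaitMapError(ValueError):
    """Malformed or inconsistent bait map."""


def chrom_sort_key(chrom: str):
    """Natural genomic order: chr1..chr22, then X, Y, then others by name."""
    c = chrom.lower()
    if c.startswith("chr"):
        c = c[3:]
    if re.fullmatch(r"\d+", c):
        return (0, int(c), "")
    if c == "x":
        return (1, 0, "")
    if c == "y":
        return (1, 1, "")
    return (2, 0, c)


@dataclass(frozen=True)
class BaitMap:
    """Sorted, validated collection of capture targets with gene labels."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("chrom", "start", "end", "bait_id", "gene_id")

    def __post_init__(self):
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise BaitMapError(f"bait table missing columns: {missing}")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise BaitMapError(f"bait {df.loc[bad, 'bait_id']!r}: start >= end")
        if df["bait_id"].duplicated().any():
            dup = df.loc[df["bait_id"].duplicated(), "bait_id"].iloc[0]
            raise BaitMapError(f"duplicate bait_id {dup!r}")
        order = sorted(
            range(len(df)),
            key=lambda i: (
                chrom_sort_key(df["chrom"].iat[i]),
                df["start"].iat[i],
                df["end"].iat[i],
                df["bait_id"].iat[i],
            ),
        )
        sorted_df = df.iloc[order].reset_index(drop=True)
        object.__setattr__(self, "table", sorted_df)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.table["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.table["end"].to_numpy()

    @property
    def bait_id(self) -> np.ndarray:
        return self.table["bait_id"].to_numpy()

    @property
    def gene_id(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()

    @property
    def is_x(self) -> np.ndarray:
        return np.array([c.lower() in _X_NAMES for c in self.chrom])

    @property
    def is_autosome(self) -> np.ndarray:
        return np.array(
            [c.lower() not in _X_NAMES | _Y_NAMES for c in self.chrom]
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in map order."""
        out: dict[str, slice] = {}
        chroms = self.chrom
        i = 0
        while i < len(chroms):
            j = i
            while j < len(chroms) and chroms[j] == chroms[i]:
                j += 1
            out[chroms[i]] = slice(i, j)
            i = j
        return out

    def index_of(self, bait_ids) -> np.ndarray:
        lookup = {b: i for i, b in enumerate(self.bait_id)}
        return np.array([lookup[b] for b in bait_ids])

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_bed(cls, path) -> "BaitMap":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise BaitMapError(
                        f"{path}:{lineno}: expected >=4 tab-separated columns"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise BaitMapError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                gene = fields[4] if len(fields) > 4 else ""
                rows.append((fields[0], start, end, fields[3], gene))
        if not rows:
            raise BaitMapError(f"{path}: empty bait map")
        df = pd.DataFrame(rows, columns=list(cls.REQUIRED))
        return cls(df)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e, b, g in self.table.itertuples(index=False):
                fh.write(f"{c}\t{s}\t{e}\t{b}\t{g}\n")


def read_bait_map(path) -> BaitMap:
    """Read a 4+ column BED file (5th column = gene label) into a BaitMap."""
    return BaitMap.from_bed(path)
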