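"""Per-bait read counting from coordinate-sorted SAM/BAM alignments.

A read contributes one count to the bait containing its leftmost aligned base
(so a read spanning two baits is counted once), provided it passes all of:
MAPQ > 1, proper pair, primary (not secondary), not a PCR duplicate, not
supplementary.
"""
from __future__ import annotations

import logging

import numpy as np
import pysam
from intervaltree import IntervalTree

from .baits import BaitMap
from .matrixio import CoverageMatrix

__all__ = ["extract_coverage", "extract_coverage_matrix", "UnsortedInputError"]

log = logging.getLogger(__name__)


class UnsortedInputError(ValueError):
    """Alignments are not coordinate sorted."""


def _bait_trees(bait_map: BaitMap) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, (c, s, e) in enumerate(zip(bait_map.chrom, bait_map.start, bait_map.end)):
        trees.setdefault(c, IntervalTree()).addi(s, e, i)
    return trees


def _passes_filters(read) -> bool:
    return (
        not read.is_unmapped
        and read.mapping_quality > 1
        and read.is_proper_pair
        and not read.is_secondary
        and not read.is_duplicate
        and not read.is_supplementary
    )


def extract_coverage(alignments, bait_map: BaitMap) -> np.ndarray:
    """Count filter-passing reads per bait for one sample.

    Parameters
    ----------
    alignments
        Path to a SAM/BAM file or an open ``pysam.AlignmentFile``. Must be
        coordinate sorted.

    Returns
    -------
    Integer array of length ``len(bait_map)``.
    """
    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    trees = _bait_trees(bait_map)
    counts = np.zeros(len(bait_map), dtype=np.int64)
    n_foreign = 0
    last = (-1, -1)  # (tid, pos) for sort checking
    seen_tids: set[int] = set()
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            tid, pos = read.reference_id, read.reference_start
            if tid != last[0]:
                if tid in seen_tids:
                    raise UnsortedInputError(
                        f"reference {read.reference_name} appears twice"
                    )
                seen_tids.add(tid)
            elif pos < last[1]:
                raise UnsortedInputError(
                    f"position {pos} < {last[1]} on {read.reference_name}"
                )
            last = (tid, pos)
            if not _passes_filters(read):
                continue
            tree = trees.get(read.reference_name)
            if tree is None:
                n_foreign += 1
                continue
            hits = tree[pos]
            if hits:
                # leftmost bait wins when baits overlap
                counts[min(hits, key=lambda iv: (iv.begin, iv.data)).data] += 1
    finally:
        if own:
            af.close()
    if n_foreign:
        log.info("ignored %d reads on references absent from the bait map", n_foreign)
    return counts


def extract_coverage_matrix(paths: dict[str, str], bait_map: BaitMap) -> CoverageMatrix:
    """Extract coverage for several samples ({sample_id: alignment path})."""
    ids = list(paths)
    values = np.zeros((len(ids), len(bait_map)), dtype=np.int32)
    for i, sid in enumerate(ids):
        values[i] = extract_coverage(paths[sid], bait_map)
    return CoverageMatrix(ids, values, bait_map)
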