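import numpy as np
import pandas as pd
import pytest

from cnkit.baits import BaitMap
from cnkit.simulate import default_config, simulate_cohort
from cnkit.workflows import call_all, normalize


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample default synthetic cohort (2,000 baits, CNVs, SNPs, traits)."""
    return simulate_cohort(default_config(seed=11, n_samples=60))


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    return normalize(small_cohort.coverage, small_cohort.bait_map, reference_n=20)


@pytest.fixture(scope="session")
def small_calls(small_norm):
    calls, models = call_all(small_norm, max_train_rows=10, max_iter=20, tol=1e-3)
    return calls


def make_bait_map(intervals):
    """BaitMap from (chrom, start, end, bait_id[, gene_id]) tuples."""
    rows = [tuple(iv) + ("",) * (5 - len(iv)) for iv in intervals]
    return BaitMap(pd.DataFrame(rows, columns=list(BaitMap.REQUIRED)))


@pytest.fixture
def three_exon_map():
    return make_bait_map(
        [
            ("chr1", 100, 200, "b1", "GENE1"),
            ("chr1", 300, 400, "b2", "GENE1"),
            ("chr1", 500, 600, "b3", "GENE1"),
        ]
    )


def write_sam(path, reads, chroms=(("chr1", 100000),)):
    """Write a minimal coordinate-sorted SAM file.

    ``reads`` are dicts with keys name, chrom, pos (0-based), flag, mapq.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in chroms:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in reads:
            fh.write(
                "\t".join(
                    [
                        r["name"],
                        str(r["flag"]),
                        r["chrom"],
                        str(r["pos"] + 1),  # SAM is 1-based
                        str(r["mapq"]),
                        "50M",
                        "=",
                        str(r["pos"] + 101),
                        "150",
                        "A" * 50,
                        "I" * 50,
                    ]
                )
                + "\n"
            )
    return path


# canonical filter-passing flag: paired, proper pair, mate reverse
PASS_FLAG = 0x1 | 0x2 | 0x20


def flag(proper_pair=True, duplicate=False, secondary=False, supplementary=False,
         unmapped=False):
    f = 0x1 | 0x20
    if proper_pair:
        f |= 0x2
    if duplicate:
        f |= 0x400
    if secondary:
        f |= 0x100
    if supplementary:
        f |= 0x800
    if unmapped:
        f |= 0x4
    return f
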