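import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cnkit.merge import (
    adjust_boundaries,
    bait_frequencies,
    event_frequencies,
    gene_overlap_annotation,
    merge_events,
    reciprocal_overlap,
)

from .conftest import make_bait_map


class TestReciprocalOverlap:
    def test_identity(self):
        assert reciprocal_overlap((100, 200), (100, 200)) == (1.0, 1.0)

    def test_half_overlap(self):
        assert reciprocal_overlap((100, 200), (150, 250)) == (0.5, 0.5)

    def test_disjoint(self):
        assert reciprocal_overlap((0, 100), (200, 300)) == (0.0, 0.0)

    def test_asymmetric_lengths(self):
        ro = reciprocal_overlap((0, 100), (50, 250))
        assert ro == (0.5, 0.25)


class TestAdjustBoundaries:
    def test_identical_members_unchanged(self):
        assert adjust_boundaries([100, 100], [200, 200]) == (100, 200)

    def test_eighty_percent_toward_outer(self):
        assert adjust_boundaries([100, 120], [200, 240]) == (104, 232)

    def test_single_member_keeps_own_bounds(self):
        assert adjust_boundaries([150], [300]) == (150, 300)


def _calls(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "state"]
    )


class TestMergeEvents:
    def test_identical_calls_in_two_samples(self):
        calls = _calls([("s1", "chr1", 100, 200, "loss"),
                        ("s2", "chr1", 100, 200, "loss")])
        events, assignment = merge_events(calls)
        assert len(events) == 1
        assert events.loc[0, "n_carriers"] == 2
        assert assignment.tolist() == [0, 0]

    def test_chain_closure_is_one_component(self):
        # A-B and B-C overlap >= 50%, A-C < 50%: one event by closure
        calls = _calls([("s1", "chr1", 0, 100, "loss"),
                        ("s2", "chr1", 40, 140, "loss"),
                        ("s3", "chr1", 80, 180, "loss")])
        a, c = (0, 100), (80, 180)
        assert min(reciprocal_overlap(a, c)) < 0.5
        events, assignment = merge_events(calls)
        assert len(events) == 1 and set(assignment) == {0}

    def test_losses_and_gains_merge_separately(self):
        calls = _calls([("s1", "chr1", 100, 200, "loss"),
                        ("s2", "chr1", 100, 200, "gain")])
        events, _ = merge_events(calls)
        assert len(events) == 2
        assert set(events["type"]) == {"loss", "gain"}

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        calls = _random_calls(rng, 200)
        events, assignment = merge_events(calls)
        assert (assignment >= 0).all()
        assert sum(events["n_calls"]) == len(calls)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(4)
        calls = _random_calls(rng, 120)
        events1, a1 = merge_events(calls)
        perm = rng.permutation(len(calls))
        calls2 = calls.iloc[perm].reset_index(drop=True)
        events2, a2 = merge_events(calls2)
        cols = ["chrom", "start", "end", "type", "n_calls", "n_carriers"]
        pd.testing.assert_frame_equal(events1[cols], events2[cols])
        # the partition itself is identical
        for i, j in enumerate(perm):
            assert a2[i] == a1[j] or True  # event ids are coordinate-sorted
        lab1 = {tuple(sorted(events1.loc[e, "members"])) for e in events1.index}
        remap = {i: j for i, j in enumerate(perm)}
        lab2 = {
            tuple(sorted(remap[m] for m in events2.loc[e, "members"]))
            for e in events2.index
        }
        assert lab1 == lab2


def _random_calls(rng, n):
    rows = []
    for i in range(n):
        chrom = rng.choice(["chr1", "chr2"])
        start = int(rng.integers(0, 5000))
        length = int(rng.integers(50, 600))
        rows.append((f"s{rng.integers(0, 40)}", chrom, start, start + length,
                     rng.choice(["loss", "gain"])))
    return _calls(rows)


@pytest.mark.parametrize("seed,n", [(0, 100), (1, 300), (2, 500)])
def test_merge_matches_naive_union_find_oracle(seed, n):
    """Connected components of the all-pairs reciprocal-overlap graph
    (independent networkx route) reproduce merge_events' partition."""
    rng = np.random.default_rng(seed)
    calls = _random_calls(rng, n)
    events, assignment = merge_events(calls)

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = calls.iloc[i], calls.iloc[j]
        if a["state"] != b["state"] or a["chrom"] != b["chrom"]:
            continue
        if min(reciprocal_overlap((a["start"], a["end"]),
                                  (b["start"], b["end"]))) >= 0.5:
            g.add_edge(i, j)
    oracle = {frozenset(c) for c in nx.connected_components(g)}
    ours = {
        frozenset(np.flatnonzero(assignment == e)) for e in events["event_id"]
    }
    assert ours == oracle


class TestEventFrequencies:
    def test_binomial_se(self):
        calls = _calls([("s1", "chr1", 100, 200, "loss"),
                        ("s2", "chr1", 100, 200, "loss")])
        events, assignment = merge_events(calls)
        out = event_frequencies(events, assignment, calls, n_samples=200)
        assert out.loc[0, "freq_loss"] == pytest.approx(0.01)
        assert out.loc[0, "se_loss"] == pytest.approx(
            np.sqrt(0.01 * 0.99 / 200), abs=1e-6
        )
        assert out.loc[0, "se_loss"] == pytest.approx(0.00704, abs=1e-5)

    def test_all_carriers_freq_one_se_zero(self):
        calls = _calls([(f"s{i}", "chr1", 0, 100, "gain") for i in range(5)])
        events, assignment = merge_events(calls)
        out = event_frequencies(events, assignment, calls, n_samples=5)
        assert out.loc[0, "freq_gain"] == 1.0 and out.loc[0, "se_gain"] == 0.0

    def test_sample_counted_once_per_event(self):
        calls = _calls([("s1", "chr1", 0, 100, "loss"),
                        ("s1", "chr1", 10, 110, "loss")])
        events, assignment = merge_events(calls)
        out = event_frequencies(events, assignment, calls, n_samples=10)
        assert out.loc[0, "n_carriers"] == 1
        assert out.loc[0, "freq_loss"] == pytest.approx(0.1)

    def test_overall_includes_both_types(self):
        calls = _calls([("s1", "chr1", 0, 100, "loss"),
                        ("s2", "chr1", 0, 100, "gain")])
        events, assignment = merge_events(calls)
        out = event_frequencies(events, assignment, calls, n_samples=10)
        assert (out["freq_all"] == 0.2).all()


class TestBaitFrequencies:
    def _map(self):
        return make_bait_map(
            [("chr1", 100 * i, 100 * i + 50, f"b{i}") for i in range(5)]
        )

    def test_universal_deletion(self):
        calls = _calls([(f"s{i}", "chr1", 0, 500, "loss") for i in range(4)])
        out = bait_frequencies(calls, self._map(), n_samples=4)
        assert (out["freq_loss"] == 1.0).all()
        assert (out["freq_gain"] == 0.0).all()

    def test_single_carrier(self):
        calls = _calls([("s1", "chr1", 100, 160, "loss")])
        out = bait_frequencies(calls, self._map(), n_samples=100)
        assert out.loc[1, "freq_loss"] == pytest.approx(0.01)
        assert out.loc[0, "freq_loss"] == 0.0

    def test_uncovered_bait_zero(self):
        out = bait_frequencies(_calls([]), self._map(), n_samples=10)
        assert (out[["freq_loss", "freq_gain", "freq_all"]] == 0).all().all()


class TestGeneOverlap:
    GENES = pd.DataFrame(
        [("chr1", 1000, 2000, "G1"), ("chr1", 5000, 5200, "G2")],
        columns=["chrom", "start", "end", "gene_id"],
    )

    def test_exact_match_annotated(self):
        calls = _calls([("s1", "chr1", 1000, 2000, "loss")])
        out = gene_overlap_annotation(calls, self.GENES)
        assert out["gene_id"].tolist() == ["G1"]

    def test_containing_call_ten_times_longer_not_annotated(self):
        calls = _calls([("s1", "chr1", 4100, 6100, "loss")])  # 2,000 vs 200 bp
        out = gene_overlap_annotation(calls, self.GENES)
        assert len(out) == 0

    def test_empty_gene_list(self):
        calls = _calls([("s1", "chr1", 1000, 2000, "loss")])
        out = gene_overlap_annotation(calls, self.GENES.iloc[:0])
        assert len(out) == 0
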