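import numpy as np
import pytest

from cnkit.matrixio import CoverageMatrix
from cnkit.sexref import (
    ReferenceSelector,
    classify_sex,
    compute_log2_ratios,
    select_reference,
    wave_scale,
)

from .conftest import make_bait_map


def _xy_map(n_auto=40, n_x=10):
    baits = [("chr1", 100 * i, 100 * i + 50, f"a{i}") for i in range(n_auto)]
    baits += [("chrX", 100 * i, 100 * i + 50, f"x{i}") for i in range(n_x)]
    return make_bait_map(baits)


def _cohort_with_relx(rel_x_values, depth=200, seed=0):
    """Coverage rows whose chrX/autosome mean ratio equals the given rel_x."""
    bm = _xy_map()
    rng = np.random.default_rng(seed)
    rows = []
    for r in rel_x_values:
        auto = np.full(40, depth) + rng.integers(-2, 3, 40)
        x = np.round(r * auto.mean()) * np.ones(10)
        rows.append(np.concatenate([auto, x]))
    ids = [f"s{i}" for i in range(len(rel_x_values))]
    return CoverageMatrix(ids, np.array(rows, dtype=np.int32), bm)


class TestClassifySex:
    def test_two_clean_clusters(self):
        rng = np.random.default_rng(1)
        rel = np.concatenate([rng.normal(1.0, 0.02, 10), rng.normal(0.5, 0.02, 10)])
        calls = classify_sex(_cohort_with_relx(rel))
        labels = [c.label for c in calls]
        assert labels[:10] == ["female"] * 10
        assert labels[10:] == ["male"] * 10

    def test_high_outlier_is_ambiguous_high(self):
        rng = np.random.default_rng(1)
        rel = np.concatenate(
            [rng.normal(1.0, 0.02, 10), rng.normal(0.5, 0.02, 10), [1.5]]
        )
        calls = classify_sex(_cohort_with_relx(rel))
        assert calls[-1].label == "ambiguous_high"

    def test_midway_sample_is_ambiguous_mid(self):
        rng = np.random.default_rng(1)
        rel = np.concatenate(
            [rng.normal(1.0, 0.02, 10), rng.normal(0.5, 0.02, 10), [0.75]]
        )
        calls = classify_sex(_cohort_with_relx(rel))
        assert calls[-1].label == "ambiguous_mid"

    def test_low_outlier_is_ambiguous_low(self):
        rng = np.random.default_rng(1)
        rel = np.concatenate(
            [rng.normal(1.0, 0.02, 10), rng.normal(0.5, 0.02, 10), [0.1]]
        )
        calls = classify_sex(_cohort_with_relx(rel))
        assert calls[-1].label == "ambiguous_low"

    def test_no_x_baits_is_error(self):
        bm = make_bait_map([("chr1", 0, 50, "a")])
        cov = CoverageMatrix(["s"], np.array([[10]], dtype=np.int32), bm)
        with pytest.raises(ValueError, match="chrX"):
            classify_sex(cov)

    def test_recovers_simulated_sex_exactly(self, small_cohort, small_norm):
        labels = np.array([c.label for c in small_norm.sex_calls])
        assert (labels == small_cohort.truth.sex).all()


class TestWaveScale:
    def test_constant_row_scores_zero(self):
        assert wave_scale(np.full(2000, 3.0)) == 0.0

    def test_white_noise_scores_low(self):
        rng = np.random.default_rng(5)
        assert wave_scale(rng.normal(0, 1, 5000)) < 0.2

    def test_slow_wave_scores_high(self):
        rng = np.random.default_rng(5)
        n = 5000
        row = rng.normal(0, 1, n) + 3.0 * np.sin(2 * np.pi * np.arange(n) / 2000)
        assert wave_scale(row) > 1.0

    def test_short_row_shrinks_span_with_warning(self):
        with pytest.warns(UserWarning, match="shrunk"):
            wave_scale(np.random.default_rng(0).normal(0, 1, 100))


class TestSelectReference:
    def _cohort(self, seed=0, n=8, n_baits=300):
        """Candidates with graded correlation to the target (sample 0)."""
        rng = np.random.default_rng(seed)
        bm = make_bait_map(
            [("chr1", 100 * i, 100 * i + 50, f"a{i}") for i in range(n_baits)]
            + [("chrX", 100 * i, 100 * i + 50, f"x{i}") for i in range(20)]
        )
        target = rng.normal(200, 20, n_baits + 20)
        mix = [1.0, 0.95, 0.8, 0.6, 0.3, 0.1, 0.05, 0.0][:n]
        rows = [target]
        for a in mix[1:]:
            noise = rng.normal(200, 20, n_baits + 20)
            rows.append(a * target + (1 - a) * noise)
        sexes = ["female", "male"] * ((n + 1) // 2)
        calls = []
        from cnkit.sexref import SexCall

        for i, s in enumerate(sexes[:n]):
            calls.append(SexCall(f"s{i}", 1.0 if s == "female" else 0.5, s))
        cov = CoverageMatrix(
            [f"s{i}" for i in range(n)],
            np.maximum(np.array(rows), 1).astype(np.int32),
            bm,
        )
        return cov, calls

    def test_top_candidates_by_correlation(self):
        cov, calls = self._cohort()
        rs = select_reference("s0", cov, calls, 2)
        assert rs.members == ["s1", "s2"]

    def test_target_never_in_its_own_reference(self):
        cov, calls = self._cohort()
        for sid in cov.sample_ids:
            rs = select_reference(sid, cov, calls, 3)
            assert sid not in rs.members

    def test_exact_size_and_shortfall_error(self):
        cov, calls = self._cohort()
        assert len(select_reference("s0", cov, calls, 5).members) == 5
        with pytest.raises(ValueError, match="eligible"):
            select_reference("s0", cov, calls, 99)

    def test_permutation_invariance(self):
        cov, calls = self._cohort()
        rs1 = select_reference("s0", cov, calls, 4)
        perm = [0, 5, 3, 1, 7, 2, 6, 4]
        cov2 = CoverageMatrix(
            [cov.sample_ids[i] for i in perm], cov.values[perm], cov.bait_map
        )
        calls2 = [calls[i] for i in perm]
        rs2 = select_reference("s0", cov2, calls2, 4)
        assert sorted(rs1.members) == sorted(rs2.members)

    def test_ambiguous_samples_excluded(self):
        cov, calls = self._cohort()
        from cnkit.sexref import SexCall

        calls[1] = SexCall("s1", 0.75, "ambiguous_mid")
        rs = select_reference("s0", cov, calls, 3)
        assert "s1" not in rs.members


class TestLog2Ratios:
    def test_count_double_reference_gives_one(self, small_cohort):
        """A sample identical to its reference except one doubled bait has
        ratio ~1 there and ~0 elsewhere after centering."""
        bm = _xy_map()
        base = np.full(50, 50, dtype=np.int32)
        rows = [base.copy() for _ in range(6)]
        rows[0] = base.copy()
        rows[0][3] = 100
        cov = CoverageMatrix([f"s{i}" for i in range(6)], np.array(rows), bm)
        from cnkit.sexref import ReferenceSet, SexCall

        calls = [SexCall(f"s{i}", 1.0, "female") for i in range(6)]
        refsets = {
            s: ReferenceSet(s, [m for m in cov.sample_ids if m != s], None, 0.0)
            for s in cov.sample_ids
        }
        rm = compute_log2_ratios(cov, refsets, calls, "matched")
        row = rm.row("s0")
        assert row[3] == pytest.approx(np.log2(100.5 / 50.5), abs=1e-6)
        assert np.abs(np.delete(row, 3)).max() < 1e-9

    def test_identity_sample_all_zero(self):
        bm = _xy_map()
        cov = CoverageMatrix(
            [f"s{i}" for i in range(4)],
            np.full((4, 50), 80, dtype=np.int32),
            bm,
        )
        from cnkit.sexref import ReferenceSet, SexCall

        calls = [SexCall(f"s{i}", 1.0, "female") for i in range(4)]
        refsets = {
            s: ReferenceSet(s, [m for m in cov.sample_ids if m != s], None, 0.0)
            for s in cov.sample_ids
        }
        rm = compute_log2_ratios(cov, refsets, calls, "matched")
        assert np.abs(rm.values).max() < 1e-12

    def test_autosomal_median_centering_invariant(self, small_cohort, small_norm):
        auto = small_cohort.bait_map.is_autosome
        med = np.nanmedian(small_norm.ratios["matched"].values[:, auto], axis=1)
        assert np.abs(med).max() < 1e-9

    def test_mismatched_chrx_dose_response(self, small_cohort, small_norm):
        """Opposite-sex reference gives a +-1 chrX shift for >=95% of samples."""
        xm = small_cohort.bait_map.is_x
        med = np.nanmedian(small_norm.ratios["mismatched"].values[:, xm], axis=1)
        within = np.abs(np.abs(med) - 1.0) <= 0.1
        assert within.mean() >= 0.95

    def test_mismatched_requires_opposite_sex_members(self):
        bm = _xy_map()
        cov = CoverageMatrix(
            ["a", "b", "c"], np.full((3, 50), 80, dtype=np.int32), bm
        )
        from cnkit.sexref import ReferenceSet, SexCall

        calls = [SexCall(s, 1.0, "female") for s in cov.sample_ids]
        refsets = {
            s: ReferenceSet(s, [m for m in cov.sample_ids if m != s], None, 0.0)
            for s in cov.sample_ids
        }
        with pytest.raises(ValueError, match="opposite-sex"):
            compute_log2_ratios(cov, refsets, calls, "mismatched")
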