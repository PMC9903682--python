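import json
from itertools import product

import numpy as np
import pytest

from cnkit.baits import BaitMap
from cnkit.hmm import (
    GAIN,
    LOSS,
    NEUTRAL,
    HmmModel,
    _emission_likelihoods,
    call_sample,
    posteriors,
    segment_calls,
    train_hmm,
    viterbi,
)

from .conftest import make_bait_map


def random_model(rng):
    pi = rng.dirichlet(np.ones(3))
    A = rng.dirichlet(np.ones(3), size=3)
    means = np.sort(rng.normal([-1, 0, 0.6], 0.2))
    while (np.diff(means) <= 0).any():
        means = np.sort(rng.normal([-1, 0, 0.6], 0.2))
    sds = rng.uniform(0.05, 0.4, 3)
    return HmmModel(pi, A, means, sds)


def brute_force(row, model):
    """Exhaustive path enumeration: MAP path (ties toward lower state tuple)
    and exact posteriors."""
    T = len(row)
    B = _emission_likelihoods(row, model)
    paths = np.array(list(product(range(3), repeat=T)))
    logp = np.log(model.pi[paths[:, 0]]) + np.log(B[0, paths[:, 0]])
    for t in range(1, T):
        logp += np.log(model.A[paths[:, t - 1], paths[:, t]])
        logp += np.log(B[t, paths[:, t]])
    best = paths[np.argmax(logp)]  # product() is lexicographic: lowest tuple wins ties
    w = np.exp(logp - logp.max())
    post = np.zeros((T, 3))
    for t in range(T):
        for s in range(3):
            post[t, s] = w[paths[:, t] == s].sum()
    post /= post.sum(axis=1, keepdims=True)
    return best, post


@pytest.mark.parametrize("block", range(8))
def test_viterbi_and_posteriors_match_enumeration(block):
    """Exact decoding: 200 seeded random models, all T <= 8, against the
    brute-force oracle."""
    rng = np.random.default_rng(1000 + block)
    for _ in range(25):
        model = random_model(rng)
        T = int(rng.integers(1, 9))
        row = rng.normal(0, 1, T)
        path = viterbi(row, model)
        post = posteriors(row, model)
        bpath, bpost = brute_force(row, model)
        np.testing.assert_array_equal(path, bpath)
        np.testing.assert_allclose(post, bpost, atol=1e-9)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


def test_posterior_t1_closed_form():
    model = HmmModel.canonical(0.2)
    x = np.array([-0.7])
    B = _emission_likelihoods(x, model)
    expected = model.pi * B[0]
    expected /= expected.sum()
    np.testing.assert_allclose(posteriors(x, model)[0], expected, atol=1e-12)


def test_symmetric_model_gives_symmetric_posteriors():
    A = np.full((3, 3), 0.05)
    np.fill_diagonal(A, 0.9)
    model = HmmModel(np.array([0.25, 0.5, 0.25]), A,
                     np.array([-1.0, 0.0, 1.0]), np.array([0.3, 0.3, 0.3]))
    post = posteriors(np.zeros(5), model)
    np.testing.assert_allclose(post[:, LOSS], post[:, GAIN], atol=1e-12)


def test_identical_emissions_decided_by_transitions():
    A = np.array([[0.90, 0.05, 0.05], [0.02, 0.97, 0.01], [0.05, 0.05, 0.90]])
    model = HmmModel(np.full(3, 1 / 3), A, np.array([-1.0, 0.0, 1.0]),
                     np.array([0.2] * 3))
    # missing observations emit 1 in every state: transitions decide
    row = np.full(6, np.nan)
    row[0] = 0.0  # keep the row decodable
    path = viterbi(row, model)
    assert (path[1:] == NEUTRAL).all()


def test_hand_viterbi_six_steps():
    model = HmmModel.canonical(0.2)
    row = np.array([-1.0, -1.0, -1.0, 0.0, 0.0, 0.0])
    assert viterbi(row, model).tolist() == [LOSS] * 3 + [NEUTRAL] * 3


def test_all_missing_row_gives_empty_path():
    assert viterbi(np.full(4, np.nan), HmmModel.canonical()).size == 0


class TestTraining:
    @staticmethod
    def _sample_rows(model, n_rows, T, rng):
        rows = np.zeros((n_rows, T))
        for r in range(n_rows):
            s = rng.choice(3, p=model.pi)
            for t in range(T):
                rows[r, t] = rng.normal(model.means[s], model.sds[s])
                s = rng.choice(3, p=model.A[s])
        return rows

    def test_parameter_recovery(self):
        """EM on 50 x 2,000 sequences from a known model recovers means
        within +-0.05 and self-transitions within +-0.01."""
        rng = np.random.default_rng(99)
        A = np.full((3, 3), 0.005)
        np.fill_diagonal(A, 0.99)
        true = HmmModel(np.array([0.05, 0.9, 0.05]), A,
                        np.array([-1.0, 0.0, 0.58]), np.array([0.15] * 3))
        rows = self._sample_rows(true, 50, 2000, rng)
        m = train_hmm(rows, max_iter=200, tol=1e-6)
        np.testing.assert_allclose(m.means, true.means, atol=0.05)
        np.testing.assert_allclose(np.diag(m.A), np.diag(true.A), atol=0.01)

    def test_fixed_point_neighborhood(self):
        """Initializing at the generating model moves parameters < 0.02."""
        rng = np.random.default_rng(17)
        A = np.full((3, 3), 0.005)
        np.fill_diagonal(A, 0.99)
        true = HmmModel(np.array([0.05, 0.9, 0.05]), A,
                        np.array([-1.0, 0.0, 0.58]), np.array([0.15] * 3))
        rows = self._sample_rows(true, 30, 1500, rng)
        m = train_hmm(rows, init=true, max_iter=50, tol=1e-8)
        assert np.abs(m.means - true.means).max() < 0.02
        assert np.abs(np.diag(m.A) - np.diag(true.A)).max() < 0.02

    def test_constant_zero_sequence_absorbed_by_neutral(self):
        m = train_hmm(np.zeros((1, 500)), max_iter=50, tol=1e-8)
        post = posteriors(np.zeros(500), m)
        assert post[:, LOSS].max() < 1e-3 and post[:, GAIN].max() < 1e-3

    def test_sigma_floored_with_warning(self):
        rows = np.concatenate([np.zeros(300), np.full(50, -1.0), np.full(50, 0.585)])
        with pytest.warns(UserWarning, match="floored"):
            train_hmm(rows[None, :], max_iter=60, tol=1e-10)


class TestSegmentation:
    def test_run_length_semantics(self, three_exon_map):
        bm = make_bait_map(
            [("chr1", 100 * i, 100 * i + 50, f"b{i}") for i in range(6)]
        )
        path = np.array([LOSS, LOSS, NEUTRAL, NEUTRAL, NEUTRAL, GAIN])
        post = np.full((6, 3), 1 / 3)
        row = np.array([-1, -1, 0, 0, 0, 0.6])
        calls = segment_calls(path, post, row, bm, "s")
        assert len(calls) == 2
        loss, gain = calls.iloc[0], calls.iloc[1]
        assert loss["state"] == "loss" and loss["n_baits"] == 2
        assert loss["start"] == 0 and loss["end"] == 150
        assert gain["state"] == "gain" and gain["n_baits"] == 1

    def test_all_neutral_is_empty(self, three_exon_map):
        calls = segment_calls(
            np.full(3, NEUTRAL), np.full((3, 3), 1 / 3), np.zeros(3),
            three_exon_map, "s"
        )
        assert len(calls) == 0

    def test_runs_split_at_chromosome_boundary(self):
        bm = make_bait_map(
            [("chr1", 0, 50, "a"), ("chr1", 100, 150, "b"),
             ("chr2", 0, 50, "c"), ("chr2", 100, 150, "d")]
        )
        path = np.array([LOSS, LOSS, LOSS, LOSS])
        calls = segment_calls(path, np.full((4, 3), 1 / 3),
                              np.full(4, -1.0), bm, "s")
        assert len(calls) == 2
        assert calls["chrom"].tolist() == ["chr1", "chr2"]

    def test_decoding_is_per_chromosome(self):
        """A run crossing the boundary restarts from pi on the next chromosome."""
        bm = make_bait_map(
            [("chr1", 0, 50, "a"), ("chr1", 100, 150, "b"),
             ("chr2", 0, 50, "c")]
        )
        model = HmmModel.canonical(0.2)
        row = np.array([-1.0, -1.0, -1.0])
        calls = call_sample(row, model, bm, "s")
        assert len(calls) == 2


def test_model_json_round_trip(tmp_path):
    m = HmmModel.canonical(0.17)
    path = tmp_path / "m.json"
    m.to_json(path)
    again = HmmModel.from_json(str(path))
    np.testing.assert_allclose(again.A, m.A)
    np.testing.assert_allclose(again.means, m.means)


def test_invalid_models_rejected():
    with pytest.raises(ValueError, match="increasing"):
        HmmModel(means=np.array([0.0, -1.0, 0.5]))
    with pytest.raises(ValueError, match="sum to 1"):
        HmmModel(pi=np.array([0.5, 0.2, 0.2]))
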