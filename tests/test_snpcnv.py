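import numpy as np
import pandas as pd
import pytest

from cnkit.snpcnv import (
    classify_region,
    competitive_models,
    fit_cn_states,
    nearest_gene,
    snp_cnv_r2,
)


class TestR2:
    def test_affine_relation_is_one(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, 100)
        assert snp_cnv_r2(d, 3 * d - 2) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        assert snp_cnv_r2(rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000)) < 0.002

    def test_constant_snp_returns_zero(self):
        assert snp_cnv_r2(np.arange(10.0), np.ones(10)) == 0.0

    def test_missing_values_ignored(self):
        d = np.array([1.0, 2, 3, np.nan, 5])
        s = np.array([2.0, 4, 6, 100, 10])
        assert snp_cnv_r2(d, s) == pytest.approx(1.0)


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp_id", "assoc_p", "nearest_gene_id"])


class TestClassifyRegion:
    """Exhaustive truth table over (SNP significance, nearest gene, r2)."""

    N = 400

    def _dosages(self, kinds, seed=0):
        """Columns: 'tag' = r2~1 to lead, 'indep' = independent."""
        rng = np.random.default_rng(seed)
        lead = rng.normal(0, 1, self.N)
        cols = []
        for kind in kinds:
            if kind == "tag":
                cols.append(lead + rng.normal(0, 0.05, self.N))  # r2 ~ 0.998
            else:
                cols.append(rng.normal(0, 1, self.N))
        return lead, np.column_stack(cols) if cols else np.zeros((self.N, 0))

    def _run(self, rows, kinds, genes={"G"}):
        lead, D = self._dosages(kinds)
        return classify_region("r1", genes, _snps(rows), lead, D)

    def test_empty_window_is_cnv_only(self):
        lead, D = self._dosages([])
        cls = classify_region("r1", {"G"}, _snps([]), lead, D)
        assert cls.label == "CNV_only" and cls.supporting_snps == []

    def test_no_significant_snps_is_cnv_only(self):
        cls = self._run([("s1", 0.5, "G"), ("s2", 0.2, "X")], ["tag", "tag"])
        assert cls.label == "CNV_only"

    def test_significant_far_untagged_is_cnv_only(self):
        cls = self._run([("s1", 1e-10, "X")], ["indep"])
        assert cls.label == "CNV_only"

    def test_significant_near_untagged_is_cnv_allele(self):
        cls = self._run([("s1", 1e-10, "G")], ["indep"])
        assert cls.label == "CNV_allele"

    def test_near_untagged_with_far_tagged_is_cnv_allele(self):
        # decision order: near SNPs exist, none tagging -> CNV_allele
        cls = self._run([("s1", 1e-10, "G"), ("s2", 1e-10, "X")],
                        ["indep", "tag"])
        assert cls.label == "CNV_allele"

    def test_near_tagged_is_snp_cnv_near(self):
        cls = self._run([("s1", 1e-10, "G")], ["tag"])
        assert cls.label == "SNP_CNV_near"
        assert cls.supporting_snps == ["s1"]

    def test_near_tagged_wins_over_far_tagged(self):
        cls = self._run([("s1", 1e-10, "G"), ("s2", 1e-10, "X")], ["tag", "tag"])
        assert cls.label == "SNP_CNV_near"

    def test_far_tagged_only_is_snp_cnv_far(self):
        cls = self._run([("s1", 1e-10, "X")], ["tag"])
        assert cls.label == "SNP_CNV_far"

    def test_far_tagged_with_insignificant_near_is_snp_cnv_far(self):
        cls = self._run([("s1", 1e-10, "X"), ("s2", 0.4, "G")], ["tag", "indep"])
        assert cls.label == "SNP_CNV_far"

    def test_marginal_r2_below_cut_not_tagging(self):
        rng = np.random.default_rng(3)
        lead = rng.normal(0, 1, self.N)
        snp = 0.5 * lead + rng.normal(0, 1, self.N)  # r2 ~ 0.2 < 0.6
        cls = classify_region("r1", {"G"}, _snps([("s1", 1e-10, "G")]),
                              lead, snp[:, None])
        assert cls.label == "CNV_allele"

    def test_multiple_region_genes_any_counts_as_near(self):
        cls = self._run([("s1", 1e-10, "G2")], ["tag"], genes={"G", "G2"})
        assert cls.label == "SNP_CNV_near"

    def test_exactly_one_label_always(self):
        rows = [("s1", 1e-10, "G"), ("s2", 0.3, "X")]
        cls = self._run(rows, ["tag", "indep"])
        assert cls.label in {"CNV_only", "CNV_allele", "SNP_CNV_near", "SNP_CNV_far"}


class TestNearestGene:
    GENES = pd.DataFrame(
        [("chr1", 100, 200, "A"), ("chr1", 500, 600, "B")],
        columns=["chrom", "start", "end", "gene_id"],
    )

    def test_inside_gene(self):
        assert nearest_gene(150, self.GENES) == "A"

    def test_between_genes_closer_wins(self):
        assert nearest_gene(480, self.GENES) == "B"


class TestCnStates:
    def test_well_separated_clusters_fully_recovered(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(3, 600, p=[0.2, 0.6, 0.2])
        centers = np.array([-1.0, 0.0, 0.58])
        x = rng.normal(centers[labels], 0.05)
        fit = fit_cn_states(x, seed=0)
        assert (fit.states == labels).all()
        np.testing.assert_allclose(fit.means, centers, atol=0.03)

    def test_unimodal_data_dominated_by_middle(self):
        rng = np.random.default_rng(5)
        fit = fit_cn_states(rng.normal(0, 0.1, 500))
        occupancy = np.bincount(fit.states, minlength=3) / 500
        assert occupancy[0] < 0.05 and occupancy[2] < 0.05

    def test_clamping_postcondition(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([
            rng.normal(-1, 0.3, 100), rng.normal(0, 0.3, 300), rng.normal(0.6, 0.3, 100)
        ])
        fit = fit_cn_states(x, seed=0)
        for xi, s in zip(x, fit.states):
            if s < 2:
                assert xi <= fit.means[s + 1] + 1e-9
            if s > 0:
                assert xi >= fit.means[s - 1] - 1e-9

    def test_value_above_high_mean_assigned_high(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([
            rng.normal(-1, 0.08, 60), rng.normal(0, 0.08, 300),
            rng.normal(0.58, 0.08, 60), [2.5],
        ])
        fit = fit_cn_states(x, seed=0)
        assert fit.states[-1] == 2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="50"):
            fit_cn_states(np.zeros(10))


class TestCompetitiveModels:
    def _setting(self, tagging, seed=0):
        rng = np.random.default_rng(seed)
        n = 2000
        cn = rng.choice([-1.0, 0.0], n, p=[0.3, 0.7]) + rng.normal(0, 0.1, n)
        state = (cn > -0.5).astype(float) + 1.0  # crude ordinal
        # near-perfect tagging (r2 ~ 0.99); an exact copy would be singular
        snp = cn + rng.normal(0, 0.05, n) if tagging else rng.normal(0, 1, n)
        trait = 0.3 * cn + (0.0 if tagging else 0.3 * snp) + rng.normal(0, 1, n)
        return cn, state, snp, trait

    def test_tagging_snp_controls_cnv_signal(self):
        cn, state, snp, trait = self._setting(tagging=True)
        out = competitive_models(cn, state, trait, snp, snp)
        single = out[(out["model"] == "cn_estimate") & (out["term"] == "cn_estimate")]
        assert single["p"].iloc[0] < 5e-8
        joint = out[(out["model"] == "cn_estimate+max_r2_snp")
                    & (out["term"] == "cn_estimate")]
        assert bool(joint["controlled"].iloc[0])

    def test_independent_causal_snp_leaves_both_significant(self):
        cn, state, snp, trait = self._setting(tagging=False)
        out = competitive_models(cn, state, trait, snp, snp)
        joint = out[out["model"] == "cn_estimate+max_snp"]
        assert (joint["p"] < 5e-8).all()
        assert not joint["controlled"].any()

    def test_eight_models_with_expected_terms(self):
        cn, state, snp, trait = self._setting(tagging=False)
        out = competitive_models(cn, state, trait, snp, snp)
        assert out["model"].nunique() == 8
        assert len(out) == 12  # 4 single-term + 4 joint x 2 terms
        assert out[out["joint"]]["model"].nunique() == 4

    def test_state_and_estimate_agree_on_separated_clusters(self):
        rng = np.random.default_rng(8)
        n = 3000
        state_true = rng.choice(3, n, p=[0.25, 0.5, 0.25])
        cn = rng.normal([-1, 0, 0.58][0], 0.0)  # placeholder replaced below
        cn = np.array([-1, 0, 0.58])[state_true] + rng.normal(0, 0.05, n)
        trait = 0.2 * state_true + rng.normal(0, 1, n)
        snp = rng.normal(0, 1, n)
        out = competitive_models(cn, state_true.astype(float), trait, snp, snp)
        p_est = out[(out["model"] == "cn_estimate")]["p"].iloc[0]
        p_state = out[(out["model"] == "cn_state")]["p"].iloc[0]
        assert abs(np.log10(p_est) - np.log10(p_state)) < 1.0
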