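import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from clonesweep.data_io import ExpressionMatrix
from clonesweep.signatures import (
    GeneSignature,
    differential_information,
    information_coefficient,
    normalize_expression,
    permutation_pvalue,
    prune_signature,
    score_samples,
    select_variable_genes,
)
from clonesweep.synthetic import simulate_expression


def planted_matrix(seed=7, effect=2.0):
    return simulate_expression(20, 20, 160, 25, effect_size=effect, seed=seed)


class TestNormalize:
    def test_hand_computed_row(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], np.array([[0.0, 1.0, 2.0]]))
        normed, flagged = normalize_expression(m)
        np.testing.assert_allclose(normed.values, [[-1.0, 0.0, 1.0]])
        assert flagged == []

    def test_constant_gene_flagged_zero(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], np.full((1, 3), 5.0))
        normed, flagged = normalize_expression(m)
        np.testing.assert_array_equal(normed.values, 0.0)
        assert flagged == ["g"]

    def test_row_medians_centered(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(20)],
            [f"s{j}" for j in range(15)],
            rng.normal(3, 2, size=(20, 15)),
        )
        normed, _ = normalize_expression(m)
        np.testing.assert_allclose(np.median(normed.values, axis=1), 0.0, atol=1e-12)

    def test_too_few_samples(self):
        m = ExpressionMatrix(["g"], ["a", "b"], np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            normalize_expression(m)


class TestSelectVariableGenes:
    def test_planted_high_mad_gene_ranks_first(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, size=(10, 30))
        vals[3] *= 20
        m = ExpressionMatrix([f"g{i}" for i in range(10)], [f"s{j}" for j in range(30)], vals)
        assert select_variable_genes(m, 1) == ["g3"]

    def test_constant_genes_rank_last(self):
        vals = np.vstack([np.random.default_rng(2).normal(0, 1, (3, 10)), np.zeros((2, 10))])
        m = ExpressionMatrix(["a", "b", "c", "flat1", "flat2"],
                             [f"s{j}" for j in range(10)], vals)
        ranked = select_variable_genes(m, 5)
        assert set(ranked[-2:]) == {"flat1", "flat2"}

    def test_overlong_request_returns_all(self):
        m = ExpressionMatrix(["a", "b"], ["s1", "s2", "s3"],
                             np.arange(6, dtype=float).reshape(2, 3))
        assert len(select_variable_genes(m, 10)) == 2


class TestPruneSignature:
    def test_planted_blocks_recovered(self):
        mat, truth = planted_matrix()
        normed, _ = normalize_expression(mat)
        sig = prune_signature(normed, list(normed.gene_ids), target_size=40)
        up, dn = set(sig.up_genes), set(sig.down_genes)
        tu, td = set(truth["up_genes"]), set(truth["down_genes"])
        acc = max(len(up & tu) + len(dn & td), len(up & td) + len(dn & tu)) / 40
        assert acc >= 0.9

    def test_uncorrelated_noise_gene_dropped_first(self):
        rng = np.random.default_rng(3)
        shared = rng.normal(0, 1, 40)
        vals = np.vstack([shared + rng.normal(0, 0.1, 40) for _ in range(11)])
        vals = np.vstack([vals, rng.normal(0, 1, (1, 40))])  # lone noise gene
        genes = [f"c{i}" for i in range(11)] + ["noise"]
        m = ExpressionMatrix(genes, [f"s{j}" for j in range(40)], vals)
        sig = prune_signature(m, genes, target_size=11)
        assert "noise" not in sig.up_genes + sig.down_genes

    def test_target_equal_to_candidates_is_identity(self):
        mat, _ = planted_matrix(seed=11)
        normed, _ = normalize_expression(mat)
        genes = list(normed.gene_ids)[:20]
        sig = prune_signature(normed, genes, target_size=20)
        assert sorted(sig.up_genes + sig.down_genes) == sorted(genes)

    def test_too_few_candidates_rejected(self):
        mat, _ = planted_matrix(seed=12)
        with pytest.raises(ValueError):
            prune_signature(mat, list(mat.gene_ids)[:5])


class TestScoreSamples:
    def _sig(self):
        return GeneSignature(up_genes=["u1", "u2"], down_genes=["d1", "d2"])

    def test_antisymmetric_under_swap(self):
        mat, truth = planted_matrix(seed=4)
        normed, _ = normalize_expression(mat)
        sig = GeneSignature(up_genes=truth["up_genes"], down_genes=truth["down_genes"])
        scores = score_samples(normed, sig)
        swapped = score_samples(normed, sig.swapped())
        for k in scores:
            assert scores[k] == pytest.approx(-swapped[k], abs=1e-12)

    def test_planted_effect_separates_classes(self):
        mat, truth = planted_matrix(seed=5)
        normed, _ = normalize_expression(mat)
        sig = GeneSignature(up_genes=truth["up_genes"], down_genes=truth["down_genes"])
        scores = score_samples(normed, sig)
        hi = [scores[s] for s in truth["high_samples"]]
        lo = [scores[s] for s in truth["low_samples"]]
        pairs = sum(h > l for h in hi for l in lo)
        assert pairs / (len(hi) * len(lo)) >= 0.95

    def test_invariant_to_sample_constant_shift(self):
        rng = np.random.default_rng(6)
        genes = ["u1", "u2", "d1", "d2"]
        vals = rng.normal(0, 1, size=(4, 5))
        m1 = ExpressionMatrix(genes, [f"s{j}" for j in range(5)], vals)
        m2 = ExpressionMatrix(genes, [f"s{j}" for j in range(5)], vals + 7.0)
        s1 = score_samples(m1, self._sig())
        s2 = score_samples(m2, self._sig())
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=1e-9)

    def test_balanced_means_score_zero(self):
        vals = np.array([[1.0, 2.0], [3.0, -1.0], [1.0, 2.0], [3.0, -1.0]])
        m = ExpressionMatrix(["u1", "u2", "d1", "d2"], ["a", "b"], vals)
        scores = score_samples(m, self._sig())
        assert scores["a"] == pytest.approx(0.0, abs=1e-12)


class TestInformationCoefficient:
    def test_identical_class_profiles_give_zero(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, 20)
        feature = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert information_coefficient(feature, np.r_[vals, vals]) == pytest.approx(0.0, abs=1e-9)

    def test_separated_classes_near_one(self):
        rng = np.random.default_rng(9)
        profile = np.r_[rng.normal(0, 1, 20), rng.normal(10, 1, 20)]
        feature = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert information_coefficient(feature, profile) > 0.9

    def test_matches_two_gaussian_oracle(self):
        # numerically integrated symmetrized KL of N(0,1) vs N(2,1)
        j_true = 0.5 * quad(
            lambda x: (norm.pdf(x, 0, 1) - norm.pdf(x, 2, 1))
            * (norm.logpdf(x, 0, 1) - norm.logpdf(x, 2, 1)),
            -12, 14,
        )[0]
        ic_true = np.sqrt(1 - np.exp(-2 * j_true))
        rng = np.random.default_rng(10)
        n = 1000
        profile = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
        feature = np.r_[np.zeros(n, int), np.ones(n, int)]
        assert information_coefficient(feature, profile) == pytest.approx(ic_true, abs=0.05)

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        profile = np.r_[rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)]
        feature = np.r_[np.zeros(40, int), np.ones(40, int)]
        a = information_coefficient(feature, profile)
        b = information_coefficient(feature, 3.0 * profile - 11.0)
        assert a == pytest.approx(b, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            differential_information(np.zeros(10, int), np.arange(10.0))


class TestPermutationTest:
    def test_perfect_separation_hits_add_one_floor(self):
        rng = np.random.default_rng(12)
        profile = np.r_[rng.normal(0, 0.5, 10), rng.normal(20, 0.5, 10)]
        feature = np.r_[np.zeros(10, int), np.ones(10, int)]
        res = permutation_pvalue(feature, profile, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_never_below_add_one_bound(self):
        rng = np.random.default_rng(13)
        res = permutation_pvalue(
            np.r_[np.zeros(8, int), np.ones(8, int)], rng.normal(0, 1, 16),
            n_perm=100, seed=1,
        )
        assert res.p_value >= 1 / 101

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.array([0, 1, 0, 1, 0]), np.arange(5.0), n_perm=10)
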