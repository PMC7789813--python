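import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoref.expression_io import ExpressionMatrix, ValidationError
from exoref.stability import (
    av_combination,
    compare_stability_groups,
    cv_stability,
    m_values,
    normfinder_stability,
    pairwise_variation,
    rank_candidates,
)
from tests.conftest import make_design, make_matrix


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def naive_v_matrix(arr):
    """Two-loop pairwise variation on a (features x samples) array."""
    n = arr.shape[0]
    v = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            ratios = [math.log2(arr[j, i] / arr[k, i]) for i in range(arr.shape[1])]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            v[j, k] = math.sqrt(var)
    return v


def naive_m(arr):
    v = naive_v_matrix(arr)
    n = arr.shape[0]
    return np.array([sum(v[j, k] for k in range(n) if k != j) / (n - 1) for j in range(n)])


def naive_normfinder(arr, group_sizes):
    """Loop recomputation of the group-aware stability score."""
    logx = np.log2(arr)
    p, m = logx.shape
    z = logx.copy()
    for i in range(m):
        z[:, i] -= logx[:, i].mean()
    bounds = np.cumsum([0] + group_sizes)
    scores = np.zeros(p)
    for j in range(p):
        grand = z[j].mean()
        total = 0.0
        for g in range(len(group_sizes)):
            block = z[j, bounds[g]:bounds[g + 1]]
            d = block.mean() - grand
            s2 = block.var(ddof=1)
            total += abs(d) + math.sqrt(s2 / len(block))
        scores[j] = total / len(group_sizes)
    return scores


class TestCV:
    def test_hand_computed(self):
        mat = make_matrix([[2.0, 4.0, 6.0]], scale="TPM")
        assert cv_stability(mat).iloc[0] == pytest.approx(0.5)

    def test_constant_vector_is_zero(self):
        mat = make_matrix([[7.0, 7.0, 7.0]], scale="TPM")
        assert cv_stability(mat).iloc[0] == 0.0

    def test_scale_invariance(self, rng):
        arr = rng.uniform(1, 100, size=(5, 8))
        m1 = make_matrix(arr, scale="TPM")
        m2 = make_matrix(arr * rng.uniform(0.1, 10, size=(5, 1)), scale="TPM")
        np.testing.assert_allclose(
            cv_stability(m1).to_numpy(), cv_stability(m2).to_numpy(), rtol=1e-10
        )

    def test_zero_mean_feature_errors(self):
        mat = make_matrix([[0.0, 0.0]], scale="TPM")
        with pytest.raises(ValidationError):
            cv_stability(mat)

    def test_missing_excluded_pairwise(self):
        df = pd.DataFrame([[2.0, 4.0, 6.0, np.nan]], index=["g"], columns=list("abcd"))
        mat = ExpressionMatrix(df, scale="abundance")
        assert cv_stability(mat).iloc[0] == pytest.approx(0.5)


class TestPairwiseVariation:
    def test_proportional_features_have_zero_v(self):
        mat = make_matrix([[1.0, 2.0, 4.0], [2.0, 4.0, 8.0]], scale="TPM")
        v = pairwise_variation(mat)
        assert v.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sd_one(self):
        mat = make_matrix([[1.0, 2.0, 4.0], [1.0, 1.0, 1.0]], scale="TPM")
        v = pairwise_variation(mat)
        assert v.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(20):
            arr = rng.uniform(0.5, 500, size=(6, 8))
            v = pairwise_variation(make_matrix(arr, scale="TPM")).to_numpy()
            np.testing.assert_allclose(v, naive_v_matrix(arr), atol=1e-10)

    def test_symmetric_zero_diagonal(self, rng):
        arr = rng.uniform(1, 10, size=(5, 6))
        v = pairwise_variation(make_matrix(arr, scale="TPM")).to_numpy()
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(v), 0.0)

    def test_zeros_need_pseudocount(self, caplog):
        mat = make_matrix([[0.0, 1.0], [1.0, 1.0]], scale="TPM")
        with caplog.at_level("WARNING"):
            v = pairwise_variation(mat, pseudocount=1.0)
        assert "pseudocount" in caplog.text
        assert np.isfinite(v.to_numpy()).all()
        with pytest.raises(ValidationError):
            pairwise_variation(mat, pseudocount=0.0)


class TestMValues:
    def test_hand_computed_three_features(self):
        mat = make_matrix(
            [[1.0, 2.0, 4.0], [2.0, 4.0, 8.0], [1.0, 1.0, 1.0]], scale="TPM"
        )
        m = m_values(mat)
        assert m.iloc[0] == pytest.approx(0.5)

    def test_two_proportional_features(self):
        mat = make_matrix([[1.0, 3.0], [10.0, 30.0]], scale="TPM")
        np.testing.assert_allclose(m_values(mat).to_numpy(), [0.0, 0.0], atol=1e-12)

    def test_two_feature_identity_with_v(self, rng):
        arr = rng.uniform(1, 50, size=(2, 7))
        mat = make_matrix(arr, scale="TPM")
        v = pairwise_variation(mat)
        m = m_values(mat)
        assert m.iloc[0] == pytest.approx(m.iloc[1], rel=1e-12)
        assert m.iloc[0] == pytest.approx(v.iloc[0, 1], rel=1e-12)

    def test_per_sample_scaling_invariance(self, rng):
        arr = rng.uniform(1, 100, size=(6, 9))
        scales = rng.uniform(0.2, 5, size=9)
        m1 = m_values(make_matrix(arr, scale="TPM"))
        m2 = m_values(make_matrix(arr * scales[None, :], scale="TPM"))
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), rtol=1e-9)

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            arr = rng.uniform(0.5, 200, size=(7, 10))
            m = m_values(make_matrix(arr, scale="TPM")).to_numpy()
            np.testing.assert_allclose(m, naive_m(arr), atol=1e-10)

    def test_single_feature_errors(self):
        with pytest.raises(ValidationError):
            m_values(make_matrix([[1.0, 2.0]], scale="TPM"))


class TestAVCombination:
    def test_equal_members(self):
        m = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5})
        assert av_combination(m, ("a", "b", "c")).av == pytest.approx(0.5)

    def test_published_trio_value(self, gene_m):
        combo = av_combination(gene_m, ("OAZ1", "SERF2", "MPP1"))
        # oracle: direct arithmetic, cube root of the product
        expected = (0.561 * 0.588 * 0.597) ** (1.0 / 3.0)
        assert combo.av == pytest.approx(expected, rel=1e-12)
        assert combo.av == pytest.approx(0.5819, abs=5e-4)

    def test_permutation_invariance(self, gene_m):
        a = av_combination(gene_m, ("OAZ1", "SERF2", "MPP1")).av
        b = av_combination(gene_m, ("MPP1", "OAZ1", "SERF2")).av
        assert a == pytest.approx(b, rel=1e-15)

    def test_zero_member_gives_zero(self):
        m = pd.Series({"a": 0.0, "b": 0.5})
        assert av_combination(m, ("a", "b")).av == 0.0

    def test_too_few_members_rejected(self):
        with pytest.raises(ValidationError):
            av_combination(pd.Series({"a": 0.5}), ("a",))


class TestRankCandidates:
    def test_published_gene_table_untied_rows(self, gene_cv, gene_m):
        table = rank_candidates(gene_cv, gene_m)
        final = table["final_rank"]
        assert final["OAZ1"] == 1
        assert final["H3F3AP4"] == 4
        assert final["SOD2"] == 8
        assert final["B2M"] == 9
        assert final["ITM2B"] == 10
        # tie blocks
        assert {final["SERF2"], final["MPP1"]} == {2, 3}
        assert {final["WIPF1"], final["PCMTD1"], final["ARF1"]} == {5, 6, 7}

    def test_published_mirna_table(self, mirna_cv, mirna_m):
        final = rank_candidates(mirna_cv, mirna_m)["final_rank"]
        assert final["hsa-miR-4468"] == 1
        assert final["hsa-miR-6835-3p"] == 2
        assert final["hsa-miR-4469"] == 5
        assert final["hsa-miR-6731-5p"] == 6

    def test_all_identical_ranked_by_identifier(self):
        cv = pd.Series({"b": 0.3, "a": 0.3, "c": 0.3})
        m = pd.Series({"b": 0.5, "a": 0.5, "c": 0.5})
        final = rank_candidates(cv, m)["final_rank"]
        assert final["a"] == 1 and final["b"] == 2 and final["c"] == 3

    def test_input_order_irrelevant(self, gene_cv, gene_m):
        shuffled = gene_cv.sample(frac=1, random_state=5)
        t1 = rank_candidates(gene_cv, gene_m)["final_rank"].sort_index()
        t2 = rank_candidates(shuffled, gene_m)["final_rank"].sort_index()
        pd.testing.assert_series_equal(t1, t2)

    def test_rank_columns_are_permutations(self, mirna_cv, mirna_m):
        table = rank_candidates(mirna_cv, mirna_m)
        n = len(table)
        for col in ("cv_rank", "m_rank", "final_rank"):
            assert sorted(table[col]) == list(range(1, n + 1))

    def test_mismatched_features_rejected(self):
        with pytest.raises(ValidationError):
            rank_candidates(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


class TestNormFinder:
    def test_no_signal_gives_zero_scores(self):
        # proportional features: feature effect x sample effect exactly
        feat = np.array([1.0, 4.0, 16.0])
        samp = np.array([1.0, 2.0, 3.0, 4.0])
        mat = make_matrix(np.outer(feat, samp), scale="TPM",
                          samples=["A_0", "A_1", "B_0", "B_1"])
        design = make_design({"A": ("case", 2), "B": ("control", 2)})
        scores = normfinder_stability(mat, design)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_planted_group_shift_is_least_stable(self, rng):
        p, per_group = 10, 6
        log_arr = rng.normal(6.0, 0.3, size=(p, 2 * per_group))
        log_arr[0, :per_group] += 3.0  # strong group shift on one feature
        mat = make_matrix(2.0 ** log_arr, scale="TPM",
                          samples=[f"A_{i}" for i in range(per_group)]
                          + [f"B_{i}" for i in range(per_group)])
        design = make_design({"A": ("case", per_group), "B": ("control", per_group)})
        scores = normfinder_stability(mat, design)
        assert scores.idxmax() == "g0"

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            arr = rng.uniform(1, 500, size=(8, 12))
            mat = make_matrix(arr, scale="TPM",
                              samples=[f"A_{i}" for i in range(6)] + [f"B_{i}" for i in range(6)])
            design = make_design({"A": ("case", 6), "B": ("control", 6)})
            scores = normfinder_stability(mat, design).to_numpy()
            np.testing.assert_allclose(scores, naive_normfinder(arr, [6, 6]), atol=1e-10)

    def test_group_with_single_sample_errors(self):
        mat = make_matrix(np.ones((3, 3)) + 1, scale="TPM",
                          samples=["A_0", "A_1", "B_0"])
        design = make_design({"A": ("case", 2), "B": ("control", 1)})
        with pytest.raises(ValidationError, match="B"):
            normfinder_stability(mat, design)


class TestWilcoxonComparison:
    def test_identical_lists_give_p_one(self):
        stat, p = compare_stability_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_minimal_exact_p_three_vs_three(self):
        _, p = compare_stability_groups([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        # exact enumeration: 2 / C(6,3) one-sided extremes doubled
        assert p == pytest.approx(2.0 / 20.0)

    def test_symmetry(self, rng):
        a = rng.uniform(0, 1, size=8).tolist()
        b = rng.uniform(0.5, 1.5, size=6).tolist()
        _, p1 = compare_stability_groups(a, b)
        _, p2 = compare_stability_groups(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_list_errors(self):
        with pytest.raises(ValidationError):
            compare_stability_groups([], [1.0])


@settings(max_examples=40, deadline=None)
@given(
    st.integers(2, 6),
    st.integers(2, 6),
    st.integers(0, 10_000),
)
def test_m_scaling_and_cv_scaling_invariants(n_feat, n_samp, seed):
    rng = np.random.default_rng(seed)
    arr = rng.uniform(0.5, 100, size=(n_feat, n_samp))
    col_scale = rng.uniform(0.5, 4, size=n_samp)
    row_scale = rng.uniform(0.5, 4, size=n_feat)
    m1 = m_values(make_matrix(arr, scale="TPM"))
    m2 = m_values(make_matrix(arr * col_scale[None, :], scale="TPM"))
    np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), rtol=1e-8, atol=1e-10)
    cv1 = cv_stability(make_matrix(arr, scale="TPM"))
    cv2 = cv_stability(make_matrix(arr * row_scale[:, None], scale="TPM"))
    np.testing.assert_allclose(cv1.to_numpy(), cv2.to_numpy(), rtol=1e-8)
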