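import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from remsig import (
    ExpressionMatrix,
    GeneSet,
    gene_set_null_test,
    induction_signature,
    make_signature,
    storey_qvalues,
    two_group_test,
    v_statistic,
)
from remsig.stats import storey_pi0


def _expr(values, samples=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestTwoGroupTest:
    def test_identical_groups(self):
        expr = _expr([[1, 1, 1, 1, 1, 1]])
        res = two_group_test(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.loc["g0", "p"] == 1.0
        assert res.loc["g0", "s"] == 0.0

    def test_3v3_against_exhaustive_permutation_oracle(self):
        # a=[5,6,7], b=[1,2,3]: the observed |mean difference| is attained by
        # exactly 2 of the 20 label permutations → permutation p = 0.10
        vals = np.array([5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        obs = abs(vals[:3].mean() - vals[3:].mean())
        count = sum(
            abs(vals[list(c)].mean() - np.delete(vals, list(c)).mean()) >= obs - 1e-12
            for c in itertools.combinations(range(6), 3)
        )
        assert count / 20 == pytest.approx(0.10)
        res = two_group_test(_expr([vals]), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        # direct evaluation: t = 4/√(2/3) ≈ 4.899, df 4, two-sided p ≈ 0.00805
        t_ref = 4.0 / np.sqrt(2 / 3)
        from scipy import stats as sps

        assert res.loc["g0", "p"] == pytest.approx(2 * sps.t.sf(t_ref, 4), rel=1e-9)
        assert res.loc["g0", "s"] == 1.0

    def test_group_swap_flips_sign_preserves_p(self, null_expression):
        a = null_expression.samples_with_label("A")
        b = null_expression.samples_with_label("B")
        ab = two_group_test(null_expression, a, b)
        ba = two_group_test(null_expression, b, a)
        np.testing.assert_array_equal(ab["p"].to_numpy(), ba["p"].to_numpy())
        np.testing.assert_array_equal(ab["s"].to_numpy(), -ba["s"].to_numpy())

    def test_zero_variance_unequal_means(self):
        expr = _expr([[2, 2, 2, 1, 1, 1]])
        res = two_group_test(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert 0 < res.loc["g0", "p"] <= np.finfo(float).tiny
        assert res.loc["g0", "s"] == 1.0

    def test_student_equals_welch_with_equal_variances(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (30, 6))
        b = a[:, :6] + 0.7  # identical sample variance, shifted mean
        expr = _expr(np.hstack([a, b]))
        ga = [f"s{i}" for i in range(6)]
        gb = [f"s{i}" for i in range(6, 12)]
        student = two_group_test(expr, ga, gb, equal_var=True)
        welch = two_group_test(expr, ga, gb, equal_var=False)
        np.testing.assert_allclose(
            student["p"].to_numpy(), welch["p"].to_numpy(), atol=1e-10
        )

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="≥2"):
            two_group_test(_expr([[1, 2, 3]]), ["s0"], ["s1", "s2"])


class TestVStatistic:
    def test_reference_points(self):
        assert v_statistic(1.0, 1) == 0.0
        assert v_statistic(0.05, 1) == pytest.approx(0.95)
        assert v_statistic(1e-12, -1) == pytest.approx(-1.0, abs=1e-11)

    @pytest.mark.parametrize("p,s", [(0.0, 1), (1.5, 1), (0.5, 2)])
    def test_domain_errors(self, p, s):
        with pytest.raises(ValueError):
            v_statistic(p, s)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(1e-300, 1.0, allow_nan=False), st.sampled_from([-1, 0, 1])
    )
    def test_identity_and_bounds(self, p, s):
        v = v_statistic(p, s)
        assert v == s * (1 - p)
        assert abs(v) <= 1.0
        assert (v == 0.0) == (s == 0 or p == 1.0)


class TestStoreyQvalues:
    def test_extreme_case_all_tiny(self):
        p = np.full(1000, 1e-6)
        q, pi0 = storey_qvalues(p)
        assert (q <= 1e-5).all()

    def test_bh_equivalence_with_pi0_one(self):
        p = np.random.default_rng(1).uniform(0, 1, 500)
        q, _ = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-10)

    def test_fewer_than_100_falls_back_to_pi0_one(self):
        p = np.random.default_rng(2).uniform(0, 1, 50)
        q, pi0 = storey_qvalues(p)
        assert pi0 == 1.0

    def test_q_monotone_in_p(self):
        p = np.random.default_rng(3).uniform(0, 1, 5000)
        q, _ = storey_qvalues(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_q_bounds_with_ties(self):
        # q_i is a running minimum over genes with p_j ≥ p_i, so it is capped
        # by the gene's own raw value π0·m·p/rank and floored by π0·p
        p = np.concatenate([np.random.default_rng(4).uniform(0, 1, 3000), [0.5] * 10])
        q, pi0 = storey_qvalues(p)
        m = p.size
        ranks = pd.Series(p).rank(method="max").to_numpy()
        raw = np.minimum(pi0 * m * p / ranks, 1.0)
        assert (q <= raw + 1e-12).all()
        assert (q >= pi0 * p - 1e-12).all()

    def test_pi0_spline_on_uniform(self):
        p = np.random.default_rng(5).uniform(0, 1, 10000)
        assert 0.9 <= storey_pi0(p) <= 1.0


class TestInductionSignature:
    def _world(self, seed, n_up=150, n_down=30, effect=6.0, n_genes=2000):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n_genes, 6))
        X[:n_up, 3:] += effect
        X[n_up : n_up + n_down, 3:] -= effect
        expr = _expr(X)
        return expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"]

    def test_planted_recovery_sensitivity_and_fpr(self):
        # at a strong induction effect the P<0.01 & FDR<10% filter recovers
        # nearly all planted genes with ~1% leakage from the null background
        sens_list, fpr_list = [], []
        for seed in range(5):
            expr, ctrl, ind = self._world(seed)
            sig, n_up, n_down = induction_signature(expr, ctrl, ind)
            passing = (sig.table["p"] < 0.01) & (sig.table["q"] < 0.10)
            planted = passing.index[:180]
            sens_list.append(passing.loc[planted].mean())
            fpr_list.append(passing.iloc[180:].mean())
            assert n_up + n_down == int(passing.sum())
        assert np.median(sens_list) >= 0.9
        assert np.median(fpr_list) <= 0.02

    def test_null_experiment_passing_fraction(self):
        fracs = []
        for seed in range(5):
            expr, ctrl, ind = self._world(seed, n_up=0, n_down=0, effect=0.0)
            sig, n_up, n_down = induction_signature(expr, ctrl, ind, alpha=0.01)
            fracs.append((n_up + n_down) / len(sig.table))
        assert np.median(fracs) <= 0.02

    def test_control_equals_induced_passes_nothing(self):
        rng = np.random.default_rng(9)
        expr = _expr(rng.normal(0, 1, (200, 3)), samples=["a", "b", "c"])
        dup = ExpressionMatrix(
            pd.concat([expr.values, expr.values.add_suffix("_i")], axis=1).rename(
                columns=lambda c: c
            )
        )
        sig, n_up, n_down = induction_signature(
            dup, ["a", "b", "c"], ["a_i", "b_i", "c_i"]
        )
        assert n_up == 0 and n_down == 0


class TestGeneSetNullTest:
    def _signature(self, seed, m=2000):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(m)]
        p = rng.uniform(0, 1, m)
        table = pd.DataFrame(
            {
                "mean_diff": 0.0,
                "s": 1.0,
                "p": p,
                "q": p,
                "v": 1 - p,
            },
            index=genes,
        )
        from remsig import SignatureVector

        return SignatureVector("null", table)

    def test_deterministic_given_seed(self):
        sig = self._signature(0)
        gs = GeneSet("set", [f"g{i}" for i in range(36)])
        r1 = gene_set_null_test(sig, gs, rng=123)
        r2 = gene_set_null_test(sig, gs, rng=123)
        assert r1.expected_count == r2.expected_count
        assert r1.p_chi2 == r2.p_chi2

    def test_fully_significant_set_rejects(self):
        sig = self._signature(1)
        sig.table.iloc[:36, sig.table.columns.get_loc("p")] = 1e-8
        gs = GeneSet("hot", [f"g{i}" for i in range(36)])
        res = gene_set_null_test(sig, gs, alpha=0.05, n_random=10, rng=0)
        assert res.observed_count == 36
        assert res.p_chi2 < 0.001
        assert res.p_binomial < 0.001

    def test_missing_members_dropped_with_warning(self, caplog):
        sig = self._signature(2)
        gs = GeneSet("partial", ["g0", "g1", "NOT_THERE"])
        with caplog.at_level("WARNING"):
            res = gene_set_null_test(sig, gs, rng=0)
        assert res.set_size == 2
        assert any("absent" in r.message for r in caplog.records)

    def test_empty_intersection_errors(self):
        sig = self._signature(3)
        gs = GeneSet("alien", ["X1", "X2"])
        with pytest.raises(ValueError, match="alien"):
            gene_set_null_test(sig, gs, rng=0)


def test_make_signature_invariants(null_expression):
    a = null_expression.samples_with_label("A")
    b = null_expression.samples_with_label("B")
    sig = make_signature("null", null_expression, a, b)
    t = sig.table
    np.testing.assert_array_equal(
        t["v"].to_numpy(), t["s"].to_numpy() * (1 - t["p"].to_numpy())
    )
    assert (t["v"].abs() <= 1).all()
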