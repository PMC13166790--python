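"""Wald/IVW estimators, heterogeneity and pleiotropy diagnostics, Steiger,
and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcpmr.estimators import (
    bh_fdr,
    cochran_q,
    egger,
    ivw,
    presso,
    steiger,
    wald_ratio,
)
from mcpmr.simulate import simulate_iv_summary

from conftest import make_pairs


class TestWaldRatio:
    def test_arithmetic(self):
        pairs = make_pairs([0.2], [0.1], se_gy=[0.05])
        e = wald_ratio(pairs.iloc[0])
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.25)

    def test_null_outcome(self):
        e = wald_ratio(make_pairs([0.2], [0.0]).iloc[0])
        assert e.beta == 0.0
        assert e.pvalue == pytest.approx(1.0)

    def test_sign_symmetry(self):
        plus = wald_ratio(make_pairs([0.2], [0.1]).iloc[0])
        minus = wald_ratio(make_pairs([-0.2], [0.1]).iloc[0])
        assert minus.beta == pytest.approx(-plus.beta)
        assert minus.se == pytest.approx(plus.se)

    def test_zero_exposure_effect_is_hard_error(self):
        with pytest.raises(ValueError):
            wald_ratio(make_pairs([0.0], [0.1]).iloc[0])

    def test_ci_is_beta_plus_minus_196_se(self):
        e = wald_ratio(make_pairs([0.2], [0.1]).iloc[0])
        assert e.ci_low == pytest.approx(e.beta - 1.959964 * e.se)
        assert e.ci_high == pytest.approx(e.beta + 1.959964 * e.se)


class TestIVW:
    def test_single_pair_equals_wald(self):
        pairs = make_pairs([0.2], [0.1], se_gy=[0.05])
        w = wald_ratio(pairs.iloc[0])
        for model in ("fixed", "random"):
            e = ivw(pairs, model)
            assert e.beta == w.beta
            assert e.se == w.se

    def test_two_identical_pairs_halve_variance(self):
        one = make_pairs([0.2], [0.1], se_gy=[0.05])
        two = make_pairs([0.2, 0.2], [0.1, 0.1], se_gy=[0.05, 0.05])
        assert ivw(two, "fixed").beta == pytest.approx(ivw(one, "fixed").beta)
        assert ivw(two, "fixed").se == pytest.approx(
            ivw(one, "fixed").se / np.sqrt(2))

    def test_equals_wls_through_origin_oracle(self):
        # IVW with first-order weights is WLS of beta_gy on beta_gx
        # through the origin with weights 1/se_gy^2
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.3, 5)
        by = 0.2 * bx + rng.normal(0, 0.02, 5)
        sy = rng.uniform(0.01, 0.04, 5)
        pairs = make_pairs(bx, by, se_gy=sy)
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert ivw(pairs, "fixed").beta == pytest.approx(fit.params[0])

    def test_random_se_never_below_fixed(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pairs = simulate_iv_summary(rng, k=8, theta=0.1,
                                        pleiotropy=rng.normal(0, 0.01, 8))
            assert ivw(pairs, "random").se >= ivw(pairs, "fixed").se

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            ivw(make_pairs([], []))


class TestCochranQ:
    def test_equal_ratios_give_zero(self):
        pairs = make_pairs([0.1, 0.2], [0.05, 0.10])
        q, p = cochran_q(pairs)
        assert q == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_snp_case(self):
        # ratios (0.1, 0.3), ratio SEs (0.1, 0.1): weights 100 each,
        # pooled 0.2, Q = 100*0.01 + 100*0.01 = 2
        pairs = make_pairs([1.0, 1.0], [0.1, 0.3], se_gy=[0.1, 0.1])
        q, p = cochran_q(pairs)
        assert q == pytest.approx(2.0)
        assert p == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        pairs = simulate_iv_summary(rng, k=6, theta=0.1)
        q1, _ = cochran_q(pairs)
        q2, _ = cochran_q(pairs.iloc[::-1].reset_index(drop=True))
        assert q1 == pytest.approx(q2)

    def test_single_snp_is_hard_error(self):
        with pytest.raises(ValueError):
            cochran_q(make_pairs([0.1], [0.05]))


class TestEgger:
    def test_line_through_origin_gives_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        pairs = make_pairs(bx, 0.5 * bx)
        res = egger(pairs)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.5)

    def test_constant_pleiotropy_recovered_as_intercept(self):
        # instrument strengths must vary for the intercept to be identified
        rng = np.random.default_rng(6)
        delta = 0.02
        ve = np.linspace(0.005, 0.04, 50)
        found = []
        for _ in range(50):
            pairs = simulate_iv_summary(rng, k=50, theta=0.1,
                                        var_explained=ve, pleiotropy=delta)
            found.append(egger(pairs).intercept)
        assert np.mean(found) == pytest.approx(delta, abs=0.004)

    def test_orientation_invariance(self):
        # flipping an instrument's alleles (sign of both effects) must not
        # change the Egger fit
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.5 * bx + np.array([0.01, -0.02, 0.015, 0.0])
        pairs = make_pairs(bx, by)
        flip = pairs.copy()
        flip.loc[1, ["beta_gx", "beta_gy"]] *= -1
        a, b = egger(pairs), egger(flip)
        assert a.intercept == pytest.approx(b.intercept)
        assert a.slope.beta == pytest.approx(b.slope.beta)

    def test_fewer_than_three_is_hard_error(self):
        with pytest.raises(ValueError):
            egger(make_pairs([0.1, 0.2], [0.05, 0.1]))


class TestPresso:
    def test_colinear_null_gives_large_global_p(self):
        rng = np.random.default_rng(7)
        pairs = simulate_iv_summary(rng, k=20, theta=0.1)
        res = presso(pairs, n_sim=500, seed=0)
        assert res.global_pvalue > 0.5
        assert res.outlier_ids == []

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(8)
        pairs = simulate_iv_summary(rng, k=20, theta=0.1,
                                    outlier_idx=7, outlier_shift_se=10.0)
        res = presso(pairs, n_sim=500, seed=0)
        assert res.global_pvalue < 0.05
        assert "iv007" in res.outlier_ids

    def test_fixed_seed_is_bit_identical(self):
        rng = np.random.default_rng(9)
        pairs = simulate_iv_summary(rng, k=10, theta=0.1)
        a = presso(pairs, n_sim=300, seed=5)
        b = presso(pairs, n_sim=300, seed=5)
        assert a.global_pvalue == b.global_pvalue
        assert a.outlier_pvalues == b.outlier_pvalues

    def test_seed_required_and_minimum_k(self):
        rng = np.random.default_rng(10)
        pairs = simulate_iv_summary(rng, k=10, theta=0.1)
        with pytest.raises(ValueError):
            presso(pairs, seed=None)
        with pytest.raises(ValueError):
            presso(pairs.head(3), n_sim=100, seed=1)


class TestSteiger:
    def test_symmetric_case_is_tie(self):
        pairs = make_pairs([0.1], [0.1])
        p, correct = steiger(pairs)
        assert p == pytest.approx(1.0)
        assert correct is False  # ties resolved conservatively

    def test_strong_forward_direction(self):
        # r_x = 0.1, r_y = 0.01 at n = 100k on both sides
        eaf = 0.5
        bx = 0.1 / np.sqrt(2 * eaf * (1 - eaf))
        by = 0.01 / np.sqrt(2 * eaf * (1 - eaf))
        pairs = make_pairs([bx], [by], eaf=eaf, n_gx=100_000, n_gy=100_000)
        p, correct = steiger(pairs)
        assert correct is True
        assert p < 1e-10

    def test_swapping_sides_negates_z(self):
        pairs = make_pairs([0.12], [0.05])
        p1, c1 = steiger(pairs)
        swapped = pairs.rename(columns={
            "beta_gx": "beta_gy", "beta_gy": "beta_gx",
            "se_gx": "se_gy", "se_gy": "se_gx",
            "n_gx": "n_gy", "n_gy": "n_gx"})
        p2, c2 = steiger(swapped)
        assert p1 == pytest.approx(p2)
        assert c1 != c2

    def test_oversized_r2_is_hard_error(self):
        with pytest.raises(ValueError):
            steiger(make_pairs([2.0], [0.1], eaf=0.5))


def _bh_oracle(p):
    """Quadratic-time step-up: q_i = min over j with p_j >= p_i of
    min(1, m * p_j / rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(min(1.0, m * ranked[j] / (j + 1))
                   for j in range(i, m))
    out = np.empty(m)
    out[order] = q
    return out


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_equals_quadratic_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 30))
            np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_pointwise_at_least_input(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(1e-6, 1, 100)
        assert np.all(bh_fdr(p) >= p)

    def test_empty_passthrough(self):
        assert len(bh_fdr([])) == 0


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                min_size=1, max_size=25))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_bh_fdr_oracle_property(pvalues):
    """BH adjustment equals the step-up oracle and never shrinks a p-value,
    for arbitrary valid inputs."""
    q = bh_fdr(pvalues)
    np.testing.assert_allclose(q, _bh_oracle(pvalues), atol=1e-12)
    assert np.all(q >= np.asarray(pvalues) - 1e-15)
    assert np.all(q <= 1.0 + 1e-15)
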