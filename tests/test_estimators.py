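"""Wald ratio, IVW, MR-Egger, Cochran's Q, and interval construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrkit.estimators import (
    cochran_q,
    egger,
    heterogeneity_pvalue,
    ivw,
    wald_inference,
    wald_ratio,
)
from mrkit.harmonization import HarmonizedPair
from conftest import make_pairs


def pair(vid, g, G, se_G=0.05, se_g=0.01):
    return HarmonizedPair(vid, g, se_g, G, se_G)


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(pair("v", 0.1, 0.2, se_G=0.05))
        assert est.beta_hat == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_negative_exposure_effect(self):
        est = wald_ratio(pair("v", -0.1, 0.2, se_G=0.05))
        assert est.beta_hat == pytest.approx(-2.0)
        assert est.se == pytest.approx(0.5)  # SE uses |gamma|

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(ZeroDivisionError, match="irrelevant"):
            wald_ratio(pair("v", 0.0, 0.2))

    def test_second_order_se_is_larger(self):
        p = pair("v", 0.1, 0.2, se_G=0.05, se_g=0.02)
        assert wald_ratio(p, second_order=True).se > wald_ratio(p).se

    def test_mean_recovers_truth_over_replicates(self):
        """Single strong instrument, no pleiotropy, beta = 0.5."""
        rng = np.random.default_rng(5)
        gamma, se_g, se_G, beta = 0.2, 0.005, 0.02, 0.5
        estimates = []
        for _ in range(2000):
            g_hat = gamma + rng.standard_normal() * se_g
            G_hat = beta * gamma + rng.standard_normal() * se_G
            estimates.append(wald_ratio(pair("v", g_hat, G_hat, se_G, se_g)).beta_hat)
        estimates = np.array(estimates)
        mcse = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - beta) < 3 * mcse


class TestIvw:
    def test_single_pair_equals_wald_ratio(self):
        p = pair("v", 0.1, 0.2)
        assert ivw([p]).beta_hat == pytest.approx(wald_ratio(p).beta_hat)

    def test_equal_weights_unit_gamma_is_plain_mean(self):
        pairs = [pair("a", 1.0, 0.4, se_G=0.1), pair("b", 1.0, 0.6, se_G=0.1)]
        assert ivw(pairs).beta_hat == pytest.approx(0.5)

    def test_equals_weighted_average_of_wald_ratios(self, rng):
        pairs = make_pairs(rng, 17)
        ratios = np.array([p.Gamma_hat / p.gamma_hat for p in pairs])
        weights = np.array([p.gamma_hat**2 / p.se_Gamma**2 for p in pairs])
        expected = float(np.sum(weights * ratios) / np.sum(weights))
        assert ivw(pairs).beta_hat == pytest.approx(expected, abs=1e-12)

    def test_matches_generic_wls_through_origin(self, rng):
        import statsmodels.api as sm

        pairs = make_pairs(rng, 17)
        g = np.array([p.gamma_hat for p in pairs])
        G = np.array([p.Gamma_hat for p in pairs])
        w = np.array([1 / p.se_Gamma**2 for p in pairs])
        fit = sm.WLS(G, g[:, None], weights=w).fit()
        assert abs(ivw(pairs).beta_hat - fit.params[0]) < 1e-10

    def test_fixed_and_random_share_the_point_estimate(self, rng):
        pairs = make_pairs(rng, 10, alpha=rng.normal(0, 0.05, 10))
        fixed, random = ivw(pairs, "fixed"), ivw(pairs, "random")
        assert fixed.beta_hat == random.beta_hat
        assert random.se >= fixed.se

    def test_random_se_floor_is_the_fixed_se(self, rng):
        # near-exact data: Q << df, so the overdispersion scale floors at 1
        pairs = [pair(f"v{i}", 0.1 + 0.01 * i, 0.05 + 0.005 * i, se_G=10.0) for i in range(5)]
        assert ivw(pairs, "random").se == pytest.approx(ivw(pairs, "fixed").se)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            ivw([])
        with pytest.raises(ValueError):
            ivw([pair("v", 0.1, 0.2)], "random")


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        gammas = [0.05, 0.1, 0.15, 0.2]
        pairs = [pair(f"v{i}", g, 0.1 + 0.5 * g) for i, g in enumerate(gammas)]
        est = egger(pairs)
        assert est.intercept == pytest.approx(0.1, abs=1e-12)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-12)
        q = cochran_q(pairs, est)
        assert q.Q == pytest.approx(0.0, abs=1e-18)
        assert q.pvalue == pytest.approx(1.0)

    def test_orients_exposure_effects_positive(self):
        gammas = [0.05, 0.1, 0.15, 0.2]
        pairs = [pair(f"v{i}", g, 0.1 + 0.5 * g) for i, g in enumerate(gammas)]
        flipped = [
            HarmonizedPair(p.variant_id, -p.gamma_hat, p.se_gamma, -p.Gamma_hat, p.se_Gamma)
            for p in pairs
        ]
        a, b = egger(pairs), egger(flipped)
        assert a.beta_hat == pytest.approx(b.beta_hat)
        assert a.intercept == pytest.approx(b.intercept)

    def test_constrained_intercept_reduces_to_ivw(self, rng):
        pairs = make_pairs(rng, 17)
        constrained = egger(pairs, constrain_intercept=True)
        reference = ivw(pairs)
        assert abs(constrained.beta_hat - reference.beta_hat) < 1e-10
        assert abs(constrained.se - reference.se) < 1e-10

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match="three"):
            egger([pair("a", 0.1, 0.05), pair("b", 0.2, 0.1)])

    def test_intercept_test_holds_its_size_under_no_pleiotropy(self):
        """Type-I error of the pleiotropy (intercept) test ~ 5%."""
        hits = 0
        n_rep = 500
        for r in range(n_rep):
            rng = np.random.default_rng(10_000 + r)
            pairs = make_pairs(rng, 30, se_gamma=1e-6)  # strong instruments
            hits += egger(pairs).intercept_pvalue < 0.05
        rate = hits / n_rep
        # 3 binomial SEs around 0.05 with n=500 is ~ +/- 0.029
        assert 0.02 < rate < 0.08

    def test_random_effect_inflates_both_ses(self, rng):
        pairs = make_pairs(rng, 12, alpha=rng.normal(0, 0.08, 12))
        fixed, random = egger(pairs, "fixed"), egger(pairs, "random")
        assert random.se >= fixed.se
        assert random.intercept_se >= fixed.intercept_se
        assert random.beta_hat == fixed.beta_hat


class TestCochranQ:
    def test_requires_fixed_effect_fit(self, rng):
        pairs = make_pairs(rng, 8)
        with pytest.raises(ValueError, match="fixed-effect"):
            cochran_q(pairs, ivw(pairs, "random"))

    def test_degrees_of_freedom_by_model(self, rng):
        pairs = make_pairs(rng, 8)
        assert cochran_q(pairs, ivw(pairs)).df == 7
        assert cochran_q(pairs, egger(pairs)).df == 6

    def test_df_error_when_underdetermined(self):
        pairs = [pair("a", 0.1, 0.05)]
        with pytest.raises(ValueError):
            cochran_q(pairs, ivw(pairs))

    def test_tail_probability_guards(self):
        with pytest.raises(ValueError):
            heterogeneity_pvalue(3.0, 0)


class TestWaldInference:
    def test_zero_estimate_symmetric_interval(self):
        lo, hi, p = wald_inference(0.0, 1.0, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(1.959964, abs=1e-5)
        assert p == pytest.approx(1.0)

    def test_t_interval_is_wider_than_normal(self):
        lo_n, hi_n, p_n = wald_inference(0.7, 0.29, 0.95)
        lo_t, hi_t, p_t = wald_inference(0.7, 0.29, 0.95, df=15)
        assert lo_t < lo_n and hi_t > hi_n and p_t > p_n

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            wald_inference(0.1, 0.0)
        with pytest.raises(ValueError):
            wald_inference(0.1, 0.1, level=1.0)
        with pytest.raises(ValueError):
            wald_inference(0.1, 0.1, df=0)


@given(
    c=st.floats(min_value=0.1, max_value=10.0, allow_nan=False),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_scale_equivariance(c, seed):
    """Rescaling the outcome (or exposure) units rescales beta, not p-values."""
    rng = np.random.default_rng(seed)
    pairs = make_pairs(rng, 8)
    base = ivw(pairs)
    out_scaled = [
        HarmonizedPair(p.variant_id, p.gamma_hat, p.se_gamma, c * p.Gamma_hat, c * p.se_Gamma)
        for p in pairs
    ]
    est = ivw(out_scaled)
    assert est.beta_hat == pytest.approx(c * base.beta_hat, rel=1e-9)
    assert est.pvalue == pytest.approx(base.pvalue, rel=1e-6)
    exp_scaled = [
        HarmonizedPair(p.variant_id, c * p.gamma_hat, c * p.se_gamma, p.Gamma_hat, p.se_Gamma)
        for p in pairs
    ]
    assert ivw(exp_scaled).beta_hat == pytest.approx(base.beta_hat / c, rel=1e-9)


@given(seed=st.integers(min_value=0, max_value=2**16))
def test_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    pairs = make_pairs(rng, 9, alpha=rng.normal(0, 0.02, 9))
    perm = list(pairs)
    rng.shuffle(perm)
    assert ivw(perm).beta_hat == pytest.approx(ivw(pairs).beta_hat, rel=1e-12)
    assert egger(perm).beta_hat == pytest.approx(egger(pairs).beta_hat, rel=1e-12)
    assert cochran_q(perm, ivw(perm)).Q == pytest.approx(cochran_q(pairs, ivw(pairs)).Q, rel=1e-12)
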