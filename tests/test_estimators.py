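import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen import cml_ma, ivw, mr_egger, wald_ratio, weighted_median
from mrscreen.estimators import (
    _cml_fit_K,
    _cml_profile_nll,
    _weighted_median_point,
    cml_bruteforce_K,
    egger_line_fit,
)
from mrscreen.harmonization import HarmonizedInstrument

from conftest import make_set


def one_instrument(bx, by, sy, sx=0.01):
    return HarmonizedInstrument(
        variant_id="rs1", effect_allele="A",
        beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy,
    )


class TestWaldRatio:
    def test_ratio_and_delta_se(self):
        est = wald_ratio(one_instrument(0.5, 0.2, 0.04))
        assert est.beta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.08)

    def test_null_outcome_effect(self):
        est = wald_ratio(one_instrument(0.5, 0.0, 0.04))
        assert est.beta == 0.0
        assert est.pval == 1.0

    def test_sign_symmetric(self):
        a = wald_ratio(one_instrument(0.5, 0.2, 0.04))
        b = wald_ratio(one_instrument(-0.5, -0.2, 0.04))
        assert a.beta == pytest.approx(b.beta)
        assert a.se == pytest.approx(b.se)

    def test_zero_exposure_beta_is_hard_error(self):
        with pytest.raises(ValueError):
            wald_ratio(one_instrument(0.0, 0.2, 0.04))


class TestIVW:
    def test_exact_three_snp_fixture(self, ivw_fixture_set):
        est = ivw(ivw_fixture_set)
        assert est.beta == pytest.approx(0.0945 / 0.4725)
        assert est.extras["cochran_q"] == pytest.approx(0.0, abs=1e-12)
        assert est.extras["re_scale"] == 1.0

    def test_duplicated_instrument_equals_wald_ratio(self):
        inst = one_instrument(0.5, 0.2, 0.04)
        dup = make_set([0.5, 0.5], [0.2, 0.2], 0.04)
        assert ivw(dup).beta == pytest.approx(wald_ratio(inst).beta)

    def test_fewer_than_two_instruments_is_hard_error(self):
        with pytest.raises(ValueError):
            ivw(make_set([0.5], [0.2], 0.04))

    def test_re_scale_never_deflates_se(self):
        # heterogeneous ratios: Q > J-1, so the SE must exceed fixed-effect
        hot = make_set([0.5, 0.4, 0.25], [0.30, 0.02, 0.10], 0.02)
        est = ivw(hot)
        assert est.extras["re_scale"] > 1.0

    def test_ci_brackets_estimate(self, ivw_fixture_set):
        est = ivw(ivw_fixture_set)
        assert est.ci_low <= est.beta <= est.ci_high


class TestEgger:
    def test_two_point_line_algebra(self):
        slope, intercept = egger_line_fit(
            np.array([0.2, 0.4]), np.array([0.05, 0.15]), np.array([1.0, 1.0])
        )
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(-0.05)

    def test_two_instruments_unavailable_in_pipeline(self):
        est = mr_egger(make_set([0.2, 0.4], [0.05, 0.15], 0.02))
        assert not est.available

    def test_no_pleiotropy_limit_matches_ivw(self):
        # data simulated with zero direct effects: intercept near 0 and
        # slope consistent with IVW
        rng = np.random.default_rng(4)
        J = 50
        bx = rng.uniform(0.2, 0.6, J)
        sy = np.full(J, 0.02)
        by = 0.3 * bx + rng.normal(0, 0.02, J)
        s = make_set(bx, by, sy)
        eg = mr_egger(s)
        assert eg.extras["intercept"] == pytest.approx(0.0, abs=0.02)
        assert eg.beta == pytest.approx(ivw(s).beta, abs=0.1)

    def test_exact_zero_intercept_slope_equals_ivw(self):
        # by exactly proportional to bx: intercept is 0 and both slope
        # estimators return the constant of proportionality
        s = make_set([0.2, 0.3, 0.5, 0.6], [0.08, 0.12, 0.20, 0.24], 0.02)
        eg = mr_egger(s)
        assert eg.extras["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert eg.beta == pytest.approx(ivw(s).beta, abs=1e-10)
        assert eg.beta == pytest.approx(0.4)

    def test_orientation_invariance(self):
        # flipping the reported allele of an instrument (both betas
        # negated) must not change the Egger fit
        s1 = make_set([0.2, 0.3, 0.5], [0.05, 0.1, 0.22], 0.02)
        s2 = make_set([-0.2, 0.3, 0.5], [-0.05, 0.1, 0.22], 0.02)
        assert mr_egger(s1).beta == pytest.approx(mr_egger(s2).beta)
        assert mr_egger(s1).extras["intercept"] == pytest.approx(
            mr_egger(s2).extras["intercept"]
        )


class TestWeightedMedian:
    def test_degenerate_identical_ratios(self):
        s = make_set([0.5, 0.4, 0.25], [0.15, 0.12, 0.075], 0.02)
        assert weighted_median(s, boot_reps=100, seed=0).beta == pytest.approx(0.3)

    def test_equal_weight_interpolation_lands_on_middle(self, ratio_set):
        assert weighted_median(ratio_set, boot_reps=100, seed=0).beta == pytest.approx(0.2)

    def test_fewer_than_three_unavailable(self):
        assert not weighted_median(make_set([0.5, 0.4], [0.1, 0.1], 0.02)).available

    def test_tracks_weighted_absolute_deviation_minimizer(self):
        # the weighted median targets the minimizer of
        # sum w |theta - ratio|; the exact grid argmin sits at an order
        # statistic while the estimator interpolates between the two
        # bracketing ones, so they must agree to within that bracket
        rng = np.random.default_rng(8)
        for _ in range(5):
            J = 9
            bx = rng.uniform(0.2, 0.6, J)
            by = rng.normal(0.3 * bx, 0.05)
            sy = rng.uniform(0.01, 0.05, J)
            ratios = by / bx
            w = (bx / sy) ** 2
            grid = np.linspace(ratios.min(), ratios.max(), 20001)
            obj = np.array([np.sum(w * np.abs(g - ratios)) for g in grid])
            argmin = grid[int(np.argmin(obj))]
            got = _weighted_median_point(ratios, w)
            r = np.sort(ratios)
            below = r[r <= got + 1e-12]
            above = r[r >= got - 1e-12]
            lo = below.max() if below.size else r[0]
            hi = above.min() if above.size else r[-1]
            assert lo - 1e-4 <= argmin <= hi + 1e-4
            assert abs(got - argmin) <= (hi - lo) + 1e-4

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_estimate_within_ratio_range(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(3, 12))
        bx = rng.uniform(0.1, 0.8, J)
        by = rng.normal(0, 0.2, J)
        sy = rng.uniform(0.01, 0.1, J)
        s = make_set(bx, by, sy)
        est = weighted_median(s, boot_reps=0)
        ratios = by / bx
        assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_bootstrap_se_reproducible(self, ratio_set):
        a = weighted_median(ratio_set, boot_reps=200, seed=5)
        b = weighted_median(ratio_set, boot_reps=200, seed=5)
        assert a.se == b.se


class TestCmlMA:
    def test_clean_data_selects_zero_invalid_and_matches_ivw(self, ivw_fixture_set):
        # tiny exposure SEs: profile likelihood reduces to fixed-effect
        # IVW, so theta must agree to 3 decimals
        est = cml_ma(ivw_fixture_set, seed=1)
        assert est.extras["k_hat"] == 0
        assert est.beta == pytest.approx(0.2, abs=1e-3)

    def test_contaminated_instruments_identified(self):
        rng = np.random.default_rng(3)
        J = 10
        bx = rng.uniform(0.2, 0.5, J)
        by = 0.3 * bx
        by[:3] += 0.5  # three large same-sign direct effects
        s = make_set(bx, by, 0.02, sx=0.01)
        est = cml_ma(s, seed=2)
        assert est.extras["k_hat"] == 3
        assert set(est.extras["invalid_at_k_hat"]) == {"rs000", "rs001", "rs002"}
        assert est.beta == pytest.approx(0.3, abs=0.02)

    def test_per_K_optimum_matches_bruteforce_enumeration(self):
        # exhaustive invalid-subset search at J = 7 is the oracle for
        # the block-coordinate fit
        rng = np.random.default_rng(12)
        J = 7
        bx = rng.uniform(0.2, 0.6, J)
        sx = np.full(J, 0.02)
        sy = np.full(J, 0.03)
        by = 0.25 * bx + rng.normal(0, 0.03, J)
        by[1] += 0.4
        grid = np.linspace(-1.0, 1.5, 2501)
        for K in range(0, 4):
            nll_bf, subset_bf, theta_bf = cml_bruteforce_K(bx, sx, by, sy, K, grid)
            theta, invalid, _ = _cml_fit_K(bx, sx, by, sy, K, theta0=0.25)
            nll = _cml_profile_nll(theta, bx, sx, by, sy, ~invalid)
            assert nll == pytest.approx(nll_bf, abs=1e-3)
            assert theta == pytest.approx(theta_bf, abs=2e-3)
            if K > 0:
                assert tuple(np.flatnonzero(invalid)) == subset_bf

    def test_bic_weights_sum_to_one(self, ivw_fixture_set):
        est = cml_ma(ivw_fixture_set, seed=0)
        assert np.sum(est.extras["bic_weights"]) == pytest.approx(1.0)

    def test_fewer_than_three_unavailable(self):
        assert not cml_ma(make_set([0.5, 0.4], [0.1, 0.1], 0.02)).available


class TestEquivariance:
    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 10.0), st.integers(0, 2**31 - 1))
    def test_outcome_scaling_scales_every_estimator(self, c, seed):
        rng = np.random.default_rng(seed)
        J = 8
        bx = rng.uniform(0.2, 0.6, J)
        by = rng.normal(0.3 * bx, 0.03)
        sy = rng.uniform(0.01, 0.05, J)
        base = make_set(bx, by, sy)
        scaled = make_set(bx, c * by, c * sy)
        assert ivw(scaled).beta == pytest.approx(c * ivw(base).beta)
        assert mr_egger(scaled).beta == pytest.approx(c * mr_egger(base).beta)
        assert weighted_median(scaled, boot_reps=0).beta == pytest.approx(
            c * weighted_median(base, boot_reps=0).beta
        )
        # cML-MA is a multi-restart local optimizer, so equivariance is
        # approximate: restart perturbations do not rescale with c
        assert cml_ma(scaled, seed=1).beta == pytest.approx(
            c * cml_ma(base, seed=1).beta, rel=2e-2
        )
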