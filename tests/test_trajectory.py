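import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abitraj import MMFit, MMParams, compare_params, fit_mm, mm_value, monte_carlo_band

POS = MMParams(-4.73, 11.56, 44.87)
NEG = MMParams(-3.01, 4.61, 91.99)
POS_SE = {"a": 2.47, "m": 1.49, "K": 33.73}
NEG_SE = {"a": 1.02, "m": 0.67, "K": 91.11}


def fit_from(params: MMParams, se: dict) -> MMFit:
    cov = np.diag([se["a"] ** 2, se["m"] ** 2, se["K"] ** 2])
    return MMFit(params=params, se=se, cov=cov, rss=0.0, n=100, converged=True)


class TestMMValue:
    def test_value_at_zero_is_baseline(self):
        assert mm_value(POS, 0.0) == pytest.approx(-4.73)

    def test_half_increment_at_K(self):
        assert mm_value(POS, 44.87) == pytest.approx(-4.73 + 11.56 / 2)
        assert mm_value(POS, 44.87) == pytest.approx(1.05)

    def test_saturating_limit(self):
        assert mm_value(POS, 1e12) == pytest.approx(POS.a + POS.m, rel=1e-9)

    def test_fractional_saturation_at_four_months(self):
        # 167 days into recovery the slow group's curve is ~64% saturated
        assert 167 / (NEG.K + 167) == pytest.approx(0.645, abs=0.005)

    @pytest.mark.parametrize("bad_t", [-1.0, -0.001])
    def test_negative_time_rejected(self, bad_t):
        with pytest.raises(ValueError):
            mm_value(POS, bad_t)

    @pytest.mark.parametrize("bad_K", [0.0, -5.0])
    def test_nonpositive_K_rejected(self, bad_K):
        with pytest.raises(ValueError):
            mm_value(MMParams(0, 1, bad_K), 1.0)

    @given(
        st.floats(0, 500),
        st.floats(0, 500),
        st.floats(-10, 10),
        st.floats(0.1, 20),
        st.floats(1.0, 300),
    )
    def test_nondecreasing_and_bounded_when_m_positive(self, t1, t2, a, m, K):
        p = MMParams(a, m, K)
        lo, hi = sorted((t1, t2))
        assert mm_value(p, lo) <= mm_value(p, hi) + 1e-12
        assert mm_value(p, hi) < a + m + 1e-12


class TestFitMM:
    def test_noiseless_recovery(self):
        t = np.array([1.0, 5, 10, 20, 50, 100, 200])
        y = mm_value(MMParams(1.0, 2.0, 10.0), t)
        fit = fit_mm(t, y)
        assert fit.params.a == pytest.approx(1.0, abs=1e-6)
        assert fit.params.m == pytest.approx(2.0, abs=1e-6)
        assert fit.params.K == pytest.approx(10.0, abs=1e-5)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_scores_flagged_degenerate(self):
        t = np.linspace(1, 100, 20)
        fit = fit_mm(t, np.full(20, 3.0))
        assert fit.degenerate
        assert fit.params.a == pytest.approx(3.0, abs=1e-6)
        assert abs(fit.params.m) < 1e-6

    def test_explicit_init_is_honoured(self):
        t = np.array([1.0, 5, 10, 20, 50, 100, 200])
        y = mm_value(MMParams(1.0, 2.0, 10.0), t)
        fit = fit_mm(t, y, init=MMParams(0.5, 1.0, 20.0))
        assert fit.n_starts == 1
        assert fit.params.K == pytest.approx(10.0, abs=1e-4)

    def test_multistart_never_worse_than_single_start(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(1, 300, 60)
        y = mm_value(NEG, t) + rng.normal(0, 1.5, 60)
        multi = fit_mm(t, y)
        single = fit_mm(t, y, init=MMParams(float(y.mean()), 1.0, 50.0))
        assert multi.rss <= single.rss + 1e-8

    def test_covariance_symmetric_psd_and_se_consistent(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(1, 400, 100)
        y = mm_value(POS, t) + rng.normal(0, 1.0, 100)
        fit = fit_mm(t, y)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert (np.linalg.eigvalsh(fit.cov) > -1e-10).all()
        for i, name in enumerate(("a", "m", "K")):
            assert fit.se[name] == pytest.approx(np.sqrt(fit.cov[i, i]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 observations"):
            fit_mm([1, 2, 3], [0.1, 0.2, 0.3])

    def test_zero_time_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            fit_mm([5, 5, 5, 5], [1, 2, 3, 4])

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        t = rng.uniform(1, 300, 50)
        y = mm_value(NEG, t) + rng.normal(0, 1, 50)
        fit = fit_mm(t, y)
        fit.to_json(tmp_path / "fit.json")
        back = MMFit.from_json(tmp_path / "fit.json")
        assert back.params == fit.params
        np.testing.assert_allclose(back.cov, fit.cov)


class TestCompareParams:
    def test_baseline_not_significant(self):
        _, p = compare_params(fit_from(POS, POS_SE), fit_from(NEG, NEG_SE), "a")
        assert p == pytest.approx(0.52, abs=0.005)

    def test_half_time_not_significant(self):
        _, p = compare_params(fit_from(POS, POS_SE), fit_from(NEG, NEG_SE), "K")
        assert p == pytest.approx(0.63, abs=0.005)

    def test_max_increment_strongly_significant(self):
        z, p = compare_params(fit_from(POS, POS_SE), fit_from(NEG, NEG_SE), "m")
        assert z > 4
        assert p < 0.001

    def test_identical_fits_give_p_one(self):
        f = fit_from(POS, POS_SE)
        z, p = compare_params(f, f, "a")
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            compare_params(fit_from(POS, POS_SE), fit_from(NEG, NEG_SE), "Vmax")


class TestMonteCarloBand:
    def test_zero_covariance_collapses_to_point(self):
        fit = MMFit(POS, {"a": 0, "m": 0, "K": 0}, np.zeros((3, 3)), 0, 50, True)
        band = monte_carlo_band(fit, np.linspace(0, 300, 31), 500, seed=1)
        np.testing.assert_allclose(band.lower, band.point, atol=1e-12)
        np.testing.assert_allclose(band.upper, band.point, atol=1e-12)

    def test_width_at_zero_matches_delta_method(self):
        # at t=0 the curve equals a, so the band halfwidth is ~1.96 SE(a)
        se = {"a": 0.8, "m": 0.5, "K": 5.0}
        fit = fit_from(MMParams(-3.0, 4.0, 50.0), se)
        band = monte_carlo_band(fit, np.array([0.0, 100.0]), 100_000, seed=2)
        width0 = band.upper[0] - band.lower[0]
        assert width0 == pytest.approx(2 * 1.96 * se["a"], rel=0.02)

    def test_deterministic_given_seed(self):
        fit = fit_from(NEG, NEG_SE)
        b1 = monte_carlo_band(fit, np.arange(0, 200.0, 5), 2000, seed=9)
        b2 = monte_carlo_band(fit, np.arange(0, 200.0, 5), 2000, seed=9)
        np.testing.assert_array_equal(b1.lower, b2.lower)
        np.testing.assert_array_equal(b1.upper, b2.upper)

    def test_band_brackets_point_prediction(self):
        fit = fit_from(NEG, NEG_SE)
        band = monte_carlo_band(fit, np.arange(0, 600.0, 10), 3000, seed=4)
        assert (band.lower <= band.point).all()
        assert (band.point <= band.upper).all()

    def test_negative_K_draws_are_redrawn(self):
        fit = fit_from(NEG, NEG_SE)  # SE(K) = 91 >> K: many draws below zero
        band = monte_carlo_band(fit, np.array([10.0, 50.0]), 2000, seed=5)
        assert band.n_redrawn > 0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_level_bounds(self, bad):
        with pytest.raises(ValueError):
            monte_carlo_band(fit_from(POS, POS_SE), np.array([0.0, 1.0]), 100, level=bad)

    def test_band_width_shrinks_with_sample_size(self):
        """More data -> tighter confidence band, on average."""
        rng = np.random.default_rng(11)
        widths = []
        for n in (40, 400):
            t = rng.uniform(1, 400, n)
            y = mm_value(NEG, t) + rng.normal(0, 1.5, n)
            fit = fit_mm(t, y)
            band = monte_carlo_band(fit, np.array([30.0, 100.0, 250.0]), 4000, seed=n)
            widths.append((band.upper - band.lower).mean())
        assert widths[1] < widths[0]
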