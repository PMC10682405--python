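"""Thermal performance fitting: quadratic, segmented, Davies' test, T_pref, IQR."""

import numpy as np
import pandas as pd
import pytest

from otofmr import tpc
from otofmr.tpc import (
    QuadraticThermalModel,
    SegmentedThermalModel,
    davies_test,
    fit_quadratic,
    fit_segmented,
    fit_thermal_performance,
    iqr_curve,
    modal_temperature,
    summarize_replicates,
)


def piecewise(t, b0=0.30, b1=0.007, psi=28.0, slope_high=-0.012):
    return b0 + b1 * t + (slope_high - b1) * np.maximum(t - psi, 0.0)


class TestQuadratic:
    def test_symmetric_parabola_vertex(self):
        t = np.linspace(20, 36, 60)
        y = -((t - 28.0) ** 2)
        fit = fit_quadratic(t, y)
        assert fit.vertex_ == pytest.approx(28.0, abs=1e-8)
        assert fit.vertex_interior_

    def test_exact_coefficient_recovery(self):
        t = np.linspace(18, 34, 40)
        c0, c1, c2 = 0.2, 0.04, -0.0008
        y = c0 + c1 * t + c2 * t**2
        fit = fit_quadratic(t, y)
        assert np.allclose(fit.coef_, [c0, c1, c2], atol=1e-8)
        assert fit.rss_ == pytest.approx(0.0, abs=1e-12)

    def test_linear_data_flags_non_interior_vertex(self):
        t = np.linspace(20, 30, 50)
        fit = fit_quadratic(t, 0.1 + 0.01 * t)
        assert abs(fit.coef_[2]) < 1e-10
        assert not fit.vertex_interior_

    def test_degenerate_design_raises(self):
        with pytest.raises(ValueError):
            fit_quadratic(np.full(10, 25.0), np.random.default_rng(0).normal(size=10))

    def test_sklearn_contract(self):
        m = QuadraticThermalModel()
        params = m.get_params()
        assert isinstance(params, dict)
        t = np.linspace(20, 30, 30)
        y = 0.5 - 0.001 * (t - 26) ** 2
        m.fit(t[:, None], y)
        assert np.allclose(m.predict(t[:, None]), y, atol=1e-8)


class TestSegmented:
    def test_noise_free_exact_recovery(self):
        t = np.linspace(22, 32, 400)
        y = piecewise(t)
        fit = fit_segmented(t, y)
        assert fit.has_breakpoint_
        assert fit.breakpoint_ == pytest.approx(28.0, abs=1e-3)
        assert fit.slope_low_ == pytest.approx(0.007, abs=1e-5)
        assert fit.slope_high_ == pytest.approx(-0.012, abs=1e-5)
        assert fit.rss_ <= fit.rss_linear_

    def test_exact_linear_data_collapses_to_line(self):
        t = np.linspace(20, 32, 200)
        fit = fit_segmented(t, 0.3 + 0.007 * t)
        assert not fit.has_breakpoint_
        assert np.isnan(fit.breakpoint_)
        assert fit.slope_low_ == pytest.approx(0.007, abs=1e-8)

    def test_noisy_linear_data_gives_no_evidence_for_break(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(20, 32, 500)
        y = 0.3 + 0.007 * t + rng.normal(0, 0.02, t.size)
        fit = fit_segmented(t, y)
        # any spurious breakpoint barely improves the fit, and Davies' p is not small
        assert fit.rss_ > 0.97 * fit.rss_linear_
        assert davies_test(t, y) > 0.01

    def test_segmented_rss_never_exceeds_linear(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = rng.uniform(20, 32, 120)
            y = piecewise(t) + rng.normal(0, 0.03, t.size)
            fit = fit_segmented(t, y)
            assert fit.rss_ <= fit.rss_linear_ + 1e-12

    def test_grid_matches_exhaustive_midpoint_oracle(self):
        """Grid-profiled breakpoint agrees with brute-force search over all
        interior data-interval midpoints, to within the grid step."""
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(22, 32, 150))
        y = piecewise(t) + rng.normal(0, 0.01, t.size)
        fit = fit_segmented(t, y, grid_step=0.05)

        uniq = np.unique(t)
        mids = (uniq[:-1] + uniq[1:]) / 2
        lo, hi = np.percentile(t, [5, 95])
        mids = mids[(mids >= lo) & (mids <= hi)]
        rss = [tpc._segmented_rss(t, y, m)[0] for m in mids]
        best = mids[int(np.argmin(rss))]
        assert abs(fit.breakpoint_ - best) <= 0.1

    def test_recovery_on_synthetic_cohort(self, recovery_cohort):
        from otofmr.proxies import central_estimates

        records, _ = recovery_cohort
        est = central_estimates(records)
        fit = fit_segmented(est["temperature"], est["c_resp"])
        assert fit.breakpoint_ == pytest.approx(28.0, abs=0.5)
        assert fit.slope_low_ > 0 > fit.slope_high_

    def test_estimator_params_round_trip(self):
        m = SegmentedThermalModel(grid_step=0.1, min_side=4)
        assert m.get_params() == {"grid_step": 0.1, "min_side": 4}
        m.set_params(grid_step=0.2)
        assert m.grid_step == 0.2


class TestDavies:
    def test_strong_break_tiny_p(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(22, 32, 2000)
        y = piecewise(t, slope_high=-0.013) + rng.normal(0, 0.005, t.size)
        assert davies_test(t, y) < 1e-6

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        t = rng.uniform(20, 30, 300)
        y = piecewise(t) + rng.normal(0, 0.02, t.size)
        assert davies_test(t, y) == davies_test(t, y)

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError):
            davies_test(np.full(50, 25.0), np.linspace(0, 1, 50))
        with pytest.raises(ValueError):
            davies_test(np.linspace(20, 30, 50), np.full(50, 0.5))

    def test_p_tracks_rss_improvement(self):
        """Small Davies' p goes with a large segmented-over-linear RSS gain."""
        rng = np.random.default_rng(6)
        t = rng.uniform(22, 32, 800)
        gains, ps = [], []
        for beta2 in (0.0, -0.005, -0.02):
            y = 0.3 + 0.007 * t + beta2 * np.maximum(t - 27, 0) + rng.normal(0, 0.02, t.size)
            fit = fit_segmented(t, y)
            gains.append(1 - fit.rss_ / fit.rss_linear_)
            ps.append(davies_test(t, y))
        assert gains[2] > gains[1] > gains[0] - 1e-9
        assert ps[2] < ps[1] <= 1.0


class TestModalTemperature:
    def test_constant_sample(self):
        t = np.full(100, 26.0) + np.random.default_rng(0).normal(0, 1e-9, 100)
        assert modal_temperature(t) == pytest.approx(26.0, abs=0.05)

    def test_normal_sample_mode(self):
        t = np.random.default_rng(1).normal(25.5, 1.0, 20000)
        assert modal_temperature(t) == pytest.approx(25.5, abs=0.2)

    def test_bimodal_dominant_mass(self):
        rng = np.random.default_rng(2)
        t = np.concatenate([rng.normal(26, 0.5, 7000), rng.normal(29, 0.5, 3000)])
        assert modal_temperature(t) == pytest.approx(26.0, abs=0.3)

    def test_small_sample_raises(self):
        with pytest.raises(ValueError, match="histogram"):
            modal_temperature(np.linspace(20, 30, 10))


class TestIqrCurve:
    def test_max_bin_identified(self):
        rng = np.random.default_rng(3)
        temps, cresp = [], []
        for b in (25, 26, 27, 28):
            n = 100
            temps.append(np.full(n, float(b)))
            spread = 0.06 if b == 27 else 0.02
            cresp.append(0.5 + rng.uniform(-spread / 2, spread / 2, n))
        curve = iqr_curve(np.concatenate(temps), np.concatenate(cresp))
        assert curve.attrs["t_iqr_max"] == 27

    def test_small_bins_excluded(self):
        t = np.concatenate([np.full(10, 24.0), np.full(40, 26.0)])
        c = np.linspace(0.3, 0.7, 50)
        curve = iqr_curve(t, c, min_n=15)
        assert 24 not in set(curve["t_bin"])
        assert 26 in set(curve["t_bin"])

    def test_boundary_is_strict(self):
        # exactly min_n observations is not enough ("more than 15")
        t = np.full(15, 25.0)
        c = np.linspace(0, 1, 15)
        assert len(iqr_curve(t, c, min_n=15)) == 0
        t16 = np.full(16, 25.0)
        c16 = np.linspace(0, 1, 16)
        assert len(iqr_curve(t16, c16, min_n=15)) == 1

    def test_constant_cresp_ties_break_low(self):
        t = np.concatenate([np.full(20, 25.0), np.full(20, 28.0)])
        c = np.full(40, 0.5)
        curve = iqr_curve(t, c)
        assert (curve["iqr"] == 0).all()
        assert curve.attrs["t_iqr_max"] == 25

    def test_empty_curve_when_no_bin_qualifies(self):
        curve = iqr_curve(np.linspace(20, 30, 12), np.linspace(0, 1, 12))
        assert len(curve) == 0
        assert np.isnan(curve.attrs["t_iqr_max"])

    def test_rounding_half_away_from_zero(self):
        t = np.full(20, 26.5)
        curve = iqr_curve(t, np.linspace(0, 1, 20))
        assert set(curve["t_bin"]) == {27}


class TestSummaries:
    def test_identical_replicates_zero_sd(self):
        reps = pd.DataFrame({"t_pref": [25.5] * 4, "breakpoint_T": [28.0] * 4})
        summary = summarize_replicates(reps)
        assert summary.loc["sd", "t_pref"] == 0
        assert summary.loc["mean", "breakpoint_T"] == 28.0

    def test_two_replicate_arithmetic(self):
        reps = pd.DataFrame({"breakpoint_T": [27.0, 29.0]})
        summary = summarize_replicates(reps)
        assert summary.loc["mean", "breakpoint_T"] == pytest.approx(28.0)
        assert summary.loc["sd", "breakpoint_T"] == pytest.approx(np.sqrt(2.0))

    def test_zscored_curves_are_standardised(self):
        grid = np.arange(20.0, 30.0, 0.5)
        curves = {"density": pd.DataFrame({"t": grid, "v": np.exp(-((grid - 25) ** 2))})}
        _, z = summarize_replicates(
            pd.DataFrame({"t_pref": [25.0, 25.5]}), curves=curves
        )
        vals = z["density"]["z"].to_numpy()
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates(pd.DataFrame({"t_pref": [25.0]}))


def test_vertex_and_breakpoint_agree_on_smooth_truth():
    """On a noise-free concave parabola both T_lim estimators land close."""
    t = np.linspace(22, 33, 500)
    y = 0.5 - 0.002 * (t - 28.0) ** 2
    quad = fit_quadratic(t, y)
    seg = fit_segmented(t, y)
    assert abs(quad.vertex_ - 28.0) < 1e-6
    assert abs(seg.breakpoint_ - quad.vertex_) < 1.5


def test_combined_fit_record(recovery_cohort):
    from otofmr.proxies import central_estimates

    records, _ = recovery_cohort
    est = central_estimates(records)
    fit = fit_thermal_performance(est["temperature"], est["c_resp"])
    assert fit.n == len(records)
    assert fit.rss_segmented <= fit.rss_linear
    assert fit.davies_p < 1e-6
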