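"""LOWESS smoothing, rate extraction, threshold crossing and current
integration, checked against closed forms and a brute-force weighted
least-squares oracle."""

import numpy as np
import pytest

from phenox import kinetics as kin
from phenox.kinetics import NOT_DETECTED, OxidationCurve


def brute_force_lowess(t, f, fraction):
    """Independent per-point tricube weighted-least-squares oracle.

    Neighbor sets by stable sort on |t - t_i| (ties fall to earlier
    points); scaling by the neighbor-window span; normal-equations fit.
    """
    n = len(t)
    k = int(np.ceil(fraction * n))
    smoothed = np.empty(n)
    slopes = np.empty(n)
    for i in range(n):
        idx = np.argsort(np.abs(t - t[i]), kind="stable")[:k]
        dt = t[idx] - t[i]
        span = np.abs(dt).max()
        w = (1 - np.abs(dt / span) ** 3) ** 3 if span > 0 else np.ones(k)
        if np.count_nonzero(w) < 2:
            w = np.ones(k)  # degenerate window: unweighted fit
        X = np.column_stack([np.ones(k), dt])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ f[idx])
        smoothed[i], slopes[i] = beta
    return smoothed, slopes


class TestLowess:
    def test_exact_on_linear_input(self):
        t = np.linspace(0, 10, 40)
        f = 500.0 - 10.0 * t
        for fraction in (0.1, 0.3, 1.0):
            fit = kin.lowess_smooth(OxidationCurve(t, f), fraction)
            np.testing.assert_allclose(fit.smoothed, f, rtol=1e-10)
            np.testing.assert_allclose(fit.slopes, -10.0, rtol=1e-10)

    def test_constant_input(self):
        t = np.linspace(0, 5, 20)
        fit = kin.lowess_smooth(OxidationCurve(t, np.full(20, 7.0)), 0.5)
        np.testing.assert_allclose(fit.smoothed, 7.0)
        np.testing.assert_allclose(fit.slopes, 0.0, atol=1e-12)

    def test_fraction_one_quadratic_matches_oracle(self):
        t = np.linspace(0, 8, 30)
        f = 100 + 5 * t - 0.8 * t**2
        fit = kin.lowess_smooth(OxidationCurve(t, f), 1.0)
        sm, sl = brute_force_lowess(t, f, 1.0)
        np.testing.assert_allclose(fit.smoothed, sm, atol=1e-8)
        np.testing.assert_allclose(fit.slopes, sl, atol=1e-8)

    @pytest.mark.parametrize("n", [3, 7, 12, 25, 50])
    @pytest.mark.parametrize("uniform", [True, False])
    def test_matches_oracle_random_instances(self, n, uniform, rng):
        """Exhaustive neighbor-set equivalence across window sizes."""
        t = (np.linspace(0, 12, n) if uniform
             else np.sort(rng.uniform(0, 12, n)))
        f = np.abs(rng.normal(500, 100, n))
        for k in {2, 3, max(2, n // 2), n}:
            fraction = k / n
            fit = kin.lowess_smooth(OxidationCurve(t, f), fraction)
            sm, sl = brute_force_lowess(t, f, fraction)
            np.testing.assert_allclose(fit.smoothed, sm, atol=1e-8)
            np.testing.assert_allclose(fit.slopes, sl, atol=1e-8)

    def test_matches_statsmodels_at_full_window(self, rng):
        """Cross-check fitted values against an independent LOWESS
        implementation where the window conventions coincide."""
        statsmodels = pytest.importorskip("statsmodels.api")
        t = np.sort(rng.uniform(0, 10, 40))
        f = 300 * np.exp(-0.2 * t) + rng.normal(0, 5, 40)
        fit = kin.lowess_smooth(OxidationCurve(t, np.abs(f)), 1.0)
        ref = statsmodels.nonparametric.lowess(
            np.abs(f), t, frac=1.0, it=0, return_sorted=False)
        np.testing.assert_allclose(fit.smoothed, ref, atol=1e-6)

    def test_parameter_errors(self):
        t = np.linspace(0, 5, 10)
        curve = OxidationCurve(t, np.full(10, 5.0))
        with pytest.raises(kin.ParameterError):
            kin.lowess_smooth(curve, 0.0)
        with pytest.raises(kin.ParameterError):
            kin.lowess_smooth(curve, 1.5)
        with pytest.raises(kin.ParameterError):
            kin.lowess_smooth(curve, 0.05)  # ceil(0.5) = 1 neighbor

    def test_robustness_iterations_downweight_outlier(self):
        t = np.linspace(0, 10, 60)
        f = 400.0 - 20.0 * t
        f = np.clip(f, 0, None)
        f[30] += 150.0  # spike
        plain = kin.lowess_smooth(OxidationCurve(t, f), 0.4, iterations=0)
        robust = kin.lowess_smooth(OxidationCurve(t, f), 0.4, iterations=2)
        true = 400.0 - 20.0 * t[30]
        assert abs(robust.smoothed[30] - true) < abs(plain.smoothed[30] - true)


class TestCurveValidation:
    def test_rejects_bad_inputs(self):
        with pytest.raises(kin.ParameterError):
            OxidationCurve(np.array([0, 1]), np.array([1.0, 2.0]))
        with pytest.raises(kin.ParameterError):
            OxidationCurve(np.array([0, 1, 1]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(kin.ParameterError):
            OxidationCurve(np.array([0, 1, 2]), np.array([1.0, -2.0, 3.0]))

    def test_drops_nonfinite_points(self):
        t = np.linspace(0, 5, 10)
        f = np.full(10, 3.0)
        f[4] = np.nan
        curve = OxidationCurve(t, f)
        assert len(curve) == 9


class TestRateSeries:
    def test_sign_convention_on_decay(self):
        t = np.linspace(0, 10, 50)
        fit = kin.lowess_smooth(OxidationCurve(t, 600.0 - 10.0 * t), 0.3)
        np.testing.assert_allclose(kin.oxidation_rate_series(fit), 10.0, rtol=1e-9)

    def test_rising_curve_negative_rates(self):
        t = np.linspace(0, 10, 50)
        fit = kin.lowess_smooth(OxidationCurve(t, 100.0 + 10.0 * t), 0.3)
        assert np.all(kin.oxidation_rate_series(fit) < 0)


class TestExtractMetrics:
    def test_exponential_half_life_closed_form(self, t_grid):
        k = 0.3
        f = 1000.0 * np.exp(-k * t_grid)
        # decay starts at t=0, so the first point is the 100% anchor
        res = kin.extract_metrics(OxidationCurve(t_grid, f), fraction=0.05,
                                  baseline_points=1)
        assert res.t_half == pytest.approx(np.log(2) / k, abs=0.25)

    def test_lagged_exponential_half_life(self, t_grid):
        from phenox import synthetic_data as sd
        p = sd.CurveParams(lag_h=5.0, lag_transition_h=0.0, k_fast=0.3,
                           fast_weight=1.0, floor_frac=0.0)
        # closed form: half of the decayable signal gone at lag + ln2/k
        t_star = 5.0 + np.log(2) / 0.3
        assert p.expectation(np.array([t_star]))[0] == pytest.approx(500.0, rel=1e-9)
        res = kin.extract_metrics(OxidationCurve(t_grid, p.expectation(t_grid)))
        assert res.t_half == pytest.approx(t_star, abs=0.25)

    def test_not_detected_when_threshold_not_reached(self, t_grid):
        f = 1000.0 * (0.7 + 0.3 * np.exp(-0.1 * t_grid))  # floors at 70%
        res = kin.extract_metrics(OxidationCurve(t_grid, f), threshold=0.5)
        assert res.t_half is NOT_DETECTED
        assert res.t_half is not None and res.t_half != 0.0

    def test_pure_rise_negative_rate_and_nd(self, t_grid):
        f = 500.0 + 8.0 * t_grid
        res = kin.extract_metrics(OxidationCurve(t_grid, f))
        assert res.max_oxidation_rate < 0
        assert res.t_half is NOT_DETECTED

    def test_rescaling_invariance(self, t_grid, fast_params):
        f = fast_params.expectation(t_grid)
        base = kin.extract_metrics(OxidationCurve(t_grid, f))
        scaled = kin.extract_metrics(OxidationCurve(t_grid, 3.5 * f))
        assert scaled.t_half == pytest.approx(base.t_half, rel=1e-9)
        assert scaled.max_oxidation_rate == pytest.approx(
            3.5 * base.max_oxidation_rate, rel=1e-9)

    def test_baseline_error(self):
        t = np.linspace(0, 5, 10)
        with pytest.raises(kin.BaselineError):
            kin.extract_metrics(OxidationCurve(t, np.zeros(10)), fraction=0.5)


class TestScanFraction:
    def test_linear_decay_invariant_across_fractions(self, t_grid):
        f = np.clip(800.0 - 12.0 * t_grid, 1.0, None)[:150]
        curve = OxidationCurve(t_grid[:150], f)
        table = kin.scan_fraction(curve, [0.05, 0.1, 0.3, 0.6, 1.0])
        np.testing.assert_allclose(table["max_rate"], 12.0, rtol=1e-6)

    def test_single_fraction_matches_extract(self, t_grid, fast_params):
        curve = OxidationCurve(t_grid, fast_params.expectation(t_grid))
        row = kin.scan_fraction(curve, [0.05]).iloc[0]
        res = kin.extract_metrics(curve, fraction=0.05)
        assert row["max_rate"] == res.max_oxidation_rate
        assert row["t_half"] == res.t_half

    def test_failures_recorded_not_raised(self, t_grid, fast_params):
        curve = OxidationCurve(t_grid, fast_params.expectation(t_grid))
        table = kin.scan_fraction(curve, [0.003, 0.05])
        assert table.loc[0, "error"] != ""
        assert table.loc[1, "error"] == ""

    def test_smoothing_attenuates_peaks_over_seeds(self, fast_params):
        """Trend over seeds: heavy smoothing lowers the apparent max rate
        relative to the plateau window."""
        from phenox import synthetic_data as sd
        t = sd.default_t_grid()
        rates = {0.05: [], 0.25: [], 0.6: []}
        for seed in range(20):
            f = sd.generate_curve(fast_params, t, sd.NoiseModel(seed=seed))
            curve = OxidationCurve(t, f)
            for frac in rates:
                rates[frac].append(
                    kin.extract_metrics(curve, fraction=frac).max_oxidation_rate)
        means = {frac: np.mean(v) for frac, v in rates.items()}
        assert means[0.05] > means[0.25] > means[0.6]


class TestSummarizeReplicates:
    def test_identical_technical_wells_collapse(self, t_grid, fast_params):
        from phenox import synthetic_data as sd
        design = [sd.PlateEntry("wt", fast_params, n_bio=1, n_tech=3)]
        plate, _ = sd.generate_plate(design, t_grid,
                                     noise=sd.NoiseModel(cv=0, sd=0),
                                     seed=0, bio_jitter=0.0)
        out = kin.summarize_replicates(plate)
        single = kin.extract_metrics(
            OxidationCurve(t_grid, fast_params.expectation(t_grid)))
        assert len(out) == 1
        assert out.loc[0, "max_rate"] == pytest.approx(
            single.max_oxidation_rate, rel=1e-12)

    def test_row_count_two_strains(self, t_grid, recovery_design):
        from phenox import synthetic_data as sd
        plate, _ = sd.generate_plate(recovery_design, t_grid, seed=3)
        out = kin.summarize_replicates(plate)
        assert len(out) == 6  # 2 strains x 3 biological replicates

    def test_abiotic_group_passes_through(self, t_grid):
        from phenox import synthetic_data as sd
        design = [sd.PlateEntry("abiotic", sd.default_abiotic_params(),
                                n_bio=2, n_tech=1, kind="abiotic")]
        plate, _ = sd.generate_plate(design, t_grid, seed=1)
        out = kin.summarize_replicates(plate)
        assert set(out["strain"]) == {"abiotic"}
        assert len(out) == 2


class TestIntegrateCurrent:
    def test_hand_arithmetic_constant_current(self):
        t = np.linspace(0, 2, 200)
        charge, moles = kin.integrate_current(t, np.full(200, 10.0))
        assert charge == pytest.approx(0.072, rel=1e-9)
        assert moles == pytest.approx(3.731e-7, rel=1e-3)

    def test_zero_current(self):
        t = np.linspace(0, 5, 50)
        assert kin.integrate_current(t, np.zeros(50)) == (0.0, 0.0)

    def test_refinement_consistency(self):
        # piecewise-linear trace: adding midpoints must not change the
        # trapezoidal integral
        t = np.linspace(0, 10, 201)
        i = np.clip(20.0 - 2.5 * t, 0.0, None)
        t2 = np.linspace(0, 10, 401)
        i2 = np.clip(20.0 - 2.5 * t2, 0.0, None)
        c1, _ = kin.integrate_current(t, i)
        c2, _ = kin.integrate_current(t2, i2)
        assert abs(c1 - c2) < 1e-9

    def test_smooth_trace_refinement_converges(self):
        t = np.linspace(0, 10, 201)
        t2 = np.linspace(0, 10, 401)
        c1, _ = kin.integrate_current(t, 20 * np.exp(-0.3 * t))
        c2, _ = kin.integrate_current(t2, 20 * np.exp(-0.3 * t2))
        assert abs(c1 - c2) < 1e-5
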