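"""Slope fitting, tracer-dilution correction and detection limits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ureanox import (
    SimConfig,
    SubstratePool,
    TimeCourse,
    detection_limit,
    fit_time_course,
    n2o_production_rate,
    nitrite_production_rate,
    simulate_incubation,
)
from ureanox.rate_estimation import InsufficientDesignError, LOW_LABEL_FLOOR


def make_tc(times, no2, reps=None, F=0.1, substrate="ammonium", n2o45=None, n2o46=None):
    times = list(times)
    n = len(times)
    reps = reps or ["b1"] * n
    tracer = 1.0 * (F - 0.003663) / (0.99 - F)
    pool = SubstratePool(substrate, ambient_conc=1.0, tracer_conc=tracer)
    points = pd.DataFrame(
        {
            "time_h": times,
            "replicate_id": reps,
            "n2o44": [10.0] * n,
            "n2o45": n2o45 if n2o45 is not None else [0.0] * n,
            "n2o46": n2o46 if n2o46 is not None else [0.0] * n,
            "no2_15N": no2,
        }
    )
    return TimeCourse("T1", 5.0, substrate, "in_situ", pool, points)


class TestFitTimeCourse:
    def test_exact_line_slope_per_day(self):
        tc = make_tc([0, 4, 8, 12], [0.0, 1.0, 2.0, 3.0])
        fit = fit_time_course(tc, "no2_15N")
        assert fit.slope == pytest.approx(6.0, abs=1e-12)  # 0.25 nM/h → 6 nM/d
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_pooled_duplicates_match_closed_form_ols(self):
        """Duplicate bottles enter as independent points; slope and SE must
        equal the closed-form OLS solution on the pooled design."""
        rng = np.random.default_rng(3)
        times = [0, 0, 4, 4, 8, 8, 12, 12]
        y = [0.1 * t / 24 + rng.normal(0, 0.05) for t in times]
        tc = make_tc(times, y, reps=["b1", "b2"] * 4)
        fit = fit_time_course(tc, "no2_15N")
        x = np.array(times) / 24.0
        xm, ym = x.mean(), np.mean(y)
        sxx = np.sum((x - xm) ** 2)
        slope = np.sum((x - xm) * (y - ym)) / sxx
        resid = y - (ym + slope * (x - xm))
        se = np.sqrt(np.sum(resid**2) / (len(x) - 2) / sxx)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.slope_se == pytest.approx(se, rel=1e-10)
        assert fit.n == 8

    def test_duplicate_identical_values_same_slope(self):
        single = make_tc([0, 4, 8, 12], [0.0, 1.0, 2.0, 3.0])
        double = make_tc(
            [0, 0, 4, 4, 8, 8, 12, 12],
            [0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
            reps=["b1", "b2"] * 4,
        )
        f1 = fit_time_course(single, "no2_15N")
        f2 = fit_time_course(double, "no2_15N")
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)

    def test_excess_series_combines_masses(self):
        tc = make_tc(
            [0, 4, 8, 12],
            [0.0] * 4,
            n2o45=[0.0, 0.09, 0.18, 0.27],
            n2o46=[0.0, 0.005, 0.01, 0.015],
        )
        fit = fit_time_course(tc, "n2o_excess")
        # excess = 45 + 2·46 accumulates 0.1 per 4 h → 0.6 per day
        assert fit.slope == pytest.approx(0.6, abs=1e-12)

    def test_insufficient_design(self):
        with pytest.raises(InsufficientDesignError):
            make_tc([0, 0], [0.0, 0.1], reps=["b1", "b2"])

    def test_row_order_and_replicate_labels_irrelevant(self):
        times = [0, 4, 8, 12, 0, 4, 8, 12]
        y = [0.0, 1.1, 1.9, 3.2, 0.1, 0.9, 2.1, 2.8]
        tc1 = make_tc(times, y, reps=["a"] * 4 + ["b"] * 4)
        order = [7, 2, 5, 0, 3, 6, 1, 4]
        tc2 = make_tc(
            [times[i] for i in order],
            [y[i] for i in order],
            reps=["x"] * 8,
        )
        f1, f2 = fit_time_course(tc1, "no2_15N"), fit_time_course(tc2, "no2_15N")
        assert f1.slope == pytest.approx(f2.slope, rel=1e-12)
        assert f1.slope_se == pytest.approx(f2.slope_se, rel=1e-12)


class TestNitriteRate:
    def test_definition_slope_over_F(self):
        tc = make_tc([0, 4, 8, 12], [0.0, 1.0, 2.0, 3.0], F=0.1)
        est = nitrite_production_rate(tc)
        assert est.value == pytest.approx(6.0 / tc.label_fraction, rel=1e-9)

    def test_homogeneous_degree_minus_one_in_F(self):
        y = [0.0, 1.0, 2.1, 2.9]
        e1 = nitrite_production_rate(make_tc([0, 4, 8, 12], y, F=0.1))
        e2 = nitrite_production_rate(make_tc([0, 4, 8, 12], y, F=0.2))
        F1 = make_tc([0, 4, 8, 12], y, F=0.1).label_fraction
        F2 = make_tc([0, 4, 8, 12], y, F=0.2).label_fraction
        assert e1.value * F1 == pytest.approx(e2.value * F2, rel=1e-9)

    def test_low_label_fraction_flagged(self):
        tc = make_tc([0, 4, 8, 12], [0.0, 1.0, 2.0, 3.0], F=0.005)
        with pytest.warns(UserWarning, match="label fraction"):
            est = nitrite_production_rate(tc)
        assert "low_label_fraction" in est.flags
        assert tc.label_fraction < LOW_LABEL_FLOOR

    def test_negative_slope_retained_and_below_detection(self):
        tc = make_tc([0, 4, 8, 12], [0.3, 0.2, 0.1, 0.0])
        est = nitrite_production_rate(tc, noise_sd=0.05)
        assert est.value < 0
        assert est.below_detection

    def test_simulator_round_trip_within_2se(self, cfg):
        cfg2 = SimConfig(seed=9, true_rates={"ammonium": (2.0, 0.004)},
                         F_targets={"ammonium": 0.12})
        tc = simulate_incubation(cfg2)
        est = nitrite_production_rate(tc, noise_sd=cfg2.no2_noise_sd)
        assert abs(est.value - 2.0) < 2 * est.se + 1e-9


class TestN2ORate:
    def test_noiseless_forward_inversion_exact(self):
        cfg = SimConfig(seed=1, n2o_noise_sd=0.0, no2_noise_sd=0.0,
                        true_rates={"ammonium": (5.0, 0.05)})
        tc = simulate_incubation(cfg)
        est = n2o_production_rate(tc)
        assert est.value == pytest.approx(0.05, rel=1e-9)
        nit = nitrite_production_rate(tc)
        assert nit.value == pytest.approx(5.0, rel=1e-9)

    def test_zero_rate_below_detection(self):
        cfg = SimConfig(seed=5, true_rates={"ammonium": (5.0, 0.0)})
        tc = simulate_incubation(cfg)
        est = n2o_production_rate(tc, noise_sd=cfg.n2o_noise_sd * np.sqrt(5))
        assert est.below_detection
        assert abs(est.value) < 3 * est.se + est.detection_limit


class TestDetectionLimit:
    def test_zero_noise_zero_dl(self):
        assert detection_limit([0, 4, 8, 12], 2, 0.0, F=0.1) == 0.0

    def test_dl_inverse_in_F(self):
        d1 = detection_limit([0, 4, 8, 12], 2, 0.01, F=0.1)
        d2 = detection_limit([0, 4, 8, 12], 2, 0.01, F=0.2)
        assert d1 == pytest.approx(2 * d2, rel=1e-12)

    def test_n2o_dl_has_extra_factor_two(self):
        d_nit = detection_limit([0, 4, 8, 12], 2, 0.01, F=0.1, product="nitrite")
        d_n2o = detection_limit([0, 4, 8, 12], 2, 0.01, F=0.1, product="n2o")
        assert d_nit == pytest.approx(2 * d_n2o, rel=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(InsufficientDesignError):
            detection_limit([5, 5, 5], 2, 0.01, F=0.1)

    def test_against_null_slope_monte_carlo(self):
        """The one-sided t-quantile DL must agree with a simulated null.

        10⁴ pure-noise series are fit; the 95th percentile of the
        studentized slope, rescaled by the design slope SE and 1/F, is an
        independent estimate of the detection limit (within 10 %).
        """
        rng = np.random.default_rng(17)
        times = np.repeat(np.array([0, 4, 8, 12]) / 24.0, 2)
        sigma, F = 0.01, 0.1
        n = times.size
        xm = times.mean()
        sxx = np.sum((times - xm) ** 2)
        tstats = np.empty(10_000)
        for i in range(10_000):
            y = rng.normal(0.0, sigma, n)
            slope = np.sum((times - xm) * (y - y.mean())) / sxx
            resid = y - y.mean() - slope * (times - xm)
            se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
            tstats[i] = slope / se
        dl_mc = np.quantile(tstats, 0.95) * (sigma / np.sqrt(sxx)) / F
        dl = detection_limit([0, 4, 8, 12], 2, sigma, F=F)
        assert dl == pytest.approx(dl_mc, rel=0.10)

    def test_noisy_series_within_3se(self):
        """σ = 0.33 nM noise at a known slope: estimate within 3 SE nearly always."""
        rng = np.random.default_rng(23)
        cfg = SimConfig(seed=0, n2o_noise_sd=0.33,
                        true_rates={"ammonium": (50.0, 0.04)})
        hits = 0
        n_runs = 400
        for _ in range(n_runs):
            tc = simulate_incubation(cfg, rng=rng)
            est = nitrite_production_rate(tc, noise_sd=cfg.no2_noise_sd)
            if abs(est.value - 50.0) <= 3 * est.se:
                hits += 1
        assert hits / n_runs >= 0.97
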