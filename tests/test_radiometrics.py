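import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toothsr import (
    AssayCalibration,
    CountSeries,
    NuclideConstants,
    background_sigma,
    decay_correct_to_reference,
    detection_limit,
    equilibrium_activity,
    expected_gross_rate,
    fit_absorption_curve,
    fit_ingrowth_series,
    ingrowth_fraction,
    self_absorption_factor,
)
from toothsr.radiometrics import CalibrationError, InsufficientDataError


class TestIngrowthFraction:
    @pytest.mark.parametrize(
        "t_hours, expected",
        [
            (0.0, 0.0),  # no daughter immediately after separation
            (64.05, 0.5),  # one Y-90 half-life reaches half of equilibrium
            (336.0, 1.0 - 2.0 ** (-336.0 / 64.05)),  # ~0.974 after a fortnight
        ],
    )
    def test_closed_form(self, t_hours, expected, constants):
        assert ingrowth_fraction(t_hours, constants) == pytest.approx(expected, abs=1e-12)

    def test_negative_time_rejected(self, constants):
        with pytest.raises(ValueError):
            ingrowth_fraction(-1.0, constants)

    def test_monotone_and_bounded(self, constants):
        t = np.linspace(0, 2000, 500)
        g = ingrowth_fraction(t, constants)
        assert np.all(np.diff(g) >= 0)
        assert g[0] == 0.0
        assert np.all(g < 1.0)

    def test_parent_decay_negligible_over_fortnight(self, constants):
        # 28.8 y >> 14 d: the Sr-90 decay factor moves the expected rate by <0.1%
        decay = math.exp(-constants.lambda_sr90_per_hour * 336.0)
        assert 1.0 - decay < 1e-3


class TestSelfAbsorption:
    def test_unity_at_standard_thickness(self):
        assert self_absorption_factor(24.0, mu=0.01) == 1.0

    def test_zero_mu_is_unity(self):
        assert self_absorption_factor(100.0, mu=0.0) == 1.0

    def test_strictly_decreasing_in_thickness(self):
        x = np.linspace(0, 60, 50)
        f = self_absorption_factor(x, mu=0.008)
        assert np.all(np.diff(f) < 0)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            self_absorption_factor(-1.0, mu=0.01)


class TestAbsorptionCurveFit:
    def test_exact_model_recovery(self):
        x = np.array([5.0, 15.0, 24.0, 35.0])
        pairs = list(zip(x, np.exp(-0.01 * x)))
        assert fit_absorption_curve(pairs) == pytest.approx(0.01, rel=1e-9)

    def test_single_thickness_unidentifiable(self):
        with pytest.raises(CalibrationError):
            fit_absorption_curve([(24.0, 1.0), (24.0, 0.99)])

    def test_response_above_one_rejected(self):
        with pytest.raises(CalibrationError):
            fit_absorption_curve([(5.0, 1.2), (24.0, 0.8)])

    def test_round_trip_at_standard_thickness(self):
        # noisy synthetic calibration; factor at 24 mg/cm2 within 1 % of truth
        rng = np.random.default_rng(7)
        mu_true = 0.009
        x = np.linspace(5, 40, 8)
        r = np.exp(-mu_true * x) * (1 + rng.normal(0, 0.005, x.size))
        mu = fit_absorption_curve(list(zip(x, r)))
        f_fit = math.exp(-mu * 24.0)
        assert f_fit == pytest.approx(math.exp(-mu_true * 24.0), rel=0.01)


class TestExpectedGrossRate:
    def test_blank_returns_background(self, calib, constants):
        assert expected_gross_rate(0.0, 100.0, 24.0, calib, constants) == calib.background_rate

    def test_secular_equilibrium_limit(self, constants):
        # 1 Bq, eps=0.339, f=1, zero background: 60*0.339*2 = 40.68 cpm
        calib = AssayCalibration(background_rate=0.0)
        rate = expected_gross_rate(1.0, 1e6, 24.0, calib, constants)
        # the tiny parent-decay factor is undone for the asymptotic comparison
        decay = math.exp(-constants.lambda_sr90_per_hour * 1e6)
        assert rate / decay == pytest.approx(40.68, rel=1e-9)

    def test_negative_activity_rejected(self, calib, constants):
        with pytest.raises(ValueError):
            expected_gross_rate(-1.0, 10.0, 24.0, calib, constants)


def _make_series(A, t_hours, durations, calib, constants, rng=None, yield_=1.0):
    rates = expected_gross_rate(A * yield_, np.asarray(t_hours), 24.0, calib, constants)
    mean_counts = rates * np.asarray(durations)
    counts = rng.poisson(mean_counts) if rng is not None else mean_counts
    return CountSeries(
        "s", tuple((float(t), float(d), float(c)) for t, d, c in zip(t_hours, durations, counts))
    )


class TestFitIngrowthSeries:
    T = [12.0, 60.0, 120.0, 200.0, 336.0]
    DUR = [720.0] * 5

    def test_noiseless_recovery(self, calib, constants):
        series = _make_series(0.05, self.T, self.DUR, calib, constants)
        res = fit_ingrowth_series(series, 24.0, calib, constants)
        assert res.activity_at_separation == pytest.approx(0.05, rel=1e-8)
        assert res.goodness_of_fit_p == pytest.approx(1.0, abs=1e-9)
        assert not res.below_detection

    def test_noiseless_recovery_with_yield(self, calib, constants):
        series = _make_series(0.05, self.T, self.DUR, calib, constants, yield_=0.7)
        res = fit_ingrowth_series(series, 24.0, calib, constants, chemical_yield=0.7)
        assert res.activity_at_separation == pytest.approx(0.05, rel=1e-8)

    def test_too_few_observations(self, calib, constants):
        series = CountSeries("s", ((1.0, 60.0, 10.0), (2.0, 60.0, 12.0)))
        with pytest.raises(InsufficientDataError):
            fit_ingrowth_series(series, 24.0, calib, constants)

    def test_flat_series_flagged_by_gof(self, calib, constants):
        # a constant rate well above background cannot follow the ingrowth curve
        flat_rate = calib.background_rate + 2.0
        series = CountSeries(
            "s", tuple((t, 720.0, flat_rate * 720.0) for t in self.T)
        )
        res = fit_ingrowth_series(series, 24.0, calib, constants)
        assert res.goodness_of_fit_p < 0.05

    def test_monte_carlo_unbiased(self, calib, constants):
        # small-scale unbiasedness check; the full 1000-replicate version
        # lives with the end-to-end tests
        rng = np.random.default_rng(11)
        A = 0.05
        est = [
            fit_ingrowth_series(
                _make_series(A, self.T, self.DUR, calib, constants, rng),
                24.0, calib, constants,
            ).activity_at_separation
            for _ in range(300)
        ]
        est = np.array(est)
        se = est.std(ddof=1) / math.sqrt(est.size)
        assert abs(est.mean() - A) < 2 * se

    def test_blank_false_positive_rate(self, calib, constants):
        # 3-sigma criterion: blanks rarely exceed the per-sample detection limit
        rng = np.random.default_rng(5)
        dl_mBq_per_gCa = detection_limit(calib, 720.0, 0.70, 1.0, 0.37)
        dl_Bq = dl_mBq_per_gCa * 0.37 / 1000.0
        n_exceed = 0
        n = 500
        for _ in range(n):
            series = _make_series(0.0, self.T, self.DUR, calib, constants, rng)
            res = fit_ingrowth_series(series, 24.0, calib, constants, chemical_yield=0.70)
            if res.activity_at_separation > dl_Bq:
                n_exceed += 1
        assert n_exceed / n <= 0.01

    def test_negative_fit_clamped_and_flagged(self, calib, constants):
        # counts systematically below background force a negative raw estimate
        low = max(calib.background_rate - 0.05, 0.01)
        series = CountSeries("s", tuple((t, 720.0, low * 720.0) for t in self.T))
        res = fit_ingrowth_series(series, 24.0, calib, constants)
        assert res.activity_at_separation == 0.0
        assert res.below_detection


class TestEquilibriumActivity:
    def test_closed_form(self, calib):
        A, flag = equilibrium_activity(1.0, 24.0, 0.70, calib)
        assert A == pytest.approx((1.0 / 60.0) / (2.0 * 0.339 * 0.70), rel=1e-12)
        assert not flag

    def test_zero_net_rate(self, calib):
        assert equilibrium_activity(0.0, 24.0, 0.7, calib)[0] == 0.0

    def test_yield_proportionality(self, calib):
        a1, _ = equilibrium_activity(1.0, 24.0, 0.4, calib)
        a2, _ = equilibrium_activity(1.0, 24.0, 0.8, calib)
        assert a1 == pytest.approx(2.0 * a2, rel=1e-12)

    def test_negative_net_rate_flagged(self, calib):
        A, flag = equilibrium_activity(-0.1, 24.0, 0.7, calib)
        assert A == 0.0 and flag

    def test_round_trip_with_forward_model(self, calib, constants):
        # net equilibrium rate of A Bq, divided back out, returns A
        A = 0.123
        rate = expected_gross_rate(A, 1e6, 30.0, calib, constants)
        decay = math.exp(-constants.lambda_sr90_per_hour * 1e6)
        net = (rate - calib.background_rate) / decay
        est, _ = equilibrium_activity(net, 30.0, 1.0, calib)
        # bracket (1+g) -> 2 at large t
        assert est == pytest.approx(A, rel=1e-6)


class TestDecayCorrection:
    def test_identity_at_reference(self, constants):
        assert decay_correct_to_reference(1.0, date(2011, 3, 11), constants) == 1.0

    def test_one_halflife_doubles(self):
        # exactly 28.8 * 365.25 days later
        c = NuclideConstants()
        target = c.reference_date.toordinal() + round(28.8 * 365.25)
        factor = decay_correct_to_reference(1.0, date.fromordinal(target), c)
        # whole-day date arithmetic rounds 28.8*365.25 = 10519.2 d to 10519 d
        assert factor == pytest.approx(2.0, rel=1e-4)

    def test_two_years(self, constants):
        d = date.fromordinal(constants.reference_date.toordinal() + round(2 * 365.25))
        assert decay_correct_to_reference(1.0, d, constants) == pytest.approx(
            math.exp(math.log(2) * 2 / 28.8), rel=1e-4
        )

    def test_measurement_before_reference_rejected(self, constants):
        with pytest.raises(ValueError):
            decay_correct_to_reference(1.0, date(2011, 3, 10), constants)

    @given(
        d1=st.integers(min_value=0, max_value=4000),
        d2=st.integers(min_value=0, max_value=4000),
    )
    @settings(max_examples=50, deadline=None)
    def test_correction_composes(self, d1, d2):
        # correcting t1 -> t0 equals scaling through any intermediate date
        c = NuclideConstants()
        lam = c.lambda_sr90_per_year
        full = decay_correct_to_reference(1.0, date.fromordinal(c.reference_date.toordinal() + d1 + d2), c)
        part = decay_correct_to_reference(1.0, date.fromordinal(c.reference_date.toordinal() + d1), c)
        rest = math.exp(lam * d2 / 365.25)
        assert full == pytest.approx(part * rest, rel=1e-12)


class TestBackgroundAndDetectionLimit:
    def test_published_background_sigma(self):
        # 0.155 cpm over 12 h: sigma ~ 0.015 cpm, 3 sigma = 0.044 cpm
        sigma = background_sigma(0.155, 720.0)
        assert sigma == pytest.approx(0.0147, abs=5e-4)
        assert 3 * sigma == pytest.approx(0.044, abs=5e-4)

    def test_zero_rate(self):
        assert background_sigma(0.0, 720.0) == 0.0

    def test_sqrt_duration_scaling(self):
        assert background_sigma(0.155, 4 * 720.0) == pytest.approx(
            background_sigma(0.155, 720.0) / 2.0, rel=1e-12
        )

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            background_sigma(0.155, 0.0)

    def test_per_sample_limit(self, calib):
        # (0.044/60) / (2 * 0.339 * 0.70) = 1.55 mBq in 1 g of ash
        dl = detection_limit(calib, 720.0, 0.70, 1.0, ca_fraction=1.0)
        assert dl == pytest.approx(1.55, abs=0.01)

    def test_per_gram_calcium_limit(self, calib):
        dl = detection_limit(calib, 720.0, 0.70, 1.0, ca_fraction=0.313)
        assert dl == pytest.approx(4.94, abs=0.01)

    def test_inverse_scaling(self, calib):
        base = detection_limit(calib, 720.0, 0.70, 1.0, 0.37)
        assert detection_limit(calib, 720.0, 0.35, 1.0, 0.37) == pytest.approx(2 * base, rel=1e-12)
        assert detection_limit(calib, 720.0, 0.70, 2.0, 0.37) == pytest.approx(base / 2, rel=1e-12)
        assert detection_limit(calib, 720.0, 0.70, 1.0, 0.74) == pytest.approx(base / 2, rel=1e-12)

    def test_sqrt_duration_scaling_of_limit(self, calib):
        base = detection_limit(calib, 720.0, 0.70, 1.0, 0.37)
        assert detection_limit(calib, 4 * 720.0, 0.70, 1.0, 0.37) == pytest.approx(
            base / 2.0, rel=1e-12
        )

    def test_zero_ca_fraction_rejected(self, calib):
        with pytest.raises(ValueError):
            detection_limit(calib, 720.0, 0.70, 1.0, 0.0)
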