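"""Relaxation-observable estimators and the dispersion fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrdyn.exchange import CpmgSchedule, ExchangeParams, model_rex, simulate_dispersion
from nmrdyn.relax import (
    DecaySeries,
    InsufficientDataError,
    NoePair,
    compute_hetnoe,
    compute_r2eff,
    estimate_rex,
    fit_dispersion,
    fit_monoexponential,
)

DELAYS = np.array([0.02, 0.06, 0.12, 0.2, 0.35, 0.5, 0.8, 1.2])


class TestMonoexponential:
    def test_noiseless_recovery_is_exact(self):
        y = 2.5 * np.exp(-1.2 * DELAYS)
        i0, rate = fit_monoexponential(DecaySeries(1, DELAYS, y, 1e-6))
        assert rate.value == pytest.approx(1.2, rel=1e-6)
        assert i0.value == pytest.approx(2.5, rel=1e-6)

    def test_constant_series_gives_zero_rate(self):
        y = np.ones_like(DELAYS)
        _, rate = fit_monoexponential(DecaySeries(1, DELAYS, y, 0.01))
        assert abs(rate.value) < 1e-6

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_rate_invariant_under_intensity_scaling(self, scale):
        y = np.exp(-3.0 * DELAYS)
        _, r1 = fit_monoexponential(DecaySeries(1, DELAYS, y, 0.01))
        _, r2 = fit_monoexponential(DecaySeries(1, DELAYS, scale * y,
                                                0.01 * scale))
        assert r2.value == pytest.approx(r1.value, rel=1e-6)

    def test_requires_four_distinct_delays(self):
        with pytest.raises(InsufficientDataError):
            DecaySeries(1, [0.1, 0.1, 0.2, 0.3], np.ones(4), 0.01)


class TestR2eff:
    def test_equal_intensities_give_zero(self):
        assert compute_r2eff(0.7, 0.7, 0.04, 0.01, 0.01).value == 0.0

    def test_half_intensity_worked_value(self):
        est = compute_r2eff(0.5, 1.0, 0.04, 0.01, 0.01)
        assert est.value == pytest.approx(np.log(2) / 0.04, rel=1e-6)  # 17.33

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            compute_r2eff(-0.1, 1.0, 0.04, 0.01, 0.01)


class TestHetNoe:
    def test_equal_intensities_give_unity(self):
        pair = NoePair(1, 0.9, 0.9, 0.01, 0.01)
        assert compute_hetnoe(pair).value == pytest.approx(1.0)

    def test_worked_ratio_and_sigma(self):
        est = compute_hetnoe(NoePair(1, 0.8, 1.0, 0.01, 0.01))
        assert est.value == pytest.approx(0.8)
        expected = 0.8 * np.sqrt((0.01 / 0.8) ** 2 + (0.01 / 1.0) ** 2)
        assert est.sigma == pytest.approx(expected, rel=1e-6)  # ~0.0128

    def test_negative_saturated_intensity_allowed(self):
        est = compute_hetnoe(NoePair(1, -0.2, 1.0, 0.01, 0.01))
        assert est.value == pytest.approx(-0.2)

    def test_near_zero_reference_flagged(self):
        est = compute_hetnoe(NoePair(1, 0.5, 0.02, 0.01, 0.01))
        assert est.flag == "unreliable-ratio"


class TestDispersionFit:
    def test_flat_curve_selects_flat_model(self, schedule, rng):
        flat = ExchangeParams(p_b=0.0, k_ex=0.0, delta_omega=0.0, r2_a=11.0)
        curve = simulate_dispersion(flat, schedule, 0.015, 5)
        fit = fit_dispersion(curve, schedule)
        assert fit.model == "flat"
        assert fit.rex.value == 0.0
        assert fit.r2_0 == pytest.approx(11.0, abs=1.0)

    def test_noiseless_two_site_recovers_rex(self, schedule):
        truth = ExchangeParams(p_b=0.03, k_ex=1500.0, delta_omega=500.0,
                               r2_a=10.0)
        curve = simulate_dispersion(truth, schedule, 0.0, 1)
        curve.sigma_r2_eff = np.full_like(curve.r2_eff, 0.05)
        fit = fit_dispersion(curve, schedule)
        assert fit.model == "two_site"
        assert fit.rex.value == pytest.approx(model_rex(truth, schedule),
                                              rel=0.02)

    def test_flat_selection_rate_controls_type_one_error(self, schedule):
        flat = ExchangeParams(p_b=0.0, k_ex=0.0, delta_omega=0.0, r2_a=12.0)
        n_flat = 0
        for seed in range(40):
            curve = simulate_dispersion(flat, schedule, 0.015, 100 + seed)
            if fit_dispersion(curve, schedule).model == "flat":
                n_flat += 1
        assert n_flat >= 36  # >= 90% at the alpha = 0.01 selection rule

    def test_estimate_rex_consistent_with_fit(self, schedule):
        truth = ExchangeParams(p_b=0.05, k_ex=1200.0, delta_omega=900.0,
                               r2_a=10.0)
        curve = simulate_dispersion(truth, schedule, 0.0, 1)
        curve.sigma_r2_eff = np.full_like(curve.r2_eff, 0.05)
        fit = fit_dispersion(curve, schedule)
        est = estimate_rex(fit, schedule)
        assert est.value == pytest.approx(fit.rex.value, rel=1e-6)
        assert est.value >= 0.0

    def test_too_few_points_rejected(self, schedule):
        curve = simulate_dispersion(
            ExchangeParams(p_b=0.0, k_ex=0.0, delta_omega=0.0, r2_a=10.0),
            CpmgSchedule(t_relax=0.04, nu_cpmg=(25.0, 100.0, 500.0, 1000.0)),
            0.0, 1,
        )
        with pytest.raises(InsufficientDataError):
            fit_dispersion(curve, schedule)


class TestSigmaCalibration:
    def test_r2eff_sigma_matches_monte_carlo(self, rng):
        t_relax, noise = 0.04, 0.02
        i_true, i0_true = np.exp(-15.0 * t_relax), 1.0
        draws_i = i_true + rng.normal(0, noise, 10_000)
        draws_i0 = i0_true + rng.normal(0, noise, 10_000)
        emp = (-np.log(draws_i / draws_i0) / t_relax).std(ddof=1)
        prop = compute_r2eff(i_true, i0_true, t_relax, noise, noise).sigma
        assert prop == pytest.approx(emp, rel=0.05)
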