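"""Two-site exchange model: limits, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrdyn.exchange import (
    CpmgSchedule,
    ExchangeParams,
    ScheduleError,
    carver_richards,
    luz_meiboom,
    model_rex,
    propagate_cpmg,
    simulate_dispersion,
)

NUS = np.array([25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0])
T_RELAX = 0.04


class TestDegenerateLimits:
    def test_no_minor_state_gives_flat_intrinsic_rate(self):
        p = ExchangeParams(p_b=0.0, k_ex=1500.0, delta_omega=800.0, r2_a=10.0)
        for nu in NUS:
            assert propagate_cpmg(p, T_RELAX, nu) == pytest.approx(10.0, abs=1e-8)

    def test_identical_shifts_give_flat_intrinsic_rate(self):
        p = ExchangeParams(p_b=0.2, k_ex=1500.0, delta_omega=0.0, r2_a=12.0)
        for nu in NUS:
            assert propagate_cpmg(p, T_RELAX, nu) == pytest.approx(12.0, abs=1e-8)
            assert carver_richards(p, nu) == pytest.approx(12.0, abs=1e-8)

    def test_model_rex_vanishes_without_exchange_contrast(self, schedule):
        for p in (
            ExchangeParams(p_b=0.0, k_ex=2000.0, delta_omega=500.0, r2_a=10.0),
            ExchangeParams(p_b=0.05, k_ex=2000.0, delta_omega=0.0, r2_a=10.0),
        ):
            assert model_rex(p, schedule) == pytest.approx(0.0, abs=1e-8)


class TestOracleEquivalence:
    @pytest.mark.parametrize("kex", [200.0, 600.0, 6000.0],
                             ids=["slow", "intermediate", "fast"])
    def test_closed_form_matches_propagator(self, kex):
        p = ExchangeParams(p_b=0.03, k_ex=kex, delta_omega=600.0, r2_a=10.0)
        prop = np.array([propagate_cpmg(p, T_RELAX, nu) for nu in NUS])
        closed = np.asarray(carver_richards(p, NUS, t_relax=T_RELAX))
        assert np.max(np.abs(closed / prop - 1.0)) < 0.005

    def test_asymptotic_form_matches_at_many_pulses(self):
        # the classic large-n expression converges to the propagator once
        # the echo train is long (here n >= 16)
        p = ExchangeParams(p_b=0.03, k_ex=600.0, delta_omega=600.0, r2_a=10.0)
        for nu in (200.0, 500.0, 1000.0):
            prop = propagate_cpmg(p, T_RELAX, nu)
            assert carver_richards(p, nu) == pytest.approx(prop, rel=5e-3)

    def test_fast_exchange_three_way_agreement(self):
        p = ExchangeParams(p_b=0.05, k_ex=2000.0, delta_omega=200.0, r2_a=10.0)
        assert p.k_ex >= 10 * abs(p.delta_omega)
        for nu in (50.0, 250.0, 1000.0):
            prop = propagate_cpmg(p, T_RELAX, nu)
            assert carver_richards(p, nu) == pytest.approx(prop, rel=0.01)
            assert luz_meiboom(p, nu) == pytest.approx(prop, rel=0.01)


class TestLuzMeiboom:
    def test_high_frequency_limit_is_intrinsic_rate(self, fast_params):
        assert luz_meiboom(fast_params, 1e7) == pytest.approx(10.0, rel=1e-4)

    def test_zero_frequency_exchange_term(self, fast_params):
        # pA pB dw^2 / kex = 0.95 * 0.05 * 600^2 / 2000 = 8.55 1/s
        lo = luz_meiboom(fast_params, 1e-4)
        assert lo - 10.0 == pytest.approx(8.55, rel=1e-3)

    def test_model_rex_close_to_closed_form_difference(self, fast_params,
                                                       schedule):
        lm = luz_meiboom(fast_params, schedule.nu_min) - luz_meiboom(
            fast_params, schedule.nu_max
        )
        assert model_rex(fast_params, schedule) == pytest.approx(lm, rel=0.10)


class TestInvariances:
    @given(
        pb=st.floats(0.01, 0.45),
        kex=st.floats(100.0, 8000.0),
        dw=st.floats(50.0, 2000.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_state_relabeling_symmetry(self, pb, kex, dw):
        a = ExchangeParams(p_b=pb, k_ex=kex, delta_omega=dw, r2_a=10.0, r2_b=14.0)
        b = ExchangeParams(p_b=1.0 - pb, k_ex=kex, delta_omega=-dw, r2_a=14.0,
                           r2_b=10.0)
        for nu in (50.0, 500.0):
            assert propagate_cpmg(a, T_RELAX, nu) == pytest.approx(
                propagate_cpmg(b, T_RELAX, nu), rel=1e-9
            )

    @pytest.mark.parametrize("kex,dw", [(600.0, 600.0), (6000.0, 600.0)])
    def test_dispersion_monotone_decreasing_for_kex_ge_dw(self, kex, dw):
        p = ExchangeParams(p_b=0.05, k_ex=kex, delta_omega=dw, r2_a=10.0)
        r2 = np.array([propagate_cpmg(p, T_RELAX, nu) for nu in NUS])
        assert np.all(np.diff(r2) <= 1e-6)

    def test_rejects_incompatible_frequency(self):
        with pytest.raises(ScheduleError):
            CpmgSchedule(t_relax=0.04, nu_cpmg=(33.0,))

    def test_rejects_unphysical_parameters(self):
        with pytest.raises(ValueError):
            ExchangeParams(p_b=-0.1, k_ex=100.0, delta_omega=0.0, r2_a=10.0)
        with pytest.raises(ValueError):
            ExchangeParams(p_b=0.1, k_ex=-5.0, delta_omega=0.0, r2_a=10.0)


class TestSimulateDispersion:
    def test_zero_noise_reproduces_model(self, fast_params, schedule):
        curve = simulate_dispersion(fast_params, schedule, 0.0, 7)
        expect = [propagate_cpmg(fast_params, schedule.t_relax, nu)
                  for nu in curve.nu_cpmg]
        assert np.allclose(curve.r2_eff, expect, atol=1e-10)

    def test_same_seed_is_deterministic(self, fast_params, schedule):
        a = simulate_dispersion(fast_params, schedule, 0.02, 42)
        b = simulate_dispersion(fast_params, schedule, 0.02, 42)
        assert np.array_equal(a.r2_eff, b.r2_eff)
        assert np.array_equal(a.sigma_r2_eff, b.sigma_r2_eff)

    def test_mean_over_replicates_unbiased(self, fast_params, schedule):
        nus = schedule.nu_cpmg
        truth = np.array([propagate_cpmg(fast_params, schedule.t_relax, nu)
                          for nu in nus])
        reps = np.array([
            simulate_dispersion(fast_params, schedule, 0.01, 1000 + k).r2_eff
            for k in range(500)
        ])
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(mean - truth) < 2.5 * se + 1e-3)
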