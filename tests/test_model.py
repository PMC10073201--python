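"""Core phase model: frequencies, right-hand sides, simulation, wrapping."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import phasekit as pk
from phasekit.model import wrap_pd_hours


def free_params(**kw):
    base = dict(tau_a=25.7, tau_n=22.5, tau_v=23.4, K_an=0.0, K_na=0.0,
                K_av=0.0, K_va=0.0, gamma=0.77)
    base.update(kw)
    return pk.OscillatorParams(**base)


class TestIntrinsicFrequency:
    @pytest.mark.parametrize("tau, expected", [
        (24.0, 2 * np.pi / 24.0),
        (25.7, 0.244482),
        (22.5, 0.279253),
    ])
    def test_values(self, tau, expected):
        assert pk.intrinsic_frequency(tau) == pytest.approx(expected, rel=1e-5)

    def test_detuning_from_fitted_periods(self, fitted):
        assert fitted.omega_an == pytest.approx(-0.03477, abs=2e-5)

    def test_rejects_nonpositive_period(self):
        with pytest.raises(ValueError):
            pk.intrinsic_frequency(0.0)
        with pytest.raises(ValueError):
            pk.OscillatorParams(tau_a=-1, tau_n=22.5, tau_v=23.4, K_an=0,
                                K_na=0, K_av=0, K_va=0, gamma=0)


class TestPhaseRhs:
    def test_uncoupled_limit_returns_intrinsic_frequencies(self):
        p = free_params()
        assert pk.phase_rhs(0.3, -1.0, 2.0, p) == pytest.approx(
            (p.omega_a, p.omega_n, p.omega_v))

    def test_ap_velocity_when_both_sine_terms_vanish(self, fitted):
        # θ_n − θ_a = −γ kills the AN term; θ_v = θ_a with K_av = 0 kills AV
        p = replace(fitted, K_av=0.0)
        th_a = 0.8
        dth_a, _, _ = pk.phase_rhs(th_a, th_a - p.gamma, th_a, p)
        assert dth_a == pytest.approx(p.omega_a)

    def test_synchronised_state_velocities_equal(self, fitted, stable_fp):
        th_a = 0.0
        th_n = th_a - stable_fp.theta_an
        th_v = th_a - stable_fp.theta_av
        da, dn, dv = pk.phase_rhs(th_a, th_n, th_v, fitted)
        assert da == pytest.approx(dn, abs=1e-12)
        assert da == pytest.approx(dv, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10),
           st.floats(0, 2))
    def test_pd_rhs_equals_phase_rhs_differences(self, th_a, th_n, th_v, s):
        """The PD reduction is an algebraic identity when K_nv = K_vn = 0."""
        p = pk.default_params()
        da, dn, dv = pk.phase_rhs(th_a, th_n, th_v, p, s_n=s, s_v=s)
        d_an, d_av = pk.pd_rhs(th_a - th_n, th_a - th_v, p, s)
        assert d_an == pytest.approx(da - dn, abs=1e-12)
        assert d_av == pytest.approx(da - dv, abs=1e-12)

    def test_pd_rhs_uncoupled(self):
        p = free_params()
        assert pk.pd_rhs(1.0, -2.0, p, s=0.0) == pytest.approx(
            (p.omega_an, p.omega_av))

    def test_pd_rhs_vanishes_at_fixed_point(self, fitted, stable_fp):
        d = pk.pd_rhs(stable_fp.theta_an, stable_fp.theta_av, fitted, 1.0)
        assert np.hypot(*d) < 1e-12


class TestWrapping:
    @pytest.mark.parametrize("x, expected", [
        (13.0, -11.0), (12.0, 12.0), (-12.0, 12.0), (0.0, 0.0),
        (25.0, 1.0), (-13.0, 11.0),
    ])
    def test_wrap_examples(self, x, expected):
        assert wrap_pd_hours(x) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(-1e4, 1e4))
    def test_wrap_is_24h_periodic_and_in_range(self, x):
        w = wrap_pd_hours(x)
        assert -12.0 < w <= 12.0
        assert wrap_pd_hours(x + 24.0) == pytest.approx(w, abs=1e-9)

    def test_radian_hour_round_trip_is_exact(self):
        x = np.linspace(-11.9, 12.0, 41)
        assert np.allclose(x / pk.HOURS_PER_RAD * pk.HOURS_PER_RAD, x,
                           atol=1e-14)


class TestSimulate:
    def test_uncoupled_nts_advances_at_intrinsic_frequency(self):
        p = free_params()
        traj = pk.simulate(p, initial_phases=(0.0, 1.2, 0.0),
                           t_span=(0, 150))
        expected = 1.2 + p.omega_n * traj.t
        assert np.abs(traj.theta_n - expected).max() < 1e-6

    def test_fitted_params_converge_to_constant_pds(self, fitted, stable_fp):
        traj = pk.simulate(fitted, initial_phases=(0.5, 0.0, -2.0),
                           t_span=(0, 400))
        pdt = pk.phases_to_pd(traj)
        # last 50 h: both PDs constant at the fixed point
        tail = pdt.t > 350
        assert np.ptp(pdt.theta_an[tail]) < 0.05
        assert np.mean(pdt.theta_an[tail]) == pytest.approx(
            stable_fp.theta_an * pk.HOURS_PER_RAD, abs=0.05)
        assert np.mean(pdt.theta_av[tail]) == pytest.approx(
            stable_fp.theta_av * pk.HOURS_PER_RAD, abs=0.05)

    def test_late_drift_slope_is_detuning_after_coupling_decays(self, fitted):
        sched = pk.CouplingSchedule(s0_n=1.0, c_n=1 / 100, s0_v=1.0,
                                    c_v=1 / 100)
        traj = pk.simulate(fitted, sched, t_span=(0, 200))
        an = traj.theta_a - traj.theta_n
        late = traj.t >= 120          # coupling is zero from t = 100 h
        slope = np.polyfit(traj.t[late], an[late], 1)[0]
        assert slope == pytest.approx(fitted.omega_an, rel=1e-3)

    def test_pd_reduction_equivalence_over_200h(self, fitted):
        """Simulating the three-phase system and the reduced PD system agree."""
        tol = dict(rtol=1e-10, atol=1e-12)
        traj = pk.simulate(fitted, initial_phases=(1.0, 0.3, -0.5),
                           t_span=(0, 200), **tol)
        pdt = pk.phases_to_pd(traj)
        _, an, av = pk.simulate_pd(fitted, s=1.0, initial_pd_rad=(0.7, 1.5),
                                   t_span=(0, 200), **tol)
        d_an = np.abs(wrap_pd_hours(an * pk.HOURS_PER_RAD) - pdt.theta_an)
        d_av = np.abs(wrap_pd_hours(av * pk.HOURS_PER_RAD) - pdt.theta_av)
        assert max(d_an.max(), d_av.max()) / pk.HOURS_PER_RAD < 1e-3

    def test_translational_invariance_of_pds(self, fitted):
        shift = 2.345
        tol = dict(rtol=1e-9, atol=1e-11)   # isolate the model property
        t1 = pk.simulate(fitted, initial_phases=(0.1, 0.2, 0.3),
                         t_span=(0, 150), **tol)
        t2 = pk.simulate(fitted,
                         initial_phases=(0.1 + shift, 0.2 + shift, 0.3 + shift),
                         t_span=(0, 150), **tol)
        p1, p2 = pk.phases_to_pd(t1), pk.phases_to_pd(t2)
        assert np.abs(p1.theta_an - p2.theta_an).max() < 1e-4
        assert np.abs(p1.theta_av - p2.theta_av).max() < 1e-4

    def test_uncoupled_wrapped_pd_recurrence(self):
        """Wrapped AN-PD recurs with period 2π/|ω_an| ≈ 180.7 h."""
        p = free_params()
        recur = 2 * np.pi / abs(p.omega_an)
        assert recur == pytest.approx(180.70, abs=0.01)
        traj = pk.simulate(p, t_span=(0, 362), output_step=0.5)
        pdt = pk.phases_to_pd(traj)
        i = np.argmin(np.abs(traj.t - recur))
        assert pdt.theta_an[i] == pytest.approx(pdt.theta_an[0], abs=0.05)


class TestDisconnectionTransform:
    def test_halves_only_K_an(self, fitted):
        cut = pk.disconnection_transform(fitted)
        assert cut.K_an == pytest.approx(0.0155)
        assert cut.K_na == fitted.K_na
        assert cut.K_av == fitted.K_av
        assert cut.gamma == fitted.gamma

    def test_total_coupling_reduction_about_20_percent(self, fitted):
        cut = pk.disconnection_transform(fitted)
        reduction = (fitted.K_tilde_an - cut.K_tilde_an) / fitted.K_tilde_an
        assert reduction == pytest.approx(0.215, abs=0.005)

    def test_composition(self, fitted):
        twice = pk.disconnection_transform(pk.disconnection_transform(fitted))
        assert twice.K_an == pytest.approx(fitted.K_an / 4)
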