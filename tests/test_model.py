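"""Core model: right-hand sides, conservation, integration, spectral rates."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radcell.model import (
    InvalidStateError,
    ModelParams,
    RadiationSchedule,
    ScheduleSegment,
    Trajectory,
    asymptotic_decline_rate,
    communication_model,
    full_model,
    integrate,
    linear_unaltered_fraction,
    memory_model,
    rhs,
)

from conftest import FIG_MEMORY, K, X0, log_grid


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(alpha=-0.1, p=0.1), dict(alpha=0.1, p=1.5),
        dict(alpha=0.1, p=0.1, c=0.0), dict(alpha=0.1, p=0.1, eta=-1),
        dict(alpha=0.1, p=0.1, memory=2),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_variant_constructors(self):
        assert memory_model(0.1, 0.05).memory == 1
        assert memory_model(0.1, 0.05).is_linear
        assert communication_model(0.1, 0.05, beta0=10.0).memory == 0
        assert not communication_model(0.1, 0.05, beta0=10.0).is_linear
        assert full_model(0.1, 0.05, beta0=1.0, beta1=1.0).memory == 1


class TestRhs:
    def test_all_healthy_under_exposure(self, memory_params):
        # only the hit flow is active from an all-healthy state
        assert rhs(X0, memory_params) == pytest.approx([-10.0, 10.0, 0.0, 0.0])

    def test_quiescent_state_is_fixed_point(self):
        pr = memory_model(0.0, 0.05, c=1.0, eta=0.01)
        assert rhs((100.0, 0.0, 0.0, 0.0), pr) == pytest.approx([0.0] * 4)

    def test_full_model_conserves(self):
        pr = full_model(0.1, 0.05, c=1.0, eta=0.01, beta0=10.0, beta1=1.0)
        d = rhs((50.0, 10.0, 5.0, 35.0), pr)
        assert abs(d.sum()) < 1e-10 * np.abs(d).sum()

    def test_negative_state_rejected(self, memory_params):
        with pytest.raises(InvalidStateError):
            rhs((-1.0, 0.0, 0.0, 0.0), memory_params)

    @given(
        x=st.floats(0, 1e6), y=st.floats(0, 1e6),
        w=st.floats(0, 1e6), z=st.floats(0, 1e6),
        alpha=st.floats(0, 100), p=st.floats(0, 1),
        c=st.floats(0.01, 10), eta=st.floats(0, 10),
        beta0=st.floats(0, 10), beta1=st.floats(0, 10),
        memory=st.integers(0, 1),
    )
    def test_conservation_and_damage_sign(self, x, y, w, z, alpha, p, c,
                                          eta, beta0, beta1, memory):
        pr = ModelParams(alpha=alpha, p=p, c=c, eta=eta,
                         beta0=beta0, beta1=beta1, memory=memory)
        d = rhs((x, y, w, z), pr)
        scale = np.abs(d).sum() + 1.0
        assert abs(d.sum()) < 1e-9 * scale  # total population conserved
        assert d[3] >= 0.0                  # permanent damage never reverses


class TestIntegrate:
    def test_no_radiation_is_constant(self):
        pr = memory_model(0.0, 0.05, c=1.0, eta=0.01)
        traj = integrate(pr, X0, np.linspace(0, 1e3, 50))
        assert np.allclose(traj.states, np.tile(X0, (50, 1)), atol=1e-8)

    def test_memory_model_reaches_all_altered(self, memory_traj):
        assert memory_traj.z[-1] == pytest.approx(K, rel=1e-6)
        assert memory_traj.conservation_error() <= 1e-6 * K

    def test_z_monotone(self, memory_traj, comm_traj):
        for traj in (memory_traj, comm_traj):
            assert np.all(np.diff(traj.z) >= -1e-9 * K)

    def test_unaltered_nonincreasing_under_exposure(self, memory_traj):
        assert np.all(np.diff(memory_traj.unaltered) <= 1e-9 * K)

    def test_eta_zero_flux_accounting(self):
        # without protection loss every cell transits y exactly once, so a
        # fraction p ends altered and 1-p ends protected
        pr = memory_model(0.1, 0.05, c=1.0, eta=0.0)
        traj = integrate(pr, X0, np.linspace(0, 2000.0, 60))
        assert traj.z[-1] == pytest.approx(0.05 * K, abs=1e-6 * K)
        assert traj.w[-1] == pytest.approx(0.95 * K, abs=1e-6 * K)

    def test_invalid_grid_rejected(self, memory_params):
        with pytest.raises(ValueError):
            integrate(memory_params, X0, [0.0, 0.0, 1.0])
        with pytest.raises(InvalidStateError):
            integrate(memory_params, (-5.0, 0, 0, 0), [0.0, 1.0])

    def test_schedule_gap_uses_last_p_and_no_alpha(self):
        # during the gap no new hits occur and repairing cells resolve with
        # the previous segment's p
        sched = RadiationSchedule(
            segments=(ScheduleSegment(0.0, 5.0, 1.0, 0.4),), default_p=0.4)
        pr = memory_model(1.0, 0.4, c=1.0, eta=0.0)
        traj = integrate(pr, X0, np.linspace(0.0, 60.0, 61), schedule=sched)
        i5 = 5
        # after the beam stops x never declines again
        assert np.all(np.diff(traj.x[i5:]) >= -1e-9 * K)
        # every cell hit during [0,5] eventually fails with probability 0.4
        hit_total = K - traj.x[-1]
        assert traj.z[-1] == pytest.approx(0.4 * hit_total, rel=1e-6)

    def test_schedule_segments_validated(self):
        with pytest.raises(ValueError):
            RadiationSchedule(segments=(
                ScheduleSegment(0.0, 10.0, 1.0, 0.1),
                ScheduleSegment(5.0, 15.0, 1.0, 0.1),
            ))


class TestTrajectoryIO:
    def test_csv_round_trip(self, memory_traj, tmp_path):
        path = tmp_path / "traj.csv"
        memory_traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.states, memory_traj.states, rtol=1e-12)
        assert np.allclose(back.times, memory_traj.times, rtol=1e-12)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,x,y\n0,1,2\n1,3,4\n")
        import pandas as pd
        with pytest.raises(ValueError, match="lacks columns"):
            Trajectory.from_frame(pd.read_csv(path))


class TestSpectralRate:
    def test_memory_rate_matches_long_simulation(self, memory_params):
        oracle = asymptotic_decline_rate(memory_params)
        traj = integrate(memory_params, X0, log_grid(4e4, 2000), atol=1e-12)
        mask = (traj.unaltered > 1e-8) & (traj.unaltered < 1e-4)
        slope = np.polyfit(traj.times[mask], np.log(traj.unaltered[mask]), 1)[0]
        assert -slope == pytest.approx(oracle, rel=0.01)

    def test_p_zero_rate_is_zero(self):
        pr = memory_model(0.1, 0.0, c=1.0, eta=0.01)
        assert asymptotic_decline_rate(pr) == pytest.approx(0.0, abs=1e-12)

    def test_pure_repair_loop_matches_two_state_closed_form(self):
        # beta = 0 communication: (x, y) decouple and the dominant rate is
        # the closed-form root of s^2 + (alpha+c)s + alpha*c*p = 0
        alpha, p, c, eta = 0.1, 0.05, 1.0, 0.01
        pr = communication_model(alpha, p, c=c, eta=eta)
        tr = alpha + c
        expected = (tr - np.sqrt(tr ** 2 - 4 * alpha * c * p)) / 2.0
        assert asymptotic_decline_rate(pr) == pytest.approx(expected, rel=1e-10)

    def test_requires_exposure(self):
        with pytest.raises(ValueError):
            asymptotic_decline_rate(memory_model(0.0, 0.05))


class TestLinearFastPath:
    @pytest.mark.parametrize("params", [
        memory_model(**FIG_MEMORY),
        memory_model(0.42, 0.6, c=1.0, eta=0.052),
        communication_model(0.1, 0.05, c=1.0, eta=0.01),
    ])
    def test_matches_ode_integration(self, params):
        times = np.array([0.5, 5.0, 50.0, 500.0])
        fast = linear_unaltered_fraction(params, times)
        grid = np.concatenate([[0.0], times])
        traj = integrate(params, X0, grid, atol=1e-12)
        slow = traj.unaltered[1:] / K
        assert np.allclose(fast, slow, rtol=1e-7, atol=1e-12)

    def test_rejects_nonlinear_models(self):
        with pytest.raises(ValueError):
            linear_unaltered_fraction(
                communication_model(0.1, 0.05, beta0=10.0), [1.0])
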