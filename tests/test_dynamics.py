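"""ODE core: conservation, closed forms, fixed points, monotone switching."""

import numpy as np
import pytest

import flcdyn as fd
from flcdyn.dynamics import (IDX_F, IDX_K36, IDX_V, ScheduleOutOfRange,
                             SimulationError, nucleation_efficiency, rhs,
                             simulate, steady_state_warm)
from flcdyn.temperature import DayProfile, TemperatureSchedule, make_profile

from conftest import run_condition


@pytest.fixture(scope="module")
def defaults():
    return fd.ModelParams(), fd.AntisenseParams()


class TestRHS:
    def test_no_nucleation_in_warm(self, defaults):
        p, a = defaults
        y = steady_state_warm(p, a)
        sched = fd.condition_schedule("warm", weeks_cold=1)
        dy = rhs(0.5, y, sched, p, a)
        assert dy[IDX_F["U"]] == 0.0  # dU/dt = 0 without cold

    def test_fraction_flux_sums_to_zero(self, defaults):
        p, a = defaults
        sched = fd.condition_schedule("CC")
        y = steady_state_warm(p, a)
        y[IDX_V] = 0.7
        for t in (1.0, 20.0, 60.0):
            dy = rhs(t, y, sched, p, a)
            assert abs(dy[IDX_F["U"]] + dy[IDX_F["N"]] + dy[IDX_F["S"]]) < 1e-15

    def test_gross_invariant_breach_raises(self, defaults):
        p, a = defaults
        sched = fd.condition_schedule("CC")
        y = steady_state_warm(p, a)
        y[IDX_F["U"]] = 1.5
        with pytest.raises(SimulationError):
            rhs(1.0, y, sched, p, a)


class TestSteadyStateWarm:
    def test_zero_transcription_means_no_k36_no_mrna(self, defaults):
        _, a = defaults
        p = fd.ModelParams(beta_U=3e-9, beta_N=2e-9, beta_S=1e-9)
        y = steady_state_warm(p, a)
        assert y[IDX_K36["U", "body"]] < 2e-8
        assert y[-1] < 2e-9

    def test_warm_k36_fixed_point_solves_balance(self, defaults):
        # alpha*beta_U*(cap - K36 - K27) = gamma36*K36 in state U
        p, a = defaults
        y = steady_state_warm(p, a)
        k36 = y[IDX_K36["U", "body"]]
        lhs = p.alpha36_body * p.beta_U * (p.coexistence_cap - k36 - 0.0)
        assert lhs == pytest.approx(p.gamma36 * k36, rel=1e-12)

    def test_warm_fixed_point_matches_long_simulation(self, defaults):
        p, a = defaults
        sched = fd.condition_schedule("warm", weeks_cold=5, pre_days=0.5,
                                      post_days=0.5)
        y0 = steady_state_warm(p, a)
        y0[IDX_K36["U", "body"]] = 0.1  # perturb away from the fixed point
        traj = simulate(sched, p, a, t_eval=np.linspace(0, 36, 37), y0=y0)
        assert traj.mark("K36", "U", "body")[-1] == pytest.approx(
            steady_state_warm(p, a)[IDX_K36["U", "body"]], abs=1e-6)

    def test_defective_starts_lower_k27_similar_k36(self, defaults):
        p, a = defaults
        dp, da = fd.apply_genotype(p, a, "coolair_defective")
        y_wt = steady_state_warm(p, a)
        y_def = steady_state_warm(dp, da)
        k27_wt = sum(y_wt[IDX_F[s]] * y_wt[fd.dynamics.IDX_K27[s, "nucleation"]]
                     for s in ("U", "N", "S"))
        k27_def = sum(y_def[IDX_F[s]] * y_def[fd.dynamics.IDX_K27[s, "nucleation"]]
                      for s in ("U", "N", "S"))
        k36_wt = sum(y_wt[IDX_F[s]] * y_wt[IDX_K36[s, "nucleation"]]
                     for s in ("U", "N", "S"))
        k36_def = sum(y_def[IDX_F[s]] * y_def[IDX_K36[s, "nucleation"]]
                      for s in ("U", "N", "S"))
        assert k27_def < k27_wt
        assert abs(k36_def - k36_wt) / k36_wt < 0.05


class TestSimulate:
    def test_conservation_all_genotypes(self):
        for gt in ("wild_type", "coolair_defective", "nucleation_mutant"):
            traj = run_condition(gt, "CC", n=401)
            total = (traj.fraction("U") + traj.fraction("N")
                     + traj.fraction("S"))
            assert np.max(np.abs(total - 1.0)) < 1e-6

    def test_monotone_switching(self, wt_cc):
        f_U = wt_cc.fraction("U")
        f_S = wt_cc.fraction("S")
        assert np.all(np.diff(f_U) <= 1e-10)
        assert np.all(np.diff(f_S) >= -1e-10)
        cold = ((wt_cc.times >= wt_cc.schedule.cold_start)
                & (wt_cc.times <= wt_cc.schedule.cold_end))
        nucleated = (wt_cc.fraction("N") + f_S)[cold]
        assert np.all(np.diff(nucleated) >= -1e-10)

    def test_saturated_cold_fu_decay_closed_form(self, defaults):
        # with V pinned at its cold fixed point the U->N switch is linear
        p, a = defaults
        cold = TemperatureSchedule(
            phases=((10.0, DayProfile(kind="constant", T_const=5.0)),),
            cold_phase_index=0)
        y0 = steady_state_warm(p, a)
        y0[IDX_V] = 1.0
        ts = np.linspace(0, 10, 41)
        traj = simulate(cold, p, a, t_eval=ts, y0=y0)
        k = p.k_nuc0 * nucleation_efficiency(5.0, p)
        expected = y0[IDX_F["U"]] * np.exp(-k * ts)
        assert np.max(np.abs(traj.fraction("U") - expected)) < 1e-4

    def test_pure_warm_schedule_keeps_nucleated_fraction(self, defaults):
        _, a = defaults
        p = fd.ModelParams(spreading_enabled=False)
        sched = fd.condition_schedule("warm", weeks_cold=2)
        traj = simulate(sched, p, a, t_eval=np.linspace(0, 20, 21))
        assert np.allclose(traj.fraction("N"), p.f_N0, atol=1e-9)
        p2 = fd.ModelParams()  # spreading on: f_S grows from f_N0
        traj2 = simulate(sched, p2, a, t_eval=np.linspace(0, 20, 21))
        assert traj2.fraction("S")[-1] > traj2.fraction("S")[0]

    def test_six_week_cold_switches_alleles(self, wt_cc):
        sched = wt_cc.schedule
        i_nv = np.argmin(np.abs(wt_cc.times - sched.resolve_label("NV")))
        i_6wt0 = np.argmin(np.abs(wt_cc.times - sched.resolve_label("6WT0")))
        i_6wt20 = np.argmin(np.abs(wt_cc.times - sched.resolve_label("6WT20")))
        nucleated = wt_cc.fraction("N") + wt_cc.fraction("S")
        assert nucleated[i_6wt0] > nucleated[i_nv]
        assert wt_cc.fraction("S")[i_6wt20] > wt_cc.fraction("S")[i_6wt0]

    def test_nucleation_mutant_never_acquires_k27(self):
        traj = run_condition("nucleation_mutant", "CC", n=401)
        from flcdyn.observables import population_average
        for region in ("nucleation", "body"):
            k27 = population_average(traj, "K27", region)
            assert np.max(k27.values) == 0.0

    def test_t_eval_outside_schedule_rejected(self, defaults):
        p, a = defaults
        sched = fd.condition_schedule("CC")
        with pytest.raises(ScheduleOutOfRange):
            simulate(sched, p, a, t_eval=np.linspace(0, 100, 11))

    def test_trajectory_tidy_export_roundtrip_values(self, wt_cc):
        frame = wt_cc.to_frame()
        assert set(frame.columns) == {"time_days", "variable", "state",
                                      "region", "value"}
        sub = frame[(frame.variable == "fraction") & (frame.state == "U")]
        assert np.allclose(sub["value"].to_numpy(), wt_cc.fraction("U"))


class TestOracleEquivalence:
    def test_adaptive_matches_fixed_step_euler(self, defaults):
        """Adaptive solver vs dt=1e-4 Euler on a 3-day schedule with edges."""
        p, a = defaults
        sched = TemperatureSchedule(
            phases=((1.0, DayProfile(kind="constant", T_const=22.0)),
                    (2.0, make_profile("cycle", (-1.0, 12.0),
                                       cold_fraction=0.625))),
            cold_phase_index=1)
        dt = 1e-4
        y = steady_state_warm(p, a).copy()
        chk = np.linspace(0, 3, 31)
        out, ci, t = [], 0, 0.0
        for i in range(int(round(3.0 / dt)) + 1):
            if ci < len(chk) and abs(t - chk[ci]) < dt / 2:
                out.append(y.copy())
                ci += 1
            y = y + dt * rhs(t, y, sched, p, a)
            t = (i + 1) * dt
        euler = np.array(out)
        traj = simulate(sched, p, a, t_eval=chk)
        scale = np.maximum(np.abs(euler), 1e-6)
        assert np.max(np.abs(traj.states - euler) / scale) < 1e-3
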