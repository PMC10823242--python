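"""The ODE core: allele-state switching, histone-mark kinetics, mRNA.

State vector (length 18):

====  =========================================================
0     V        cold-memory level (VIN3-like), saturating at 1
1     a_slow   slow antisense component
2-4   f_U, f_N, f_S   allele-state fractions (sum to 1)
5-10  K36[state][region]   cotranscriptional mark, per state/region
11-16 K27[state][region]   Polycomb mark, per state/region
17    M        unspliced-mRNA proxy (arbitrary units)
====  =========================================================

State order is (U, N, S) x (nucleation, body).  The population
observable for a mark is the f-weighted mean over states.

Nucleation converts U alleles to N at rate k_nuc0 * V * eta(T) inside
the cold, where eta is a Gaussian temperature-efficiency centred near
the constant-cold optimum; spreading converts N to S in proportion to
cell-cycle activity (low in cold, full in warm).  K36 is deposited per
transcription event with a Pol II dwell-time factor that grows as
temperature falls, limited by free nucleosome capacity
(cap - K36 - K27)+; K27 relaxes to a per-state target.  Transcription is
repressed by the antisense factor in states U and N only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .antisense import a_slow_rhs, repression_factor
from .params import AntisenseParams, ModelParams, REGIONS, STATES
from .temperature import TemperatureSchedule

N_STATE = 18
IDX_V, IDX_A = 0, 1
IDX_F = {"U": 2, "N": 3, "S": 4}
IDX_K36 = {(s, r): 5 + 2 * i + j
           for i, s in enumerate(STATES) for j, r in enumerate(REGIONS)}
IDX_K27 = {(s, r): 11 + 2 * i + j
           for i, s in enumerate(STATES) for j, r in enumerate(REGIONS)}
IDX_M = 17


class SimulationError(RuntimeError):
    pass


def _is_cold(T: float, antisense: AntisenseParams) -> bool:
    return T < antisense.T_cold


def nucleation_efficiency(T: float, p: ModelParams) -> float:
    """Gaussian temperature dependence of PRC2 nucleation, peak at nuc_T_opt."""
    z = (T - p.nuc_T_opt) / p.nuc_T_width
    return math.exp(-z * z)


def dwell_factor(T: float, p: ModelParams, region: str) -> float:
    """Pol II dwell-time multiplier >= 1; grows linearly as T drops from
    dwell_T_on, saturating at dwell_T_sat."""
    if region == "body" and not p.dwell_body_enabled:
        return 1.0
    span = p.dwell_T_on - p.dwell_T_sat
    phi = min(1.0, max(0.0, (p.dwell_T_on - T) / span))
    return 1.0 + p.delta_dwell * phi


def transcription_rates(r: float, p: ModelParams) -> dict:
    """Per-state transcription rates; antisense represses U and N only."""
    return {"U": p.beta_U * r, "N": p.beta_N * r, "S": p.beta_S}


def rhs(t: float, y: np.ndarray, schedule: TemperatureSchedule,
        params: ModelParams, antisense: AntisenseParams) -> np.ndarray:
    """Time derivative of the full state vector at time t (days)."""
    f_U, f_N, f_S = y[IDX_F["U"]], y[IDX_F["N"]], y[IDX_F["S"]]
    eps = 1e-3
    for f in (f_U, f_N, f_S):
        if f < -eps or f > 1 + eps:
            raise SimulationError(f"state fraction {f} outside [0,1] at t={t}")

    T = schedule.temperature(t)
    cold = 1.0 if _is_cold(T, antisense) else 0.0
    V = y[IDX_V]
    a = y[IDX_A]
    r = repression_factor(a, T, antisense)

    dy = np.zeros(N_STATE)
    # cold memory: saturating ramp in cold, fast reset in warm
    dy[IDX_V] = params.v_ramp * (1.0 - V) * cold - params.v_decay * (1.0 - cold) * V
    dy[IDX_A] = a_slow_rhs(a, T, antisense)

    k_nuc = (params.k_nuc0 * V * nucleation_efficiency(T, params) * cold
             if params.nucleation_enabled else 0.0)
    g = params.g_cold if cold else params.g_warm
    k_sp = params.k_spread * g if params.spreading_enabled else 0.0

    dy[IDX_F["U"]] = -k_nuc * f_U
    dy[IDX_F["N"]] = k_nuc * f_U - k_sp * f_N
    dy[IDX_F["S"]] = k_sp * f_N

    tau = transcription_rates(r, params)
    cap = params.coexistence_cap
    for s in STATES:
        for reg in REGIONS:
            k36 = y[IDX_K36[s, reg]]
            k27 = y[IDX_K27[s, reg]]
            free = max(0.0, cap - k36 - k27)
            dy[IDX_K36[s, reg]] = (params.alpha36(reg) * tau[s]
                                   * dwell_factor(T, params, reg) * free
                                   - params.gamma36 * k36)
            dy[IDX_K27[s, reg]] = params.k27_relax * (params.K27_target[s][reg] - k27)

    production = f_U * tau["U"] + f_N * tau["N"] + f_S * tau["S"]
    dy[IDX_M] = production - params.lambda_m * y[IDX_M]
    return dy


def steady_state_warm(params: ModelParams, antisense: AntisenseParams,
                      warm_T: float = 22.0) -> np.ndarray:
    """Pre-cold (NV) equilibrium state vector.

    V = 0; a_slow = 0 (or a_slow_max for constitutive antisense);
    fractions (1 - f_N0 - f_S0, f_N0, f_S0); K27 at its per-state
    targets; K36 at the warm balance of cotranscriptional addition and
    removal, alpha*tau*(cap - K36 - K27*) = gamma36*K36; M at
    production/degradation balance.
    """
    params.validate()
    antisense.validate()
    y = np.zeros(N_STATE)
    a = antisense.a_slow_max if antisense.constitutive else 0.0
    if antisense.disabled:
        a = 0.0
    y[IDX_A] = a
    r = repression_factor(a, warm_T, antisense)
    f_U0 = 1.0 - params.f_N0 - params.f_S0
    y[IDX_F["U"]], y[IDX_F["N"]], y[IDX_F["S"]] = f_U0, params.f_N0, params.f_S0
    tau = transcription_rates(r, params)
    cap = params.coexistence_cap
    for s in STATES:
        for reg in REGIONS:
            k27 = params.K27_target[s][reg]
            y[IDX_K27[s, reg]] = k27
            dep = params.alpha36(reg) * tau[s] * dwell_factor(warm_T, params, reg)
            denom = params.gamma36 + dep
            y[IDX_K36[s, reg]] = dep * max(0.0, cap - k27) / denom if denom > 0 else 0.0
    prod = f_U0 * tau["U"] + params.f_N0 * tau["N"] + params.f_S0 * tau["S"]
    y[IDX_M] = prod / params.lambda_m if params.lambda_m > 0 else 0.0
    return y


@dataclass
class Trajectory:
    """Dense simulation output on a fixed evaluation grid."""

    times: np.ndarray          # days, strictly increasing
    states: np.ndarray         # (len(times), N_STATE)
    schedule: TemperatureSchedule
    params: ModelParams
    antisense: AntisenseParams
    genotype: str = "wild_type"

    def fraction(self, state: str) -> np.ndarray:
        return self.states[:, IDX_F[state]]

    def mark(self, quantity: str, state: str, region: str) -> np.ndarray:
        idx = IDX_K36 if quantity == "K36" else IDX_K27
        return self.states[:, idx[state, region]]

    @property
    def mRNA(self) -> np.ndarray:
        return self.states[:, IDX_M]

    @property
    def a_slow(self) -> np.ndarray:
        return self.states[:, IDX_A]

    def repression(self) -> np.ndarray:
        return np.array([
            repression_factor(a, self.schedule.temperature(t), self.antisense)
            for t, a in zip(self.times, self.a_slow)])

    def to_frame(self):
        """Tidy export: columns time_days, variable, state, region, value."""
        import pandas as pd
        rows = []
        for i, t in enumerate(self.times):
            for s in STATES:
                rows.append((t, "fraction", s, "", self.states[i, IDX_F[s]]))
                for reg in REGIONS:
                    rows.append((t, "K36", s, reg, self.states[i, IDX_K36[s, reg]]))
                    rows.append((t, "K27", s, reg, self.states[i, IDX_K27[s, reg]]))
            rows.append((t, "mRNA", "", "", self.states[i, IDX_M]))
            rows.append((t, "V", "", "", self.states[i, IDX_V]))
            rows.append((t, "a_slow", "", "", self.states[i, IDX_A]))
        return pd.DataFrame(rows, columns=["time_days", "variable", "state",
                                           "region", "value"])


def simulate(schedule: TemperatureSchedule, params: ModelParams,
             antisense: AntisenseParams, t_eval=None,
             genotype: str = "wild_type", y0: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA", conservation_tol: float = 1e-6) -> Trajectory:
    """Integrate the model over a temperature schedule.

    The integration restarts at every temperature discontinuity (phase
    boundary or square-wave edge) so the stiff adaptive solver never
    steps across a jump in the forcing.  Raises SimulationError on
    integrator failure or if the allele-fraction conservation
    f_U + f_N + f_S = 1 drifts beyond ``conservation_tol``.
    """
    params.validate()
    antisense.validate()
    if t_eval is None:
        t_eval = np.linspace(0.0, schedule.total_days, 701)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    if t_eval[0] < 0 or t_eval[-1] > schedule.total_days + 1e-9:
        raise ScheduleOutOfRange(
            f"t_eval spans [{t_eval[0]}, {t_eval[-1]}] but schedule covers "
            f"[0, {schedule.total_days}]")

    if y0 is None:
        y0 = steady_state_warm(params, antisense)
    y = np.array(y0, dtype=float)

    edges = [p for p in schedule.discontinuities() if p < t_eval[-1]]
    segments = sorted(set(edges + [float(t_eval[-1])]))
    if segments[0] > 0.0:
        segments = [0.0] + segments

    out = np.empty((len(t_eval), N_STATE))
    filled = 0
    t_start = segments[0]
    if t_eval[0] == t_start:
        out[0] = y
        filled = 1
    for t_end in segments[1:]:
        mask = (t_eval > t_start + 1e-12) & (t_eval <= t_end + 1e-12)
        seg_eval = np.clip(t_eval[mask], t_start, t_end)
        # always solve through to t_end so the next segment starts exactly
        # at the edge; requested output points are a subset
        solve_points = np.unique(np.concatenate([seg_eval, [t_end]]))
        max_step = max((t_end - t_start) / 4.0, 1e-3)
        _, _, prof = schedule.phase_at(0.5 * (t_start + t_end))
        if prof.kind == "cycle" and prof.shape == "sinusoid":
            # resolve the smooth within-day oscillation
            max_step = min(max_step, prof.period_hours / 24.0 / 8.0)
        sol = solve_ivp(
            rhs, (t_start, t_end), y, t_eval=solve_points,
            args=(schedule, params, antisense),
            method=method, rtol=rtol, atol=atol, dense_output=False,
            max_step=max_step)
        if not sol.success:
            raise SimulationError(f"integrator failed on [{t_start}, {t_end}]: "
                                  f"{sol.message}")
        if seg_eval.size:
            pos = np.clip(np.searchsorted(sol.t, seg_eval), 0, len(sol.t) - 1)
            out[filled:filled + seg_eval.size] = sol.y.T[pos]
            filled += seg_eval.size
        y = sol.y[:, -1]
        t_start = t_end
    if filled != len(t_eval):
        raise SimulationError("internal error: evaluation grid not covered")

    frac_sum = out[:, IDX_F["U"]] + out[:, IDX_F["N"]] + out[:, IDX_F["S"]]
    drift = np.max(np.abs(frac_sum - 1.0))
    if drift > conservation_tol:
        raise SimulationError(f"allele-fraction conservation violated: {drift:g}")

    return Trajectory(times=t_eval, states=out, schedule=schedule,
                      params=params, antisense=antisense, genotype=genotype)


class ScheduleOutOfRange(ValueError):
    pass
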