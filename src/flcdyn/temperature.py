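"""Experimental temperature schedules.

A schedule is an ordered list of phases (duration in days, within-day
profile).  Profiles are either constant or a daily min–max cycle (square
or sinusoid).  Time unit is days throughout the package; within-day
profiles are parameterized in hours and converted internally.

Presets follow the vernalization cabinet conditions: CC (constant 5 C),
FM (fluctuating mild, 3–9 C daily cycle) and FS (fluctuating strong,
−1–12 C daily cycle), embedded in a warm 22 C pre- and post-cold phase.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

HOURS_PER_DAY = 24.0


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class DayProfile:
    """Within-day temperature profile.

    ``square`` cycles spend ``cold_fraction`` of each period at ``T_min``
    (starting at the beginning of the period, i.e. the night segment)
    and the remainder at ``T_max``.  ``sinusoid`` cycles attain ``T_min``
    at the start of the period and ``T_max`` half a period later.
    """

    kind: str = "constant"            # "constant" | "cycle"
    T_const: float = 22.0             # degC, constant kind
    T_min: float = 0.0                # degC, cycle kind
    T_max: float = 0.0
    period_hours: float = 24.0
    shape: str = "square"             # "square" | "sinusoid"
    cold_fraction: float = 0.5        # square only: fraction of period at T_min

    def __post_init__(self):
        if self.kind not in ("constant", "cycle"):
            raise ScheduleError(f"unknown profile kind {self.kind!r}")
        if self.kind == "cycle":
            if self.T_min > self.T_max:
                raise ScheduleError(f"T_min={self.T_min} > T_max={self.T_max}")
            if self.period_hours <= 0:
                raise ScheduleError("period must be positive")
            if self.shape not in ("square", "sinusoid"):
                raise ScheduleError(f"unknown cycle shape {self.shape!r}")
            if not 0.0 < self.cold_fraction < 1.0:
                raise ScheduleError("cold_fraction must be in (0,1)")

    def temperature(self, t_days: float) -> float:
        """Temperature at time ``t_days`` measured from the phase start."""
        if self.kind == "constant":
            return self.T_const
        period_days = self.period_hours / HOURS_PER_DAY
        frac = (t_days / period_days) % 1.0
        if self.shape == "square":
            return self.T_min if frac < self.cold_fraction else self.T_max
        mid = 0.5 * (self.T_min + self.T_max)
        amp = 0.5 * (self.T_max - self.T_min)
        return mid - amp * math.cos(2.0 * math.pi * frac)


def make_profile(kind: str, temperatures, period_hours: float = 24.0,
                 shape: str = "square", cold_fraction: float = 0.5) -> DayProfile:
    """Build a DayProfile from a kind and its temperature(s).

    ``temperatures`` is a single value for ``constant`` and a
    ``(T_min, T_max)`` pair for ``cycle``.
    """
    if kind == "constant":
        T = float(temperatures if not isinstance(temperatures, (tuple, list))
                  else temperatures[0])
        return DayProfile(kind="constant", T_const=T)
    if kind == "cycle":
        T_min, T_max = (float(temperatures[0]), float(temperatures[1]))
        return DayProfile(kind="cycle", T_min=T_min, T_max=T_max,
                          period_hours=period_hours, shape=shape,
                          cold_fraction=cold_fraction)
    raise ScheduleError(f"unknown profile kind {kind!r}")


@dataclass(frozen=True)
class TemperatureSchedule:
    """Piecewise experiment protocol: ordered (duration_days, profile) phases.

    Phase intervals are half-open [start, end), so T(t) is single-valued
    at boundaries (a boundary time belongs to the later phase).  The time
    origin t = 0 is the start of the first phase.
    """

    phases: tuple = ()
    # indices of (pre-cold end, cold end); None for schedules without the
    # canonical warm/cold/warm structure
    cold_phase_index: int | None = None

    def __post_init__(self):
        if not self.phases:
            raise ScheduleError("schedule needs at least one phase")
        for dur, prof in self.phases:
            if dur <= 0:
                raise ScheduleError("phase durations must be positive")
            if not isinstance(prof, DayProfile):
                raise ScheduleError("phase profile must be a DayProfile")

    @property
    def total_days(self) -> float:
        return sum(d for d, _ in self.phases)

    @property
    def boundaries(self) -> list:
        """Phase start times, plus the final end time."""
        b, t = [0.0], 0.0
        for d, _ in self.phases:
            t += d
            b.append(t)
        return b

    def phase_at(self, t: float):
        """(phase start, duration, profile) containing time t (half-open)."""
        if t < 0 or t > self.total_days:
            raise ScheduleError(f"t={t} outside schedule [0, {self.total_days}]")
        start = 0.0
        for d, prof in self.phases:
            if t < start + d:
                return start, d, prof
            start += d
        # t == total duration: belongs to the last phase's closure
        d, prof = self.phases[-1]
        return start - d, d, prof

    def temperature(self, t: float) -> float:
        start, _, prof = self.phase_at(t)
        return prof.temperature(t - start)

    def discontinuities(self) -> list:
        """Sorted interior times where T(t) may jump (phase edges and
        square-wave switch points); integration restarts at each."""
        pts = set()
        start = 0.0
        for d, prof in self.phases:
            pts.add(start)
            if prof.kind == "cycle" and prof.shape == "square":
                period = prof.period_hours / HOURS_PER_DAY
                k = 0
                while k * period < d:
                    pts.add(start + k * period)
                    tc = start + (k + prof.cold_fraction) * period
                    if tc < start + d:
                        pts.add(tc)
                    k += 1
            start += d
        pts.add(start)
        return sorted(p for p in pts if 0.0 <= p <= self.total_days)

    # --- canonical protocol helpers -----------------------------------
    @property
    def cold_start(self) -> float:
        if self.cold_phase_index is None:
            raise ScheduleError("schedule has no designated cold phase")
        return sum(d for d, _ in self.phases[: self.cold_phase_index])

    @property
    def cold_end(self) -> float:
        return self.cold_start + self.phases[self.cold_phase_index][0]

    def resolve_label(self, label: str) -> float:
        """Map a timepoint label (NV, 2WT0, 6WT10, ...) to a time in days.

        NV is the end of the pre-cold warm phase; kWT0 is after k weeks
        of cold; kWTm is m days after the end of a k-week cold treatment
        (requires the schedule's cold phase to be exactly k weeks).
        """
        label = label.strip()
        if label.upper() == "NV":
            return self.cold_start
        m = re.fullmatch(r"(\d+)WT(\d+)", label.upper())
        if not m:
            raise ScheduleError(f"unrecognized timepoint label {label!r}")
        weeks, days_after = int(m.group(1)), int(m.group(2))
        cold_days = self.cold_end - self.cold_start
        if weeks * 7 > cold_days + 1e-9:
            raise ScheduleError(
                f"label {label!r} needs {weeks} wk of cold but schedule has "
                f"{cold_days / 7:g} wk")
        if days_after > 0 and abs(weeks * 7 - cold_days) > 1e-9:
            raise ScheduleError(
                f"post-cold label {label!r} requires a {weeks}-wk cold phase")
        t = self.cold_start + weeks * 7 + days_after
        if t > self.total_days + 1e-9:
            raise ScheduleError(f"label {label!r} lies beyond the schedule end")
        return t


CONDITION_PROFILES = {
    "CC": dict(kind="constant", temperatures=5.0),
    "FM": dict(kind="cycle", temperatures=(3.0, 9.0)),
    "FS": dict(kind="cycle", temperatures=(-1.0, 12.0)),
}


def condition_schedule(condition: str = "CC", weeks_cold: float = 6.0,
                       pre_days: float = 14.0, post_days: float = 28.0,
                       warm_T: float = 22.0, shape: str = "square",
                       cold_fraction: float = 0.625) -> TemperatureSchedule:
    """Canonical vernalization protocol: warm, N weeks cold, warm.

    ``condition`` is one of the presets CC/FM/FS or "warm" for a
    cold-free control of the same total length.  The fluctuating
    presets spend ``cold_fraction`` of each day at their minimum; the
    default 0.625 (15 h night / 9 h day) reflects the short photoperiod
    of late-autumn cabinet programs.
    """
    warm = DayProfile(kind="constant", T_const=warm_T)
    if condition == "warm":
        total = pre_days + weeks_cold * 7 + post_days
        return TemperatureSchedule(phases=((total, warm),), cold_phase_index=None)
    if condition not in CONDITION_PROFILES:
        raise ScheduleError(f"unknown condition {condition!r} (use CC, FM, FS)")
    spec = CONDITION_PROFILES[condition]
    cold = make_profile(spec["kind"], spec["temperatures"], shape=shape,
                        cold_fraction=cold_fraction)
    phases = ((pre_days, warm), (weeks_cold * 7.0, cold), (post_days, warm))
    return TemperatureSchedule(phases=phases, cold_phase_index=1)


def evaluate(schedule: TemperatureSchedule, t: float) -> float:
    """Temperature (degC) of the schedule at time t (days)."""
    return schedule.temperature(t)


def below_threshold_indicator(schedule: TemperatureSchedule, t: float,
                              T_thresh: float) -> int:
    """1 iff T(t) < T_thresh, else 0."""
    return 1 if schedule.temperature(t) < T_thresh else 0
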