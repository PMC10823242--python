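"""Measurement-comparable observables from simulated trajectories.

ChIP-style observables are population averages: the f-weighted mean of
the per-state mark level in a region, mirroring how ChIP enrichment
averages over all alleles in the tissue.  The mRNA observable passes the
single mRNA pool through.  Series can be normalized to their NV
(nonvernalized) value, matching how time-course data are usually shown
relative to the pre-cold sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .params import REGIONS, STATES

QUANTITIES = ("K36", "K27", "mRNA")


class ObservableError(ValueError):
    pass


@dataclass
class ObservableSeries:
    """A single population-averaged time series for one (quantity, region)."""

    quantity: str                  # K36 | K27 | mRNA
    region: str                    # nucleation | body | NA (mRNA)
    times: np.ndarray              # days
    values: np.ndarray             # dimensionless, >= 0
    normalization: str = "none"    # none | relative_to_NV
    genotype: str = "wild_type"
    schedule: object = None

    def value_at(self, t: float, tol: float = 0.01) -> float:
        """Value at the stored time nearest to t (within tol days)."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > tol:
            raise ObservableError(
                f"no stored time within {tol} d of t={t} "
                f"(nearest is {self.times[i]})")
        return float(self.values[i])

    def relative_to_nv(self, nv_time: float | None = None) -> "ObservableSeries":
        """Normalize so the series is 1 at the NV timepoint (idempotent)."""
        if nv_time is None:
            if self.schedule is None:
                raise ObservableError("need a schedule or explicit nv_time")
            nv_time = self.schedule.resolve_label("NV")
        nv = self.value_at(nv_time)
        if nv <= 0:
            raise ObservableError("NV value is zero; cannot normalize")
        return replace(self, values=self.values / nv,
                       normalization="relative_to_NV")


def population_average(traj: Trajectory, quantity: str,
                       region: str = "NA") -> ObservableSeries:
    """Population-averaged observable: sum_state f_state * mark[state][region]."""
    if quantity == "mRNA":
        vals = traj.mRNA.copy()
        region = "NA"
    elif quantity in ("K36", "K27"):
        if region not in REGIONS:
            raise ObservableError(f"unknown region {region!r} (use "
                                  f"{REGIONS[0]!r} or {REGIONS[1]!r})")
        vals = np.zeros_like(traj.times, dtype=float)
        for s in STATES:
            vals += traj.fraction(s) * traj.mark(quantity, s, region)
    else:
        raise ObservableError(f"unknown quantity {quantity!r}")
    return ObservableSeries(quantity=quantity, region=region, times=traj.times,
                            values=vals, genotype=traj.genotype,
                            schedule=traj.schedule)


def sample_at_timepoints(series: ObservableSeries, labels,
                         tol: float = 0.01) -> pd.DataFrame:
    """Sample a series at named protocol timepoints (NV, 2WT0, ...).

    Nearest-time sampling with tolerance ``tol`` days.  Returns a tidy
    table with columns timepoint, time_days, quantity, region, value.
    """
    if series.schedule is None:
        raise ObservableError("series carries no schedule; labels unresolvable")
    rows = []
    for label in labels:
        t = series.schedule.resolve_label(label)
        rows.append((label, t, series.quantity, series.region,
                     series.value_at(t, tol=tol)))
    return pd.DataFrame(rows, columns=["timepoint", "time_days", "quantity",
                                       "region", "value"])


def condition_contrast(trajectories: dict, quantity: str, region: str,
                       label: str, nv_label: str = "NV") -> pd.DataFrame:
    """Compare one observable across conditions (e.g. CC/FM/FS) at a label.

    ``trajectories`` maps condition name -> Trajectory; all must share a
    genotype.  Returns a table with the value at the label, the change
    from NV, and the rank of |change| (1 = largest change).
    """
    genotypes = {t.genotype for t in trajectories.values()}
    if len(genotypes) > 1:
        raise ObservableError(f"mismatched genotypes across conditions: "
                              f"{sorted(genotypes)}")
    rows = []
    for cond, traj in trajectories.items():
        series = population_average(traj, quantity, region)
        nv = series.value_at(traj.schedule.resolve_label(nv_label))
        val = series.value_at(traj.schedule.resolve_label(label))
        rows.append((cond, quantity, region, label, val, nv, val - nv))
    df = pd.DataFrame(rows, columns=["condition", "quantity", "region",
                                     "timepoint", "value", "nv_value",
                                     "change_from_nv"])
    df["abs_change_rank"] = (df["change_from_nv"].abs()
                             .rank(ascending=False, method="min").astype(int))
    return df.sort_values("abs_change_rank").reset_index(drop=True)


def observable_table(traj: Trajectory, labels,
                     quantities_regions=None) -> pd.DataFrame:
    """All standard observables of one trajectory at protocol timepoints.

    Default grid: K36 and K27 in both regions, plus mRNA.
    """
    if quantities_regions is None:
        quantities_regions = ([("K36", r) for r in REGIONS]
                              + [("K27", r) for r in REGIONS]
                              + [("mRNA", "NA")])
    frames = []
    for q, reg in quantities_regions:
        series = population_average(traj, q, reg)
        frames.append(sample_at_timepoints(series, labels))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "genotype", traj.genotype)
    return out
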