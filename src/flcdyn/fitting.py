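"""Weighted least-squares fitting of model parameters to time-course data.

The objective compares model observables (population-averaged K36/K27
per region, mRNA) with replicate means at the dataset's timepoints.
Absolute ChIP units are arbitrary, so a per-(quantity, region) scale
factor is profiled analytically (closed-form weighted least-squares
optimum) before the nonlinear step; the optimizer therefore only sees
shape information.  Optimization is bounded local search (L-BFGS-B on a
unit box) from multiple reproducible starts — the aim is qualitative
capture of the dynamics, not posterior inference.

Free parameters are addressed by path ("k_nuc0", "antisense.a_slow_max",
...).  Two virtual paths keep the transcription hierarchy
beta_U > beta_N > beta_S under fitting by construction:
``beta_N_frac`` = beta_N/beta_U and ``beta_S_frac`` = beta_S/beta_N,
both bounded inside (0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dynamics import simulate
from .genotypes import apply_genotype
from .observables import observable_table
from .params import AntisenseParams, ModelParams, set_param
from .temperature import condition_schedule

PENALTY_LOSS = 1e12
VIRTUAL_PATHS = ("beta_N_frac", "beta_S_frac")


class FitError(RuntimeError):
    pass


@dataclass
class FitSpec:
    """Declaration of the fitting problem.

    ``free_params`` maps parameter paths to finite (lo, hi) bounds.
    ``fixed_overrides`` are applied to the baseline before fitting.
    ``loss`` is "linear" (residuals on the measurement scale) or "log"
    (residuals on log scale).  Weights default to 1/SEM^2 where a cell
    has >= 2 replicates (with a relative SEM floor), else 1.
    """

    free_params: dict = field(default_factory=dict)   # path -> (lo, hi)
    fixed_overrides: dict = field(default_factory=dict)
    loss: str = "linear"
    weights: str = "sem"          # "sem" | "uniform"
    weight_scale: float = 1.0     # global multiplier on all weights
    starts: int = 10
    seed: int = 0
    init: dict | None = None      # optional explicit first start (path -> value)
    weeks_cold: float = 6.0
    post_days: float = 28.0
    sem_rel_floor: float = 0.02   # SEM floor as a fraction of the cell mean
    maxiter: int = 80

    def __post_init__(self):
        if not self.free_params:
            raise FitError("free_params must be nonempty")
        for path, (lo, hi) in self.free_params.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise FitError(f"bounds for {path!r} must be finite and "
                               f"ordered, got ({lo}, {hi})")
        if self.loss not in ("linear", "log"):
            raise FitError(f"unknown loss {self.loss!r}")

    @property
    def paths(self) -> list:
        return list(self.free_params)


def _apply_candidate(base_params: ModelParams, base_antisense: AntisenseParams,
                     fitspec: FitSpec, x: np.ndarray):
    """Baseline + fixed overrides + free values -> validated param objects."""
    p = base_params.copy()
    a = base_antisense.copy()
    for path, v in fitspec.fixed_overrides.items():
        _set_with_virtual(p, a, path, v)
    for path, v in zip(fitspec.paths, x):
        _set_with_virtual(p, a, path, float(v))
    p.validate()
    a.validate()
    return p, a


def _set_with_virtual(p: ModelParams, a: AntisenseParams, path: str, value):
    if path == "beta_N_frac":
        p.beta_N = value * p.beta_U
    elif path == "beta_S_frac":
        p.beta_S = value * p.beta_N
    else:
        set_param(p, a, path, value)


def _model_predictions(p: ModelParams, a: AntisenseParams, cells: pd.DataFrame,
                       fitspec: FitSpec) -> pd.DataFrame:
    """Model observable for every measurement cell in ``cells``."""
    preds = []
    for (gt, cond), grp in cells.groupby(["genotype", "condition"], sort=True):
        gp, ga = apply_genotype(p, a, gt)
        sched = condition_schedule(cond, weeks_cold=fitspec.weeks_cold,
                                   post_days=fitspec.post_days)
        labels = sorted(grp["timepoint"].unique(),
                        key=lambda lb: sched.resolve_label(lb))
        times = np.unique([0.0, sched.total_days]
                          + [sched.resolve_label(lb) for lb in labels])
        traj = simulate(sched, gp, ga, t_eval=times, genotype=gt)
        tab = observable_table(traj, labels)
        tab["condition"] = cond
        preds.append(tab.rename(columns={"value": "model"}))
    pred = pd.concat(preds, ignore_index=True)
    return cells.merge(
        pred[["genotype", "condition", "quantity", "region", "timepoint",
              "model"]],
        on=["genotype", "condition", "quantity", "region", "timepoint"],
        how="left", validate="one_to_one")


def _cell_table(dataset, fitspec: FitSpec) -> pd.DataFrame:
    cells = dataset.cell_means()
    if fitspec.weights == "uniform":
        cells["weight"] = 1.0
    else:
        sem = cells["sem"].to_numpy(dtype=float)
        floor = fitspec.sem_rel_floor * cells["mean"].to_numpy(dtype=float)
        sem = np.where(np.isfinite(sem) & (cells["n"].to_numpy() >= 2),
                       np.maximum(sem, floor), np.nan)
        w = np.where(np.isnan(sem), 1.0, 1.0 / sem ** 2)
        cells["weight"] = w
    cells["weight"] *= fitspec.weight_scale
    return cells


def _profiled_scales(merged: pd.DataFrame, loss_kind: str) -> dict:
    """Closed-form optimal scale per (quantity, region) group."""
    scales = {}
    for (q, reg), grp in merged.groupby(["quantity", "region"], sort=True):
        w = grp["weight"].to_numpy(float)
        m = grp["model"].to_numpy(float)
        y = grp["mean"].to_numpy(float)
        if loss_kind == "log":
            ok = (m > 0) & (y > 0)
            if not ok.any():
                scales[(q, reg)] = 1.0
                continue
            lw = w[ok]
            scales[(q, reg)] = float(np.exp(
                np.sum(lw * (np.log(y[ok]) - np.log(m[ok]))) / np.sum(lw)))
        else:
            denom = float(np.sum(w * m * m))
            scales[(q, reg)] = (float(np.sum(w * m * y)) / denom
                                if denom > 0 else 1.0)
    return scales


def _residual_table(merged: pd.DataFrame, scales: dict,
                    loss_kind: str) -> pd.DataFrame:
    out = merged.copy()
    out["scale"] = [scales[(q, r)] for q, r in zip(out["quantity"],
                                                   out["region"])]
    out["fitted"] = out["scale"] * out["model"]
    if loss_kind == "log":
        fitted = np.maximum(out["fitted"].to_numpy(float), 1e-12)
        mean = np.maximum(out["mean"].to_numpy(float), 1e-12)
        out["residual"] = np.log(fitted) - np.log(mean)
    else:
        out["residual"] = out["fitted"] - out["mean"]
    out["loss_term"] = out["weight"] * out["residual"] ** 2
    return out


def loss(candidate, dataset, fitspec: FitSpec,
         base_params: ModelParams | None = None,
         base_antisense: AntisenseParams | None = None,
         return_detail: bool = False):
    """Weighted least-squares objective for a free-parameter vector.

    Simulation or validation failures return a large penalty value (with
    a warning) rather than raising, so optimization can continue.
    """
    base_params = base_params or ModelParams()
    base_antisense = base_antisense or AntisenseParams()
    x = np.asarray(candidate, dtype=float)
    if x.shape != (len(fitspec.paths),):
        raise FitError(f"candidate must have {len(fitspec.paths)} entries")
    try:
        p, a = _apply_candidate(base_params, base_antisense, fitspec, x)
        cells = _cell_table(dataset, fitspec)
        merged = _model_predictions(p, a, cells, fitspec)
    except Exception as exc:  # noqa: BLE001 - penalty by design
        if isinstance(exc, FitError):
            raise
        warnings.warn(f"candidate {dict(zip(fitspec.paths, x))} penalized: "
                      f"{exc}", stacklevel=2)
        return (PENALTY_LOSS, None) if return_detail else PENALTY_LOSS
    scales = _profiled_scales(merged, fitspec.loss)
    detail = _residual_table(merged, scales, fitspec.loss)
    value = float(detail["loss_term"].sum())
    if return_detail:
        return value, {"residuals": detail, "scales": scales,
                       "params": p, "antisense": a}
    return value


@dataclass
class FitResult:
    """Outcome of a multi-start fit."""

    best_params: dict              # path -> fitted value
    best_loss: float
    scales: dict                   # (quantity, region) -> calibration factor
    starts_table: pd.DataFrame     # per-start record
    residuals: pd.DataFrame        # per-cell fitted values and residuals
    fitspec: FitSpec
    params: ModelParams            # realized best parameter objects
    antisense: AntisenseParams
    converged: bool

    @property
    def x(self) -> np.ndarray:
        return np.array([self.best_params[p] for p in self.fitspec.paths])


def fit(dataset, fitspec: FitSpec,
        base_params: ModelParams | None = None,
        base_antisense: AntisenseParams | None = None) -> FitResult:
    """Bounded multi-start local optimization of the fitting objective.

    Starts are drawn reproducibly from the bounds with the fitspec's
    seed (an explicit ``fitspec.init`` replaces the first draw), so the
    best loss over the first k starts is nonincreasing in k for a fixed
    seed.  Deterministic for fixed inputs.  Raises FitError if every
    start fails.
    """
    base_params = base_params or ModelParams()
    base_antisense = base_antisense or AntisenseParams()
    paths = fitspec.paths
    lo = np.array([fitspec.free_params[p][0] for p in paths], dtype=float)
    hi = np.array([fitspec.free_params[p][1] for p in paths], dtype=float)
    span = hi - lo
    degenerate = span <= 0

    def to_unit(x):
        u = np.zeros_like(x)
        nz = ~degenerate
        u[nz] = (x[nz] - lo[nz]) / span[nz]
        return u

    def from_unit(u):
        return np.where(degenerate, lo, lo + u * span)

    def objective(u):
        return loss(from_unit(np.clip(u, 0, 1)), dataset, fitspec,
                    base_params, base_antisense)

    rng = np.random.default_rng(fitspec.seed)
    start_units = rng.uniform(size=(fitspec.starts, len(paths)))
    if fitspec.init is not None:
        x0 = np.array([fitspec.init[p] for p in paths], dtype=float)
        start_units[0] = to_unit(x0)

    records = []
    best = None
    for k, u0 in enumerate(start_units):
        try:
            if degenerate.all():
                u_best, f_best, ok = u0, objective(u0), True
            else:
                res = minimize(objective, u0, method="L-BFGS-B",
                               bounds=[(0.0, 1.0)] * len(paths),
                               options={"maxiter": fitspec.maxiter,
                                        "eps": 1e-4})
                u_best, f_best, ok = res.x, float(res.fun), bool(res.success)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"start {k} failed: {exc}", stacklevel=2)
            records.append({"start": k, "loss": np.nan, "converged": False,
                            **{f"x0_{p}": v for p, v in
                               zip(paths, from_unit(u0))}})
            continue
        x_best = from_unit(np.clip(u_best, 0, 1))
        rec = {"start": k, "loss": f_best, "converged": ok}
        rec.update({f"x0_{p}": v for p, v in zip(paths, from_unit(u0))})
        rec.update({f"x_{p}": v for p, v in zip(paths, x_best)})
        records.append(rec)
        if np.isfinite(f_best) and (best is None or f_best < best[1]):
            best = (x_best, f_best, ok)
    starts_table = pd.DataFrame(records)
    if best is None:
        raise FitError("all optimization starts failed")

    x_best, f_best, ok = best
    f_check, detail = loss(x_best, dataset, fitspec, base_params,
                           base_antisense, return_detail=True)
    if detail is None:
        raise FitError("best candidate failed on re-evaluation")
    return FitResult(
        best_params={p: float(v) for p, v in zip(paths, x_best)},
        best_loss=float(f_check), scales=detail["scales"],
        starts_table=starts_table, residuals=detail["residuals"],
        fitspec=fitspec, params=detail["params"],
        antisense=detail["antisense"], converged=ok)
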