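"""Model/Results surface for fitting the FLC silencing ODEs to data.

``FLCSilencingModel`` is constructed from a tidy measurement table (a
:class:`~flcdyn.synthetic.Dataset` or a DataFrame with the same
columns); ``fit()`` returns an ``FLCSilencingResults`` carrying the
estimates, their multi-start spread, calibration scales, residual
diagnostics, and a ``summary()`` table.  Simulation and plotting hang
off the results object so a fitted model can immediately be re-run on
any genotype/condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import simulate
from .fitting import FitResult, FitSpec, fit as _fit, loss as _loss
from .genotypes import apply_genotype
from .observables import population_average
from .params import AntisenseParams, ModelParams
from .synthetic import Dataset, DATASET_COLUMNS
from .temperature import condition_schedule


class FLCSilencingModel:
    """Vernalization FLC-silencing model bound to a measurement table.

    Parameters
    ----------
    data : Dataset or DataFrame
        Tidy replicate-level measurements (columns genotype, condition,
        quantity, region, timepoint, replicate, value).
    fitspec : FitSpec
        Free parameters with bounds, loss options and multi-start
        configuration.
    params, antisense : optional
        Baseline parameter objects; defaults are the package defaults.
    """

    def __init__(self, data, fitspec: FitSpec,
                 params: ModelParams | None = None,
                 antisense: AntisenseParams | None = None):
        if isinstance(data, Dataset):
            self.dataset = data
        else:
            self.dataset = Dataset(data=pd.DataFrame(data, columns=None))
        self.fitspec = fitspec
        self.params = params or ModelParams()
        self.antisense = antisense or AntisenseParams()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, fitspec: FitSpec,
                       **kwargs) -> "FLCSilencingModel":
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"data frame missing column(s): "
                             f"{', '.join(missing)}")
        return cls(Dataset(data=frame.copy()), fitspec, **kwargs)

    def loss(self, candidate) -> float:
        """Objective value for a free-parameter vector (fitspec order)."""
        return _loss(candidate, self.dataset, self.fitspec,
                     self.params, self.antisense)

    def fit(self) -> "FLCSilencingResults":
        result = _fit(self.dataset, self.fitspec, self.params, self.antisense)
        return FLCSilencingResults(self, result)


class FLCSilencingResults:
    """Fit outcome: estimates, diagnostics, simulation and plotting."""

    def __init__(self, model: FLCSilencingModel, result: FitResult):
        self.model = model
        self._result = result

    # --- estimates ----------------------------------------------------
    @property
    def params(self) -> dict:
        """Fitted free-parameter values by path."""
        return dict(self._result.best_params)

    @property
    def loss(self) -> float:
        return self._result.best_loss

    @property
    def scales(self) -> dict:
        """Profiled per-(quantity, region) calibration factors."""
        return dict(self._result.scales)

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def starts_table(self) -> pd.DataFrame:
        return self._result.starts_table.copy()

    @property
    def residuals(self) -> pd.DataFrame:
        return self._result.residuals.copy()

    def param_spread(self) -> pd.DataFrame:
        """Dispersion of per-start optima near the best loss.

        Starts within 2x of the best loss are pooled; their standard
        deviation is the multi-start spread — a rough stability
        diagnostic, not a confidence interval.
        """
        tab = self._result.starts_table
        rows = []
        for path in self._result.fitspec.paths:
            col = f"x_{path}"
            if col not in tab.columns:
                continue
            good = tab[np.isfinite(tab["loss"])
                       & (tab["loss"] <= 2 * self.loss + 1e-30)]
            rows.append({"param": path,
                         "estimate": self._result.best_params[path],
                         "n_starts_near_best": len(good),
                         "spread": float(good[col].std(ddof=0))
                         if len(good) else np.nan})
        return pd.DataFrame(rows)

    # --- presentation -------------------------------------------------
    def summary(self) -> str:
        spec = self._result.fitspec
        lines = [
            "FLC silencing model — weighted least-squares fit",
            "=" * 56,
            f"observations (cells): {len(self._result.residuals):d}"
            f"    loss ({spec.loss}): {self.loss:.6g}",
            f"multi-starts: {spec.starts}    seed: {spec.seed}"
            f"    converged: {self.converged}",
            "-" * 56,
            f"{'parameter':<28}{'estimate':>12}{'spread':>12}",
        ]
        spread = {r["param"]: r["spread"]
                  for _, r in self.param_spread().iterrows()}
        for path, value in self._result.best_params.items():
            sp = spread.get(path, np.nan)
            lines.append(f"{path:<28}{value:>12.5g}{sp:>12.3g}")
        lines.append("-" * 56)
        lines.append(f"{'scale factor':<28}{'value':>12}")
        for (q, reg), s in sorted(self._result.scales.items()):
            lines.append(f"{q + '/' + reg:<28}{s:>12.5g}")
        lines.append("=" * 56)
        return "\n".join(lines)

    # --- reuse --------------------------------------------------------
    def realized_params(self):
        """(ModelParams, AntisenseParams) at the fitted optimum."""
        return self._result.params, self._result.antisense

    def simulate(self, condition: str = "CC", genotype: str = "wild_type",
                 t_eval=None, **schedule_kwargs):
        """Simulate the fitted model for one genotype and condition."""
        p, a = self.realized_params()
        gp, ga = apply_genotype(p, a, genotype)
        sched = condition_schedule(
            condition, weeks_cold=self._result.fitspec.weeks_cold,
            post_days=self._result.fitspec.post_days, **schedule_kwargs)
        return simulate(sched, gp, ga, t_eval=t_eval, genotype=genotype)

    def plot_fit(self, quantity: str = "K36", region: str = "nucleation",
                 ax=None):
        """Overlay fitted trajectories on the data cells for one observable."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        res = self._result.residuals
        sel = res[(res["quantity"] == quantity) & (res["region"] == region)]
        scale = self._result.scales.get((quantity, region), 1.0)
        for (gt, cond), grp in sel.groupby(["genotype", "condition"]):
            traj = self.simulate(condition=cond, genotype=gt)
            series = population_average(traj, quantity, region)
            line, = ax.plot(series.times, scale * series.values,
                            label=f"{gt} {cond}")
            sched = traj.schedule
            tps = [sched.resolve_label(lb) for lb in grp["timepoint"]]
            ax.errorbar(tps, grp["mean"], yerr=grp["sem"].fillna(0.0),
                        fmt="o", color=line.get_color(), capsize=3)
        ax.set_xlabel("time (days)")
        ax.set_ylabel(f"{quantity} ({region})")
        ax.legend(fontsize=8)
        return ax
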