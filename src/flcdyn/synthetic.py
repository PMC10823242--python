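"""Synthetic ChIP-qPCR-style time-course datasets.

Emulates relative-enrichment measurements (H3K36me3, H3K27me3 in two
locus regions, plus an unspliced-RNA proxy) at the protocol timepoints
NV, 2WT0, 6WT0, 6WT10, 6WT20, with a small number of biological
replicates and multiplicative lognormal noise — the structure of a
typical vernalization ChIP time course.  Replicate draws use per-cell
substreams derived by stable hashing of the cell coordinates, so adding
genotypes, conditions or replicates never perturbs existing draws.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import simulate
from .genotypes import apply_genotype
from .observables import observable_table
from .params import AntisenseParams, ModelParams, REGIONS
from .temperature import condition_schedule

DEFAULT_TIMEPOINTS = ("NV", "2WT0", "6WT0", "6WT10", "6WT20")
DATASET_COLUMNS = ["genotype", "condition", "quantity", "region",
                   "timepoint", "replicate", "value"]


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    ``cv`` is the coefficient of variation of a replicate around the
    noiseless value; the lognormal is mean-one so replicate averages are
    unbiased.  ``cv = 0`` reproduces the noiseless observable exactly.
    """

    cv: float = 0.25
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise DatasetError("cv must be nonnegative")
        if self.n_reps < 1:
            raise DatasetError("n_reps must be at least 1")

    def multiplier(self, cell_key: tuple) -> float:
        """Mean-one lognormal multiplier for one (cell, replicate)."""
        if self.cv == 0:
            return 1.0
        sigma2 = math.log(1.0 + self.cv ** 2)
        rng = np.random.default_rng(_substream_seed(self.seed, cell_key))
        return float(np.exp(rng.normal(-0.5 * sigma2, math.sqrt(sigma2))))


def _substream_seed(master_seed: int, cell_key: tuple) -> int:
    """Stable 32-bit substream seed from the master seed and cell coords."""
    payload = repr((int(master_seed),) + tuple(cell_key)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class Dataset:
    """Tidy measurement table plus provenance.

    ``data`` has columns genotype, condition, quantity, region,
    timepoint, replicate, value; values are positive; replicate indices
    run 1..n per cell.  ``provenance`` records the generating seed or
    "external" for loaded files.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"source": "external"})

    def __post_init__(self):
        missing = [c for c in DATASET_COLUMNS if c not in self.data.columns]
        if missing:
            raise DatasetError(f"dataset missing column(s): {', '.join(missing)}")
        self.data = self.data[DATASET_COLUMNS].reset_index(drop=True)
        if len(self.data):
            vals = pd.to_numeric(self.data["value"], errors="coerce")
            if vals.isna().any():
                raise DatasetError("non-numeric values in dataset")
            if (vals <= 0).any():
                raise DatasetError("dataset values must be positive")
            self.data["value"] = vals.astype(float)

    def cell_means(self) -> pd.DataFrame:
        """Replicate mean, SEM and count per measurement cell."""
        g = self.data.groupby(
            ["genotype", "condition", "quantity", "region", "timepoint"],
            sort=True)["value"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        out["sem"] = out["sd"] / np.sqrt(out["n"])
        return out

    def __len__(self) -> int:
        return len(self.data)


def generate_dataset(params: ModelParams, antisense: AntisenseParams,
                     genotypes=("wild_type",), conditions=("CC",),
                     timepoints=DEFAULT_TIMEPOINTS,
                     noise: NoiseModel | None = None,
                     weeks_cold: float = 6.0, post_days: float = 28.0,
                     value_floor: float = 1e-9) -> Dataset:
    """Simulate each (genotype, condition) and draw noisy replicates.

    Quantities are K36/K27 in both regions plus mRNA.  A simulation
    failure is re-raised with the offending cell named.  ``value_floor``
    keeps stored values positive when an observable is exactly zero
    (e.g. K27 in a nucleation mutant).
    """
    noise = noise or NoiseModel()
    rows = []
    for gt in genotypes:
        for cond in conditions:
            try:
                p, a = apply_genotype(params, antisense, gt)
                sched = condition_schedule(cond, weeks_cold=weeks_cold,
                                           post_days=post_days)
                t_eval = _grid_with_labels(sched, timepoints)
                traj = simulate(sched, p, a, t_eval=t_eval, genotype=gt)
            except Exception as exc:
                raise DatasetError(
                    f"simulation failed for genotype={gt!r}, "
                    f"condition={cond!r}: {exc}") from exc
            table = observable_table(traj, timepoints)
            for _, row in table.iterrows():
                for rep in range(1, noise.n_reps + 1):
                    key = (gt, cond, row["quantity"], row["region"],
                           row["timepoint"], rep)
                    mult = noise.multiplier(key)
                    rows.append((gt, cond, row["quantity"], row["region"],
                                 row["timepoint"], rep,
                                 max(row["value"] * mult, value_floor)))
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return Dataset(data=df, provenance={
        "source": "synthetic", "seed": noise.seed, "cv": noise.cv,
        "n_reps": noise.n_reps, "conditions": list(conditions),
        "genotypes": list(genotypes), "weeks_cold": weeks_cold})


def _grid_with_labels(schedule, labels, n_base: int = 301) -> np.ndarray:
    """Evaluation grid containing every label time exactly."""
    base = np.linspace(0.0, schedule.total_days, n_base)
    times = np.unique(np.concatenate(
        [base, [schedule.resolve_label(lb) for lb in labels]]))
    return times


def write_dataset(dataset: Dataset, path) -> None:
    """Write tab-delimited text with provenance in '#' header comments."""
    with open(path, "w") as fh:
        for k in sorted(dataset.provenance):
            fh.write(f"# {k}: {dataset.provenance[k]}\n")
        dataset.data.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset` (or hand-made TSV)."""
    provenance = {"source": "external"}
    with open(path) as fh:
        text = fh.read()
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                provenance[k.strip()] = v.strip()
        else:
            body.append(line)
    if not body or not body[0].strip():
        raise DatasetError(f"{path}: empty file, expected a header line")
    df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing column(s): {', '.join(missing)}")
    if len(df):
        df["replicate"] = df["replicate"].astype(int)
    return Dataset(data=df, provenance=provenance)
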