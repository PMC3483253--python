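"""Trajectory tensors, parameter tables, preprocessing and aggregation.

The central container is the :class:`TrajectoryTensor`, a 3-way array of
simulated state trajectories with modes (observation, state variable, time
point).  Time points are phases of one oscillation cycle on a common grid in
[0, 1); the cycle length in real time units is carried separately per
observation (``period``).  Parameter tables hold the design (observation x
parameter) together with per-parameter range metadata.

Preprocessing follows common PLSR practice: calibration data are mean-centred
and standardised using calibration statistics only; test data reuse those
statistics.  Two standardisation schemes are offered for tensors:

* ``columnwise`` - centre and scale every (variable, time) column of the
  unfolded array (default);
* ``slab``       - centre every column but use one pooled dispersion per
  state variable.

Unfolding concatenates the time series of all state variables into a 2-way
matrix (variable-major column order), the classical way to feed 3-way data to
a 2-way method.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "TrajectoryTensor", "ParameterTable", "Preprocessor", "AggregatedOutputs",
    "fit_preprocessor", "apply_preprocessor", "unfold", "refold",
    "aggregate_outputs", "save_tensor", "load_tensor",
    "save_tensor_csv", "load_tensor_csv", "save_table", "load_table",
    "save_preprocessor", "load_preprocessor",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryTensor:
    """3-way array of trajectories: (observation, state variable, time point).

    Parameters
    ----------
    values : ndarray, shape (n_obs, n_vars, n_time)
        Finite trajectory values (concentrations, typically nM).
    obs_ids : sequence of str
        Observation identifiers, one per design row.
    var_names : sequence of str
        Unique state-variable labels.
    time_grid : ndarray, shape (n_time,)
        Strictly increasing phase points in [0, 1) of one cycle.
    period : ndarray or None, shape (n_obs,)
        Optional cycle length per observation (hours).
    """

    values: np.ndarray
    obs_ids: Sequence[str]
    var_names: Sequence[str]
    time_grid: np.ndarray
    period: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-way, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must all be finite")
        n_obs, n_vars, n_time = self.values.shape
        if n_time < 2:
            raise ValueError("need at least 2 time points")
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.var_names = [str(v) for v in self.var_names]
        if len(self.obs_ids) != n_obs:
            raise ValueError("obs_ids length does not match first mode")
        if len(self.var_names) != n_vars:
            raise ValueError("var_names length does not match second mode")
        if len(set(self.var_names)) != n_vars:
            raise ValueError("var_names must be unique")
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.time_grid.shape != (n_time,):
            raise ValueError("time_grid length does not match third mode")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if self.period is not None:
            self.period = np.asarray(self.period, dtype=float)
            if self.period.shape != (n_obs,):
                raise ValueError("period must have one entry per observation")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def n_time(self) -> int:
        return self.values.shape[2]

    def subset(self, idx: np.ndarray) -> "TrajectoryTensor":
        """Return a tensor restricted to the observations in ``idx``."""
        idx = np.asarray(idx)
        return TrajectoryTensor(
            self.values[idx],
            [self.obs_ids[i] for i in np.atleast_1d(idx)],
            list(self.var_names),
            self.time_grid.copy(),
            None if self.period is None else self.period[idx],
        )

    def to_xarray(self) -> xr.Dataset:
        da = xr.DataArray(
            self.values,
            dims=("observation", "variable", "time"),
            coords={
                "observation": list(self.obs_ids),
                "variable": list(self.var_names),
                "time": self.time_grid,
            },
            name="values",
        )
        ds = da.to_dataset()
        if self.period is not None:
            ds["period"] = xr.DataArray(self.period, dims=("observation",))
        return ds

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "TrajectoryTensor":
        period = ds["period"].values if "period" in ds else None
        return cls(
            ds["values"].values,
            [str(o) for o in ds["observation"].values],
            [str(v) for v in ds["variable"].values],
            ds["time"].values,
            period,
        )


@dataclass
class ParameterTable:
    """Observations x input parameters, with optional per-parameter ranges.

    ``ranges`` maps parameter name -> (min, max, n_levels); when present,
    stored values must lie within the declared range.
    """

    values: np.ndarray
    param_names: Sequence[str]
    ranges: dict[str, tuple[float, float, int]] | None = None
    obs_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("parameter table must be 2-way")
        self.param_names = [str(p) for p in self.param_names]
        if len(self.param_names) != self.values.shape[1]:
            raise ValueError("param_names length mismatch")
        if len(set(self.param_names)) != len(self.param_names):
            raise ValueError("param_names must be unique")
        if self.obs_ids is None:
            self.obs_ids = [f"obs{i}" for i in range(self.values.shape[0])]
        else:
            self.obs_ids = [str(o) for o in self.obs_ids]
        if len(self.obs_ids) != self.values.shape[0]:
            raise ValueError("obs_ids length mismatch")
        if self.ranges:
            for j, name in enumerate(self.param_names):
                if name in self.ranges:
                    lo, hi, _ = self.ranges[name]
                    col = self.values[:, j]
                    if col.size and (col.min() < lo - 1e-12 or col.max() > hi + 1e-12):
                        raise ValueError(f"values of {name!r} outside declared range [{lo}, {hi}]")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "ParameterTable":
        idx = np.asarray(idx)
        return ParameterTable(
            self.values[idx],
            list(self.param_names),
            self.ranges,
            [self.obs_ids[i] for i in np.atleast_1d(idx)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.param_names), index=list(self.obs_ids))


@dataclass
class AggregatedOutputs:
    """Scalar trajectory summaries: period plus 4 features per variable."""

    values: np.ndarray
    names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


# ---------------------------------------------------------------------------
# unfolding
# ---------------------------------------------------------------------------

def unfold(t: TrajectoryTensor | np.ndarray) -> np.ndarray:
    """Unfold a 3-way tensor into (n_obs, n_vars*n_time), variable-major.

    Column order: all time points of variable 1, then all of variable 2, ...
    i.e. column index = j * n_time + k for variable j, time k.
    """
    values = t.values if isinstance(t, TrajectoryTensor) else np.asarray(t)
    n_obs = values.shape[0]
    return values.reshape(n_obs, -1)


def refold(matrix: np.ndarray, n_vars: int, n_time: int) -> np.ndarray:
    """Inverse of :func:`unfold` (values only)."""
    matrix = np.asarray(matrix)
    if matrix.shape[1] != n_vars * n_time:
        raise ValueError("column count does not match n_vars * n_time")
    return matrix.reshape(matrix.shape[0], n_vars, n_time)


def unfold_column_names(var_names: Sequence[str], n_time: int) -> list[str]:
    return [f"{v}@t{k}" for v in var_names for k in range(n_time)]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class Preprocessor:
    """Centring/scaling statistics estimated on a calibration set.

    ``scheme`` is ``columnwise`` (per-column mean and sd of the unfolded
    array) or ``slab`` (per-column mean, one pooled sd per state variable;
    tensors only).  ``log_vars`` lists state variables natural-log transformed
    before centring.  ``scale`` may be disabled (centre only) via
    ``with_scaling=False`` at fit time.
    """

    means: np.ndarray
    scales: np.ndarray
    scheme: str
    column_names: list[str]
    log_vars: list[str] = field(default_factory=list)
    n_vars: int | None = None
    n_time: int | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive")


def _as_matrix(data) -> tuple[np.ndarray, list[str], int | None, int | None]:
    """Return (unfolded matrix, column names, n_vars, n_time)."""
    if isinstance(data, TrajectoryTensor):
        return (
            unfold(data),
            unfold_column_names(data.var_names, data.n_time),
            data.n_vars,
            data.n_time,
        )
    if isinstance(data, ParameterTable):
        return data.values.copy(), list(data.param_names), None, None
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-way array")
    return arr.copy(), [f"col{j}" for j in range(arr.shape[1])], None, None


def _apply_log(matrix: np.ndarray, column_names: list[str], log_vars: list[str]) -> np.ndarray:
    if not log_vars:
        return matrix
    out = matrix.copy()
    hit = np.zeros(matrix.shape[1], dtype=bool)
    for j, name in enumerate(column_names):
        base = name.split("@t")[0]
        if base in log_vars or name in log_vars:
            hit[j] = True
    if not hit.any():
        raise ValueError(f"log_vars {log_vars} match no variable")
    block = out[:, hit]
    if np.any(block <= 0):
        raise ValueError("log transform requested for non-positive values")
    out[:, hit] = np.log(block)
    return out


def fit_preprocessor(
    data,
    scheme: str = "columnwise",
    log_vars: Sequence[str] | None = None,
    with_scaling: bool = True,
) -> Preprocessor:
    """Estimate centring/scaling statistics from calibration data.

    Sample (n-1) standard deviations are used.  A zero-variance column raises
    an error naming the column.
    """
    log_vars = list(log_vars or [])
    matrix, names, n_vars, n_time = _as_matrix(data)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 observations to fit a preprocessor")
    if scheme not in ("columnwise", "slab"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "slab" and n_vars is None:
        raise ValueError("slab scheme requires a TrajectoryTensor")
    matrix = _apply_log(matrix, names, log_vars)

    means = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    zero = np.where(sd <= 0)[0]
    if zero.size:
        raise ValueError(f"zero variance in column {names[zero[0]]!r}")
    if not with_scaling:
        scales = np.ones_like(sd)
    elif scheme == "columnwise":
        scales = sd
    else:  # slab: pooled dispersion per state variable
        var_cols = sd.reshape(n_vars, n_time) ** 2
        pooled = np.sqrt(var_cols.mean(axis=1))
        scales = np.repeat(pooled, n_time)
    return Preprocessor(means, scales, scheme, names, log_vars, n_vars, n_time)


def apply_preprocessor(p: Preprocessor, data, direction: str = "forward"):
    """Apply (or invert) calibration centring/scaling.

    Forward: (optionally log,) subtract calibration means, divide by
    calibration scales.  Inverse: exact inverse.  Returns the same container
    type as given.
    """
    matrix, names, n_vars, n_time = _as_matrix(data)
    if names != p.column_names:
        if len(names) != len(p.column_names):
            raise ValueError(
                f"layout mismatch: {len(names)} columns, preprocessor has {len(p.column_names)}"
            )
        raise ValueError("layout mismatch: column names differ from preprocessor")
    if direction == "forward":
        matrix = _apply_log(matrix, names, p.log_vars)
        out = (matrix - p.means) / p.scales
    elif direction == "inverse":
        out = matrix * p.scales + p.means
        if p.log_vars:
            hit = np.array([n.split("@t")[0] in p.log_vars or n in p.log_vars for n in names])
            out[:, hit] = np.exp(out[:, hit])
    else:
        raise ValueError(f"unknown direction {direction!r}")

    if isinstance(data, TrajectoryTensor):
        return TrajectoryTensor(
            refold(out, data.n_vars, data.n_time),
            data.obs_ids, data.var_names, data.time_grid, data.period,
        )
    if isinstance(data, ParameterTable):
        return ParameterTable(out, data.param_names, None, data.obs_ids)
    return out


# ---------------------------------------------------------------------------
# aggregated outputs
# ---------------------------------------------------------------------------

def aggregate_outputs(t: TrajectoryTensor) -> AggregatedOutputs:
    """Summarise each trajectory as period + {bottom, peak, time-to-bottom,
    time-to-peak} per state variable.

    Yields 1 + 4*n_vars columns (65 for a 16-variable system).  Times to
    extremum are measured from the cycle start in the cycle's own time units
    (phase * period); ties are broken by the earliest time index.
    """
    if t.period is None:
        raise ValueError("aggregate_outputs requires per-observation periods")
    n_obs, n_vars, _ = t.values.shape
    cols = [t.period.astype(float)]
    names = ["period"]
    for j, var in enumerate(t.var_names):
        block = t.values[:, j, :]                  # (n_obs, n_time)
        i_min = np.argmin(block, axis=1)           # argmin/argmax take first tie
        i_max = np.argmax(block, axis=1)
        cols += [
            block[np.arange(n_obs), i_min],
            block[np.arange(n_obs), i_max],
            t.time_grid[i_min] * t.period,
            t.time_grid[i_max] * t.period,
        ]
        names += [f"{var}:bottom", f"{var}:peak", f"{var}:time_to_bottom", f"{var}:time_to_peak"]
    return AggregatedOutputs(np.column_stack(cols), names)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_tensor(t: TrajectoryTensor, path: str | Path) -> None:
    """Write a tensor to a NetCDF file (dims observation/variable/time)."""
    t.to_xarray().to_netcdf(Path(path), engine="scipy")


def load_tensor(path: str | Path) -> TrajectoryTensor:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        return TrajectoryTensor.from_xarray(ds.load())


def save_tensor_csv(t: TrajectoryTensor, path: str | Path) -> None:
    """Write a tensor in long format: obs_id, variable, time_index, value."""
    n_obs, n_vars, n_time = t.values.shape
    df = pd.DataFrame({
        "obs_id": np.repeat(t.obs_ids, n_vars * n_time),
        "variable": np.tile(np.repeat(t.var_names, n_time), n_obs),
        "time_index": np.tile(np.arange(n_time), n_obs * n_vars),
        "value": t.values.ravel(),
    })
    if t.period is not None:
        df["period"] = np.repeat(t.period, n_vars * n_time)
    df.to_csv(Path(path), index=False)


def load_tensor_csv(path: str | Path, time_grid: np.ndarray | None = None) -> TrajectoryTensor:
    """Read a long-format tensor CSV, checking completeness of the grid."""
    df = pd.read_csv(Path(path))
    required = {"obs_id", "variable", "time_index", "value"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"long-format CSV missing columns {sorted(missing_cols)}")
    obs_ids = list(pd.unique(df["obs_id"].astype(str)))
    var_names = list(pd.unique(df["variable"].astype(str)))
    time_idx = np.sort(pd.unique(df["time_index"]))
    n_time = len(time_idx)
    pivot = df.set_index(["obs_id", "variable", "time_index"])["value"]
    if pivot.index.has_duplicates:
        dup = pivot.index[pivot.index.duplicated()][0]
        raise ValueError(f"duplicate cell at (obs={dup[0]}, var={dup[1]}, time={dup[2]})")
    full = pd.MultiIndex.from_product(
        [[str(o) for o in obs_ids], var_names, time_idx],
        names=["obs_id", "variable", "time_index"],
    )
    pivot.index = pd.MultiIndex.from_arrays(
        [df["obs_id"].astype(str), df["variable"].astype(str), df["time_index"]],
        names=["obs_id", "variable", "time_index"],
    )
    reindexed = pivot.reindex(full)
    if reindexed.isna().any():
        o, v, k = reindexed.index[int(np.argmax(reindexed.isna().values))]
        raise ValueError(f"missing cell at (obs={o}, var={v}, time={k})")
    values = reindexed.values.reshape(len(obs_ids), len(var_names), n_time)
    period = None
    if "period" in df.columns:
        period = df.groupby("obs_id", sort=False)["period"].first().loc[obs_ids].values
    if time_grid is None:
        time_grid = np.asarray(time_idx, dtype=float) / n_time
    return TrajectoryTensor(values, obs_ids, var_names, time_grid, period)


def save_table(table: ParameterTable, path: str | Path) -> None:
    table.to_frame().to_csv(Path(path), index_label="obs_id")


def load_table(path: str | Path, ranges: dict | None = None) -> ParameterTable:
    df = pd.read_csv(Path(path))
    if df.columns[0] == "obs_id":
        obs_ids = df["obs_id"].astype(str).tolist()
        df = df.drop(columns=["obs_id"])
    else:
        obs_ids = None
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValueError(f"missing value in parameter column {col!r}")
    return ParameterTable(df.values, list(df.columns), ranges, obs_ids)


def save_preprocessor(p: Preprocessor, path: str | Path) -> None:
    payload = dataclasses.asdict(p)
    payload["means"] = p.means.tolist()
    payload["scales"] = p.scales.tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def load_preprocessor(path: str | Path) -> Preprocessor:
    payload = json.loads(Path(path).read_text())
    return Preprocessor(
        np.asarray(payload["means"]), np.asarray(payload["scales"]),
        payload["scheme"], payload["column_names"], payload.get("log_vars", []),
        payload.get("n_vars"), payload.get("n_time"),
    )
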