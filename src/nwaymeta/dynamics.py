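"""ODE integration to stable limit cycles and fixture generators.

For every design row an ODE system is integrated from its default initial
condition until it has settled on a stable limit cycle.  Cycles are delimited
by upward crossings of a designated reference state variable through its
running mean (the crossing level itself is not critical as long as it is hit
once per cycle; the running mean is robust to offsets).  Two consecutive
complete cycles are extracted and the run is declared converged when

* the period difference relative to the mean period is below ``period_tol``
  (default 0.001), and
* after interpolating all variables at ``n_grid`` equally spaced points per
  cycle and min-max rescaling each variable's cycle to [0, 1], the summed
  absolute difference between the two cycles over all n_vars * n_grid points
  is below ``synchrony_tol`` (default 0.0001; 3200 points for a 16-variable
  system at 200 points per cycle).

The second (later, more converged) cycle is returned un-rescaled; its start
phase anchors the time-to-extremum summaries in :mod:`nwaymeta.tensorio`.

Two self-contained data sources ship with the package: a 3-state Goodwin
oscillator (a minimal negative-feedback loop standing in for large circadian
models, pluggable wherever a user-supplied system would go) and a synthetic
trilinear generator producing regime-structured tensors with a known truth
record for validation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .tensorio import ParameterTable, TrajectoryTensor

__all__ = [
    "ODESystem", "LimitCycle", "NonConverged", "ConvergenceControls",
    "simulate_to_limit_cycle", "goodwin_demo_system", "build_tensor",
    "make_synthetic_trilinear", "SyntheticTruth",
]


@dataclass
class ODESystem:
    """Adapter contract for a user-supplied ODE model.

    ``rhs(t, state, params)`` returns the state derivative; ``params`` is a
    mapping name -> value.  ``reference_var`` is the state variable whose
    upward mean-crossings delimit cycles.
    """

    state_names: list[str]
    rhs: Callable[[float, np.ndarray, dict], np.ndarray]
    initial_state: np.ndarray
    reference_var: str
    default_params: dict = field(default_factory=dict)

    @property
    def n_vars(self) -> int:
        return len(self.state_names)

    @property
    def reference_index(self) -> int:
        return self.state_names.index(self.reference_var)


@dataclass
class ConvergenceControls:
    """Limit-cycle convergence settings (two-cycle period and synchrony tests)."""

    period_tol: float = 0.001
    synchrony_tol: float = 0.0001
    n_grid: int = 200
    max_time: float = 4000.0
    transient: float = 200.0
    window: float = 400.0
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if min(self.period_tol, self.synchrony_tol, self.max_time, self.rtol, self.atol) <= 0:
            raise ValueError("all tolerances must be positive")


@dataclass
class LimitCycle:
    """One converged cycle: period, values (n_vars x n_grid) and diagnostics."""

    period: float
    values: np.ndarray
    period_rel_diff: float
    synchrony_sum: float
    n_synchrony_points: int


@dataclass
class NonConverged:
    """Returned when no stable limit cycle was certified; ``reason`` is one of
    integration_failure, no_oscillation, no_crossings, max_time, period, synchrony."""

    reason: str
    detail: str = ""


def _upward_crossings(ts: np.ndarray, ref: np.ndarray, level: float, interp) -> np.ndarray:
    """Times of upward crossings of ``ref`` through ``level``, brentq-refined."""
    s = ref - level
    idx = np.where((s[:-1] < 0) & (s[1:] >= 0))[0]
    out = []
    ref_i = None
    for i in idx:
        f = lambda t: interp(t) - level
        try:
            out.append(brentq(f, ts[i], ts[i + 1], xtol=1e-12, rtol=1e-14))
        except ValueError:
            continue
    return np.asarray(out)


def simulate_to_limit_cycle(
    sys: ODESystem,
    params: dict,
    controls: ConvergenceControls | None = None,
) -> LimitCycle | NonConverged:
    """Integrate ``sys`` at ``params`` until two consecutive cycles agree.

    The integration proceeds in windows after an initial transient; the test
    is repeated on the three most recent reference-variable crossings until it
    passes or ``max_time`` is exhausted.
    """
    controls = controls or ConvergenceControls()
    p = {**sys.default_params, **params}
    ref_i = sys.reference_index

    try:
        sol = solve_ivp(
            lambda t, y: sys.rhs(t, y, p), (0.0, controls.transient), sys.initial_state,
            method="RK45", rtol=controls.rtol, atol=controls.atol,
        )
    except Exception as e:  # noqa: BLE001 - integrator failures become a status
        return NonConverged("integration_failure", str(e))
    if not sol.success:
        return NonConverged("integration_failure", sol.message)

    t_start = controls.transient
    state = sol.y[:, -1]
    last: NonConverged = NonConverged("no_crossings")
    while t_start < controls.max_time:
        t_end = min(t_start + controls.window, controls.max_time)
        try:
            sol = solve_ivp(
                lambda t, y: sys.rhs(t, y, p), (t_start, t_end), state,
                method="RK45", rtol=controls.rtol, atol=controls.atol, dense_output=True,
            )
        except Exception as e:  # noqa: BLE001
            return NonConverged("integration_failure", str(e))
        if not sol.success:
            return NonConverged("integration_failure", sol.message)
        ts = np.linspace(t_start, t_end, 4096)
        ref = sol.sol(ts)[ref_i]
        amp = ref.max() - ref.min()
        if amp < 1e-6 * max(1.0, abs(ref.mean())):
            return NonConverged("no_oscillation", "reference variable settled to a fixed point")
        level = ref.mean()
        crossings = _upward_crossings(ts, ref, level, lambda t: sol.sol(t)[ref_i])
        if len(crossings) >= 3:
            c0, c1, c2 = crossings[-3], crossings[-2], crossings[-1]
            p1, p2 = c1 - c0, c2 - c1
            rel = abs(p1 - p2) / ((p1 + p2) / 2)
            if rel >= controls.period_tol:
                last = NonConverged("period", f"relative period difference {rel:.2e}")
            else:
                phases = np.arange(controls.n_grid) / controls.n_grid
                cyc1 = sol.sol(c0 + phases * p1)            # (n_vars, n_grid)
                cyc2 = sol.sol(c1 + phases * p2)
                def rescale(c: np.ndarray) -> np.ndarray:
                    lo = c.min(axis=1, keepdims=True)
                    rng = np.ptp(c, axis=1, keepdims=True)
                    rng[rng == 0] = 1.0
                    return (c - lo) / rng
                sync = float(np.abs(rescale(cyc1) - rescale(cyc2)).sum())
                n_points = cyc1.size
                if sync < controls.synchrony_tol:
                    return LimitCycle(float(p2), cyc2, float(rel), sync, n_points)
                last = NonConverged("synchrony", f"synchrony sum {sync:.2e} over {n_points} points")
        else:
            last = NonConverged("no_crossings", f"{len(crossings)} crossings in window")
        state = sol.y[:, -1]
        t_start = t_end
    if last.reason in ("period", "synchrony", "no_crossings"):
        return NonConverged("max_time", f"max integration time reached; last failure: {last.reason}")
    return last


# ---------------------------------------------------------------------------
# demo system
# ---------------------------------------------------------------------------

def goodwin_demo_system() -> ODESystem:
    """3-state Goodwin-type oscillator (negative feedback with Hill repression).

    dX1/dt = v1 / (1 + X3^h) - d1 X1
    dX2/dt = v2 X1 - d2 X2
    dX3/dt = v3 X2 - d3 X3

    Defaults v1 = v2 = v3 = 1, d1 = d2 = d3 = 0.1, h = 10 give sustained
    oscillation (for an equal-rate 3-stage chain the Hopf condition requires
    an effective Hill slope above 8).  Reference variable: X1.
    """
    def rhs(t: float, y: np.ndarray, p: dict) -> np.ndarray:
        x1, x2, x3 = y
        return np.array([
            p["v1"] / (1.0 + max(x3, 0.0) ** p["h"]) - p["d1"] * x1,
            p["v2"] * x1 - p["d2"] * x2,
            p["v3"] * x2 - p["d3"] * x3,
        ])

    defaults = {"v1": 1.0, "v2": 1.0, "v3": 1.0, "d1": 0.1, "d2": 0.1, "d3": 0.1, "h": 10.0}
    return ODESystem(["X1", "X2", "X3"], rhs, np.array([0.1, 0.2, 2.5]), "X1", defaults)


def goodwin_chain_system(n_vars: int = 16) -> ODESystem:
    """Goodwin core driving a chain of first-order followers.

    Variables X4..Xn relax toward their predecessor, dXi/dt = k (X_{i-1} - Xi),
    producing progressively phase-shifted, damped copies of the core
    oscillation.  Handy for exercising the pipeline at the dimensionality of
    large biochemical models (16 state variables) while staying cheap to
    integrate.
    """
    if n_vars < 3:
        raise ValueError("need at least the 3 Goodwin core variables")
    core = goodwin_demo_system()

    def rhs(t: float, y: np.ndarray, p: dict) -> np.ndarray:
        dy = np.empty_like(y)
        dy[:3] = core.rhs(t, y[:3], p)
        dy[3:] = p["k_follow"] * (y[2:-1] - y[3:])
        return dy

    defaults = {**core.default_params, "k_follow": 0.5}
    init = np.concatenate([core.initial_state, np.full(n_vars - 3, 1.0)])
    names = [f"X{i+1}" for i in range(n_vars)]
    return ODESystem(names, rhs, init, "X1", defaults)


# ---------------------------------------------------------------------------
# tensor assembly
# ---------------------------------------------------------------------------

def build_tensor(
    design: ParameterTable,
    sys: ODESystem,
    controls: ConvergenceControls | None = None,
) -> tuple[TrajectoryTensor, ParameterTable, pd.DataFrame]:
    """Simulate every design row and stack the converged cycles into a tensor.

    Returns (tensor, converged subset of the design, convergence log).  The
    log has one row per design row with columns status / reason / period /
    period_rel_diff / synchrony_sum.
    """
    controls = controls or ConvergenceControls()
    cycles: list[np.ndarray] = []
    periods: list[float] = []
    keep: list[int] = []
    log_rows = []
    for i in range(design.n_obs):
        params = dict(zip(design.param_names, design.values[i]))
        result = simulate_to_limit_cycle(sys, params, controls)
        if isinstance(result, LimitCycle):
            cycles.append(result.values)
            periods.append(result.period)
            keep.append(i)
            log_rows.append({
                "obs_id": design.obs_ids[i], "status": "converged", "reason": "",
                "period": result.period, "period_rel_diff": result.period_rel_diff,
                "synchrony_sum": result.synchrony_sum,
            })
        else:
            log_rows.append({
                "obs_id": design.obs_ids[i], "status": "non_converged",
                "reason": result.reason, "period": np.nan,
                "period_rel_diff": np.nan, "synchrony_sum": np.nan,
            })
    if not keep:
        raise ValueError("no design row converged to a stable limit cycle")
    keep_arr = np.asarray(keep)
    tensor = TrajectoryTensor(
        np.stack(cycles),
        [design.obs_ids[i] for i in keep],
        sys.state_names,
        np.arange(controls.n_grid) / controls.n_grid,
        np.asarray(periods),
    )
    # transpose cycle blocks from (n_vars, n_grid) stacking is already right
    return tensor, design.subset(keep_arr), pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# synthetic trilinear fixture generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic trilinear data set."""

    regime_labels: np.ndarray                 # (n_obs,)
    thresholds: np.ndarray                    # regime edges on parameter 1
    score_offsets: np.ndarray                 # (n_regimes, n_factors)
    score_maps: np.ndarray                    # (n_regimes, n_params, n_factors)
    var_loadings: np.ndarray                  # (n_regimes, n_vars, n_factors)
    time_loadings: np.ndarray                 # (n_regimes, n_time, n_factors)
    scores: np.ndarray                        # (n_obs, n_factors)

    def sensitivity(self, regime: int) -> np.ndarray:
        """True parameter x variable effect pattern within one regime
        (score map times variable loadings, summed over factors; time
        loadings are non-negative by construction, so signs are unambiguous)."""
        return self.score_maps[regime] @ self.var_loadings[regime].T


def make_synthetic_trilinear(
    n_obs: int = 1500,
    n_vars: int = 8,
    n_time: int = 32,
    n_factors: int = 3,
    n_regimes: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_params: int | None = None,
    separation: float = 4.0,
) -> tuple[ParameterTable, TrajectoryTensor, SyntheticTruth]:
    """Generate regime-structured trilinear data with a known truth record.

    Parameters are drawn uniformly on [0, 1]; observations are partitioned
    into ``n_regimes`` regimes by equal-quantile thresholds on the first
    parameter.  Within regime r the factor scores are an affine regime
    specific map of the parameters, t = c_r + (p - 1/2) M_r, and the tensor is
    sum_a t_a * (w_a^var (x) w_a^time) + Gaussian noise with regime-specific
    loadings.  Regime centres c_r are ``separation`` apart so that regimes are
    recoverable from a global score space.  Per-factor score scales decay
    geometrically (1, 0.8, 0.64, ...) so every generating factor carries a
    non-trivial share of the response variance.

    ``n_params`` defaults to ``n_factors``; it must not exceed ``n_factors``
    if the parameters are to be identifiable from the tensor.  A synthetic
    per-observation period 18 + 12 * p1 hours is attached so that aggregated
    output summaries are well defined.
    """
    if n_factors > min(n_vars, n_time):
        raise ValueError("n_factors must not exceed min(n_vars, n_time)")
    if n_regimes < 1:
        raise ValueError("n_regimes must be >= 1")
    n_params = n_params or n_factors
    rng = np.random.default_rng(seed)

    params = rng.uniform(0.0, 1.0, size=(n_obs, n_params))
    edges = np.quantile(params[:, 0], np.linspace(0, 1, n_regimes + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    labels = np.digitize(params[:, 0], edges[1:-1])

    factor_scale = 0.8 ** np.arange(n_factors)
    offsets = np.zeros((n_regimes, n_factors))
    for r in range(n_regimes):
        offsets[r, r % n_factors] = separation * (1 + r // n_factors)
    score_maps = rng.normal(size=(n_regimes, n_params, n_factors)) * factor_scale
    var_loadings = np.empty((n_regimes, n_vars, n_factors))
    time_loadings = np.empty((n_regimes, n_time, n_factors))
    for r in range(n_regimes):
        wv = rng.normal(size=(n_vars, n_factors))
        wt = np.abs(rng.normal(size=(n_time, n_factors)))   # non-negative: sign-unambiguous
        var_loadings[r] = wv / np.linalg.norm(wv, axis=0)
        time_loadings[r] = wt / np.linalg.norm(wt, axis=0)

    scores = np.empty((n_obs, n_factors))
    values = np.empty((n_obs, n_vars, n_time))
    for r in range(n_regimes):
        mask = labels == r
        t_r = offsets[r] + (params[mask] - 0.5) @ score_maps[r]
        scores[mask] = t_r
        values[mask] = np.einsum("na,ja,ka->njk", t_r, var_loadings[r], time_loadings[r])
    if noise_sd > 0:
        values += rng.normal(scale=noise_sd, size=values.shape)

    obs_ids = [f"syn{i}" for i in range(n_obs)]
    table = ParameterTable(params, [f"p{j+1}" for j in range(n_params)],
                           {f"p{j+1}": (0.0, 1.0, 0) for j in range(n_params)}, obs_ids)
    tensor = TrajectoryTensor(
        values, obs_ids, [f"V{j+1}" for j in range(n_vars)],
        np.arange(n_time) / n_time, period=18.0 + 12.0 * params[:, 0],
    )
    truth = SyntheticTruth(labels, edges, offsets, score_maps, var_loadings, time_loadings, scores)
    return table, tensor, truth
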