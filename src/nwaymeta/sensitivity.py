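"""Sensitivity estimation from fitted metamodels and 2-way comparators.

From a *classical*-direction trilinear PLS model (parameters as regressors,
trajectory tensor as response) the sensitivity of each state variable to each
parameter is read off as the product of the second-mode regressor loadings
with the transpose of the second-mode response loadings, summed over the
model's retained factors.  On autoscaled data these are standardised effect
estimates.  A caveat inherited from the methodology: the per-mode loadings
are not orthogonal, so factor-wise contributions overlap; treat the maps as
semi-quantitative screens rather than calibrated effect sizes.

For individual badly-described outputs a follow-up 2-way second-order
polynomial hierarchical PLSR is provided: the regressors are the parameters
plus their squares and cross-terms (autoscaled; responses only centred, with
an optional log transform first), and within regional models the nonlinear
columns are deflated against the first-order block so that first-order and
nonlinear effects separate.  The per-term regression coefficients of the
fitted model are the sensitivity report.

:func:`benchmark_2way` reruns the inverse analysis with the tensor unfolded
to a 2-way matrix and with aggregated outputs (period + per-variable
extremum summaries), the two classical alternatives to keeping the 3-way
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .npls import NPLSModel, regression_coefficients
from .tensorio import (
    ParameterTable,
    TrajectoryTensor,
    aggregate_outputs,
    unfold,
)

__all__ = [
    "SensitivityMatrix", "PolyExpansion", "npls_sensitivity",
    "regional_sensitivities", "expand_polynomial", "deflate_nonlinear_terms",
    "poly_hcplsr_2way", "benchmark_2way",
]


@dataclass
class SensitivityMatrix:
    """Parameters x state variables loading-product sensitivities."""

    values: np.ndarray
    param_names: list[str]
    var_names: list[str]
    source: str                 # "global" or "cluster <id>"
    n_factors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.param_names, columns=self.var_names)


def npls_sensitivity(
    model: NPLSModel,
    param_names: list[str] | None = None,
    var_names: list[str] | None = None,
    source: str = "global",
) -> SensitivityMatrix:
    """Loading-product sensitivity map of a classical-direction model.

    values = W_var^X  (Q_var^Y)^T over the model's factors; rows are
    parameters, columns are state variables.  Refuses inverse-direction
    models (tensor regressor / matrix response), where the product would
    transpose the roles.
    """
    if model.x_is_tensor or not model.y_is_tensor:
        raise ValueError(
            "sensitivity maps require a classical-direction model "
            "(parameters as regressors, trajectory tensor as response)"
        )
    values = model.x_weights_var @ model.y_weights_var.T
    p = param_names or [f"p{j+1}" for j in range(values.shape[0])]
    v = var_names or [f"V{j+1}" for j in range(values.shape[1])]
    return SensitivityMatrix(values, list(p), list(v), source, model.n_factors)


def regional_sensitivities(model) -> list[SensitivityMatrix]:
    """One sensitivity matrix per retained cluster of a fitted classical
    hierarchical model (cluster ids recorded in ``source``)."""
    if model.direction != "classical":
        raise ValueError("regional sensitivities require a classical hierarchical model")
    param_names = model.x_preprocessor.column_names
    var_names = list(model.y_template.var_names) if model.y_template is not None else None
    out = []
    for c, regional in model.regional_models.items():
        label = "global" if model.fcm is None else f"cluster {c}"
        out.append(npls_sensitivity(regional, param_names, var_names, label))
    return out


# ---------------------------------------------------------------------------
# polynomial expansion
# ---------------------------------------------------------------------------

@dataclass
class PolyExpansion:
    """Second-order polynomial regressor blocks.

    ``linear`` holds the p first-order columns; ``nonlinear`` the p squares
    followed by the p(p-1)/2 cross terms, in a fixed documented order.
    """

    linear: np.ndarray
    nonlinear: np.ndarray
    linear_names: list[str]
    nonlinear_names: list[str]
    deflated: bool = False

    @property
    def matrix(self) -> np.ndarray:
        return np.hstack([self.linear, self.nonlinear])

    @property
    def names(self) -> list[str]:
        return self.linear_names + self.nonlinear_names


def expand_polynomial(params: np.ndarray | ParameterTable,
                      names: list[str] | None = None) -> PolyExpansion:
    """Expand parameters into linear + square + cross-term columns.

    Order: p linear terms, p squares (``x^2``), then cross terms ``xi*xj``
    for i < j in row-major order.  For p = 9 this yields 9 + 9 + 36 = 54
    columns.
    """
    if isinstance(params, ParameterTable):
        names = list(params.param_names)
        X = params.values
    else:
        X = np.asarray(params, dtype=float)
        names = names or [f"p{j+1}" for j in range(X.shape[1])]
    p = X.shape[1]
    squares = X ** 2
    cross_cols = [X[:, [i]] * X[:, [j]] for i in range(p) for j in range(i + 1, p)]
    cross = np.hstack(cross_cols) if cross_cols else np.empty((X.shape[0], 0))
    sq_names = [f"{n}^2" for n in names]
    cross_names = [f"{names[i]}*{names[j]}" for i in range(p) for j in range(i + 1, p)]
    return PolyExpansion(X.copy(), np.hstack([squares, cross]), names, sq_names + cross_names)


def deflate_nonlinear_terms(expansion: PolyExpansion) -> PolyExpansion:
    """Replace the nonlinear block by its OLS residual against the
    first-order block (plus intercept), separating first-order from genuinely
    nonlinear variation.  Idempotent; errors on a rank-deficient first-order
    block."""
    D = np.hstack([np.ones((expansion.linear.shape[0], 1)), expansion.linear])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("first-order block is rank deficient; cannot deflate")
    coef, *_ = np.linalg.lstsq(D, expansion.nonlinear, rcond=None)
    resid = expansion.nonlinear - D @ coef
    return replace(expansion, nonlinear=resid, deflated=True)


# ---------------------------------------------------------------------------
# 2-way polynomial HC-PLSR
# ---------------------------------------------------------------------------

@dataclass
class PolyHCPLSRResult:
    model: object                                  # HCPLSRModel over the expansion
    coefficients: pd.DataFrame                     # per-term global coefficients
    regional_coefficients: dict[int, pd.DataFrame]
    term_names: list[str]


def poly_hcplsr_2way(
    params: ParameterTable,
    response,
    clusters=None,
    config=None,
    log_response: bool = False,
) -> PolyHCPLSRResult:
    """2-way second-order polynomial hierarchical PLSR.

    Regressors are the autoscaled polynomial expansion of the parameters;
    the response (a single trajectory slab, aggregated outputs or any
    matrix) is only centred, optionally log-transformed first.  ``clusters``
    is an :class:`~nwaymeta.hcplsr.FCMResult` to reuse (normally the N-way
    model's clusters); with ``None`` a single global model is fitted.  Within
    regional models the nonlinear terms are deflated against the first-order
    block.  Regression coefficients per term are returned as the sensitivity
    report.
    """
    from .hcplsr import HCConfig
    from .npls import cv_select_factors, fit_npls

    config = config or HCConfig()
    expansion = expand_polynomial(params)

    Y = response.values if isinstance(response, ParameterTable) else np.asarray(response, dtype=float)
    if Y.ndim == 3:
        Y = Y.reshape(Y.shape[0], -1)
    if Y.ndim == 1:
        Y = Y[:, None]
    if log_response:
        if np.any(Y <= 0):
            raise ValueError("log transform requested for non-positive response")
        Y = np.log(Y)
    Yc = Y - Y.mean(axis=0)                      # responses only centred

    def _fit_block(expn: PolyExpansion, y: np.ndarray, idx: np.ndarray | None):
        M = expn.matrix if idx is None else expn.matrix[idx]
        yb = y if idx is None else y[idx]
        mean, sd = M.mean(axis=0), M.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            bad = expn.names[int(np.where(sd <= 0)[0][0])]
            raise ValueError(f"zero variance in polynomial term {bad!r}")
        Ms = (M - mean) / sd
        cv = cv_select_factors(Ms, yb - yb.mean(axis=0), config.a_max,
                               config.cv_folds, config.min_cv_variance, config.seed)
        model = fit_npls(Ms, yb - yb.mean(axis=0), cv.chosen)
        coefs = regression_coefficients(model)
        return model, cv, pd.DataFrame(coefs, index=expn.names)

    global_model, global_cv, global_coef = _fit_block(expansion, Yc, None)

    regional_coefs: dict[int, pd.DataFrame] = {}
    regional_models: dict[int, object] = {}
    if clusters is not None and len(clusters.retained) > 1:
        for c in clusters.retained:
            idx = np.where((clusters.labels == c) & ~clusters.outlier)[0]
            sub = expand_polynomial(params.values[idx], list(params.param_names))
            sub = deflate_nonlinear_terms(sub)
            model_c, _, coef_c = _fit_block(sub, Yc[idx], None)
            regional_models[c] = model_c
            regional_coefs[c] = coef_c
    return PolyHCPLSRResult(
        {"global": global_model, "regional": regional_models, "cv": global_cv},
        global_coef, regional_coefs, expansion.names,
    )


# ---------------------------------------------------------------------------
# 2-way benchmarking
# ---------------------------------------------------------------------------

def benchmark_2way(
    tensor: TrajectoryTensor,
    params: ParameterTable,
    config=None,
    nway_model=None,
    test_tensor: TrajectoryTensor | None = None,
    test_params: ParameterTable | None = None,
) -> pd.DataFrame:
    """Compare inverse N-way HC-PLSR against its two 2-way alternatives.

    Fits inverse hierarchical models on (i) the 3-way tensor, (ii) the
    unfolded tensor and (iii) aggregated outputs, all with the same cluster
    count, and reports per-parameter and mean prediction R^2 side by side.
    Evaluation uses a test set when given, else the calibration set treated
    as new observations (classification in the prediction stage).
    """
    from .hcplsr import HCConfig, fit_hcplsr_inverse, predict, r2_scores

    config = config or HCConfig()
    agg = aggregate_outputs(tensor)
    variants = {
        "nway": tensor,
        "unfolded_2way": unfold(tensor),
        "aggregated_2way": agg.values,
    }
    eval_params = test_params or params
    rows = []
    for name, X in variants.items():
        if name == "nway" and nway_model is not None:
            model = nway_model
        else:
            model = fit_hcplsr_inverse(X, params, config)
        if test_tensor is not None:
            X_eval = {
                "nway": test_tensor,
                "unfolded_2way": unfold(test_tensor),
                "aggregated_2way": aggregate_outputs(test_tensor).values,
            }[name]
        else:
            X_eval = X
        y_hat, _ = predict(model, X_eval)
        r2 = r2_scores(eval_params, y_hat, config.r2_method)
        rows.append({"approach": name, "mean_r2": float(np.nanmean(r2)),
                     "n_predictors": np.asarray(X if not isinstance(X, TrajectoryTensor)
                                                else unfold(X)).shape[1],
                     **{p: r2[j] for j, p in enumerate(params.param_names)}})
    return pd.DataFrame(rows)
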