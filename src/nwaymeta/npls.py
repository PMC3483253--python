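"""Trilinear PLS regression (tri-PLS1/tri-PLS2).

Fits a sequence of latent factors between a regressor block X and a response
block Y, where either block may be a 3-way trajectory tensor or an ordinary
matrix.  For factor a the second/third-mode weight pair (w_var, w_time)
maximises the covariance between the X first-mode score t_a = X (w_time (x)
w_var) and the current response score u_a; it is obtained as the dominant
singular pair of the J x K reshaping of X' u_a.  After each factor both
blocks are deflated by their projection onto t_a (unstructured loading
vectors p_a = X' t_a / t_a' t_a and c_a = Y' t_a / t_a' t_a), which makes the
score vectors mutually orthogonal while the per-mode weight vectors remain
non-orthogonal.  When the third mode is singleton the procedure *is* 2-way
NIPALS PLS2, so ordinary PLSR is available through the same code path.

The inner relation maps X-scores to predicted response-side scores
(T_hat_Y = T C); these predicted Y-scores feed the classification bridge of
the hierarchical metamodel.  Note that the construction of this score map is
a standard inner-relation least-squares fit; other conventions exist and the
choice is surfaced here rather than hidden.

Factor counts are chosen by seeded 10-fold cross-validation: the CV-MSE
minimiser, truncated so that every included factor adds at least ``min_var``
(default 1%) of the total cross-validated response variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensorio import TrajectoryTensor, unfold

__all__ = [
    "NPLSModel", "CVReport", "fit_npls", "predict_npls",
    "cv_select_factors", "explained_y_variance", "regression_coefficients",
]

_TOL = 1e-10
_MAX_ITER = 500


def _block(data) -> tuple[np.ndarray, tuple[int, int]]:
    """Unfold a tensor or pass through a matrix; return (matrix, (J, K))."""
    if isinstance(data, TrajectoryTensor):
        return unfold(data), (data.n_vars, data.n_time)
    if hasattr(data, "values") and hasattr(data, "param_names"):
        data = data.values
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a matrix or TrajectoryTensor")
    return arr, (arr.shape[1], 1)


@dataclass
class NPLSModel:
    """One fitted trilinear PLS regression.

    Attributes
    ----------
    n_factors : number of extracted factors A.
    x_weights_var, x_weights_time : per-factor second/third-mode weights for
        the X block (unit norm; columns = factors).
    x_loadings : unstructured deflation loadings P (JK x A).
    y_weights_var, y_weights_time : response-side per-mode weights.
    y_loadings : response deflation loadings C (M*L x A); the prediction is
        Y_hat = T C'.
    scores : training first-mode X-scores T (n x A).
    y_scores : training response scores U (n x A).
    score_map : least-squares coefficients mapping X-scores to predicted
        response-side scores, T_hat_Y = T @ score_map.
    """

    n_factors: int
    x_shape: tuple[int, int]
    y_shape: tuple[int, int]
    x_weights_var: np.ndarray
    x_weights_time: np.ndarray
    x_loadings: np.ndarray
    y_weights_var: np.ndarray
    y_weights_time: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    y_scores: np.ndarray
    score_map: np.ndarray
    x_is_tensor: bool
    y_is_tensor: bool
    explained_y: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def A(self) -> int:
        return self.n_factors


def _dominant_pair(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading left/right singular vectors of a (possibly thin) matrix."""
    if z.shape[1] == 1:
        w = z[:, 0]
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ValueError("degenerate (zero) weight vector; response exhausted")
        return w / nrm, np.ones(1)
    if z.shape[0] == 1:
        w = z[0]
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ValueError("degenerate (zero) weight vector; response exhausted")
        return np.ones(1), w / nrm
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    return u[:, 0], vt[0]


def fit_npls(X, Y, A: int) -> NPLSModel:
    """Fit a trilinear PLS model with ``A`` factors.

    ``X`` and ``Y`` may each be a :class:`TrajectoryTensor` or a 2-way array;
    both are assumed already preprocessed (centred, usually scaled).
    """
    Xu, x_shape = _block(X)
    Yu, y_shape = _block(Y)
    if Xu.shape[0] != Yu.shape[0]:
        raise ValueError("X and Y must have the same number of observations")
    if np.isnan(Xu).any() or np.isnan(Yu).any():
        raise ValueError("NaNs in input data")
    n = Xu.shape[0]
    max_rank = min(n - 1 if n > 1 else 1, Xu.shape[1])
    if A < 1 or A > max_rank:
        raise ValueError(f"A={A} outside feasible range 1..{max_rank}")

    J, K = x_shape
    M, L = y_shape
    Xr, Yr = Xu.copy(), Yu.copy()
    Wv = np.empty((J, A)); Wt = np.empty((K, A))
    Qv = np.empty((M, A)); Qt = np.empty((L, A))
    P = np.empty((Xu.shape[1], A)); C = np.empty((Yu.shape[1], A))
    T = np.empty((n, A)); U = np.empty((n, A))
    ss_y_total = float((Yu ** 2).sum())
    explained = np.empty(A)

    for a in range(A):
        u = Yr[:, np.argmax((Yr ** 2).sum(axis=0))]
        t = np.zeros(n)
        for _ in range(_MAX_ITER):
            z = (Xr.T @ u).reshape(J, K)
            wv, wt = _dominant_pair(z)
            w = np.outer(wv, wt).ravel()
            t_new = Xr @ w
            zy = (Yr.T @ t_new).reshape(M, L)
            qv, qt = _dominant_pair(zy)
            u = Yr @ np.outer(qv, qt).ravel()
            if np.linalg.norm(t_new - t) <= _TOL * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        # deterministic sign: largest-magnitude element of w_var positive
        if wv[np.argmax(np.abs(wv))] < 0:
            wv, t = -wv, -t
            w = np.outer(wv, wt).ravel()
            zy = (Yr.T @ t).reshape(M, L)
            qv, qt = _dominant_pair(zy)
            u = Yr @ np.outer(qv, qt).ravel()
        # pin the SVD sign of the response pair: largest element of the
        # third-mode weight positive, so second-mode loadings (and the
        # loading-product sensitivities built from them) are sign-stable
        if L > 1 and qt[np.argmax(np.abs(qt))] < 0:
            qv, qt = -qv, -qt
        tt = float(t @ t)
        if tt <= 0 or not np.isfinite(tt):
            raise ValueError(f"factor {a + 1}: degenerate score vector")
        p = Xr.T @ t / tt
        c = Yr.T @ t / tt
        Xr -= np.outer(t, p)
        Yr -= np.outer(t, c)
        Wv[:, a], Wt[:, a] = wv, wt
        Qv[:, a], Qt[:, a] = qv, qt
        P[:, a], C[:, a], T[:, a], U[:, a] = p, c, t, u
        explained[a] = 100.0 * (1.0 - (Yr ** 2).sum() / ss_y_total) if ss_y_total > 0 else 0.0

    score_map, *_ = np.linalg.lstsq(T, U, rcond=None)
    return NPLSModel(
        A, x_shape, y_shape, Wv, Wt, P, Qv, Qt, C, T, U, score_map,
        isinstance(X, TrajectoryTensor), isinstance(Y, TrajectoryTensor),
        explained,
    )


def _new_scores(model: NPLSModel, Xu: np.ndarray, A: int | None = None) -> np.ndarray:
    A = A or model.n_factors
    Xr = Xu.copy()
    T = np.empty((Xu.shape[0], A))
    for a in range(A):
        w = np.outer(model.x_weights_var[:, a], model.x_weights_time[:, a]).ravel()
        t = Xr @ w
        Xr -= np.outer(t, model.x_loadings[:, a])
        T[:, a] = t
    return T


def predict_npls(
    model: NPLSModel, X_new, A: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict the (preprocessed-scale, unfolded) response for new regressors.

    Returns ``(Y_hat, T_new, T_hat_Y)`` where ``T_new`` are the new first-mode
    X-scores (projection with the training weights and deflation sequence) and
    ``T_hat_Y`` the predicted response-side scores used downstream for
    classification.
    """
    Xu, x_shape = _block(X_new)
    if x_shape != model.x_shape and Xu.shape[1] != model.x_loadings.shape[0]:
        raise ValueError(
            f"layout mismatch: new X unfolds to {Xu.shape[1]} columns, "
            f"model expects {model.x_loadings.shape[0]}"
        )
    A = A or model.n_factors
    T = _new_scores(model, Xu, A)
    y_hat = T @ model.y_loadings[:, :A].T
    t_hat_y = T @ model.score_map[:A]
    return y_hat, T, t_hat_y


def regression_coefficients(model: NPLSModel) -> np.ndarray:
    """Equivalent linear map B (JK x ML) with Y_hat = X B on preprocessed scale.

    Built from the weight/loading recursion (R = W (P'W)^-1 in 2-way PLS
    notation); useful for reading a fitted 2-way polynomial model as
    per-term sensitivities.
    """
    A = model.n_factors
    JK = model.x_loadings.shape[0]
    R = np.empty((JK, A))
    for a in range(A):
        w = np.outer(model.x_weights_var[:, a], model.x_weights_time[:, a]).ravel()
        r = w.copy()
        for b in range(a):
            r -= (model.x_loadings[:, b] @ w) * R[:, b]
        R[:, a] = r
    return R @ model.y_loadings.T


def explained_y_variance(model: NPLSModel, X, Y) -> np.ndarray:
    """Cumulative % explained response variance after each factor.

    Computed on the given (preprocessed) data: 100 * (1 - SS_res / SS_tot)
    with the residual after the first a factors.
    """
    Xu, _ = _block(X)
    Yu, _ = _block(Y)
    T = _new_scores(model, Xu)
    ss_tot = float((Yu ** 2).sum())
    out = np.empty(model.n_factors)
    for a in range(1, model.n_factors + 1):
        resid = Yu - T[:, :a] @ model.y_loadings[:, :a].T
        out[a - 1] = 100.0 * (1.0 - (resid ** 2).sum() / ss_tot) if ss_tot > 0 else 0.0
    return out


@dataclass
class CVReport:
    """Cross-validated factor selection summary."""

    mse: np.ndarray                 # CV-MSE of the response per factor count
    cv_explained: np.ndarray        # cumulative % cross-validated Y-variance
    increments: np.ndarray          # per-factor % added CV Y-variance
    chosen: int
    n_folds: int
    seed: int


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random folds as equal as possible; remainder spread one per fold."""
    folds = np.repeat(np.arange(n_folds), np.diff(np.linspace(0, n, n_folds + 1).astype(int)))
    return folds[rng.permutation(n)]


def cv_select_factors(
    X, Y, A_max: int,
    n_folds: int = 10,
    min_var: float = 0.01,
    seed: int = 0,
) -> CVReport:
    """Choose the factor count by seeded 10-fold cross-validation.

    The candidate is the CV-MSE minimiser over 1..A_max, truncated to the
    largest A such that every included factor adds at least ``min_var`` of
    the total cross-validated response variance (never below 1 factor).
    """
    Xu, _ = _block(X)
    Yu, _ = _block(Y)
    n = Xu.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} observations for {n_folds}-fold CV")
    A_max = min(A_max, Xu.shape[1], n - int(np.ceil(n / n_folds)) - 1)
    if A_max < 1:
        raise ValueError("no feasible factor count under this fold layout")
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, n_folds, rng)

    press = np.zeros(A_max)
    for f in range(n_folds):
        test = folds == f
        model = fit_npls(Xu[~test], Yu[~test], A_max)
        _, T_new, _ = predict_npls(model, Xu[test])
        for a in range(1, A_max + 1):
            resid = Yu[test] - T_new[:, :a] @ model.y_loadings[:, :a].T
            press[a - 1] += float((resid ** 2).sum())
    ss_tot = float((Yu ** 2).sum())
    mse = press / Yu.size
    cv_explained = 100.0 * (1.0 - press / ss_tot) if ss_tot > 0 else np.zeros(A_max)
    increments = np.diff(np.concatenate([[0.0], cv_explained]))

    chosen = int(np.argmin(mse)) + 1
    # every included factor must add >= min_var of total CV Y-variance
    failing = np.where(increments[:chosen] < 100.0 * min_var)[0]
    if failing.size:
        chosen = max(1, int(failing[0]))
    return CVReport(mse, cv_explained, increments, chosen, n_folds, seed)
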