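"""Hierarchical cluster-based N-way PLS regression.

A hierarchical metamodel combines one *global* trilinear PLS model with
several *regional* models fitted inside fuzzy C-means clusters of the global
first-mode score space.  The protocol follows the inverse-first scheme:

1. Fit the global inverse model (trajectory tensor -> parameters) with a
   cross-validated factor count.
2. Cluster the calibration observations with fuzzy C-means (Euclidean
   distance, fuzzifier m = 2) on the global X-scores of all factors passing
   the 1% cross-validated response-variance rule.  Crisp clusters with fewer
   than ``min_cluster_size`` (default 10) members are dissolved and their
   observations treated as outliers (kept in the global model only).
3. Train a classifier (QDA by default; LDA and naive Bayes available) on the
   scores so that *new* observations can be routed to a regional model.
4. Fit one regional model per retained cluster, each with its own
   cross-validated factor count.

The classical direction (parameters -> tensor) reuses the inverse model's
clusters.  Because new observations arrive without trajectories, their
cluster is found through a *bridge*: predicted classical response-side scores
are mapped to inverse-model score space by second-order polynomial OLS
(squares and cross-terms included), and the inverse classifier is applied to
the mapped scores.

Prediction uses either the most probable regional model or a posterior-
weighted sum of all regional predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.naive_bayes import GaussianNB

from .npls import CVReport, NPLSModel, _block, cv_select_factors, fit_npls, predict_npls
from .tensorio import (
    ParameterTable,
    Preprocessor,
    TrajectoryTensor,
    apply_preprocessor,
    fit_preprocessor,
    refold,
    unfold,
)

__all__ = [
    "HCConfig", "FCMResult", "Classifier", "PolyBridge", "HCPLSRModel",
    "fcm_cluster", "enforce_min_cluster_size", "train_classifier",
    "fit_hcplsr_inverse", "fit_hcplsr_classical", "predict",
    "select_n_clusters", "r2_scores",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class HCConfig:
    """Settings for hierarchical metamodelling.

    Defaults: fuzzifier m = 2, 10-fold CV, 1% factor rule, minimum cluster
    size 10, QDA classification, most-probable prediction."""

    n_clusters: int = 1
    classifier: str = "qda"
    fuzzifier: float = 2.0
    min_cluster_size: int = 10
    cv_folds: int = 10
    min_cv_variance: float = 0.01
    a_max: int = 10
    a_max_regional: int | None = None
    prediction_mode: str = "most_probable"
    scheme: str = "columnwise"
    r2_method: str = "correlation"
    seed: int = 0


# ---------------------------------------------------------------------------
# fuzzy C-means
# ---------------------------------------------------------------------------

@dataclass
class FCMResult:
    """Fuzzy C-means clustering of score-space points."""

    memberships: np.ndarray          # (n, C), rows sum to 1
    centres: np.ndarray              # (C, dim)
    fuzzifier: float
    objective_trace: list[float]
    labels: np.ndarray               # crisp argmax labels
    outlier: np.ndarray              # flagged by enforce_min_cluster_size
    retained: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.retained:
            self.retained = sorted(set(self.labels.tolist()))


def _fcm_once(
    points: np.ndarray, C: int, m: float, tol: float, max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[float]] | None:
    n = points.shape[0]
    centres = points[rng.choice(n, size=C, replace=False)].copy()
    if len(np.unique(centres, axis=0)) < C:
        return None
    trace: list[float] = []
    U = np.zeros((n, C))
    power = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (d2[:, :, None] / d2[:, None, :]) ** (power / 2.0)
            U = 1.0 / ratio.sum(axis=2)
        hit = zero.any(axis=1)
        if hit.any():
            U[hit] = 0.0
            U[hit, np.argmax(zero[hit], axis=1)] = 1.0
        Um = U ** m
        trace.append(float((Um * d2).sum()))
        new_centres = (Um.T @ points) / Um.sum(axis=0)[:, None]
        shift = float(np.abs(new_centres - centres).max())
        centres = new_centres
        if shift < tol:
            break
    return U, centres, trace


def fcm_cluster(
    scores: np.ndarray, C: int,
    m: float = 2.0, tol: float = 1e-6, max_iter: int = 300, seed: int = 0,
) -> FCMResult:
    """Standard fuzzy C-means with Euclidean distance on score coordinates.

    Cluster labels are ordered by the first score coordinate of the centres
    so that labellings are stable across runs.  A degenerate (duplicate)
    centre initialisation is re-seeded once, then raises.
    """
    points = np.asarray(scores, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if C < 1:
        raise ValueError("C must be >= 1")
    if n <= C:
        raise ValueError(f"need more than C={C} observations, got {n}")
    if C == 1:
        U = np.ones((n, 1))
        centre = points.mean(axis=0, keepdims=True)
        d2 = ((points - centre) ** 2).sum(axis=1)
        return FCMResult(U, centre, m, [float(d2.sum())],
                         np.zeros(n, dtype=int), np.zeros(n, dtype=bool))
    rng = np.random.default_rng(seed)
    result = _fcm_once(points, C, m, tol, max_iter, rng)
    if result is None:
        result = _fcm_once(points, C, m, tol, max_iter, rng)
    if result is None:
        raise ValueError("duplicate cluster centres after re-seeding")
    U, centres, trace = result
    order = np.argsort(centres[:, 0], kind="stable")
    U = U[:, order]
    centres = centres[order]
    labels = np.argmax(U, axis=1)
    return FCMResult(U, centres, m, trace, labels, np.zeros(n, dtype=bool))


def enforce_min_cluster_size(fcm: FCMResult, min_size: int = 10) -> FCMResult:
    """Dissolve crisp clusters smaller than ``min_size``.

    Their observations are flagged as outliers: excluded from regional
    fitting (but they remain part of the global model).  All clusters
    dissolved is an error.
    """
    counts = np.bincount(fcm.labels, minlength=fcm.memberships.shape[1])
    retained = [c for c in range(fcm.memberships.shape[1]) if counts[c] >= min_size]
    if not retained:
        raise ValueError(f"all clusters have fewer than {min_size} members")
    outlier = ~np.isin(fcm.labels, retained)
    return replace(fcm, outlier=outlier, retained=retained)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class Classifier:
    """Class-conditional Gaussian classifier over score features."""

    method: str
    estimator: object
    classes: np.ndarray

    def posterior(self, features: np.ndarray) -> np.ndarray:
        post = self.estimator.predict_proba(np.asarray(features, dtype=float))
        return post

    def classify(self, features: np.ndarray) -> np.ndarray:
        post = self.posterior(features)
        return self.classes[np.argmax(post, axis=1)]


def train_classifier(
    features: np.ndarray, labels: np.ndarray, method: str = "qda"
) -> Classifier:
    """Fit LDA (shared covariance), QDA (per-class covariance) or Gaussian
    naive Bayes on score features with crisp cluster labels."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    dim = features.shape[1]
    if method == "qda":
        small = classes[counts < dim + 2]
        if small.size:
            raise ValueError(
                f"class {small[0]} has too few members ({counts[classes == small[0]][0]}) "
                f"for a {dim}-dimensional per-class covariance"
            )
        est = QuadraticDiscriminantAnalysis(store_covariance=False)
    elif method == "lda":
        est = LinearDiscriminantAnalysis()
    elif method in ("nb", "naive_bayes"):
        est = GaussianNB()
    else:
        raise ValueError(f"unknown classifier method {method!r}")
    est.fit(features, labels)
    return Classifier(method, est, est.classes_)


# ---------------------------------------------------------------------------
# polynomial bridge (classical direction)
# ---------------------------------------------------------------------------

def _poly_design(T: np.ndarray) -> np.ndarray:
    """[1 | linear | squares | cross terms] design for second-order OLS."""
    n, A = T.shape
    cols = [np.ones((n, 1)), T, T ** 2]
    cross = [T[:, [i]] * T[:, [j]] for i in range(A) for j in range(i + 1, A)]
    return np.hstack(cols + cross) if cross else np.hstack(cols)


@dataclass
class PolyBridge:
    """Second-order polynomial OLS map from classical predicted response-side
    scores to inverse-model score space (for classification of new
    observations in the classical direction)."""

    coef: np.ndarray
    n_inputs: int
    n_outputs: int

    @classmethod
    def fit(cls, T_hat_y: np.ndarray, S_inverse: np.ndarray) -> "PolyBridge":
        D = _poly_design(np.asarray(T_hat_y, dtype=float))
        coef, *_ = np.linalg.lstsq(D, np.asarray(S_inverse, dtype=float), rcond=None)
        return cls(coef, T_hat_y.shape[1], S_inverse.shape[1])

    def predict(self, T_hat_y: np.ndarray) -> np.ndarray:
        if T_hat_y.shape[1] != self.n_inputs:
            raise ValueError("bridge input dimensionality mismatch")
        return _poly_design(np.asarray(T_hat_y, dtype=float)) @ self.coef


# ---------------------------------------------------------------------------
# hierarchical model
# ---------------------------------------------------------------------------

@dataclass
class HCPLSRModel:
    """A fitted hierarchical metamodel (one direction)."""

    direction: str                              # "inverse" | "classical"
    config: HCConfig
    x_preprocessor: Preprocessor
    y_preprocessor: Preprocessor
    cv_report: CVReport
    global_model: NPLSModel
    fcm: FCMResult | None
    classifier: Classifier | None
    regional_models: dict[int, NPLSModel]
    regional_cv: dict[int, CVReport]
    bridge: PolyBridge | None = None
    inverse_scores: np.ndarray | None = None    # calibration clustering features
    y_template: TrajectoryTensor | None = None  # layout of tensor responses
    regional_offsets: dict[int, tuple] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.regional_models)


def _preprocessed(data, preproc: Preprocessor):
    return apply_preprocessor(preproc, data, "forward")


def _subset(data, idx: np.ndarray):
    if isinstance(data, (TrajectoryTensor, ParameterTable)):
        return data.subset(idx)
    return np.asarray(data)[idx]


def _centre_subset(data, idx: np.ndarray):
    """Cluster subset re-centred around its own mean (regional models carry
    an implicit intercept; scaling stays global).  Returns (block, mean)."""
    if isinstance(data, TrajectoryTensor):
        sub = data.subset(idx)
        flat = unfold(sub)
        mean = flat.mean(axis=0)
        centred = TrajectoryTensor(
            refold(flat - mean, sub.n_vars, sub.n_time),
            sub.obs_ids, sub.var_names, sub.time_grid,
        )
        return centred, mean
    arr = data.values if isinstance(data, ParameterTable) else np.asarray(data)
    sub = arr[idx]
    mean = sub.mean(axis=0)
    return sub - mean, mean


def _fit_regionals(
    Xp, Yp, fcm: FCMResult, config: HCConfig, global_model: NPLSModel,
) -> tuple[dict[int, NPLSModel], dict[int, CVReport], dict[int, tuple]]:
    a_max = config.a_max_regional or config.a_max
    models: dict[int, NPLSModel] = {}
    reports: dict[int, CVReport] = {}
    offsets: dict[int, tuple] = {}
    for c in fcm.retained:
        idx = np.where((fcm.labels == c) & ~fcm.outlier)[0]
        Xc, x_mean = _centre_subset(Xp, idx)
        Yc, y_mean = _centre_subset(Yp, idx)
        cv = cv_select_factors(Xc, Yc, a_max, config.cv_folds,
                               config.min_cv_variance, config.seed)
        models[c] = fit_npls(Xc, Yc, cv.chosen)
        reports[c] = cv
        offsets[c] = (x_mean, y_mean)
    return models, reports, offsets


def fit_hcplsr_inverse(X, Y: ParameterTable, config: HCConfig) -> HCPLSRModel:
    """Fit the inverse hierarchical metamodel (model outputs -> parameters).

    ``X`` is normally a :class:`TrajectoryTensor`; a 2-way matrix (unfolded
    trajectories or aggregated outputs) runs through the identical machinery,
    which is how the 2-way benchmarking variants are produced.
    """
    x_pre = fit_preprocessor(X, scheme=config.scheme if isinstance(X, TrajectoryTensor) else "columnwise")
    y_pre = fit_preprocessor(Y)
    Xp, Yp = _preprocessed(X, x_pre), _preprocessed(Y, y_pre)

    cv = cv_select_factors(Xp, Yp, config.a_max, config.cv_folds,
                           config.min_cv_variance, config.seed)
    global_model = fit_npls(Xp, Yp, cv.chosen)
    scores = global_model.scores       # clustering on all factors passing the 1% rule

    if config.n_clusters <= 1:
        return HCPLSRModel("inverse", config, x_pre, y_pre, cv, global_model,
                           None, None, {0: global_model}, {0: cv},
                           inverse_scores=scores)
    fcm = fcm_cluster(scores, config.n_clusters, config.fuzzifier, seed=config.seed)
    fcm = enforce_min_cluster_size(fcm, config.min_cluster_size)
    keep = ~fcm.outlier
    classifier = train_classifier(scores[keep], fcm.labels[keep], config.classifier)
    regionals, reports, offsets = _fit_regionals(Xp, Yp, fcm, config, global_model)
    return HCPLSRModel("inverse", config, x_pre, y_pre, cv, global_model,
                       fcm, classifier, regionals, reports,
                       inverse_scores=scores, regional_offsets=offsets)


def fit_hcplsr_classical(
    X: ParameterTable, Y: TrajectoryTensor, inverse_model: HCPLSRModel,
    config: HCConfig | None = None,
) -> HCPLSRModel:
    """Fit the classical hierarchical metamodel (parameters -> outputs),
    reusing the inverse model's clusters, with the polynomial score bridge
    for prediction-stage classification."""
    config = config or inverse_model.config
    if X.n_obs != inverse_model.global_model.scores.shape[0]:
        raise ValueError("classical calibration set differs from the inverse model's")
    x_pre = fit_preprocessor(X)
    y_pre = fit_preprocessor(Y, scheme=config.scheme)
    Xp, Yp = _preprocessed(X, x_pre), _preprocessed(Y, y_pre)

    cv = cv_select_factors(Xp, Yp, config.a_max, config.cv_folds,
                           config.min_cv_variance, config.seed)
    global_model = fit_npls(Xp, Yp, cv.chosen)

    t_hat_y = global_model.scores @ global_model.score_map
    bridge = PolyBridge.fit(t_hat_y, inverse_model.inverse_scores)

    fcm = inverse_model.fcm
    if fcm is None or config.n_clusters <= 1:
        return HCPLSRModel("classical", config, x_pre, y_pre, cv, global_model,
                           None, None, {0: global_model}, {0: cv},
                           bridge=bridge, y_template=Y)
    regionals, reports, offsets = _fit_regionals(Xp, Yp, fcm, config, global_model)
    return HCPLSRModel("classical", config, x_pre, y_pre, cv, global_model,
                       fcm, inverse_model.classifier, regionals, reports,
                       bridge=bridge, y_template=Y, regional_offsets=offsets)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _classification_features(model: HCPLSRModel, T_new: np.ndarray) -> np.ndarray:
    if model.direction == "inverse":
        return T_new
    t_hat_y = T_new @ model.global_model.score_map
    return model.bridge.predict(t_hat_y)


def predict(
    model: HCPLSRModel, X_new, mode: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict responses for new observations, raw scale.

    Returns ``(Y_hat, report)``; the report lists, per observation, the
    assigned cluster and its posterior probability.  ``mode`` is
    ``most_probable`` (one regional model per observation) or ``weighted``
    (posterior-weighted sum over all regional models).
    """
    mode = mode or model.config.prediction_mode
    if mode not in ("most_probable", "weighted"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    Xp = _preprocessed(X_new, model.x_preprocessor)
    _, T_new, _ = predict_npls(model.global_model, Xp)
    n = T_new.shape[0]
    obs_ids = getattr(X_new, "obs_ids", [f"new{i}" for i in range(n)])

    if model.classifier is None:
        y_pre, _, _ = predict_npls(model.global_model, Xp)
        labels = np.zeros(n, dtype=int)
        post_max = np.ones(n)
    else:
        feats = _classification_features(model, T_new)
        post = model.classifier.posterior(feats)
        if np.isnan(post).any():
            bad = int(np.where(np.isnan(post).any(axis=1))[0][0])
            raise ValueError(f"unclassifiable observation {obs_ids[bad]}: posterior is NaN")
        classes = model.classifier.classes
        labels = classes[np.argmax(post, axis=1)]
        post_max = post.max(axis=1)
        y_dim = model.global_model.y_loadings.shape[0]
        y_pre = np.zeros((n, y_dim))
        Xu, _ = _block(Xp)
        if mode == "most_probable":
            for c in model.regional_models:
                members = labels == c
                if members.any():
                    x_mean, y_mean = model.regional_offsets.get(c, (0.0, 0.0))
                    y_c, _, _ = predict_npls(model.regional_models[c], Xu[members] - x_mean)
                    y_pre[members] = y_c + y_mean
        else:
            for j, c in enumerate(classes):
                x_mean, y_mean = model.regional_offsets.get(int(c), (0.0, 0.0))
                y_c, _, _ = predict_npls(model.regional_models[int(c)], Xu - x_mean)
                y_pre += post[:, [j]] * (y_c + y_mean)

    y_hat = y_pre * model.y_preprocessor.scales + model.y_preprocessor.means
    if model.y_template is not None:
        y_hat = y_hat.reshape(n, model.y_template.n_vars, model.y_template.n_time)
    report = pd.DataFrame({"obs_id": list(obs_ids), "cluster": labels, "posterior": post_max})
    return y_hat, report


# ---------------------------------------------------------------------------
# metrics and cluster-count selection
# ---------------------------------------------------------------------------

def r2_scores(
    y_obs, y_pred, method: str = "correlation"
) -> np.ndarray:
    """Per-variable R^2 between observed and predicted responses.

    ``correlation`` (default) is the squared Pearson correlation — note it is
    blind to scale and offset (a constant-shifted or sign-flipped prediction
    still scores 1).  ``sse`` gives 1 - SSE/SST instead.  For trajectory
    tensors the statistic is computed per state variable over all
    observations x time points.  Zero-variance observed variables yield NaN.
    """
    if isinstance(y_obs, TrajectoryTensor):
        obs = y_obs.values.transpose(1, 0, 2).reshape(y_obs.n_vars, -1).T
        if isinstance(y_pred, TrajectoryTensor):
            y_pred = y_pred.values
        pred = np.asarray(y_pred).reshape(y_obs.n_obs, y_obs.n_vars, y_obs.n_time)
        pred = pred.transpose(1, 0, 2).reshape(y_obs.n_vars, -1).T
    else:
        obs = y_obs.values if isinstance(y_obs, ParameterTable) else np.asarray(y_obs)
        pred = y_pred.values if isinstance(y_pred, ParameterTable) else np.asarray(y_pred)
    if obs.shape != pred.shape:
        raise ValueError("observed/predicted shapes differ")
    out = np.full(obs.shape[1], np.nan)
    for j in range(obs.shape[1]):
        o, p = obs[:, j], pred[:, j]
        so, sp = o.std(), p.std()
        if so == 0:
            continue
        if method == "correlation":
            if sp == 0:
                out[j] = 0.0
            else:
                r = float(np.corrcoef(o, p)[0, 1])
                out[j] = r * r
        elif method == "sse":
            out[j] = 1.0 - float(((o - p) ** 2).sum()) / float(((o - o.mean()) ** 2).sum())
        else:
            raise ValueError(f"unknown R^2 method {method!r}")
    return out


def select_n_clusters(
    X, Y: ParameterTable,
    C_range: range | list[int] = range(1, 21),
    config: HCConfig | None = None,
    margin: float = 0.02,
) -> tuple[int, pd.DataFrame]:
    """Sweep the cluster count for the inverse direction.

    For each C the hierarchical model is fitted and the calibration set is
    re-predicted *as new observations* (classification in the prediction
    stage).  The chosen C is the smallest whose mean R^2 is within ``margin``
    of the curve maximum.  Returns (chosen C, curve table with per-variable
    and mean R^2 per C).
    """
    config = config or HCConfig()
    rows = []
    for C in C_range:
        cfg = replace(config, n_clusters=int(C))
        model = fit_hcplsr_inverse(X, Y, cfg)
        y_hat, _ = predict(model, X)
        r2 = r2_scores(Y, y_hat, config.r2_method)
        rows.append({"C": int(C), "mean_r2": float(np.nanmean(r2)),
                     **{name: r2[j] for j, name in enumerate(Y.param_names)}})
    curve = pd.DataFrame(rows)
    best = curve["mean_r2"].max()
    chosen = int(curve.loc[curve["mean_r2"] >= best - margin, "C"].iloc[0])
    return chosen, curve
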