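"""Calibration models: PCA compression, PLS, ELM and SVR, and their
Rc/RMSECV/Rp/RMSEP/RPD evaluation.

The number of principal components fed to a model is chosen by minimal
cross-validated RMSE (RMSECV).  RPD — the prediction-set reference standard
deviation divided by RMSEP — grades a model: 1.4-1.8 supports rough
prediction, above 2 the prediction is considered accurate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.svm import SVR

from .synthetic import ParameterError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA compression of a band subset
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """PCA fit on calibration rows of a band subset."""

    subset: np.ndarray
    mean: np.ndarray
    loadings: np.ndarray            # (n_components, n_subset_bands)
    explained_variance: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float)[:, self.subset] - self.mean) @ self.loadings.T


def pca_reduce(cal_X: np.ndarray, pred_X: np.ndarray, subset, max_pcs: int
               ) -> tuple[np.ndarray, np.ndarray, PcaModel]:
    """Quadratic dimension reduction: PCA on the selected bands.

    The rotation is learned on calibration rows only; both sets are projected
    with the calibration loadings.
    """
    subset = np.asarray(subset, int)
    if subset.size == 0:
        raise ParameterError("band subset is empty")
    cal_X = np.asarray(cal_X, float)
    limit = min(cal_X.shape[0] - 1, subset.size)
    if not 1 <= max_pcs <= limit:
        raise ParameterError(f"max_pcs must lie in [1, {limit}]")
    pca = PCA(n_components=max_pcs, svd_solver="full")
    cal_scores = pca.fit_transform(cal_X[:, subset])
    model = PcaModel(subset, pca.mean_, pca.components_,
                     pca.explained_variance_, max_pcs)
    pred_scores = model.transform(pred_X)
    return cal_scores, pred_scores, model


# ---------------------------------------------------------------------------
# Models (uniform .predict surface)
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """Partial least squares (NIPALS) on centred data."""

    n_lv: int
    _pls: PLSRegression

    @property
    def x_scores(self) -> np.ndarray:
        return self._pls.x_scores_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._pls.predict(np.asarray(X, float)).ravel()


def pls_train(X: np.ndarray, y: np.ndarray, n_lv: int) -> PlsModel:
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ParameterError("response has zero variance")
    if not 1 <= n_lv <= min(X.shape[0] - 1, X.shape[1]):
        raise ParameterError("n_lv must lie in [1, min(samples-1, features)]")
    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(X, y)
    return PlsModel(n_lv, pls)


@dataclass
class ElmModel:
    """Extreme learning machine: random logistic hidden layer, least-squares
    output weights.  The hidden weights are drawn once from the seed and
    never updated.

    Inputs are centred and scaled by a single global factor (the largest
    column sd) so that the relative variance of PCA scores — which encodes
    which directions carry signal — survives into the hidden layer.
    """

    hidden: int
    seed: int
    input_mean: np.ndarray
    input_scale: float
    y_mean: float
    w: np.ndarray       # (features, hidden)
    b: np.ndarray       # (hidden,)
    beta: np.ndarray    # (hidden + 1,) incl. output bias

    def _hidden_layer(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.input_mean) / self.input_scale
        H = expit(Z @ self.w + self.b)
        return np.hstack([H, np.ones((H.shape[0], 1))])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._hidden_layer(X) @ self.beta + self.y_mean


def elm_train(X: np.ndarray, y: np.ndarray, hidden: int = 50, seed: int = 0,
              ridge: float = 1e-8) -> ElmModel:
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if hidden < 1:
        raise ParameterError("hidden size must be >= 1")
    rng = np.random.default_rng(seed)
    mean = X.mean(axis=0)
    scale = float(X.std(axis=0).max())
    if scale <= 0:
        scale = 1.0
    w = rng.uniform(-1.0, 1.0, size=(X.shape[1], hidden))
    b = rng.uniform(-1.0, 1.0, size=hidden)
    model = ElmModel(hidden, seed, mean, scale, float(y.mean()), w, b,
                     np.zeros(hidden + 1))
    H = model._hidden_layer(X)
    if not np.all(np.isfinite(H)):
        raise ParameterError("non-finite hidden activations")
    A = H.T @ H + ridge * np.eye(H.shape[1])
    model.beta = np.linalg.solve(A, H.T @ (y - model.y_mean))
    return model


@dataclass
class SvrModel:
    """Epsilon-SVR with an RBF kernel on standardised inputs/response."""

    c: float
    g: float
    epsilon: float
    _svr: SVR
    input_mean: np.ndarray
    input_sd: np.ndarray
    y_mean: float
    y_sd: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.input_mean) / self.input_sd
        return self._svr.predict(Z) * self.y_sd + self.y_mean


def _fit_svr(X, y, c, g, epsilon):
    mean = X.mean(axis=0)
    sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    y_mean, y_sd = float(y.mean()), float(y.std())
    if y_sd == 0:
        y_sd = 1.0
    svr = SVR(kernel="rbf", C=c, gamma=g, epsilon=epsilon)
    svr.fit((X - mean) / sd, (y - y_mean) / y_sd)
    return SvrModel(c, g, epsilon, svr, mean, sd, y_mean, y_sd)


def default_c_grid() -> np.ndarray:
    """2^(-5) .. 2^15 in steps of 2^0.5 (contains 2.83, 4, 16, 32)."""
    return 2.0 ** np.arange(-5.0, 15.0 + 0.25, 0.5)


def default_g_grid() -> np.ndarray:
    """2^(-15) .. 2^3 in steps of 2^0.5 (contains 0.5 and ~0.35, 0.63, 0.063)."""
    return 2.0 ** np.arange(-15.0, 3.0 + 0.25, 0.5)


def svr_train_tuned(X: np.ndarray, y: np.ndarray, c_grid=None, g_grid=None,
                    folds: int = 5, seed: int = 0, epsilon: float = 0.01
                    ) -> tuple[SvrModel, float, float]:
    """Grid-search (c, g) by cross-validated RMSE; ties take smaller c, then g."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ParameterError("response has zero variance")
    c_grid = np.sort(np.asarray(default_c_grid() if c_grid is None else c_grid, float))
    g_grid = np.sort(np.asarray(default_g_grid() if g_grid is None else g_grid, float))
    if c_grid.size == 0 or g_grid.size == 0 or c_grid[0] <= 0 or g_grid[0] <= 0:
        raise ParameterError("c and g grids must be non-empty and positive")
    from .selection import _cv_folds
    test_sets = _cv_folds(len(y), folds, seed)
    n = len(y)
    best = (np.inf, np.inf, np.inf)
    for c in c_grid:
        for g in g_grid:
            resid = np.empty(n)
            for test in test_sets:
                train = np.setdiff1d(np.arange(n), test)
                m = _fit_svr(X[train], y[train], c, g, epsilon)
                resid[test] = m.predict(X[test]) - y[test]
            rmse = float(np.sqrt(np.mean(resid ** 2)))
            if (rmse, c, g) < best:
                best = (rmse, c, g)
    _, c, g = best
    return _fit_svr(X, y, c, g, epsilon), float(c), float(g)


# ---------------------------------------------------------------------------
# RMSECV-driven component choice
# ---------------------------------------------------------------------------

def _train(kind: str, X, y, seed: int, **kw):
    if kind == "pls":
        return pls_train(X, y, n_lv=min(X.shape[1], X.shape[0] - 1))
    if kind == "elm":
        return elm_train(X, y, seed=seed, **kw)
    if kind == "svr":
        return _fit_svr(np.asarray(X, float), np.asarray(y, float),
                        kw.get("c", 4.0), kw.get("g", 0.5), kw.get("epsilon", 0.01))
    raise ParameterError(f"unknown model kind {kind!r}")


def cv_rmse(X: np.ndarray, y: np.ndarray, kind: str, folds: int, seed: int,
            **kw) -> float:
    from .selection import _cv_folds
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    test_sets = _cv_folds(len(y), folds, seed)
    resid = np.empty(len(y))
    for test in test_sets:
        train = np.setdiff1d(np.arange(len(y)), test)
        model = _train(kind, X[train], y[train], seed, **kw)
        resid[test] = model.predict(X[test]) - y[test]
    return float(np.sqrt(np.mean(resid ** 2)))


def choose_pcs_by_rmsecv(cal_scores: np.ndarray, ycal: np.ndarray,
                         model_kind: str = "pls", folds: int = 10,
                         seed: int = 0, **kw) -> tuple[int, float]:
    """Pick the PC count minimising RMSECV; ties go to the fewest PCs."""
    cal_scores = np.asarray(cal_scores, float)
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if folds > cal_scores.shape[0]:
        raise ParameterError("more folds than samples")
    best_pcs, best_rmse = 1, np.inf
    for p in range(1, cal_scores.shape[1] + 1):
        rmse = cv_rmse(cal_scores[:, :p], ycal, model_kind, folds, seed, **kw)
        if rmse < best_rmse - 1e-15:
            best_pcs, best_rmse = p, rmse
    return best_pcs, best_rmse


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelEval:
    """One report-table row for a component x method pair."""

    component: str
    method: str
    n_variables: int
    pcs: int
    rc: float
    rmsecv: float
    rp: float
    rmsep: float
    rpd: float
    grade: str = field(init=False)

    def __post_init__(self):
        self.grade = grade_rpd(self.rpd)

    def as_row(self) -> dict:
        return {"component": self.component, "method": self.method,
                "variable_number": self.n_variables, "pcs": self.pcs,
                "rc": self.rc, "rmsecv": self.rmsecv, "rp": self.rp,
                "rmsep": self.rmsep, "rpd": self.rpd, "grade": self.grade}


def grade_rpd(rpd: float) -> str:
    """1.4 <= RPD <= 1.8: rough; RPD > 2: accurate; otherwise inadequate."""
    if rpd > 2.0:
        return "accurate"
    if 1.4 <= rpd <= 1.8:
        return "rough"
    return "inadequate"


def _pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_model(model, cal_X, ycal, pred_X, ypred, component: str = "",
                   method: str = "", n_variables: int = 0, pcs: int = 0,
                   rmsecv: float = float("nan")) -> ModelEval:
    """Rc/Rp (Pearson), RMSEP and RPD = sd(reference, n-1)/RMSEP."""
    ypred = np.asarray(ypred, float)
    if ypred.size == 0 or ypred.std(ddof=1) == 0:
        raise ParameterError("prediction set must be non-empty with sd > 0")
    yc_hat = model.predict(cal_X)
    yp_hat = model.predict(pred_X)
    rc = _pearson(ycal, yc_hat)
    rp = _pearson(ypred, yp_hat)
    rmsep = float(np.sqrt(np.mean((yp_hat - ypred) ** 2)))
    sd = float(ypred.std(ddof=1))
    if rmsep == 0.0:
        log.warning("RMSEP is exactly 0 for %s/%s: RPD reported as infinite",
                    component, method)
        rpd = float("inf")
    else:
        rpd = sd / rmsep
    return ModelEval(component, method, n_variables, pcs, rc, rmsecv, rp,
                     rmsep, rpd)
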