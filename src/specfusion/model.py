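"""Calibration modelling: Kennard-Stone partitioning, PLS1 regression with
cross-validated latent-variable count, evaluation metrics, and SVM/BPNN
baselines.

The central object is :class:`PLSCalibration`, a model built from a
calibration block (X, y) whose :meth:`~PLSCalibration.fit` returns a
:class:`PLSResults` carrying the centered NIPALS state, the chosen number
of latent variables, cross-validation diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplitResult",
    "kennard_stone_order",
    "kennard_stone_split",
    "PLSCalibration",
    "PLSResults",
    "fit_pls",
    "predict_pls",
    "EvalReport",
    "evaluate",
    "fit_svm_baseline",
    "fit_bpnn_baseline",
]


# ---------------------------------------------------------------------------
# Kennard-Stone partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction index sets covering all samples."""

    calibration_indices: np.ndarray
    prediction_indices: np.ndarray

    def __post_init__(self):
        cal = np.asarray(self.calibration_indices, dtype=int)
        pred = np.asarray(self.prediction_indices, dtype=int)
        object.__setattr__(self, "calibration_indices", cal)
        object.__setattr__(self, "prediction_indices", pred)
        if np.intersect1d(cal, pred).size:
            raise ValueError("calibration and prediction sets overlap")


def kennard_stone_order(X: np.ndarray) -> np.ndarray:
    """Full Kennard-Stone selection order of the rows of X.

    Seeds with the mutually most-distant pair (Euclidean), then repeatedly
    adds the sample whose minimum distance to the already-selected set is
    maximal.  Ties break toward the lowest row index.  The prefix of this
    order is the most space-filling subset of each size, which is also how
    transfer standard samples are chosen.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least 2 samples")
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    # lowest-index tie break: argmax on the flattened matrix scans row-major
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    first, second = min(i, j), max(i, j)
    order = [first, second]
    np.fill_diagonal(d2, np.inf)
    mind = np.minimum(d2[:, first], d2[:, second])
    mind[[first, second]] = -np.inf
    for _ in range(n - 2):
        nxt = int(np.argmax(mind))
        order.append(nxt)
        mind = np.minimum(mind, d2[:, nxt])
        mind[nxt] = -np.inf
    return np.asarray(order, dtype=int)


def kennard_stone_split(X: np.ndarray, cal_fraction: float) -> SplitResult:
    """Deterministic space-filling calibration/prediction split.

    The calibration set holds the first ``round(cal_fraction * n)`` samples
    in Kennard-Stone order; the remainder is the prediction set.  A 2:1
    fraction on 63 samples gives 42/21; a 4:1 fraction on 126 gives 101/25.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_cal = int(np.floor(cal_fraction * n + 0.5))  # round-half-up
    if n_cal < 2 or n_cal >= n:
        raise ValueError(
            f"cal_fraction {cal_fraction} gives {n_cal} calibration samples "
            f"of {n}; need 2 <= |cal| < n"
        )
    order = kennard_stone_order(X)
    cal = np.sort(order[:n_cal])
    pred = np.sort(order[n_cal:])
    return SplitResult(cal, pred)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) with deterministic 10-fold CV for the latent-variable count
# ---------------------------------------------------------------------------

def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centered data.

    Returns (W, P, q, n_extracted): X-weights, X-loadings and y-loadings per
    latent variable.  Extraction stops early if the deflated X (or the
    weight vector) collapses numerically.
    """
    X = Xc.copy()
    y = yc.copy()
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    x_scale = max(float(np.linalg.norm(Xc)), 1e-300)
    y_scale = max(float(np.linalg.norm(yc)), 1e-300)
    a = 0
    for a in range(n_lv):
        if np.linalg.norm(X) <= 1e-10 * x_scale:
            break  # X fully deflated: remaining LVs are numerical noise
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * x_scale * y_scale or not np.isfinite(wn):
            break
        w /= wn
        t = X @ w
        tt = t @ t
        if tt <= (1e-8 * x_scale) ** 2:
            break
        p_a = X.T @ t / tt
        q_a = (y @ t) / tt
        X -= np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        a += 1
    return W[:, :a], P[:, :a], q[:a], a


def _pls_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Composite regression vector B so that yhat_c = X_c @ B."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)  # B = W (P^T W)^-1 q


def _cv_fold_assignment(y: np.ndarray, cv_folds: int) -> np.ndarray:
    """Deterministic stratified-by-concentration fold labels.

    Samples sorted by y are dealt round-robin into folds, so every fold
    spans the concentration range; no randomness, hence reproducible.
    Ties in y break by original index (stable sort).
    """
    n = y.size
    folds = np.empty(n, dtype=int)
    folds[np.argsort(y, kind="stable")] = np.arange(n) % cv_folds
    return folds


@dataclass
class PLSResults:
    """Fitted PLS1 calibration state.

    Attributes
    ----------
    n_lv : chosen latent-variable count (argmin of mean CV RMSE, smallest
        within 1e-10 of the minimum).
    coefficients : composite regression vector on centered data.
    cv_rmse : mean cross-validated RMSE for 1..max_lv latent variables.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    n_lv: int
    cv_rmse: np.ndarray = field(default=None)  # type: ignore[assignment]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"X has {X.shape[1]} columns; model was trained on {self.x_mean.size}"
            )
        return self.y_mean + (X - self.x_mean) @ self.coefficients

    def summary(self) -> str:
        lines = [
            "PLS1 calibration results",
            "=" * 40,
            f"wavelength columns : {self.x_mean.size}",
            f"latent variables   : {self.n_lv}",
        ]
        if self.cv_rmse is not None:
            lines.append("CV RMSE by LV      : "
                         + ", ".join(f"{v:.4f}" for v in self.cv_rmse))
        lines.append(f"|coefficients|_max : {np.abs(self.coefficients).max():.6g}")
        return "\n".join(lines)


class PLSCalibration:
    """PLS1 regression model for concentration calibration.

    Parameters
    ----------
    X, y : calibration absorbance block and concentration vector (%).
    max_lv : largest latent-variable count considered (default 6, guarding
        against over-fitting at calibration sizes of a few dozen samples).
    cv_folds : folds for the deterministic cross-validation that picks the
        latent-variable count (default 10).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, max_lv: int = 6,
                 cv_folds: int = 10):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on sample count")
        if self.y.size < cv_folds:
            raise ValueError(f"need at least cv_folds={cv_folds} samples")
        if np.ptp(self.y) == 0:
            raise ValueError("y has zero variance; nothing to calibrate")
        n, p = self.X.shape
        feasible = min(n - int(np.ceil(n / cv_folds)), p)
        if not 1 <= max_lv <= feasible:
            raise ValueError(f"max_lv must be in [1, {feasible}] here, got {max_lv}")
        self.max_lv = max_lv
        self.cv_folds = cv_folds

    def fit(self, n_lv: int | None = None) -> PLSResults:
        """Select n_lv by cross-validation (unless given) and refit on all data."""
        X, y = self.X, self.y
        cv_rmse = None
        if n_lv is None:
            folds = _cv_fold_assignment(y, self.cv_folds)
            sse = np.zeros(self.max_lv)
            counts_rmse = np.zeros((self.cv_folds, self.max_lv))
            for f in range(self.cv_folds):
                hold = folds == f
                Xt, yt = X[~hold], y[~hold]
                xm, ym = Xt.mean(axis=0), yt.mean()
                W, P, q, a = _nipals_pls1(Xt - xm, yt - ym, self.max_lv)
                for lv in range(1, self.max_lv + 1):
                    a_use = min(lv, a)
                    B = _pls_coefficients(W[:, :a_use], P[:, :a_use], q[:a_use])
                    resid = y[hold] - (ym + (X[hold] - xm) @ B)
                    counts_rmse[f, lv - 1] = np.sqrt(np.mean(resid**2))
            cv_rmse = counts_rmse.mean(axis=0)
            best = float(cv_rmse.min())
            n_lv = int(np.flatnonzero(cv_rmse <= best + 1e-10)[0]) + 1
        if not 1 <= n_lv <= self.max_lv:
            raise ValueError(f"n_lv must be in [1, {self.max_lv}]")
        xm, ym = X.mean(axis=0), float(y.mean())
        W, P, q, a = _nipals_pls1(X - xm, y - ym, n_lv)
        B = _pls_coefficients(W, P, q)
        return PLSResults(
            x_mean=xm, y_mean=ym, weights=W, x_loadings=P, y_loadings=q,
            coefficients=B, n_lv=a, cv_rmse=cv_rmse,
        )


def fit_pls(X, y, max_lv: int = 6, cv_folds: int = 10) -> PLSResults:
    """Functional wrapper: build a :class:`PLSCalibration` and fit it."""
    return PLSCalibration(X, y, max_lv=max_lv, cv_folds=cv_folds).fit()


def predict_pls(m: PLSResults, X) -> np.ndarray:
    return m.predict(X)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    """Prediction-quality report.

    ``r2`` is the squared Pearson correlation between predicted and
    reference values (the convention used when calibration curves are judged
    by linearity); ``r2_cod`` is the coefficient of determination
    1 - SSE/SST, which differs from ``r2`` under prediction bias and is
    carried for transparency.  ``rmse`` is in concentration % units.
    """

    r2: float
    rmse: float
    r2_cod: float = float("nan")

    def summary(self) -> str:
        return f"R^2 = {self.r2:.4f}, RMSE = {self.rmse:.4f} (CoD {self.r2_cod:.4f})"


def evaluate(y_true, y_pred) -> EvalReport:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(y_true) == 0:
        raise ValueError("constant reference values: correlation undefined")
    if np.ptp(y_pred) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    cod = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / sst
    return EvalReport(r2=r * r, rmse=rmse, r2_cod=cod)


# ---------------------------------------------------------------------------
# Baselines (pluggable, not on the pipeline's critical path)
# ---------------------------------------------------------------------------

def fit_svm_baseline(X, y, c: float = 5.0, max_iter: int = 100):
    """RBF support-vector regression baseline (penalty C=5, 100-iteration cap)."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.svm import SVR

    model = SVR(kernel="rbf", C=c, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())
    return model


def fit_bpnn_baseline(X, y, seed: int | None = None, hidden: tuple = (6, 6),
                      learning_rate: float = 0.01, max_iter: int = 2000):
    """Back-propagation network baseline: 2 hidden layers x 6 neurons,
    tan-sigmoid activation, learning rate 0.01.  A seed is mandatory so
    refits are bit-identical."""
    if seed is None:
        raise ValueError("fit_bpnn_baseline requires an explicit seed")
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPRegressor

    model = MLPRegressor(
        hidden_layer_sizes=hidden,
        activation="tanh",
        learning_rate_init=learning_rate,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())
    return model
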