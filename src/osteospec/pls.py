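"""Single-response partial least squares (PLS1) regression via NIPALS.

The model follows the statsmodels idiom: build ``PLS1(endog, exog)``, call
``.fit(ncomp)`` to obtain a :class:`PLS1Results` carrying the regression
vector, diagnostics and a ``summary()``; ``.cross_validate()`` returns a
:class:`CVResult` with per-component RMSECV / R2 curves, cross-validated
predictions and a parsimony-based component selection.

PLS1 extracts orthogonal score directions that maximise covariance between
the (column-centred) predictor matrix and the centred response, deflating X
after each component.  With as many components as the rank of X it coincides
with ordinary least squares; with few components it regularises the very
wide, collinear matrices typical of NIR spectra.

Error metrics follow chemometrics convention: RMSECV and RMSEC are expressed
as a percentage of the range of the reference values, and the coefficient of
determination is the squared Pearson (or, for non-normal responses, Spearman)
correlation between measured and predicted values, reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLS1",
    "PLS1Results",
    "CVResult",
    "kfold_cv",
    "select_components",
    "rmse_relative",
    "r_squared",
    "residual_percent",
]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def rmse_relative(y_true, y_pred) -> float:
    """RMSE as a percentage of the range of the reference values."""
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    rng = float(y.max() - y.min())
    if rng <= 0:
        raise ValueError("reference values have zero range")
    return 100.0 * float(np.sqrt(np.mean((y - yh) ** 2))) / rng


def r_squared(y_true, y_pred, method: str = "pearson") -> float:
    """Squared correlation of measured vs predicted, in percent.

    ``method='spearman'`` uses rank correlation, appropriate when the
    response fails a normality test.
    """
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.size < 3:
        raise ValueError("r_squared needs n >= 3")
    if np.std(y) == 0 or np.std(yh) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    if method == "pearson":
        r = stats.pearsonr(y, yh).statistic
    elif method == "spearman":
        r = stats.spearmanr(y, yh).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return 100.0 * float(r) ** 2


def residual_percent(y_true, y_pred) -> np.ndarray:
    """Per-sample signed prediction error as percent of the reference range."""
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    rng = float(y.max() - y.min())
    if rng <= 0:
        raise ValueError("reference values have zero range")
    return 100.0 * (yh - y) / rng


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class PLS1:
    """PLS regression model with a single response variable.

    Parameters
    ----------
    endog
        Response vector, length n.
    exog
        Predictor matrix, shape (n, p) — e.g. pre-processed absorbance
        spectra with one column per wavelength.
    """

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.size:
            raise ValueError(
                f"endog has {self.endog.size} rows, exog has {self.exog.shape[0]}"
            )
        if np.isnan(self.endog).any() or np.isnan(self.exog).any():
            raise ValueError("NaN in model data")
        if np.ptp(self.endog) == 0:
            raise ValueError("degenerate response: endog has zero variance")

    @property
    def nobs(self) -> int:
        return self.endog.size

    @property
    def max_ncomp(self) -> int:
        return min(self.nobs - 1, self.exog.shape[1])

    def fit(self, ncomp: int) -> "PLS1Results":
        """Fit by NIPALS with ``ncomp`` latent components."""
        if not 1 <= ncomp <= self.max_ncomp:
            raise ValueError(
                f"ncomp must be in [1, {self.max_ncomp}] "
                f"(n={self.nobs}, p={self.exog.shape[1]}); got {ncomp}"
            )
        x_mean = self.exog.mean(axis=0)
        y_mean = float(self.endog.mean())
        X = self.exog - x_mean
        y = self.endog - y_mean

        n, p = X.shape
        W = np.zeros((p, ncomp))   # x-weights
        P = np.zeros((p, ncomp))   # x-loadings
        q = np.zeros(ncomp)        # y-loadings
        T = np.zeros((n, ncomp))   # scores
        Xd = X.copy()
        yd = y.copy()
        w0 = np.linalg.norm(Xd.T @ yd)
        for a in range(ncomp):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw <= 1e-10 * max(w0, 1e-300):
                raise ValueError(
                    f"component {a + 1}: residual covariance vanished; "
                    "reduce ncomp"
                )
            w /= nw
            t = Xd @ w
            tt = float(t @ t)
            if tt < 1e-300:
                raise ValueError(f"component {a + 1}: degenerate score vector")
            pvec = Xd.T @ t / tt
            qa = float(yd @ t) / tt
            Xd -= np.outer(t, pvec)
            yd -= qa * t
            W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t

        # regression vector on original (centred) X: b = W (P'W)^{-1} q
        beta = W @ np.linalg.solve(P.T @ W, q)
        intercept = y_mean - float(x_mean @ beta)
        return PLS1Results(
            model=self,
            ncomp=ncomp,
            x_mean=x_mean,
            y_mean=y_mean,
            x_weights=W,
            x_loadings=P,
            y_loadings=q,
            scores=T,
            params=beta,
            intercept=intercept,
        )

    def cross_validate(
        self,
        k: int = 10,
        ncomp_grid=None,
        seed: int = 0,
        r2_method: str | None = None,
        selection_tolerance: float = 0.05,
        preprocessor=None,
    ) -> "CVResult":
        """k-fold cross-validation over a grid of component counts.

        See :func:`kfold_cv` for details; this is the bound convenience form.
        """
        return kfold_cv(
            self.exog,
            self.endog,
            k=k,
            ncomp_grid=ncomp_grid,
            seed=seed,
            r2_method=r2_method,
            selection_tolerance=selection_tolerance,
            preprocessor=preprocessor,
        )


@dataclass
class PLS1Results:
    """Fitted PLS1 model: centring constants, factor matrices and the
    assembled regression vector ``params`` with ``intercept``."""

    model: PLS1
    ncomp: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    params: np.ndarray
    intercept: float

    def predict(self, exog=None) -> np.ndarray:
        """Predicted response: x . b + b0."""
        X = self.model.exog if exog is None else np.atleast_2d(np.asarray(exog, float))
        if X.shape[1] != self.params.size:
            raise ValueError(
                f"exog has {X.shape[1]} features, model was trained with {self.params.size}"
            )
        return X @ self.params + self.intercept

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def rmsec(self) -> float:
        """Calibration error as percent of the response range."""
        return rmse_relative(self.model.endog, self.fittedvalues)

    def summary(self) -> str:
        lines = [
            "PLS1 Regression Results",
            "=" * 46,
            f"{'No. observations:':<28}{self.model.nobs:>18}",
            f"{'No. predictors:':<28}{self.params.size:>18}",
            f"{'No. components:':<28}{self.ncomp:>18}",
            f"{'RMSEC (% of range):':<28}{self.rmsec():>18.3f}",
            f"{'R2 calibration (%):':<28}{r_squared(self.model.endog, self.fittedvalues):>18.3f}",
            f"{'Intercept:':<28}{self.intercept:>18.6g}",
            "=" * 46,
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    """Cross-validation curves and the chosen model size.

    ``rmsecv`` and ``rmsec`` are percent of the reference range; ``cv_r2``
    is percent.  ``cv_predictions`` holds the pooled held-out prediction for
    every sample at each component count (shape len(grid) x n).
    """

    ncomp_grid: list[int]
    rmsecv: np.ndarray
    cv_r2: np.ndarray
    rmsec: np.ndarray
    chosen_ncomp: int
    cv_predictions: np.ndarray
    fold_assignment: np.ndarray
    r2_method: str
    selection_tolerance: float
    y: np.ndarray = field(repr=False, default=None)

    @property
    def chosen_index(self) -> int:
        return self.ncomp_grid.index(self.chosen_ncomp)

    @property
    def chosen_rmsecv(self) -> float:
        return float(self.rmsecv[self.chosen_index])

    @property
    def chosen_cv_r2(self) -> float:
        return float(self.cv_r2[self.chosen_index])

    @property
    def chosen_rmsec(self) -> float:
        return float(self.rmsec[self.chosen_index])

    @property
    def chosen_cv_predictions(self) -> np.ndarray:
        return self.cv_predictions[self.chosen_index]


def _nan_normality_gate(y: np.ndarray) -> str:
    """Pearson R2 if y passes the D'Agostino-Pearson test at alpha=0.05,
    Spearman otherwise (mirrors the non-parametric treatment of skewed
    bone-volume-fraction data)."""
    if y.size < 8:
        return "pearson"
    _, p = stats.normaltest(y)
    return "pearson" if p > 0.05 else "spearman"


def select_components(
    rmsecv: np.ndarray,
    ncomp_grid,
    tolerance_fraction: float = 0.05,
) -> int:
    """Smallest component count whose RMSECV is within ``tolerance_fraction``
    of the grid minimum (parsimony rule; ties break toward fewer components).
    """
    rmsecv = np.asarray(rmsecv, dtype=float)
    grid = list(ncomp_grid)
    if rmsecv.size != len(grid) or rmsecv.size == 0:
        raise ValueError("rmsecv and ncomp_grid must be equal-length and nonempty")
    threshold = (1.0 + tolerance_fraction) * float(rmsecv.min())
    for ncomp, value in sorted(zip(grid, rmsecv)):
        if value <= threshold:
            return int(ncomp)
    return int(grid[int(np.argmin(rmsecv))])  # unreachable; defensive


def _fit_path_predict(X_train, y_train, X_test, ncomp_max: int) -> np.ndarray:
    """Held-out predictions for every component count 1..ncomp_max in one
    NIPALS pass (components are nested, so the path costs one fit)."""
    x_mean = X_train.mean(axis=0)
    y_mean = float(y_train.mean())
    Xd = X_train - x_mean
    y = y_train - y_mean
    Xt = np.atleast_2d(X_test) - x_mean

    n_test = Xt.shape[0]
    preds = np.empty((ncomp_max, n_test))
    Xt_d = Xt.copy()
    y_pred = np.full(n_test, y_mean)
    w0 = np.linalg.norm(Xd.T @ y)
    tt0 = None
    for a in range(ncomp_max):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-10 * max(w0, 1e-300):
            # residual covariance exhausted: predictions stop changing
            preds[a:] = y_pred
            return preds
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt0 is None:
            tt0 = tt
        if tt <= 1e-20 * max(tt0, 1e-300):
            preds[a:] = y_pred
            return preds
        pvec = Xd.T @ t / tt
        qa = float(y @ t) / tt
        t_test = Xt_d @ w
        y_pred = y_pred + qa * t_test
        Xd -= np.outer(t, pvec)
        y = y - qa * t
        Xt_d -= np.outer(t_test, pvec)
        preds[a] = y_pred
    return preds


def kfold_cv(
    X,
    y,
    k: int = 10,
    ncomp_grid=None,
    seed: int = 0,
    r2_method: str | None = None,
    selection_tolerance: float = 0.05,
    preprocessor=None,
) -> CVResult:
    """Seeded k-fold cross-validation of PLS1 over a component grid.

    Samples are shuffled once with ``seed`` and split into k near-equal
    folds; for each fold the model is trained on the remainder and the
    held-out fold predicted, pooling predictions over folds.  RMSECV and the
    cross-validated R2 are computed on the pooled predictions; RMSEC comes
    from a final all-data fit at each component count.

    ``preprocessor``, if given, is called as ``preprocessor(X_train) ->
    (X_train_p, apply)`` where ``apply(X_test) -> X_test_p``; it is re-fit
    inside every training fold so that e.g. the MSC reference never sees
    held-out spectra.

    ``r2_method=None`` applies a normality gate on y: Pearson if the
    D'Agostino-Pearson omnibus test passes at alpha = 0.05, Spearman
    otherwise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if ncomp_grid is None:
        ncomp_grid = list(range(1, 16))
    grid = sorted(int(c) for c in ncomp_grid)
    if not grid:
        raise ValueError("ncomp_grid is empty")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    if min(len(f) for f in folds) < 2 and k > 2:
        raise ValueError(
            f"a fold would have < 2 samples at k={k}, n={n}; use a smaller k"
        )
    fold_assignment = np.empty(n, dtype=int)
    for i, f in enumerate(folds):
        fold_assignment[f] = i

    ncomp_max = grid[-1]
    max_train = n - max(len(f) for f in folds)
    if ncomp_max > max_train - 1:
        raise ValueError(
            f"largest ncomp {ncomp_max} too big for training folds of size {max_train}"
        )

    cv_pred = np.empty((len(grid), n))
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        X_tr, y_tr = X[train_mask], y[train_mask]
        X_te = X[test_idx]
        if preprocessor is not None:
            X_tr, apply = preprocessor(X_tr)
            X_te = apply(X_te)
        path = _fit_path_predict(X_tr, y_tr, X_te, ncomp_max)
        for gi, ncomp in enumerate(grid):
            cv_pred[gi, test_idx] = path[ncomp - 1]

    method = r2_method if r2_method is not None else _nan_normality_gate(y)

    rmsecv = np.array([rmse_relative(y, cv_pred[gi]) for gi in range(len(grid))])
    cv_r2 = np.array(
        [r_squared(y, cv_pred[gi], method=method) for gi in range(len(grid))]
    )

    # calibration error from an all-data fit at each size
    X_full = X
    if preprocessor is not None:
        X_full, _ = preprocessor(X)
    full_path = _fit_path_predict(X_full, y, X_full, ncomp_max)
    rmsec = np.array(
        [rmse_relative(y, full_path[ncomp - 1]) for ncomp in grid]
    )

    chosen = select_components(rmsecv, grid, tolerance_fraction=selection_tolerance)
    return CVResult(
        ncomp_grid=grid,
        rmsecv=rmsecv,
        cv_r2=cv_r2,
        rmsec=rmsec,
        chosen_ncomp=chosen,
        cv_predictions=cv_pred,
        fold_assignment=fold_assignment,
        r2_method=method,
        selection_tolerance=selection_tolerance,
        y=y,
    )
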