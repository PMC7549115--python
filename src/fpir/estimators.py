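"""scikit-learn style estimators for fractional-power interaction models.

These wrap the grid-search engine in the familiar fit/predict surface so
the models compose with pipelines and model selection:

>>> est = FPIRRegressor().fit(X, y)          # X of shape (n, 2)
>>> est.m_, est.n_                           # estimated exponents
>>> est.score(X, y)                          # R^2, the search criterion

Fitted attributes follow the trailing-underscore convention; ``result_``
holds the full search outcome (candidate table, baseline fit, sequential
sum-of-squares share of the interaction term).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InputError
from .grids import ExponentGrid
from .linalg import Dataset, TermSpec, fit_model, intercept, linear
from .search import fit_fpir_threeway, fit_fpir_twoway


def _as_dataset(X, y, n_predictors: int, names=None) -> Dataset:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != n_predictors:
        raise InputError(
            f"X must be 2-dimensional with {n_predictors} columns, got shape "
            f"{getattr(X, 'shape', None)}"
        )
    if X.shape[0] != len(y):
        raise InputError("X and y have inconsistent lengths")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InputError("X and y must be finite (drop missing rows first)")
    if names is None:
        names = [f"x{i + 1}" for i in range(n_predictors)]
    return Dataset(y=y, predictors={nm: X[:, i] for i, nm in enumerate(names)})


class _BaseInteractionRegressor(RegressorMixin, BaseEstimator):
    """Shared predict/score plumbing for the interaction-model estimators."""

    _n_predictors = 2

    def _feature_names(self, X):
        if hasattr(X, "columns"):
            return [str(c) for c in X.columns]
        return None

    def _fit_dataset(self, X, y) -> Dataset:
        names = self._feature_names(X)
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else -1
        return _as_dataset(X, y, self._n_predictors, names)

    def predict(self, X):
        check_is_fitted(self, "terms_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self._n_predictors:
            raise InputError(
                f"X must have {self._n_predictors} columns, got shape {X.shape}"
            )
        cols = {nm: X[:, i] for i, nm in enumerate(self.predictor_names_)}
        out = np.zeros(X.shape[0])
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            for coef, term in zip(self.coefficients_, self.terms_):
                col = np.ones(X.shape[0])
                for pred, expo in term.exponents.items():
                    col = col * cols[pred] ** float(expo)
                out += coef * col
        return out


class FPIRRegressor(_BaseInteractionRegressor):
    """Linear regression with a fractional-power two-way interaction term.

    Fits ``y = b0 + b1*x1 + b2*x2 + b3*x1**M * x2**N + e`` where the
    exponents (M, N) are estimated by a two-stage exhaustive grid search
    (3025 initial pairs, 100 refinement models) maximizing R^2.  The
    classical product interaction (M = N = 1) is always among the
    candidates, so the fitted R^2 can never fall below the regular
    interaction regression's.

    Parameters
    ----------
    tune : bool, default True
        Run the stage-2 refinement around the stage-1 winner.
    m_grid, n_grid : ExponentGrid or None
        Replacement stage-1 grids (reduced grids for validation); when
        given, tuning is skipped.

    Attributes
    ----------
    m_, n_ : float
        Selected exponents.
    coef_ : ndarray of shape (3,)
        Coefficients of (x1, x2, interaction).
    intercept_ : float
    result_ : FPIRResult
        Full search outcome: candidate table, baseline (regular) fit,
        interaction share of variance, tuning-step sizes.
    """

    def __init__(
        self,
        tune: bool = True,
        m_grid: ExponentGrid | None = None,
        n_grid: ExponentGrid | None = None,
    ):
        self.tune = tune
        self.m_grid = m_grid
        self.n_grid = n_grid

    _quadratics = False

    def fit(self, X, y):
        data = self._fit_dataset(X, y)
        result = fit_fpir_twoway(
            data,
            tune=self.tune,
            quadratics=self._quadratics,
            m_grid=self.m_grid,
            n_grid=self.n_grid,
        )
        self.result_ = result
        self.m_ = result.m_hat
        self.n_ = result.n_hat
        self.predictor_names_ = list(result.predictor_names)
        fit = result.best_fit
        self.terms_ = _rebuild_terms(self.predictor_names_, result, self._quadratics)
        self.coefficients_ = fit.coefficients
        self.intercept_ = float(fit.coefficients[0])
        self.coef_ = fit.coefficients[1:].copy()
        return self


class FPIRPRegressor(FPIRRegressor):
    """FPIR with quadratic main effects ("FPIR plus").

    Every candidate model additionally carries ``x1**2`` and ``x2**2``
    terms, so curvature in the main effects is absorbed by the quadratics
    rather than forced into the interaction exponents.
    """

    _quadratics = True


class FPIRThreeWayRegressor(_BaseInteractionRegressor):
    """Fractional-power three-way interaction ``x1**M * x2**N * x3**K``.

    Stage 1 scans a coarsened grid (every other initial value, 28 per
    exponent) unless ``coarsen=False``; stage 2 tunes each exponent with
    10 values around the winner.
    """

    _n_predictors = 3

    def __init__(self, tune: bool = True, coarsen: bool = True):
        self.tune = tune
        self.coarsen = coarsen

    def fit(self, X, y):
        data = self._fit_dataset(X, y)
        result = fit_fpir_threeway(data, tune=self.tune, coarsen=self.coarsen)
        self.result_ = result
        self.m_, self.n_, self.k_ = result.m_hat, result.n_hat, result.k_hat
        self.predictor_names_ = list(result.predictor_names)
        fit = result.best_fit
        p1, p2, p3 = self.predictor_names_
        self.terms_ = [
            intercept(),
            linear(p1),
            linear(p2),
            linear(p3),
            TermSpec("interaction", {p1: self.m_, p2: self.n_, p3: self.k_}),
        ]
        self.coefficients_ = fit.coefficients
        self.intercept_ = float(fit.coefficients[0])
        self.coef_ = fit.coefficients[1:].copy()
        return self


class RegularInteractionRegressor(_BaseInteractionRegressor):
    """The classical interaction regression ``y ~ x1 + x2 + x1:x2``.

    Identical to the fractional-power model at fixed exponents
    M = N = 1; serves as the comparison baseline.
    """

    def fit(self, X, y):
        data = self._fit_dataset(X, y)
        p1, p2 = data.names
        self.terms_ = [
            intercept(),
            linear(p1),
            linear(p2),
            TermSpec(f"{p1}*{p2}", {p1: 1.0, p2: 1.0}),
        ]
        self.ols_ = fit_model(data, self.terms_)
        self.predictor_names_ = [p1, p2]
        self.coefficients_ = self.ols_.coefficients
        self.intercept_ = float(self.coefficients_[0])
        self.coef_ = self.coefficients_[1:].copy()
        return self


class PolynomialInteractionRegressor(_BaseInteractionRegressor):
    """Full bivariate polynomial regression of total degree <= ``order``.

    The basis is every ``x1**a * x2**b`` with ``a + b <= order`` —
    (order+1)(order+2)/2 terms, i.e. 15 at the default order 4.
    """

    def __init__(self, order: int = 4):
        self.order = order

    def fit(self, X, y):
        data = self._fit_dataset(X, y)
        p1, p2 = data.names
        self.terms_ = polynomial_terms(p1, p2, self.order)
        self.ols_ = fit_model(data, self.terms_)
        self.predictor_names_ = [p1, p2]
        self.coefficients_ = self.ols_.coefficients
        self.intercept_ = float(self.coefficients_[0])
        self.coef_ = self.coefficients_[1:].copy()
        return self


def polynomial_terms(p1: str, p2: str, order: int) -> list[TermSpec]:
    """Bivariate total-degree basis: all x1^a x2^b with a + b <= order."""
    if order < 1:
        raise InputError("polynomial order must be >= 1")
    terms = [intercept()]
    for total in range(1, order + 1):
        for a in range(total, -1, -1):
            b = total - a
            expo = {}
            if a:
                expo[p1] = float(a)
            if b:
                expo[p2] = float(b)
            name = "*".join(
                f"{p}^{int(e)}" if e != 1 else p for p, e in expo.items()
            )
            terms.append(TermSpec(name, expo))
    return terms


def _rebuild_terms(names, result, quadratics):
    p1, p2 = names
    terms = [intercept(), linear(p1), linear(p2)]
    if quadratics:
        terms += [TermSpec(f"{p1}^2", {p1: 2.0}), TermSpec(f"{p2}^2", {p2: 2.0})]
    terms.append(
        TermSpec("interaction", {p1: result.m_hat, p2: result.n_hat})
    )
    return terms
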