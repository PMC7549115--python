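"""Ordinary-least-squares engine and model bookkeeping.

Produces every per-model statistic the interaction analysis reports:
coefficients with standard errors and t-test p-values, residual and total
sums of squares, R^2 and adjusted R^2, AIC under two parameter-counting
conventions, residual degrees of freedom, and the Type I (sequential)
sum-of-squares decomposition per term.

AIC is computed from the Gaussian profile likelihood,

    AIC = n*log(2*pi*rss/n) + n + 2*(p + 1),

with ``p + 1`` counting the residual variance.  Two variants are reported:
``aic_naive`` with p = number of linear coefficients, and ``aic_adjusted``
with p additionally counting the exponents estimated by grid search —
searched exponents consume degrees of freedom just like coefficients do,
and models selected over 302,500 candidate exponent pairs should pay for
it in model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    InputError,
    InsufficientDataError,
    SingularModelError,
)

#: relative singular-value threshold below which a design is called rank deficient
RANK_RTOL = 1e-10


@dataclass
class Dataset:
    """A response vector plus ordered, named, continuous predictor columns.

    Rows with missing values are dropped at construction (``n_dropped``
    records how many), so ``n`` is deterministic for degrees-of-freedom
    accounting.
    """

    y: np.ndarray
    predictors: dict[str, np.ndarray]
    response_name: str = "y"
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.predictors = {
            name: np.asarray(col, dtype=float) for name, col in self.predictors.items()
        }
        n = len(self.y)
        for name, col in self.predictors.items():
            if len(col) != n:
                raise InputError(
                    f"predictor {name!r} has length {len(col)}, expected {n}"
                )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def names(self) -> list[str]:
        return list(self.predictors)

    @classmethod
    def from_frame(cls, frame, response: str, predictors: Sequence[str]) -> "Dataset":
        """Build a Dataset from a DataFrame, dropping rows with missing values."""
        cols = [response, *predictors]
        for c in cols:
            if c not in frame.columns:
                raise InputError(f"column {c!r} not found in input table")
        sub = frame[cols].astype(float)
        kept = sub.dropna()
        return cls(
            y=kept[response].to_numpy(),
            predictors={p: kept[p].to_numpy() for p in predictors},
            response_name=response,
            n_dropped=len(sub) - len(kept),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({self.response_name: self.y, **self.predictors})


@dataclass(frozen=True)
class TermSpec:
    """One model term: a product of predictors raised to real exponents.

    ``exponents`` maps predictor names to exponents; an empty map is the
    intercept.  The design column is the elementwise product of
    ``predictor**exponent`` over the map.
    """

    name: str
    exponents: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "exponents", dict(self.exponents))

    @property
    def is_intercept(self) -> bool:
        return not self.exponents


def intercept() -> TermSpec:
    return TermSpec("intercept", {})


def linear(name: str) -> TermSpec:
    return TermSpec(name, {name: 1.0})


def power_term(name: str, exponents: Mapping[str, float]) -> TermSpec:
    return TermSpec(name, exponents)


@dataclass
class OLSFit:
    """One fitted linear model and all its reported statistics."""

    terms: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    rss: float
    tss: float
    r2: float
    adj_r2: float
    residual_df: int
    n: int
    n_searched_exponents: int
    aic_naive: float
    aic_adjusted: float
    seq_ss: dict[str, float] | None = None

    @property
    def k(self) -> int:
        return len(self.coefficients)

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])


def gaussian_aic(rss: float, n: int, n_params: int) -> float:
    """AIC of a Gaussian linear model with ``n_params`` mean parameters."""
    if rss <= 0.0:
        return -math.inf
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (n_params + 1)


def build_design(
    data: Dataset, terms: Sequence[TermSpec]
) -> tuple[np.ndarray, bool]:
    """Evaluate an ordered list of terms into an n x k design matrix.

    Returns ``(matrix, valid)``; ``valid`` is False when any entry is
    non-finite (e.g. 0 raised to a negative exponent), which the exponent
    search treats as a skippable candidate rather than an error.
    """
    n = data.n
    cols = []
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for t in terms:
            col = np.ones(n)
            for pred, expo in t.exponents.items():
                if pred not in data.predictors:
                    raise InputError(
                        f"term {t.name!r} references unknown predictor {pred!r}"
                    )
                col = col * data.predictors[pred] ** float(expo)
            cols.append(col)
    X = np.column_stack(cols) if cols else np.ones((n, 0))
    return X, bool(np.all(np.isfinite(X)))


def ols_fit(
    design: np.ndarray,
    y: np.ndarray,
    n_searched_exponents: int = 0,
    term_names: Sequence[str] | None = None,
) -> OLSFit:
    """Fit OLS by SVD and compute the full statistic set.

    Coefficient SEs use the unbiased residual-variance estimate; p-values
    are two-sided t tests on ``n - k`` degrees of freedom.

    Raises
    ------
    InsufficientDataError
        If ``n <= k``.
    SingularModelError
        If the design is rank deficient (relative singular value below
        1e-10), naming the collinear terms.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = list(term_names) if term_names is not None else [f"b{j}" for j in range(k)]
    if not np.all(np.isfinite(X)):
        raise DomainError("design matrix contains non-finite entries")
    if n <= k:
        raise InsufficientDataError(f"n = {n} rows cannot identify {k} coefficients")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[0] == 0.0 or s[-1] / s[0] < RANK_RTOL:
        null = Vt[-1]
        involved = [names[j] for j in range(k) if abs(null[j]) > 0.1 * np.max(np.abs(null))]
        raise SingularModelError(
            "design matrix is rank deficient; collinear terms: " + ", ".join(involved)
        )
    beta = Vt.T @ ((U.T @ y) / s)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df = n - k
    sigma2 = rss / df
    xtx_inv_diag = np.einsum("ji,j->i", Vt**2, 1.0 / s**2)
    se = np.sqrt(sigma2 * xtx_inv_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    return OLSFit(
        terms=names,
        coefficients=beta,
        std_errors=se,
        t_stats=t,
        p_values=p,
        rss=rss,
        tss=tss,
        r2=r2,
        adj_r2=adj_r2,
        residual_df=df,
        n=n,
        n_searched_exponents=n_searched_exponents,
        aic_naive=gaussian_aic(rss, n, k),
        aic_adjusted=gaussian_aic(rss, n, k + n_searched_exponents),
    )


def sequential_ss(data: Dataset, terms: Sequence[TermSpec]) -> dict[str, float]:
    """Type I sequential sum of squares in the declared term order.

    SS of term j is the drop in residual SS when term j joins the model
    containing terms 1..j-1.  With an intercept leading the list, the SS
    over non-intercept terms plus the final RSS equals the (centered) TSS.
    """
    terms = list(terms)
    if not terms or not terms[0].is_intercept:
        raise InputError("sequential decomposition requires the intercept first")
    X_full, valid = build_design(data, terms)
    if not valid:
        raise DomainError("model terms evaluate to non-finite values on these data")
    prev_rss = None
    out: dict[str, float] = {}
    for j in range(1, len(terms) + 1):
        fit = ols_fit(X_full[:, :j], data.y, term_names=[t.name for t in terms[:j]])
        if prev_rss is not None:
            out[terms[j - 1].name] = max(prev_rss - fit.rss, 0.0)
        prev_rss = fit.rss
    return out


def fit_model(
    data: Dataset,
    terms: Sequence[TermSpec],
    n_searched_exponents: int = 0,
) -> OLSFit:
    """Build the design for ``terms``, fit OLS, and attach sequential SS."""
    terms = list(terms)
    X, valid = build_design(data, terms)
    if not valid:
        raise DomainError(
            "model terms evaluate to non-finite values on these data; "
            "consider a log1p or standardize01 transform"
        )
    fit = ols_fit(
        X, data.y, n_searched_exponents=n_searched_exponents,
        term_names=[t.name for t in terms],
    )
    fit.seq_ss = sequential_ss(data, terms)
    return fit
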