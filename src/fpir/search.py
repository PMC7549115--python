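"""Two-stage grid search for fractional interaction exponents.

The model is

    Y = b0 + b1*X1 + b2*X2 + b3 * X1^M * X2^N + e          (two-way)

with real exponents (M, N) estimated by exhaustive search: stage 1 scans
all 55 x 55 = 3025 pairs of the initial grid and keeps the pair with the
highest R^2; stage 2 refits the 10 x 10 = 100 pairs of the tuning grids
around that winner.  The overall winner is the highest-R^2 valid candidate
seen in either stage, so the classical product interaction (M = N = 1,
always a stage-1 candidate) can never beat it.

Candidates whose interaction column is non-finite (a zero base under a
negative exponent, overflow) or collinear with the main effects are
skipped and recorded with a reason code, never raised — standardized
predictors routinely contain exact zeros that invalidate negative
exponents.

Scoring uses the projection identity: with Q an orthonormal basis of the
fixed columns (intercept and main effects) and r_y, r_z the residuals of
y and of a candidate column z after projecting out Q,

    RSS(full) = RSS(base) - (r_z . r_y)^2 / (r_z . r_z),

so thousands of candidates are scored with one matrix product.  The
winning model is then refit exactly through the OLS engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import grids
from .errors import DomainError, InputError, NoValidModelError
from .grids import ExponentGrid, make_initial_grid, make_tuning_grid
from .linalg import (
    Dataset,
    OLSFit,
    TermSpec,
    fit_model,
    intercept,
    linear,
)

#: candidate columns whose residual norm falls below this fraction of their
#: own norm are treated as collinear with the base design; the projection
#: gain num^2/den is numerically unstable below this, and under a null
#: interaction such candidates would win on amplified noise alone
COLLINEAR_RTOL = 1e-8


@dataclass
class FPIRResult:
    """Outcome of a fractional-power interaction search."""

    m_hat: float
    n_hat: float
    best_fit: OLSFit
    baseline_fit: OLSFit
    candidate_table: pd.DataFrame
    interaction_share: float
    stage1_winner: tuple
    m_step: float
    n_step: float
    k_hat: float | None = None
    k_step: float | None = None
    model: str = "fpir"
    predictor_names: tuple = ()
    response_name: str = "y"
    grid_values: np.ndarray = field(default_factory=lambda: make_initial_grid().values)

    @property
    def exponents(self) -> tuple:
        if self.k_hat is None:
            return (self.m_hat, self.n_hat)
        return (self.m_hat, self.n_hat, self.k_hat)

    @property
    def r2(self) -> float:
        return self.best_fit.r2

    @property
    def r2_gain(self) -> float:
        """R^2 improvement over the classical product-interaction model."""
        return self.best_fit.r2 - self.baseline_fit.r2


def interaction_column(
    x1: np.ndarray, x2: np.ndarray, m: float, n: float
) -> tuple[np.ndarray, bool]:
    """Elementwise ``x1**m * x2**n`` plus a finite-validity flag."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        col = np.asarray(x1, float) ** m * np.asarray(x2, float) ** n
    return col, bool(np.all(np.isfinite(col)))


class _Scorer:
    """Scores candidate interaction columns against a fixed base design."""

    def __init__(self, base_design: np.ndarray, y: np.ndarray):
        self.q, _ = np.linalg.qr(base_design)
        self.y = y
        self.ry = y - self.q @ (self.q.T @ y)
        self.rss_base = float(self.ry @ self.ry)
        self.tss = float(np.sum((y - y.mean()) ** 2))

    def score(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """R^2, validity and reason code for each column of ``Z``.

        Columns are normalized to unit length before projection — the
        R^2 gain is invariant to column scaling, and normalization keeps
        extreme exponents (columns with norms near the float range) from
        overflowing.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore", under="ignore"):
            znorm = np.einsum("ij,ij->j", Z, Z)
            finite = np.isfinite(znorm) & (znorm > 0)
            scale = np.where(finite, np.sqrt(np.where(znorm > 0, znorm, 1.0)), 1.0)
            Zu = np.where(np.isfinite(Z), Z, 0.0) / scale
            Rz = Zu - self.q @ (self.q.T @ Zu)
            den = np.einsum("ij,ij->j", Rz, Rz)  # in [0, 1]
            num = Rz.T @ self.ry
            valid = finite & (den > COLLINEAR_RTOL**2)
            gain = np.where(valid, num**2 / np.where(den > 0, den, 1.0), 0.0)
        rss = np.maximum(self.rss_base - gain, 0.0)
        r2 = np.where(valid, 1.0 - rss / self.tss, np.nan)
        reasons = [
            "" if v else ("nonfinite" if not f else "collinear")
            for v, f in zip(valid, finite)
        ]
        return r2, valid, reasons


def _ranked_candidates(table: pd.DataFrame, exp_cols: Sequence[str]) -> pd.DataFrame:
    """Valid rows in preference order: highest R^2 first; ties prefer
    exponents nearest all-ones (sum of |e - 1|), then lexicographically
    smallest."""
    ok = table[table["valid"]]
    if ok.empty:
        raise NoValidModelError(
            "every exponent candidate produced a non-finite or collinear model"
        )
    dist = sum((ok[c] - 1.0).abs() for c in exp_cols)
    return ok.assign(_dist=dist).sort_values(
        by=["r2", "_dist", *exp_cols],
        ascending=[False, True, *([True] * len(exp_cols))],
        kind="mergesort",
    )


def _select_best(table: pd.DataFrame, exp_cols: Sequence[str]) -> pd.Series:
    return _ranked_candidates(table, exp_cols).iloc[0]


def _refit_best(table, exp_cols, refit):
    """Refit ranked candidates exactly until one is well-posed.

    The fast projection scorer can accept a candidate that the exact SVD
    rank check rejects (near-collinear or badly scaled interaction
    column); such rows are downgraded to invalid with a reason code and
    the next-best candidate is tried.
    """
    from .errors import SingularModelError

    for idx, row in _ranked_candidates(table, exp_cols).iterrows():
        try:
            exponents = tuple(float(row[c]) for c in exp_cols)
            return exponents, refit(exponents)
        except (SingularModelError, DomainError):
            table.loc[idx, ["valid", "reason"]] = [False, "singular_refit"]
    raise NoValidModelError(
        "every exponent candidate produced a non-finite or collinear model"
    )


def _check_nonnegative(data: Dataset, names: Sequence[str]) -> None:
    for name in names:
        if np.any(data.predictors[name] < 0):
            raise DomainError(
                f"predictor {name!r} has negative values; fractional powers need "
                "non-negative bases — apply a log1p or standardize01 transform first"
            )


def _power_table(x: np.ndarray, exps: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return x[:, None] ** exps[None, :]


def _pair_scores(
    scorer: _Scorer,
    x1: np.ndarray,
    x2: np.ndarray,
    m_values: np.ndarray,
    n_values: np.ndarray,
    stage: str,
) -> pd.DataFrame:
    """Score every (m, n) pair of two exponent grids."""
    P1 = _power_table(x1, m_values)
    P2 = _power_table(x2, n_values)
    n_obs = len(x1)
    with np.errstate(invalid="ignore", over="ignore"):
        Z = (P1[:, :, None] * P2[:, None, :]).reshape(n_obs, -1)
    r2, valid, reasons = scorer.score(Z)
    mm, nn = np.meshgrid(m_values, n_values, indexing="ij")
    return pd.DataFrame(
        {
            "stage": stage,
            "m": mm.ravel(),
            "n": nn.ravel(),
            "r2": r2,
            "valid": valid,
            "reason": reasons,
        }
    )


def fit_fpir_twoway(
    data: Dataset,
    tune: bool = True,
    quadratics: bool = False,
    m_grid: ExponentGrid | None = None,
    n_grid: ExponentGrid | None = None,
) -> FPIRResult:
    """Two-stage exponent search for the two-way interaction model.

    Parameters
    ----------
    data : Dataset
        Exactly two non-negative continuous predictors.
    tune : bool
        Run the stage-2 refinement (10 x 10 models around the stage-1
        winner).  With ``tune=False`` only the initial 55 x 55 scan runs.
    quadratics : bool
        Append squared main effects to every candidate model (the
        "FPIR plus" variant).
    m_grid, n_grid : ExponentGrid, optional
        Replacement stage-1 grids (used for reduced-grid validation);
        stage-2 tuning requires the default grid and is skipped when a
        custom grid is supplied.
    """
    if len(data.predictors) != 2:
        raise InputError(
            f"two-way search needs exactly 2 predictors, got {len(data.predictors)}"
        )
    name1, name2 = data.names
    _check_nonnegative(data, (name1, name2))
    x1, x2 = data.predictors[name1], data.predictors[name2]

    custom = m_grid is not None or n_grid is not None
    initial = make_initial_grid()
    m_values = (m_grid or initial).values
    n_values = (n_grid or initial).values

    base_terms = [intercept(), linear(name1), linear(name2)]
    if quadratics:
        base_terms += [
            TermSpec(f"{name1}^2", {name1: 2.0}),
            TermSpec(f"{name2}^2", {name2: 2.0}),
        ]
    base_X, base_ok = _build_base(data, base_terms)
    scorer = _Scorer(base_X, data.y)

    table = _pair_scores(scorer, x1, x2, m_values, n_values, "initial")
    stage1 = _select_best(table, ("m", "n"))
    stage1_winner = (float(stage1["m"]), float(stage1["n"]))

    if tune and not custom:
        mg = make_tuning_grid(stage1_winner[0], initial)
        ng = make_tuning_grid(stage1_winner[1], initial)
        tuned = _pair_scores(scorer, x1, x2, mg.values, ng.values, "tuned")
        table = pd.concat([table, tuned], ignore_index=True)
        m_step = float(mg.values[1] - mg.values[0])
        n_step = float(ng.values[1] - ng.values[0])
    else:
        m_step = n_step = float("nan")

    def refit(exponents):
        m, n = exponents
        inter = TermSpec(f"{name1}^M*{name2}^N", {name1: m, name2: n})
        return inter, fit_model(data, base_terms + [inter], n_searched_exponents=2)

    (m_hat, n_hat), (inter, best_fit) = _refit_best(table, ("m", "n"), refit)
    baseline_terms = base_terms + [
        TermSpec(f"{name1}*{name2}", {name1: 1.0, name2: 1.0})
    ]
    baseline_fit = fit_model(data, baseline_terms, n_searched_exponents=0)
    share = best_fit.seq_ss[inter.name] / best_fit.tss if best_fit.tss > 0 else 0.0

    return FPIRResult(
        m_hat=m_hat,
        n_hat=n_hat,
        best_fit=best_fit,
        baseline_fit=baseline_fit,
        candidate_table=table,
        interaction_share=float(share),
        stage1_winner=stage1_winner,
        m_step=m_step,
        n_step=n_step,
        model="fpirp" if quadratics else "fpir",
        predictor_names=(name1, name2),
        response_name=data.response_name,
    )


def _build_base(data: Dataset, terms: Sequence[TermSpec]) -> tuple[np.ndarray, bool]:
    from .linalg import build_design

    X, ok = build_design(data, terms)
    if not ok:
        raise DomainError("base model terms evaluate to non-finite values")
    return X, ok


def fit_fpir_threeway(
    data: Dataset, tune: bool = True, coarsen: bool = True
) -> FPIRResult:
    """Two-stage search for a three-way interaction ``X1^M X2^N X3^K``.

    Stage 1 scans a coarsened sub-grid (every other initial value, 28 per
    exponent, keeping +/-1 so the classical product model stays a
    candidate) to bound cost at 28^3 fits; stage 2 tunes all three
    exponents with 10 values each around the winner.  ``coarsen=False``
    scans the full 55^3 grid.
    """
    if len(data.predictors) != 3:
        raise InputError(
            f"three-way search needs exactly 3 predictors, got {len(data.predictors)}"
        )
    names = data.names
    _check_nonnegative(data, names)
    x1, x2, x3 = (data.predictors[p] for p in names)

    initial = make_initial_grid()
    stage1_grid = (
        ExponentGrid(initial.values[::2], stage="initial") if coarsen else initial
    )
    stage1_values = stage1_grid.values

    base_terms = [intercept(), *(linear(p) for p in names)]
    base_X, _ = _build_base(data, base_terms)
    scorer = _Scorer(base_X, data.y)

    def triple_scores(mv, nv, kv, stage):
        P2 = _power_table(x2, nv)
        P3 = _power_table(x3, kv)
        with np.errstate(invalid="ignore", over="ignore"):
            P23 = (P2[:, :, None] * P3[:, None, :]).reshape(len(x1), -1)
        frames = []
        for m in mv:  # chunk over the first exponent to bound memory
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                Z = (x1**m)[:, None] * P23
            r2, valid, reasons = scorer.score(Z)
            nn, kk = np.meshgrid(nv, kv, indexing="ij")
            frames.append(
                pd.DataFrame(
                    {
                        "stage": stage,
                        "m": m,
                        "n": nn.ravel(),
                        "k": kk.ravel(),
                        "r2": r2,
                        "valid": valid,
                        "reason": reasons,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    table = triple_scores(stage1_values, stage1_values, stage1_values, "initial")
    stage1 = _select_best(table, ("m", "n", "k"))
    winner = tuple(float(stage1[c]) for c in ("m", "n", "k"))

    if tune:
        # neighbourhoods come from the grid stage 1 actually scanned, so a
        # coarsened scan gets proportionally wider tuning cells
        tgrids = [make_tuning_grid(w, stage1_grid) for w in winner]
        tuned = triple_scores(*(g.values for g in tgrids), "tuned")
        table = pd.concat([table, tuned], ignore_index=True)
        steps = [float(g.values[1] - g.values[0]) for g in tgrids]
    else:
        steps = [float("nan")] * 3

    def refit(exponents):
        m, n, k = exponents
        inter = TermSpec(
            "three_way_interaction", {names[0]: m, names[1]: n, names[2]: k}
        )
        return inter, fit_model(data, base_terms + [inter], n_searched_exponents=3)

    (m_hat, n_hat, k_hat), (inter, best_fit) = _refit_best(table, ("m", "n", "k"), refit)
    baseline = fit_model(
        data,
        base_terms + [TermSpec("product", {p: 1.0 for p in names})],
        n_searched_exponents=0,
    )
    share = best_fit.seq_ss[inter.name] / best_fit.tss if best_fit.tss > 0 else 0.0

    return FPIRResult(
        m_hat=m_hat,
        n_hat=n_hat,
        k_hat=k_hat,
        best_fit=best_fit,
        baseline_fit=baseline,
        candidate_table=table,
        interaction_share=float(share),
        stage1_winner=winner,
        m_step=steps[0],
        n_step=steps[1],
        k_step=steps[2],
        model="fpir3",
        predictor_names=tuple(names),
        response_name=data.response_name,
    )


def r2_surface(
    data: Dataset,
    m_values: np.ndarray,
    n_values: np.ndarray,
    quadratics: bool = False,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """R^2 of the interaction model over an arbitrary (M, N) grid.

    Returns ``(r2, valid)`` arrays of shape ``(len(m_values),
    len(n_values))``; invalid cells (non-finite or collinear interaction
    column) hold NaN with ``valid`` False.
    """
    if len(data.predictors) != 2:
        raise InputError("r2_surface needs exactly 2 predictors")
    name1, name2 = data.names
    _check_nonnegative(data, (name1, name2))
    x1, x2 = data.predictors[name1], data.predictors[name2]
    m_values = np.asarray(m_values, float)
    n_values = np.asarray(n_values, float)

    base_terms = [intercept(), linear(name1), linear(name2)]
    if quadratics:
        base_terms += [
            TermSpec(f"{name1}^2", {name1: 2.0}),
            TermSpec(f"{name2}^2", {name2: 2.0}),
        ]
    base_X, _ = _build_base(data, base_terms)
    scorer = _Scorer(base_X, data.y)

    out = np.full((len(m_values), len(n_values)), np.nan)
    ok = np.zeros_like(out, dtype=bool)
    P2 = _power_table(x2, n_values)
    for start in range(0, len(m_values), chunk):
        mv = m_values[start : start + chunk]
        P1 = _power_table(x1, mv)
        with np.errstate(invalid="ignore", over="ignore"):
            Z = (P1[:, :, None] * P2[:, None, :]).reshape(len(x1), -1)
        r2, valid, _ = scorer.score(Z)
        out[start : start + chunk] = r2.reshape(len(mv), len(n_values))
        ok[start : start + chunk] = valid.reshape(len(mv), len(n_values))
    return out, ok


def surface_frame(
    data: Dataset, m_values: np.ndarray, n_values: np.ndarray, **kw
) -> pd.DataFrame:
    """Long-format (m, n, r2, valid) table of :func:`r2_surface` for plotting."""
    r2, ok = r2_surface(data, m_values, n_values, **kw)
    mm, nn = np.meshgrid(m_values, n_values, indexing="ij")
    return pd.DataFrame(
        {"m": mm.ravel(), "n": nn.ravel(), "r2": r2.ravel(), "valid": ok.ravel()}
    )


def interaction_slope(
    fit: FPIRResult, x1: np.ndarray, x2: np.ndarray
) -> np.ndarray:
    """Simple slope of E[Y] on X1 along the X2 gradient.

    Under the fitted model the slope is nonlinear in both predictors:

        dE[Y]/dX1 = b1 + b3 * M * x1**(M-1) * x2**N,

    reducing to the classical ``b1 + b3*x2`` at M = N = 1.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    m, n = fit.m_hat, fit.n_hat
    if m < 1.0 and np.any(x1 <= 0):
        raise DomainError("slope with M < 1 requires x1 > 0 everywhere")
    name1 = fit.predictor_names[0]
    b1 = fit.best_fit.coefficient(name1)
    b3 = fit.best_fit.coefficients[-1]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return b1 + b3 * m * x1 ** (m - 1.0) * x2**n
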