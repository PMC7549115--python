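"""Comparator models and side-by-side comparison reports.

Puts the fractional-power interaction fit next to the models it competes
with — the classical product-interaction regression, the full fourth-order
bivariate polynomial, and the quadratic-augmented variant — in one table
of R^2, AIC (both parameter-counting conventions) and degrees of freedom,
plus per-term coefficient/SE/p/sequential-SS detail for the regular and
fractional fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .estimators import polynomial_terms
from .linalg import Dataset, OLSFit, TermSpec, fit_model, intercept, linear
from .search import FPIRResult, fit_fpir_twoway


def fit_regular(data: Dataset) -> OLSFit:
    """Classical interaction regression ``y ~ x1 + x2 + x1:x2``."""
    if len(data.predictors) != 2:
        raise InputError("fit_regular needs exactly 2 predictors")
    p1, p2 = data.names
    terms = [
        intercept(),
        linear(p1),
        linear(p2),
        TermSpec(f"{p1}*{p2}", {p1: 1.0, p2: 1.0}),
    ]
    return fit_model(data, terms)


def fit_polynomial(data: Dataset, order: int = 4) -> OLSFit:
    """Full bivariate polynomial of total degree <= ``order`` (15 terms at 4)."""
    if len(data.predictors) != 2:
        raise InputError("fit_polynomial needs exactly 2 predictors")
    p1, p2 = data.names
    return fit_model(data, polynomial_terms(p1, p2, order))


def fit_fpirp(data: Dataset, tune: bool = True) -> FPIRResult:
    """Fractional-power interaction search with quadratic main effects.

    The exponents are re-searched with the quadratics present in every
    candidate model (the search engine's ``quadratics`` flag), so the
    selected (M, N) describe the interaction conditional on main-effect
    curvature.
    """
    return fit_fpir_twoway(data, tune=tune, quadratics=True)


@dataclass
class ComparisonReport:
    """Model-comparison table plus per-term detail."""

    summary: pd.DataFrame
    term_details: dict[str, pd.DataFrame]
    fits: dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "summary": self.summary.to_dict(orient="records"),
            "term_details": {
                k: v.to_dict(orient="records") for k, v in self.term_details.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    def render_text(self) -> str:
        """Plain-text rendering: one comparison block and per-term blocks."""
        lines = ["Model comparison", "=" * 16, self.summary.to_string(index=False), ""]
        for label, detail in self.term_details.items():
            lines += [label, "-" * len(label), detail.to_string(index=False), ""]
        return "\n".join(lines)


def _term_detail(fit: OLSFit) -> pd.DataFrame:
    rows = []
    for i, term in enumerate(fit.terms):
        rows.append(
            {
                "term": term,
                "coefficient": fit.coefficients[i],
                "se": fit.std_errors[i],
                "t": fit.t_stats[i],
                "p": fit.p_values[i],
                "seq_ss": (fit.seq_ss or {}).get(term, np.nan),
            }
        )
    rows.append(
        {
            "term": "residual",
            "coefficient": np.nan,
            "se": np.nan,
            "t": np.nan,
            "p": np.nan,
            "seq_ss": fit.rss,
        }
    )
    return pd.DataFrame(rows)


def _summary_row(label: str, fit: OLSFit) -> dict:
    return {
        "model": label,
        "r2": fit.r2,
        "adj_r2": fit.adj_r2,
        "aic_naive": fit.aic_naive,
        "aic_adjusted": fit.aic_adjusted,
        "residual_df": fit.residual_df,
        "residual_df_effective": fit.residual_df - fit.n_searched_exponents,
        "n_terms": fit.k,
    }


def compare_models(
    data: Dataset, order: int = 4, tune: bool = True
) -> ComparisonReport:
    """Fit regular, FPIR, FPIRP and polynomial models on the same data.

    Deterministic: the grid search has no randomness, so identical data
    give an identical report.
    """
    regular = fit_regular(data)
    fpir = fit_fpir_twoway(data, tune=tune)
    fpirp = fit_fpirp(data, tune=tune)
    poly = fit_polynomial(data, order=order)

    summary = pd.DataFrame(
        [
            _summary_row("regular", regular),
            _summary_row("fpir", fpir.best_fit),
            _summary_row("fpirp", fpirp.best_fit),
            _summary_row(f"polynomial_{order}", poly),
        ]
    )
    exponents = {
        "regular": (1.0, 1.0),
        "fpir": fpir.exponents,
        "fpirp": fpirp.exponents,
        f"polynomial_{order}": None,
    }
    summary["exponents"] = [
        "" if e is None else "x".join(f"{v:g}" for v in e)
        for e in exponents.values()
    ]
    details = {
        "regular": _term_detail(regular),
        "fpir": _term_detail(fpir.best_fit),
        "fpirp": _term_detail(fpirp.best_fit),
    }
    return ComparisonReport(
        summary=summary,
        term_details=details,
        fits={"regular": regular, "fpir": fpir, "fpirp": fpirp, "polynomial": poly},
    )
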