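"""Data ingestion, variable transforms and run configuration.

Input is a comma-separated, header-first, UTF-8 table with '.' decimals —
no locale inference, for determinism.  Rows with missing values in the
selected columns are dropped with a logged count.  Per-column transforms:

* ``none`` — leave as is
* ``log1p`` — log(x + 1), the usual spread-out transform for skewed
  non-negative field variables
* ``standardize01`` — min-max rescale to [0, 1] using the post-drop rows;
  the (min, max) pair is recorded so new data can be transformed
  identically
* ``both`` — log1p then standardize01

Transform parameters and drop counts land in ``Dataset.meta`` so every
result is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, InputError
from .linalg import Dataset

logger = logging.getLogger("fpir")

TRANSFORMS = ("none", "log1p", "standardize01", "both")


@dataclass
class RunConfig:
    """Configuration of one analysis run (CLI flags mirror these fields)."""

    input: str | None = None
    response: str = "y"
    predictors: Sequence[str] = ("x1", "x2")
    transforms: dict = field(default_factory=dict)  # column -> transform name
    models: Sequence[str] = ("regular", "fpir")
    tune: bool = True
    coarsen: bool = True
    polynomial_order: int = 4
    outdir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.predictors) not in (2, 3):
            raise InputError("predictors must name 2 (two-way) or 3 (three-way) columns")
        for col, tr in self.transforms.items():
            if tr not in TRANSFORMS:
                raise InputError(
                    f"unknown transform {tr!r} for column {col!r}; "
                    f"choose from {TRANSFORMS}"
                )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def log1p_column(x: np.ndarray) -> np.ndarray:
    if np.any(x < -1):
        raise DomainError("log1p transform requires values >= -1")
    return np.log1p(x)


def standardize01_column(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise InputError("standardize01 of a constant column (zero range)")
    return (x - lo) / (hi - lo), (lo, hi)


def apply_transform(x: np.ndarray, name: str) -> tuple[np.ndarray, dict]:
    """Apply one named transform; returns the column and its metadata."""
    if name == "none":
        return x, {"transform": "none"}
    if name == "log1p":
        return log1p_column(x), {"transform": "log1p"}
    if name == "standardize01":
        out, (lo, hi) = standardize01_column(x)
        return out, {"transform": "standardize01", "min": lo, "max": hi}
    if name == "both":
        out = log1p_column(x)
        out, (lo, hi) = standardize01_column(out)
        return out, {"transform": "both", "min": lo, "max": hi}
    raise InputError(f"unknown transform {name!r}")


def load_table(path, config: RunConfig) -> Dataset:
    """Read a CSV, select and coerce columns, drop missing rows, transform.

    Raises
    ------
    InputError
        Missing column (named), non-numeric cell (with row index), or a
        degenerate transform.
    DomainError
        A predictor is negative after transforms (advises log1p or
        standardize01).
    """
    frame = pd.read_csv(path)
    cols = [config.response, *config.predictors]
    for c in cols:
        if c not in frame.columns:
            raise InputError(f"column {c!r} not found in {path}")
    numeric = {}
    for c in cols:
        coerced = pd.to_numeric(frame[c], errors="coerce")
        bad = coerced.isna() & frame[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise InputError(
                f"column {c!r} has a non-numeric value at row {row}: "
                f"{frame[c].iloc[row]!r}"
            )
        numeric[c] = coerced
    sub = pd.DataFrame(numeric)
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    if n_dropped:
        logger.info("dropped %d row(s) with missing values", n_dropped)

    meta = {"transforms": {}, "n_dropped": n_dropped, "source": str(path)}
    columns = {}
    for c in cols:
        tr = config.transforms.get(c, "none")
        columns[c], meta["transforms"][c] = apply_transform(
            kept[c].to_numpy(dtype=float), tr
        )
    for p in config.predictors:
        if np.any(columns[p] < 0):
            raise DomainError(
                f"predictor {p!r} is negative after transforms; apply log1p "
                "and/or standardize01"
            )
    return Dataset(
        y=columns[config.response],
        predictors={p: columns[p] for p in config.predictors},
        response_name=config.response,
        n_dropped=n_dropped,
        meta=meta,
    )
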