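"""Exponent candidate grids for the fractional-power interaction search.

The search estimates the exponents of the interaction term ``X1^M * X2^N``
in two stages.  Stage 1 scans a fixed symmetric grid of 55 values per
exponent spanning [-52.5, 52.5], denser near zero (where most real
exponents live) and containing 0 and +/-1 exactly — +/-1 so the classical
product interaction is always among the candidates, 0 so "no contribution
from this variable" is too.  Stage 2 refines the stage-1 winner with 10
evenly spaced values filling the half-spacing neighbourhood of the winning
grid point.  The half-spacing cells of adjacent grid points tile the line
without overlap, so the 55 x 10 refinement values are all distinct: each
exponent has 550 reachable values in [-56, 56], i.e. 302,500 reachable
exponent pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

#: number of values in the stage-1 grid (per exponent)
N_INITIAL = 55
#: extreme stage-1 candidate
GRID_MAX = 52.5
#: extreme reachable value after stage-2 tuning
REACH = 56.0
#: values per tuning grid
N_TUNED = 10

# Positive half of the stage-1 grid: 13 values (i/13)^2 ending exactly at 1,
# then 14 values 1 + 51.5*(j/14)^p ending exactly at 52.5.  p is chosen in
# closed form so the outermost spacing is exactly 2*(REACH - GRID_MAX) = 7,
# which is what lets the stage-2 half-spacing extension reach exactly +/-56.
_N_INNER = 13
_N_OUTER = 14
_INNER_POWER = 2.0
_EDGE_SPACING = 2.0 * (REACH - GRID_MAX)


@dataclass(frozen=True)
class ExponentGrid:
    """Ordered candidate values for one exponent.

    Attributes
    ----------
    values : ndarray
        Strictly increasing candidate exponents.
    stage : str
        ``"initial"`` (stage-1 scan) or ``"tuned"`` (stage-2 refinement).
    """

    values: np.ndarray
    stage: str = "initial"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, value: float) -> bool:
        return bool(np.any(np.isclose(self.values, value, rtol=0.0, atol=1e-9)))


def _positive_values() -> np.ndarray:
    inner = (np.arange(1, _N_INNER + 1) / _N_INNER) ** _INNER_POWER
    span = GRID_MAX - 1.0
    outer_power = math.log((span - _EDGE_SPACING) / span) / math.log(
        (_N_OUTER - 1) / _N_OUTER
    )
    outer = 1.0 + span * (np.arange(1, _N_OUTER + 1) / _N_OUTER) ** outer_power
    # pin the penultimate value so the edge spacing is exactly 7 in floats
    outer[-2] = GRID_MAX - _EDGE_SPACING
    outer[-1] = GRID_MAX
    return np.concatenate([inner, outer])


def make_initial_grid() -> ExponentGrid:
    """Build the deterministic 55-value stage-1 exponent grid.

    The grid is symmetric about 0, spans [-52.5, 52.5], contains 0 and
    +/-1 exactly, and its spacing is non-decreasing in ``|value|`` (denser
    near zero).
    """
    pos = _positive_values()
    values = np.concatenate([-pos[::-1], [0.0], pos])
    return ExponentGrid(values=values, stage="initial")


def make_tuning_grid(center: float, initial: ExponentGrid | None = None) -> ExponentGrid:
    """Build the 10-value stage-2 grid around a stage-1 winner.

    The grid fills the half-spacing cell of ``center``: the interval from
    the midpoint with the left initial neighbour to the midpoint with the
    right one (edge centers extend outward by half the edge spacing, which
    pushes the overall reach to +/-56).  Cells of positive centers are
    right-closed, of negative centers left-closed, and the cell of 0 is
    open and symmetric, so the cells tile the line and the union over all
    55 centers has exactly 550 distinct values.

    Parameters
    ----------
    center : float
        A member of the initial grid.
    initial : ExponentGrid, optional
        The stage-1 grid; rebuilt if omitted.

    Raises
    ------
    InputError
        If ``center`` is not a member of the initial grid.
    """
    if initial is None:
        initial = make_initial_grid()
    values = initial.values
    matches = np.flatnonzero(np.isclose(values, center, rtol=0.0, atol=1e-9))
    if len(matches) == 0:
        raise InputError(
            f"tuning center {center!r} is not a member of the initial exponent grid"
        )
    i = int(matches[0])
    center = float(values[i])
    left_nb = values[i - 1] if i > 0 else None
    right_nb = values[i + 1] if i < len(values) - 1 else None
    if left_nb is None:
        left = center - (right_nb - center) / 2.0
    else:
        left = (center + left_nb) / 2.0
    if right_nb is None:
        right = center + (center - left_nb) / 2.0
    else:
        right = (center + right_nb) / 2.0
    step = (right - left) / N_TUNED
    if center > 0:
        pts = left + step * (np.arange(N_TUNED) + 1.0)
    elif center < 0:
        pts = left + step * np.arange(N_TUNED)
    else:
        pts = left + step * (np.arange(N_TUNED) + 0.5)
    return ExponentGrid(values=pts, stage="tuned")


def tuning_step(center: float, initial: ExponentGrid | None = None) -> float:
    """Spacing of the stage-2 grid around ``center`` (the "tuned-grid step")."""
    grid = make_tuning_grid(center, initial)
    return float(grid.values[1] - grid.values[0])


def reachable_values(initial: ExponentGrid | None = None) -> np.ndarray:
    """All 550 exponent values reachable through the two-stage search."""
    if initial is None:
        initial = make_initial_grid()
    pts = np.concatenate(
        [make_tuning_grid(c, initial).values for c in initial.values]
    )
    return np.sort(pts)
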