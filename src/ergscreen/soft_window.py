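"""Temporal soft-window weighting of wildtype control mice.

Controls tested near a mutant strain's test dates receive weights near
one; temporally distant controls receive weights near zero. The kernel
is a flat-top symmetric bump built from a product of two logistics,

    g(d) = sigma(k * (1 - d/l)) * sigma(k * (1 + d/l)),   d = |t - c| days
    w(d) = g(d) / g(0)

where ``sigma`` is the standard logistic, ``k`` the dimensionless edge
sharpness and ``l`` the half-bandwidth in days. ``w`` is 1 at the
center, symmetric, non-increasing in distance, and bounded in [0, 1].
With multiple mutant test dates the per-center bumps are aggregated by
pointwise maximum, so well-separated batches produce broad or bimodal
profiles.

Window size and shape are chosen by exhaustive grid search minimizing
the weighted variance of the control values subject to a minimum
effective sample size (sum of weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "WindowShape",
    "ControlWeights",
    "DEFAULT_L_GRID",
    "DEFAULT_K_GRID",
    "weight_function",
    "optimize_window",
]

DEFAULT_L_GRID = (7.0, 14.0, 28.0, 56.0, 112.0, 224.0, 448.0)
DEFAULT_K_GRID = (1.0, 2.0, 5.0, 10.0)


@dataclass(frozen=True)
class WindowShape:
    """Kernel sharpness, bandwidth (days), and mutant-date centers."""

    k: float
    l: float
    centers: tuple[date, ...]

    def __post_init__(self) -> None:
        if self.k <= 0 or self.l <= 0:
            raise ValueError("k and l must be > 0")
        if len(self.centers) == 0:
            raise ValueError("at least one center date is required")


@dataclass
class ControlWeights:
    """Per-control weights in [0, 1] for one strain × parameter analysis."""

    weights: dict[str, float]
    shape: WindowShape | None
    fallback: bool = False
    variance: float = float("nan")

    @property
    def effective_n(self) -> float:
        return float(sum(self.weights.values()))

    def weight_array(self, mouse_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[m] for m in mouse_ids], dtype=float)


def _bump(distance_days: np.ndarray, k: float, l: float) -> np.ndarray:
    d = np.asarray(distance_days, dtype=float)
    g = expit(k * (1.0 - d / l)) * expit(k * (1.0 + d / l))
    g0 = expit(k) * expit(k)
    return g / g0


def weight_function(t: date, shape: WindowShape) -> float:
    """Evaluate the aggregated window weight at date ``t``."""
    d = np.array([abs((t - c).days) for c in shape.centers], dtype=float)
    return float(np.max(_bump(d, shape.k, shape.l)))


def _weights_for(
    control_days: np.ndarray, center_days: np.ndarray, k: float, l: float
) -> np.ndarray:
    # distance of each control to its nearest center
    d = np.min(
        np.abs(control_days[:, None] - center_days[None, :]), axis=1
    )
    return _bump(d, k, l)


def _weighted_variance(values: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    if sw <= 0:
        return float("inf")
    m = float(np.dot(w, values) / sw)
    return float(np.dot(w, (values - m) ** 2) / sw)


def optimize_window(
    control_dates: Sequence[date],
    mutant_dates: Sequence[date],
    values: Sequence[float],
    control_ids: Sequence[str] | None = None,
    l_grid: Sequence[float] = DEFAULT_L_GRID,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    min_effective_n: float = 20.0,
    n_mutant: int | None = None,
) -> ControlWeights:
    """Grid-search the window shape for one strain × parameter analysis.

    Minimizes the weighted variance of the control ``values`` subject to
    an effective control size (sum of weights) of at least
    ``max(min_effective_n, n_mutant)``. Deterministic: the grid is
    scanned in (l, k) order and ties keep the earlier candidate, i.e.
    smaller l then smaller k. If no grid point satisfies the constraint
    the optimizer falls back to all-ones weights (unwindowed ANOVA) with
    a warning.
    """
    control_dates = list(control_dates)
    mutant_dates = list(mutant_dates)
    values = np.asarray(values, dtype=float)
    if len(control_dates) != len(values):
        raise ValueError("control_dates and values must align")
    if len(mutant_dates) == 0:
        raise ValueError("at least one mutant test date is required")
    if control_ids is None:
        control_ids = [str(i) for i in range(len(control_dates))]
    if len(set(control_ids)) != len(list(control_ids)):
        raise ValueError("control_ids must be unique")

    origin = min(control_dates + mutant_dates)
    control_days = np.array([(d - origin).days for d in control_dates], float)
    center_days = np.array(
        sorted({(d - origin).days for d in mutant_dates}), dtype=float
    )
    centers = tuple(sorted(set(mutant_dates)))
    required = max(float(min_effective_n), float(n_mutant or 0))
    required = min(required, float(len(control_dates)))  # cannot exceed pool

    best: tuple[float, WindowShape, np.ndarray] | None = None
    for l in sorted(l_grid):
        for k in sorted(k_grid):
            w = _weights_for(control_days, center_days, k, l)
            if w.sum() < required:
                continue
            var = _weighted_variance(values, w)
            if best is None or var < best[0] - 1e-15:
                best = (var, WindowShape(k=k, l=l, centers=centers), w)

    if best is None:
        warnings.warn(
            "soft-window constraint unsatisfiable on grid; "
            "falling back to all-ones weights (unwindowed ANOVA)",
            stacklevel=2,
        )
        ones = {m: 1.0 for m in control_ids}
        return ControlWeights(
            weights=ones, shape=None, fallback=True,
            variance=_weighted_variance(values, np.ones(len(values))),
        )

    var, shape, w = best
    return ControlWeights(
        weights={m: float(wi) for m, wi in zip(control_ids, w)},
        shape=shape,
        variance=var,
    )
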