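"""Ks-distribution construction, peak finding and event ordering.

The modal peak of each pair class's Ks density acts as a relative timestamp:
classes with smaller primary modes arose more recently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .genome_io import ValidationError

__all__ = [
    "KsDistribution",
    "KsPeak",
    "ks_density",
    "find_peaks",
    "order_events",
]

GRID_STEP = 0.01


@dataclass
class KsDistribution:
    pair_class: str
    values: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_excluded: int  # values above ks_max dropped before estimation

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class KsPeak:
    pair_class: str
    primary_mode: float
    primary_density: float
    secondary_modes: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def ks_density(values, pair_class: str = "", ks_max: float = 3.0,
               bandwidth: str | float = "silverman") -> KsDistribution:
    """Gaussian kernel density of Ks values on a fixed 0..ks_max grid.

    ``bandwidth`` is either ``"silverman"`` or a fixed kernel factor passed
    to the estimator.  Fewer than 10 finite in-range values is an error.
    """
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[np.isfinite(arr)]
    n_excluded = int(np.sum(arr > ks_max))
    arr = np.sort(arr[arr <= ks_max])  # sorted: density independent of input order
    if arr.size < 10:
        raise ValidationError(
            f"insufficient sample for {pair_class or 'class'}: {arr.size} values")
    bw = "silverman" if bandwidth == "silverman" else float(bandwidth)
    kde = scipy.stats.gaussian_kde(arr, bw_method=bw)
    grid = np.arange(0.0, ks_max + GRID_STEP / 2, GRID_STEP)
    density = kde(grid)
    return KsDistribution(pair_class, arr, grid, density,
                          float(kde.factor), n_excluded)


def find_peaks(dist: KsDistribution,
               minor_fraction: float = 0.25) -> KsPeak:
    """Primary mode = grid argmax; secondary modes = other local maxima at
    least ``minor_fraction`` of the primary density.  A flat density yields
    the grid midpoint with a "flat" flag; tied maxima take the leftmost grid
    point and are flagged."""
    d = dist.density
    g = dist.grid
    if np.allclose(d, d[0]):
        mid = float(g[len(g) // 2])
        return KsPeak(dist.pair_class, mid, float(d[0]), [], ["flat"])
    imax = int(np.argmax(d))  # leftmost on ties
    flags = []
    if np.sum(np.isclose(d, d[imax])) > 1:
        flags.append("tied_maximum")
    peak_height = d[imax]
    secondary = []
    for i in range(len(g)):
        left = d[i - 1] if i > 0 else -np.inf
        right = d[i + 1] if i < len(g) - 1 else -np.inf
        if d[i] > left and d[i] >= right and i != imax:
            if d[i] >= minor_fraction * peak_height:
                secondary.append(float(g[i]))
    return KsPeak(dist.pair_class, float(g[imax]), float(peak_height),
                  secondary, flags)


@dataclass
class EventOrdering:
    """Classes ordered most-recent (smallest mode) to most-ancient."""

    order: list[str]
    modes: dict[str, float]
    unresolved: list[tuple[str, str]]

    def describe(self) -> str:
        parts = [f"{c} (Ks mode {self.modes[c]:.2f})" for c in self.order]
        text = " < ".join(parts)
        for a, b in self.unresolved:
            text += f"; {a} ~ {b} unresolved"
        return text


def order_events(peaks: list[KsPeak],
                 grid_step: float = GRID_STEP) -> EventOrdering:
    """Sort pair classes by ascending primary mode; modes within one grid
    step of each other are reported as unresolved."""
    modes = {p.pair_class: p.primary_mode for p in peaks}
    order = sorted(modes, key=lambda c: (modes[c], c))
    unresolved = []
    for a, b in zip(order, order[1:]):
        if abs(modes[a] - modes[b]) <= grid_step + 1e-12:
            unresolved.append((a, b))
    return EventOrdering(order, modes, unresolved)
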