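"""Amplitude cut-off curve and slope break-point detection.

The fraction of coding genes up- vs down-regulated is traced as the
amplitude cut-off is lowered; a continuous two-segment least-squares fit in
the (down%, up%) plane locates the slope break used to set the final
amplitude threshold. The break is a declared operationalization of what the
source analysis judged visually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def default_grid(lo: float = 1.0, hi: float = 4.0, step: float = 0.05) -> np.ndarray:
    """Descending amplitude grid; brackets the 1.5x/1.6x/2x conventions."""
    n = int(round((hi - lo) / step))
    return np.round(hi - step * np.arange(n + 1), 10)


@dataclass
class CutoffCurve:
    """up%/down% of the coding pool at each amplitude cut-off (descending)."""

    points: pd.DataFrame  # columns: cutoff, up_pct, down_pct
    n_coding_reference: int

    def __post_init__(self) -> None:
        required = {"cutoff", "up_pct", "down_pct"}
        if required - set(self.points.columns):
            raise ValueError("curve needs cutoff/up_pct/down_pct columns")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BreakpointResult:
    cutoff_at_break: float | None
    segment_slopes: tuple[float, float]
    rss_single: float
    rss_two_segment: float


def cutoff_curve(
    diff: pd.DataFrame,
    n_coding: int,
    grid=None,
    coding_ids=None,
) -> CutoffCurve:
    """Counts of called coding genes with fc >= c (up) or fc <= 1/c (down).

    Percentages are of ``n_coding``, the full coding-gene pool, not of the
    called set.
    """
    if n_coding <= 0:
        raise ValueError("n_coding must be > 0")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid < 1.0):
        raise ValueError("cut-off grid values must be >= 1")
    if np.any(np.diff(grid) > 0):
        raise ValueError("cut-off grid must be sorted descending")
    called = diff.loc[diff["called"].fillna(False)]
    if coding_ids is not None:
        called = called.loc[called.index.isin(set(coding_ids))]
    fc = called["fc"].to_numpy()
    rows = []
    for c in grid:
        up = int(np.sum(fc >= c))
        down = int(np.sum(fc <= 1.0 / c))
        rows.append((float(c), 100.0 * up / n_coding, 100.0 * down / n_coding))
    points = pd.DataFrame(rows, columns=["cutoff", "up_pct", "down_pct"])
    return CutoffCurve(points=points, n_coding_reference=n_coding)


def _fit_rss(x: np.ndarray, y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def detect_breakpoint(
    curve: CutoffCurve, improvement_min: float = 0.05
) -> BreakpointResult:
    """Continuous two-segment fit of up% on down% with a grid-searched knot.

    The knot is restricted to interior curve points leaving >=3 points per
    segment; a break is reported only when the two-segment fit improves the
    single-line RSS by at least ``improvement_min`` (relative).
    """
    if len(curve) < 6:
        raise ValueError(f"need >=6 curve points, got {len(curve)}")
    x = curve.points["down_pct"].to_numpy(dtype=float)
    y = curve.points["up_pct"].to_numpy(dtype=float)
    n = len(x)
    ones = np.ones(n)
    coef1, rss1 = _fit_rss(x, y, np.column_stack([ones, x]))
    if rss1 <= 1e-12:  # already collinear
        return BreakpointResult(None, (float(coef1[1]), float(coef1[1])), rss1, rss1)
    best = None
    for k in range(2, n - 2):
        design = np.column_stack([ones, x, np.maximum(x - x[k], 0.0)])
        coef, rss2 = _fit_rss(x, y, design)
        if best is None or rss2 < best[1]:
            best = (k, rss2, coef)
    k, rss2, coef = best
    slopes = (float(coef[1]), float(coef[1] + coef[2]))
    if (rss1 - rss2) / rss1 < improvement_min:
        return BreakpointResult(None, slopes, rss1, rss2)
    cutoff = float(curve.points["cutoff"].iloc[k])
    return BreakpointResult(cutoff, slopes, rss1, rss2)


def final_gene_sets(
    diff: pd.DataFrame, amplitude_min: float = 1.6
) -> tuple[set[str], set[str]]:
    """Called genes passing the amplitude threshold, split by direction.

    Boundaries are inclusive: fc == amplitude_min is up, fc == 1/amplitude_min
    is down.
    """
    called = diff.loc[diff["called"].fillna(False)]
    fc = called["fc"]
    up = set(called.index[fc >= amplitude_min])
    down = set(called.index[fc <= 1.0 / amplitude_min])
    return up, down
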