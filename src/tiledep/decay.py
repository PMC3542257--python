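"""Half-life estimation from transcription-arrest decay series.

Intensities after the arrest of transcription initiation decay (to first
order) exponentially; the half-life is obtained from the slope of the
ordinary least-squares fit of ln(intensity) on time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

#: sentinel for decays too shallow to quantify
NOT_MEASURABLE = "not_measurable"


@dataclass
class DecaySeries:
    """Time-stamped intensities for one transcript in one condition."""

    transcript_id: str
    condition: str
    times: np.ndarray  # minutes
    intensities: np.ndarray  # arbitrary units, > 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"{self.transcript_id}: times must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Bound:
    """A one-sided bound on a positive quantity (e.g. half-life '<2 min')."""

    kind: str  # "lower" | "upper"
    value: float | None

    def __post_init__(self) -> None:
        if self.kind not in ("lower", "upper"):
            raise ValueError(f"bound kind must be lower/upper, got {self.kind!r}")

    def __str__(self) -> str:
        if self.value is None:
            return ">" if self.kind == "lower" else "<"
        sym = "≥" if self.kind == "lower" else "≤"
        return f"{sym}{self.value:g}"


@dataclass
class HalfLifeResult:
    """OLS decay fit: slope on the natural-log scale and the derived t1/2."""

    transcript_id: str
    condition: str
    t_half: float | None  # minutes; None == not measurable
    slope: float  # per minute, ln scale
    r_squared: float
    n_points: int

    @property
    def measurable(self) -> bool:
        return self.t_half is not None

    def label(self) -> str:
        return f"{self.t_half:.3g}" if self.measurable else NOT_MEASURABLE


def fit_halflife(
    series: DecaySeries,
    slope_min: float = 1e-4,
    include_t0: bool = True,
) -> HalfLifeResult:
    """Fit ln(intensity) ~ time and convert the slope to a half-life.

    The decay must be genuinely downhill: slopes shallower than
    ``-slope_min`` (per minute) yield the not-measurable sentinel.
    ``include_t0=False`` drops the pre-arrest point at t=0.
    """
    t = series.times
    y = series.intensities
    if not include_t0:
        keep = t > 0
        t, y = t[keep], y[keep]
    if np.any(y <= 0):
        bad = t[y <= 0]
        raise ValueError(
            f"{series.transcript_id}: non-positive intensity at t={bad.tolist()}"
        )
    if len(t) < 3:
        raise ValueError(
            f"{series.transcript_id}: need >=3 points to fit, got {len(t)}"
        )
    fit = stats.linregress(t, np.log(y))
    slope = float(fit.slope)
    r2 = float(fit.rvalue**2)
    t_half = math.log(2.0) / (-slope) if slope < -slope_min else None
    return HalfLifeResult(
        transcript_id=series.transcript_id,
        condition=series.condition,
        t_half=t_half,
        slope=slope,
        r_squared=r2,
        n_points=len(t),
    )


HalfLifeLike = Union[HalfLifeResult, Bound, float, int, None]


def _numeric_halflife(x: HalfLifeLike) -> float | None:
    if isinstance(x, HalfLifeResult):
        return x.t_half
    if isinstance(x, Bound) or x is None:
        return None
    return float(x)


def stabilization_ratio(depleted: HalfLifeLike, induced: HalfLifeLike):
    """Fold-stabilization t1/2(depleted)/t1/2(induced).

    When the induced half-life is only an upper bound (or not measurable)
    the result is a lower-bound :class:`Bound`, never a bare number.
    """
    dep = _numeric_halflife(depleted)
    if dep is None:
        raise ValueError("depleted half-life must be numeric")
    if isinstance(induced, Bound):
        if induced.kind != "upper" or not induced.value:
            raise ValueError("induced bound must be a positive upper bound")
        return Bound("lower", dep / induced.value)
    ind = _numeric_halflife(induced)
    if ind is None:
        # stabilized beyond quantification in the reference condition
        return Bound("lower", None)
    if ind <= 0:
        raise ValueError("induced half-life must be positive")
    return dep / ind


def format_fold(ratio) -> str:
    """Human-readable fold change, e.g. 6.86 -> '≈7-fold'."""
    if isinstance(ratio, Bound):
        if ratio.value is None:
            return "stabilized (fold not quantifiable)"
        return f"≥{ratio.value:.3g}-fold"
    nearest = round(ratio)
    if nearest >= 1 and abs(ratio - nearest) < 0.25:
        return f"≈{nearest:d}-fold"
    return f"{ratio:.2f}-fold"
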