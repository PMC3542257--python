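"""Expression-level dependence of up/down calls and the direct/indirect split.

Kernel densities of reference-condition expression are estimated per
regulation class (up/down/other), scaled by class fractions so that they sum
to the total density; the up-fraction curve peaks where detection of upward
effects is easiest, and the peak up/down fractions give the aggregate
projection of indirect vs direct effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASSES = ("up", "down", "other")


@dataclass
class DensityProfile:
    grid: np.ndarray
    scaled: dict[str, np.ndarray]  # class -> density x class fraction
    fractions: dict[str, float]  # class -> fraction of genes
    bandwidth: float

    @property
    def total(self) -> np.ndarray:
        return np.sum([d for d in self.scaled.values()], axis=0)


@dataclass
class ProjectionResult:
    x_star: float | None
    up_max_pct: float
    down_pct_at_x_star: float
    indirect_share_pct: float
    direct_repertoire_pct: float


def _gauss_kde(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (
        len(values) * bandwidth * np.sqrt(2.0 * np.pi)
    )


def density_profiles(
    reference_expression: pd.Series,
    class_labels: pd.Series,
    bandwidth: float = 0.5,
    grid_size: int = 512,
    min_class_size: int = 10,
) -> DensityProfile:
    """Gaussian-kernel densities per class, scaled by class fraction.

    The kernel standard deviation equals ``bandwidth`` exactly. Classes with
    fewer than ``min_class_size`` genes are merged into "other" with a
    warning. The grid spans the data range +/- 3 bandwidths.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    expr = reference_expression.dropna()
    if expr.empty:
        raise ValueError("no expression values provided")
    labels = class_labels.reindex(expr.index).fillna("other")
    bad = set(labels.unique()) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    for cls in ("up", "down"):
        n = int((labels == cls).sum())
        if 0 < n < min_class_size:
            logger.warning(
                "class %r has only %d gene(s); merged into 'other'", cls, n
            )
            labels = labels.mask(labels == cls, "other")
    lo = float(expr.min()) - 3.0 * bandwidth
    hi = float(expr.max()) + 3.0 * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    n_total = len(expr)
    scaled: dict[str, np.ndarray] = {}
    fractions: dict[str, float] = {}
    for cls in CLASSES:
        vals = expr[labels == cls].to_numpy()
        frac = len(vals) / n_total
        fractions[cls] = frac
        if len(vals):
            scaled[cls] = frac * _gauss_kde(vals, grid, bandwidth)
        else:
            scaled[cls] = np.zeros_like(grid)
    return DensityProfile(
        grid=grid, scaled=scaled, fractions=fractions, bandwidth=bandwidth
    )


def fraction_curves(
    profile: DensityProfile, density_floor: float = 0.01
) -> pd.DataFrame:
    """Per-class fraction of the total density along the expression grid.

    Restricted to grid points where the total density exceeds
    ``density_floor`` times its maximum, preventing blow-up in empty tails.
    Fractions sum to 1 at every retained point.
    """
    total = profile.total
    keep = total > density_floor * total.max()
    out = pd.DataFrame(index=pd.Index(profile.grid[keep], name="x"))
    for cls in CLASSES:
        out[cls] = profile.scaled[cls][keep] / total[keep]
    return out


def up_fraction_peak(profile: DensityProfile) -> tuple[float, float, float]:
    """(x_star, up% at its maximum, down% at the same x)."""
    curves = fraction_curves(profile)
    i = int(np.argmax(curves["up"].to_numpy()))
    x_star = float(curves.index[i])
    return (
        x_star,
        100.0 * float(curves["up"].iloc[i]),
        100.0 * float(curves["down"].iloc[i]),
    )


def direct_indirect_projection(
    up_max_pct: float,
    down_pct_at_same_x: float,
    x_star: float | None = None,
) -> ProjectionResult:
    """Aggregate projection of direct vs indirect up-regulation.

    Under the assumptions that indirect effects cause equal amounts of up-
    and down-regulation and that all downward effects are indirect:
    indirect share = 100 * down/up, direct repertoire = up - down.
    """
    if up_max_pct <= 0:
        raise ValueError("up_max_pct must be > 0")
    if down_pct_at_same_x > up_max_pct:
        raise ValueError("down fraction cannot exceed the up fraction here")
    if down_pct_at_same_x < 0:
        raise ValueError("down fraction must be >= 0")
    indirect = 100.0 * down_pct_at_same_x / up_max_pct
    direct = up_max_pct - down_pct_at_same_x
    result = ProjectionResult(
        x_star=x_star,
        up_max_pct=float(up_max_pct),
        down_pct_at_x_star=float(down_pct_at_same_x),
        indirect_share_pct=float(indirect),
        direct_repertoire_pct=float(direct),
    )
    # algebraic identity: direct + up * indirect/100 == up
    assert abs(
        result.direct_repertoire_pct
        + result.up_max_pct * result.indirect_share_pct / 100.0
        - result.up_max_pct
    ) < 1e-9
    return result


def project_from_profile(profile: DensityProfile) -> ProjectionResult:
    x_star, up_pct, down_pct = up_fraction_peak(profile)
    return direct_indirect_projection(up_pct, down_pct, x_star=x_star)
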