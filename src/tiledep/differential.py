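"""Two-condition differential testing with local-FDR calling.

Per gene: pooled-variance t-test between depleted and induced arrays;
p-values are converted to local false discovery rates with a Grenander
(monotone non-increasing) density estimate, and genes are called at
lfdr <= 0.1 so the least-significant call still has only that probability
of being a false positive.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .model import CONDITION_DEPLETED, CONDITION_INDUCED, ExpressionMatrix

logger = logging.getLogger(__name__)

#: default variance floor added to the pooled variance (handles exact ties)
VAR_FLOOR = 1e-8

DIFF_COLUMNS = [
    "mean_depleted",
    "mean_induced",
    "delta",
    "fc",
    "amplitude",
    "t_stat",
    "p_value",
    "lfdr",
    "called",
    "direction",
]


def fold_change(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene condition means, log2 fold-change and amplitude.

    delta = mean(log2 depleted) - mean(log2 induced); fc = 2**delta;
    amplitude = 2**|delta|. Genes masked in any array get an all-NaN row.
    """
    dep_cols = matrix.columns_for(CONDITION_DEPLETED)
    ind_cols = matrix.columns_for(CONDITION_INDUCED)
    if not dep_cols or not ind_cols:
        raise ValueError("matrix design must contain both conditions")
    complete = ~matrix.data.isna().any(axis=1)
    mean_dep = matrix.data[dep_cols].mean(axis=1).where(complete)
    mean_ind = matrix.data[ind_cols].mean(axis=1).where(complete)
    delta = mean_dep - mean_ind
    out = pd.DataFrame(index=matrix.data.index)
    out["mean_depleted"] = mean_dep
    out["mean_induced"] = mean_ind
    out["delta"] = delta
    out["fc"] = np.power(2.0, delta)
    out["amplitude"] = np.power(2.0, delta.abs())
    out["direction"] = np.where(delta > 0, "up", "down")
    out.loc[delta.isna(), "direction"] = ""
    return out


def t_test_gene(
    values_depleted, values_induced, var_floor: float = VAR_FLOOR
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2, two-sided).

    A variance floor is added to the pooled variance so that exactly tied
    groups yield t = 0, p = 1 instead of 0/0.
    """
    a = np.asarray(values_depleted, dtype=float)
    b = np.asarray(values_induced, dtype=float)
    if len(a) < 2 or len(b) < 2:
        logger.warning("t-test skipped: need >=2 values per group")
        return (float("nan"), float("nan"))
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df + var_floor
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (float(t), float(min(p, 1.0)))


def _t_test_matrix(
    matrix: ExpressionMatrix, var_floor: float = VAR_FLOOR
) -> pd.DataFrame:
    """Vectorized pooled t-test over all genes (NaN rows stay NaN)."""
    dep = matrix.data[matrix.columns_for(CONDITION_DEPLETED)].to_numpy()
    ind = matrix.data[matrix.columns_for(CONDITION_INDUCED)].to_numpy()
    n1, n2 = dep.shape[1], ind.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 arrays per condition for the t-test")
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore"):
        pooled = (
            (n1 - 1) * dep.var(axis=1, ddof=1) + (n2 - 1) * ind.var(axis=1, ddof=1)
        ) / df + var_floor
        t = (dep.mean(axis=1) - ind.mean(axis=1)) / np.sqrt(
            pooled * (1.0 / n1 + 1.0 / n2)
        )
        p = np.minimum(2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return pd.DataFrame({"t_stat": t, "p_value": p}, index=matrix.data.index)


def _grenander_density(p_sorted: np.ndarray):
    """Left slopes of the least concave majorant of the p-value ECDF.

    Returns (knot_x, slopes): on [knot_x[i], knot_x[i+1]) the density is
    slopes[i]; slopes are non-increasing by construction.
    """
    m = len(p_sorted)
    ux = np.unique(np.concatenate([[0.0], p_sorted, [1.0]]))
    uy = np.searchsorted(p_sorted, ux, side="right") / m
    uy[0] = 0.0
    # upper (concave) hull via a monotone chain
    hull: list[tuple[float, float]] = []
    for x, y in zip(ux, uy):
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1) >= 0:
                hull.pop()
            else:
                break
        hull.append((x, y))
    hx = np.array([h[0] for h in hull])
    hy = np.array([h[1] for h in hull])
    slopes = np.diff(hy) / np.diff(hx)
    return hx, slopes


def estimate_lfdr(
    p_values, lambda_: float = 0.5, min_size: int = 100
) -> tuple[np.ndarray, float]:
    """Local FDR per p-value and the null-proportion estimate eta0.

    eta0 = min(1, #{p > lambda} / ((1 - lambda) m)); the p-value density is
    the Grenander estimator (left slope of the least concave majorant of the
    ECDF) and lfdr(p) = min(1, eta0 / f(p)), non-decreasing in p. With fewer
    than ``min_size`` p-values a warning is raised and all lfdrs are 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m < min_size:
        warnings.warn(
            f"only {m} p-values (< {min_size}); lfdr estimation skipped, "
            "returning all-1",
            stacklevel=2,
        )
        return np.ones(m), 1.0
    eta0 = min(1.0, float(np.mean(p > lambda_)) / (1.0 - lambda_))
    p_sorted = np.sort(p)
    hx, slopes = _grenander_density(p_sorted)
    seg = np.clip(np.searchsorted(hx, p, side="right") - 1, 0, len(slopes) - 1)
    f_hat = slopes[seg]
    with np.errstate(divide="ignore"):
        lfdr = np.minimum(1.0, eta0 / f_hat)
    lfdr[f_hat <= 0] = 1.0
    return lfdr, eta0


def call_differential(diff: pd.DataFrame, lfdr_max: float = 0.1) -> pd.DataFrame:
    """Mark genes with lfdr <= lfdr_max (inclusive boundary) as called."""
    if "lfdr" not in diff.columns:
        raise ValueError("lfdr column missing; run estimate_lfdr first")
    out = diff.copy()
    out["called"] = out["lfdr"].le(lfdr_max).fillna(False)
    return out


def average_fdr(diff: pd.DataFrame) -> float:
    """Mean lfdr over called genes: the expected false-positive fraction."""
    called = diff.loc[diff["called"].fillna(False), "lfdr"]
    if called.empty:
        raise ValueError("average FDR undefined: no called genes")
    return float(called.mean())


def differential_table(
    matrix: ExpressionMatrix,
    lfdr_max: float = 0.1,
    var_floor: float = VAR_FLOOR,
    lambda_: float = 0.5,
) -> pd.DataFrame:
    """Full per-gene table: fold-change, t, p, lfdr and the call flag."""
    table = fold_change(matrix)
    tests = _t_test_matrix(matrix, var_floor=var_floor)
    table = table.join(tests)
    table["lfdr"] = np.nan
    valid = table["p_value"].notna()
    if valid.any():
        lfdr, eta0 = estimate_lfdr(table.loc[valid, "p_value"].to_numpy(), lambda_)
        table.loc[valid, "lfdr"] = lfdr
        logger.info("lfdr estimated on %d genes (eta0=%.3f)", int(valid.sum()), eta0)
    table = call_differential(table, lfdr_max=lfdr_max)
    return table[DIFF_COLUMNS]
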