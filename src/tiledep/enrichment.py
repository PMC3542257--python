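"""Functional-category over/under-representation of the up-regulated set.

Per category: the fraction of member genes in the up-set, compared with the
whole-genome reference fraction by an exact two-sided hypergeometric test
with Benjamini-Hochberg correction across categories.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def category_fractions(
    up_set,
    category_map: dict[str, set],
    n_coding_reference: int,
    n_up_reference: int | None = None,
) -> pd.DataFrame:
    """Per-category up counts and percentages (one decimal).

    ``category_map`` maps category name -> member gene ids; a gene may
    belong to several categories. Empty categories are dropped with a
    warning. The whole-genome reference percentage is attached as
    ``df.attrs["reference_pct_up"]``.
    """
    if n_coding_reference <= 0:
        raise ValueError("n_coding_reference must be > 0")
    up = set(up_set)
    if n_up_reference is None:
        n_up_reference = len(up)
    rows = []
    for name, genes in category_map.items():
        genes = set(genes)
        if not genes:
            logger.warning("category %r has no genes; dropped", name)
            continue
        n_up = len(up & genes)
        rows.append((name, len(genes), n_up, round(100.0 * n_up / len(genes), 1)))
    table = pd.DataFrame(rows, columns=["category", "n_genes", "n_up", "pct_up"])
    table.attrs["n_coding_reference"] = int(n_coding_reference)
    table.attrs["n_up_reference"] = int(n_up_reference)
    table.attrs["reference_pct_up"] = round(
        100.0 * n_up_reference / n_coding_reference, 1
    )
    return table


def category_test(
    n_cat: int, k_cat: int, N: int, K: int
) -> tuple[float, str]:
    """Exact two-sided hypergeometric test of one category.

    X ~ Hypergeom(N population, K up-regulated, n_cat drawn);
    p = min(1, 2 * min(P(X <= k), P(X >= k))). The returned flag is the raw
    direction (over/under/none) relative to the genome fraction K/N; the
    final flag is assigned only after multiple-testing correction.
    """
    if not (0 <= k_cat <= min(n_cat, K)) or n_cat > N or K > N:
        raise ValueError(
            f"impossible counts: k={k_cat}, n={n_cat}, K={K}, N={N}"
        )
    dist = stats.hypergeom(N, K, n_cat)
    lower = dist.cdf(k_cat)
    upper = dist.sf(k_cat - 1)
    p = float(min(1.0, 2.0 * min(lower, upper)))
    expected = n_cat * K / N
    if k_cat > expected:
        flag = "over"
    elif k_cat < expected:
        flag = "under"
    else:
        flag = "none"
    return p, flag


def flag_categories(
    table: pd.DataFrame,
    n_coding_reference: int,
    n_up_reference: int,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Add p/q values and the over/under flag after BH correction."""
    out = table.copy()
    out.attrs = dict(table.attrs)
    results = [
        category_test(int(r.n_genes), int(r.n_up), n_coding_reference, n_up_reference)
        for r in out.itertuples()
    ]
    out["p_value"] = [p for p, _ in results]
    raw_flags = [f for _, f in results]
    out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    out["flag"] = [
        f if q <= q_max and f != "none" else "none"
        for f, q in zip(raw_flags, out["q_value"])
    ]
    return out


def enrich(
    up_set,
    category_map: dict[str, set],
    n_coding_reference: int,
    n_up_reference: int | None = None,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Full category table: counts, percentages, exact tests and flags."""
    table = category_fractions(
        up_set, category_map, n_coding_reference, n_up_reference
    )
    return flag_categories(
        table,
        table.attrs["n_coding_reference"],
        table.attrs["n_up_reference"],
        q_max=q_max,
    )
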