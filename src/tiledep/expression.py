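"""Probe-to-gene aggregation and least-variant-set (LVS) normalization.

Gene-level expression is the median of same-strand probe values inside the
gene interval. Between-array normalization anchors on the genes whose
within-array expression rank is most stable across arrays, and removes a
per-array affine distortion estimated on those genes only — leaving a
genuine imbalance between up- and down-effects untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, GenomeAnnotation, ProbeSignalSet, assign_probes

logger = logging.getLogger(__name__)


def aggregate_gene_level(
    signals: ProbeSignalSet, annotation: GenomeAnnotation
) -> ExpressionMatrix:
    """Median of same-strand probe values per gene and array.

    Genes spanning no probes are masked (NaN) and logged, never zero-filled.
    An even probe count yields the mean of the two middle values.
    """
    probe_chroms = set(signals.layout.probes["chrom"].unique())
    missing = sorted(annotation.chroms() - probe_chroms)
    if missing:
        raise ValueError(
            f"annotation chromosomes absent from probe data: {missing}"
        )
    probe_feature = assign_probes(signals.layout, annotation)
    values = signals.values
    keep = probe_feature.to_numpy() != ""
    grouped = values.loc[keep].groupby(probe_feature[keep]).median()
    data = grouped.reindex(annotation.ids)
    data.index.name = "id"
    n_masked = int(data.isna().any(axis=1).sum())
    if n_masked:
        logger.warning(
            "%d feature(s) span no probes and were masked: %s",
            n_masked,
            [i for i in data.index[data.isna().any(axis=1)]][:10],
        )
    return ExpressionMatrix(data=data, arrays=list(signals.arrays))


@dataclass
class LvsSelection:
    """Genes with the smallest across-array rank variance."""

    gene_ids: set[str]
    fraction: float
    variance_statistic: pd.Series  # per complete gene, across-array rank variance


def select_least_variant_set(
    matrix: ExpressionMatrix, fraction: float = 0.4
) -> LvsSelection:
    """Pick the ``fraction`` of complete genes with the most stable ranks.

    Per gene: rank its expression within each array, then take the variance
    of that rank across arrays. Ties are broken by gene id, so the selection
    is deterministic.
    """
    if len(matrix.arrays) < 2:
        raise ValueError("need >=2 arrays to select a least-variant set")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    complete = matrix.complete_genes()
    if complete.empty:
        raise ValueError("all genes are masked; nothing to select")
    ranks = complete.rank(axis=0, method="average")
    rank_var = ranks.var(axis=1, ddof=1)
    n_sel = int(np.floor(fraction * len(complete) + 0.5))
    order = rank_var.sort_index().sort_values(kind="mergesort")
    selected = set(order.index[:n_sel])
    return LvsSelection(
        gene_ids=selected, fraction=fraction, variance_statistic=rank_var
    )


def normalize_lvs(
    matrix: ExpressionMatrix,
    lvs: LvsSelection,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> ExpressionMatrix:
    """Remove per-array affine distortions estimated on the LVS genes.

    The baseline is the across-array mean of each LVS gene. Each array is
    regressed on the baseline (over LVS genes only) and the inverse affine
    map applied to all of its genes, so afterwards the regression of LVS
    genes on the baseline has slope 1 and intercept 0. The correction is
    iterated against the recomputed baseline until it is the identity to
    within ``tol``, which makes the operation idempotent.
    """
    genes = sorted(g for g in lvs.gene_ids if g in matrix.data.index)
    sub = matrix.data.loc[genes].dropna(axis=0, how="any")
    if len(sub) < 3:
        raise ValueError(
            f"affine fit under-determined: need >=3 complete LVS genes, got {len(sub)}"
        )
    data = matrix.data.copy()
    lvs_idx = sub.index
    for _ in range(max_iter):
        anchor = data.loc[lvs_idx]
        baseline = anchor.mean(axis=1).to_numpy()
        b_center = baseline - baseline.mean()
        denom = float(b_center @ b_center)
        if denom <= 0:
            raise ValueError("LVS baseline is constant; affine fit degenerate")
        worst = 0.0
        fits = []
        for col in data.columns:
            obs = anchor[col].to_numpy()
            slope = float(b_center @ (obs - obs.mean())) / denom
            if abs(slope) < 1e-8:
                raise ValueError(f"array {col!r}: degenerate affine fit (slope ~ 0)")
            intercept = float(obs.mean() - slope * baseline.mean())
            fits.append((col, slope, intercept))
            worst = max(worst, abs(slope - 1.0), abs(intercept))
        if worst < tol:
            break
        for col, slope, intercept in fits:
            data[col] = (data[col] - intercept) / slope
    else:
        logger.warning("LVS normalization did not converge to tol=%g", tol)
    return ExpressionMatrix(data=data, arrays=list(matrix.arrays))
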