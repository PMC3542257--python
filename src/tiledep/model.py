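"""Core data model shared across the pipeline.

Coordinates are 0-based, half-open throughout. Probe/feature matching is
strand-aware: a probe belongs to a feature only when chromosome, strand and
position (``start <= pos < end``) all agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: condition labels of the two-condition depletion design
CONDITION_DEPLETED = "depleted"
CONDITION_INDUCED = "induced"
CONDITIONS = (CONDITION_DEPLETED, CONDITION_INDUCED)

FEATURE_KINDS = ("coding", "ncRNA")


@dataclass(frozen=True)
class Feature:
    """A strand-aware genomic interval with a class and category labels."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "coding"
    categories: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"feature {self.id!r}: unknown strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.id!r}: unknown kind {self.kind!r}")
        object.__setattr__(self, "categories", frozenset(self.categories))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Gene/segment intervals; the denominator for every percentage we report."""

    features: list[Feature]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate feature ids: {sorted(dups)}")
        for f in self.features:
            limit = self.chrom_lengths.get(f.chrom)
            if limit is not None and f.end > limit:
                raise ValueError(
                    f"feature {f.id!r} ends at {f.end}, beyond {f.chrom} "
                    f"length {limit}"
                )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_coding(self) -> int:
        return sum(1 for f in self.features if f.kind == "coding")

    @property
    def ids(self) -> list[str]:
        return [f.id for f in self.features]

    def coding_ids(self) -> set[str]:
        return {f.id for f in self.features if f.kind == "coding"}

    def chroms(self) -> set[str]:
        return {f.chrom for f in self.features}

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [f.id for f in self.features],
                "chrom": [f.chrom for f in self.features],
                "start": [f.start for f in self.features],
                "end": [f.end for f in self.features],
                "strand": [f.strand for f in self.features],
                "kind": [f.kind for f in self.features],
                "categories": [";".join(sorted(f.categories)) for f in self.features],
            }
        )

    def category_map(self) -> dict[str, set[str]]:
        """Mapping category -> set of member feature ids."""
        out: dict[str, set[str]] = {}
        for f in self.features:
            for c in f.categories:
                out.setdefault(c, set()).add(f.id)
        return out


@dataclass(frozen=True)
class ArrayInfo:
    """One hybridization: identifier, condition and biological replicate."""

    array_id: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"array {self.array_id!r}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )


def validate_design(arrays: Iterable[ArrayInfo]) -> list[ArrayInfo]:
    arrays = list(arrays)
    if not arrays:
        raise ValueError("empty array design")
    ids = [a.array_id for a in arrays]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate array ids in design")
    return arrays


@dataclass
class ProbeLayout:
    """Regularly spaced probes on both strands.

    ``probes`` has columns probe_id, chrom, position, strand; within one
    strand of one chromosome consecutive positions differ by ``resolution``.
    """

    probes: pd.DataFrame
    resolution: int

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "position", "strand"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"probe table lacks columns: {sorted(missing)}")

    def validate_spacing(self) -> None:
        for (_, _), grp in self.probes.groupby(["chrom", "strand"]):
            pos = np.sort(grp["position"].to_numpy())
            if len(pos) > 1 and not np.all(np.diff(pos) == self.resolution):
                raise ValueError("probe spacing violates the layout resolution")

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class ProbeSignalSet:
    """Probe x array log2 intensities plus the planted per-gene truth."""

    layout: ProbeLayout
    arrays: list[ArrayInfo]
    values: pd.DataFrame  # index probe_id, one column per array_id
    truth: pd.Series | None = None  # planted log2 effect per feature id

    def __post_init__(self) -> None:
        self.arrays = validate_design(self.arrays)
        expected = [a.array_id for a in self.arrays]
        if list(self.values.columns) != expected:
            raise ValueError("signal columns do not match the array design")


@dataclass
class ExpressionMatrix:
    """Gene x array log2 expression; NaN marks genes with no probes."""

    data: pd.DataFrame  # index gene id, one column per array_id
    arrays: list[ArrayInfo]

    def __post_init__(self) -> None:
        self.arrays = validate_design(self.arrays)
        expected = [a.array_id for a in self.arrays]
        if list(self.data.columns) != expected:
            raise ValueError("matrix columns do not match the array design")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def columns_for(self, condition: str) -> list[str]:
        return [a.array_id for a in self.arrays if a.condition == condition]

    def complete_genes(self) -> pd.DataFrame:
        """Rows with a value in every array."""
        return self.data.dropna(axis=0, how="any")

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), list(self.arrays))


def assign_probes(layout: ProbeLayout, annotation: GenomeAnnotation) -> pd.Series:
    """Map each probe to the same-strand feature containing it, if any.

    Returns a Series indexed like ``layout.probes`` rows (probe_id) whose
    values are feature ids, or "" for intergenic probes. Same-strand features
    are assumed non-overlapping, so the assignment is unique.
    """
    probes = layout.probes
    result = np.full(len(probes), "", dtype=object)
    by_key: dict[tuple[str, str], list[Feature]] = {}
    for f in annotation.features:
        by_key.setdefault((f.chrom, f.strand), []).append(f)
    for key, feats in by_key.items():
        feats.sort(key=lambda f: f.start)
        starts = np.array([f.start for f in feats])
        ends = np.array([f.end for f in feats])
        fids = np.array([f.id for f in feats], dtype=object)
        mask = (probes["chrom"] == key[0]) & (probes["strand"] == key[1])
        pos = probes.loc[mask, "position"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        assigned = np.where(ok, fids[np.clip(idx, 0, len(fids) - 1)], "")
        result[np.flatnonzero(mask.to_numpy())] = assigned
    return pd.Series(result, index=probes["probe_id"].to_numpy(), name="feature_id")
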