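"""Direction-aware comparison of differential gene lists across studies."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

logger = logging.getLogger(__name__)


def _normalize(genes) -> set[str]:
    return {str(g).lower() for g in genes}


@dataclass
class StudyGeneSet:
    """Up/down gene sets of one study; ids are case-folded on construction."""

    study_id: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for attr in ("up", "down"):
            raw = list(getattr(self, attr))
            norm = _normalize(raw)
            if len(norm) < len(raw):
                logger.warning(
                    "study %s: %d duplicate gene id(s) in %s set deduplicated",
                    self.study_id,
                    len(raw) - len(norm),
                    attr,
                )
            setattr(self, attr, norm)
        if self.up & self.down:
            raise ValueError(
                f"study {self.study_id}: genes in both up and down sets: "
                f"{sorted(self.up & self.down)[:5]}"
            )


@dataclass
class VennCounts:
    """Exclusive region counts keyed by the frozenset of member studies."""

    regions: dict[frozenset, int]
    union: int

    def exclusive(self, *study_ids: str) -> int:
        return self.regions.get(frozenset(study_ids), 0)

    def common_to_all(self, study_ids) -> int:
        return self.regions.get(frozenset(study_ids), 0)


def venn_counts(sets: list[StudyGeneSet], direction: str = "up") -> VennCounts:
    """Exclusive Venn region counts for 2 or 3 direction-specific sets.

    The counts partition the union (asserted on every call).
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_counts handles 2 or 3 study sets")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    members = {s.study_id: getattr(s, direction) for s in sets}
    if len(members) != len(sets):
        raise ValueError("duplicate study ids")
    ids = list(members)
    union = set().union(*members.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            inside = set.intersection(*(members[i] for i in combo))
            outside = set().union(
                *(members[i] for i in ids if i not in combo), set()
            )
            regions[frozenset(combo)] = len(inside - outside)
    total = sum(regions.values())
    assert total == len(union), "venn regions must partition the union"
    return VennCounts(regions=regions, union=len(union))


def overlap_fraction(common: int, union: int) -> float:
    """Percentage of the union shared by all studies, to one decimal.

    Reported with the source convention of truncating (not rounding) the
    second decimal, computed in exact integer arithmetic.
    """
    if union <= 0:
        raise ValueError("union must be > 0")
    if not (0 <= common <= union):
        raise ValueError("need 0 <= common <= union")
    return (1000 * common // union) / 10.0


def sets_from_diff_table(
    study_id: str,
    diff: pd.DataFrame,
    amplitude_min: float = 1.5,
    require_called: bool = True,
) -> StudyGeneSet:
    """Direction-specific sets at a shared amplitude cut-off.

    The significance filter applies only when the table carries call flags
    (some studies published none).
    """
    if "fc" not in diff.columns:
        raise ValueError(f"study {study_id}: fold-change column 'fc' missing")
    table = diff
    if require_called and "called" in diff.columns:
        table = diff.loc[diff["called"].fillna(False)]
    fc = table["fc"]
    up = set(table.index[fc >= amplitude_min])
    down = set(table.index[fc <= 1.0 / amplitude_min])
    return StudyGeneSet(study_id=study_id, up=up, down=down)


def uniform_cutoff_comparison(
    diff_tables: dict[str, pd.DataFrame],
    amplitude_min: float = 1.5,
    require_called: bool = True,
) -> tuple[dict[str, StudyGeneSet], dict[str, VennCounts]]:
    """Re-derive every study's sets at one amplitude and recount all regions."""
    gene_sets = {
        sid: sets_from_diff_table(sid, tbl, amplitude_min, require_called)
        for sid, tbl in diff_tables.items()
    }
    sets_list = list(gene_sets.values())
    venns = {d: venn_counts(sets_list, direction=d) for d in ("up", "down")}
    return gene_sets, venns
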