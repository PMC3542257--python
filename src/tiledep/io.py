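"""Readers and writers for the exchanged plain-text formats.

Everything is TSV with "NA" for missing values; readers accept comma
decimal separators (as printed in some source tables), writers always emit
period decimals. Annotation is exchanged as BED6 (native 0-based half-open
coordinates) with a TSV sidecar for kind/categories, or as a GFF3 subset
(1-based inclusive, converted on read).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecaySeries
from .model import (
    ArrayInfo,
    ExpressionMatrix,
    Feature,
    GenomeAnnotation,
    ProbeLayout,
    ProbeSignalSet,
)

logger = logging.getLogger(__name__)

NA = "NA"
FLOAT_FMT = "%.10g"


def _parse_number(text: str) -> float:
    """Float parsing that tolerates comma decimal separators."""
    if isinstance(text, str):
        text = text.strip().replace(",", ".")
    return float(text)


# ---------------------------------------------------------------- annotation

def write_annotation(
    annotation: GenomeAnnotation, bed_path, sidecar_path=None
) -> None:
    """BED6 plus a sidecar TSV carrying kind, categories and chrom lengths."""
    bed_path = Path(bed_path)
    with bed_path.open("w") as fh:
        for f in annotation.features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n"
            )
    if sidecar_path is not None:
        with Path(sidecar_path).open("w") as fh:
            for chrom, length in sorted(annotation.chrom_lengths.items()):
                fh.write(f"#chrom_length\t{chrom}\t{length}\n")
            fh.write("id\tkind\tcategories\n")
            for f in annotation.features:
                cats = ";".join(sorted(f.categories))
                fh.write(f"{f.id}\t{f.kind}\t{cats}\n")


def _read_sidecar(path):
    chrom_lengths: dict[str, int] = {}
    meta: dict[str, tuple[str, frozenset]] = {}
    lines = Path(path).read_text().splitlines()
    body = []
    for line in lines:
        if line.startswith("#chrom_length\t"):
            _, chrom, length = line.split("\t")
            chrom_lengths[chrom] = int(length)
        elif line.strip():
            body.append(line)
    for line in body[1:]:  # skip header
        fields = line.split("\t")
        fid, kind = fields[0], fields[1]
        cats = fields[2] if len(fields) > 2 else ""
        meta[fid] = (kind, frozenset(c for c in cats.split(";") if c))
    return chrom_lengths, meta


def read_annotation(path, fmt: str = "bed6", sidecar_path=None) -> GenomeAnnotation:
    """Read BED6 or a GFF3 subset into the internal 0-based convention."""
    if fmt == "bed6":
        return _read_bed6(path, sidecar_path)
    if fmt == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_bed6(path, sidecar_path=None) -> GenomeAnnotation:
    chrom_lengths: dict[str, int] = {}
    meta: dict[str, tuple[str, frozenset]] = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        chrom_lengths, meta = _read_sidecar(sidecar_path)
    features = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
        chrom, start, end, name, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        kind, cats = meta.get(name, ("coding", frozenset()))
        try:
            features.append(
                Feature(name, chrom, int(start), int(end), strand, kind, cats)
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return GenomeAnnotation(features=features, chrom_lengths=chrom_lengths)


def _read_gff3(path) -> GenomeAnnotation:
    """Minimal GFF3 subset: seqid/type/start/end/strand and an ID attribute.

    1-based inclusive coordinates are converted to 0-based half-open. Types
    naming non-coding RNAs map to kind "ncRNA", everything else to "coding".
    """
    features = []
    chrom_lengths: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                chrom_lengths[parts[1]] = int(parts[3])
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        fid = attr_map.get("ID") or attr_map.get("Name")
        if not fid:
            raise ValueError(f"{path}:{lineno}: missing ID attribute")
        kind = "ncRNA" if "rna" in ftype.lower() and ftype.lower() != "mrna" else "coding"
        try:
            features.append(
                Feature(fid, chrom, int(start) - 1, int(end), strand, kind)
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return GenomeAnnotation(features=features, chrom_lengths=chrom_lengths)


# --------------------------------------------------------------------- design

def write_design(arrays: list[ArrayInfo], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("array_id\tcondition\treplicate\n")
        for a in arrays:
            fh.write(f"{a.array_id}\t{a.condition}\t{a.replicate}\n")


def read_design(path) -> list[ArrayInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"array_id": str})
    return [
        ArrayInfo(str(r.array_id), str(r.condition), int(r.replicate))
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------- probes

def write_probe_table(signals: ProbeSignalSet, path) -> None:
    """chrom, position, strand plus one intensity column per array."""
    probes = signals.layout.probes
    out = probes[["chrom", "position", "strand"]].copy()
    out.index = probes["probe_id"].to_numpy()
    out = out.join(signals.values)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=NA)


def read_probe_table(
    path,
    design: list[ArrayInfo],
    resolution: int,
    linear: bool = False,
    pseudo_intensity: float = 1.0,
) -> ProbeSignalSet:
    """Probe TSV back into a ProbeSignalSet (no truth).

    With ``linear=True`` intensities are log2-transformed with a floor at
    ``pseudo_intensity``; otherwise they are taken as already log2.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    array_ids = [a.array_id for a in design]
    missing = [c for c in array_ids if c not in df.columns]
    if missing:
        raise ValueError(f"probe table lacks array columns: {missing}")
    probes = df[["chrom", "position", "strand"]].copy()
    probes.insert(
        0,
        "probe_id",
        [
            f"{c}:{s}:{p}"
            for c, s, p in zip(df["chrom"], df["strand"], df["position"])
        ],
    )
    values = df[array_ids].copy()
    values.index = probes["probe_id"].to_numpy()
    if linear:
        values = np.log2(values.clip(lower=pseudo_intensity))
    layout = ProbeLayout(probes=probes, resolution=resolution)
    return ProbeSignalSet(layout=layout, arrays=list(design), values=values)


# --------------------------------------------------------------------- matrix

def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(
        path, sep="\t", float_format=FLOAT_FMT, na_rep=NA, index_label="id"
    )


def read_matrix(path, design: list[ArrayInfo]) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=[NA])
    data = df[[a.array_id for a in design]].astype(float)
    return ExpressionMatrix(data=data, arrays=design)


# ---------------------------------------------------------------- diff table

def write_diff_table(diff: pd.DataFrame, path) -> None:
    diff.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep=NA, index_label="id")


def read_diff_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=[NA])
    if "called" in df.columns:
        df["called"] = df["called"].astype(bool)
    return df


# ------------------------------------------------------------------- studies

def read_study_gene_list(path, study_id: str | None = None):
    """Per-study TSV with a gene column plus direction and/or fold-change."""
    df = pd.read_csv(
        path, sep="\t", na_values=[NA], converters={"fc": _parse_number}
    )
    if "gene" not in df.columns:
        raise ValueError(f"{path}: study list needs a 'gene' column")
    df = df.set_index("gene")
    return df


def write_truth(truth: pd.Series, path) -> None:
    truth.rename("log2_effect").to_csv(
        path, sep="\t", float_format=FLOAT_FMT, index_label="id"
    )


def read_truth(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return df["log2_effect"]


# ----------------------------------------------------------------- categories

def read_category_table(path) -> dict[str, set[str]]:
    """TSV of gene_id, category (hierarchical path with ' * ' separators)."""
    out: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if lineno == 1 and line.lower().startswith(("gene", "id")):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: need gene_id and category columns")
        out.setdefault(fields[1].strip(), set()).add(fields[0].strip())
    return out


def write_category_table(category_map: dict[str, set[str]], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tcategory\n")
        for cat in sorted(category_map):
            for gene in sorted(category_map[cat]):
                fh.write(f"{gene}\t{cat}\n")


# ---------------------------------------------------------------------- decay

def read_decay_table(path) -> list[DecaySeries]:
    """TSV of transcript, condition, time_min, intensity (comma decimals ok)."""
    df = pd.read_csv(
        path,
        sep="\t",
        converters={"time_min": _parse_number, "intensity": _parse_number},
    )
    required = {"transcript", "condition", "time_min", "intensity"}
    if required - set(df.columns):
        raise ValueError(f"{path}: decay table needs columns {sorted(required)}")
    series = []
    for (tx, cond), grp in df.groupby(["transcript", "condition"], sort=True):
        grp = grp.sort_values("time_min")
        series.append(
            DecaySeries(
                transcript_id=str(tx),
                condition=str(cond),
                times=grp["time_min"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
            )
        )
    return series


def write_decay_table(series: list[DecaySeries], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("transcript\tcondition\ttime_min\tintensity\n")
        for s in series:
            for t, i in zip(s.times, s.intensities):
                fh.write(f"{s.transcript_id}\t{s.condition}\t{t:.10g}\t{i:.10g}\n")


def write_halflife_table(results, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("transcript\tcondition\tt_half_min\tslope\tr_squared\tn_points\n")
        for r in results:
            t_half = f"{r.t_half:.10g}" if r.measurable else NA
            fh.write(
                f"{r.transcript_id}\t{r.condition}\t{t_half}\t"
                f"{r.slope:.10g}\t{r.r_squared:.10g}\t{r.n_points}\n"
            )
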