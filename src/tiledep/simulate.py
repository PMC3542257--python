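"""Synthetic tiling-array data with known ground truth.

Generates annotations, probe layouts, probe-level intensities under a
two-condition depletion design and decay time-series. Every generator is
deterministic for a fixed seed; each stage draws from its own child stream
so adding a stage does not perturb the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .decay import DecaySeries
from .model import (
    ArrayInfo,
    CONDITION_DEPLETED,
    Feature,
    GenomeAnnotation,
    ProbeLayout,
    ProbeSignalSet,
    assign_probes,
    validate_design,
)

logger = logging.getLogger(__name__)

# stage tags for independent child RNG streams
_STAGE_ANNOTATION = 1
_STAGE_EXPRESSION = 2
_STAGE_DECAY = 3


def _stage_rng(seed: int, stage: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage, sub]))


@dataclass
class EffectConfig:
    """Knobs of the planted-effect intensity model.

    Noise magnitudes are free parameters of the simulator, not estimates of
    any real array platform. Saturation is a hard clip at
    ``saturation_ceiling`` (log2): intensities above it are truncated, so a
    planted increase on an already-bright gene becomes partly undetectable.
    """

    frac_direct_up: float = 0.0
    frac_indirect_down: float = 0.0
    up_log2_mean: float = 1.5
    up_log2_sd: float = 0.5
    down_log2_mean: float = -1.0
    down_log2_sd: float = 0.4
    noise_sd_probe_affinity: float = 0.0
    noise_sd_replicate: float = 0.0
    saturation_ceiling: float = 16.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    background_mean: float = 4.0
    # per-array affine distortions (what LVS normalization must remove)
    array_slope_sd: float = 0.0
    array_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_direct_up <= 1.0):
            raise ValueError("frac_direct_up must lie in [0, 1]")
        if not (0.0 <= self.frac_indirect_down <= 1.0):
            raise ValueError("frac_indirect_down must lie in [0, 1]")
        if self.frac_direct_up + self.frac_indirect_down > 1.0:
            raise ValueError("effect fractions must sum to <= 1")
        for name in (
            "up_log2_sd",
            "down_log2_sd",
            "noise_sd_probe_affinity",
            "noise_sd_replicate",
            "array_slope_sd",
            "array_offset_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_annotation(
    n_coding: int,
    n_ncrna: int,
    genome_length: int,
    category_scheme: dict[str, float] | None = None,
    seed: int = 0,
    chrom: str = "chr1",
    length_range: tuple[int, int] = (300, 1500),
) -> GenomeAnnotation:
    """Place non-overlapping same-strand features on a single chromosome.

    Feature lengths are uniform over ``length_range``; strands are random;
    categories are drawn per ``category_scheme`` shares (shares may sum to
    less than 1, the remainder staying uncategorized). Raises when the drawn
    features cannot be packed into ``genome_length`` on a strand.
    """
    if n_coding < 0 or n_ncrna < 0 or genome_length <= 0:
        raise ValueError("counts must be >= 0 and genome_length > 0")
    n = n_coding + n_ncrna
    rng = _stage_rng(seed, _STAGE_ANNOTATION)
    if n == 0:
        return GenomeAnnotation(features=[], chrom_lengths={chrom: genome_length})

    kinds = np.array(["coding"] * n_coding + ["ncRNA"] * n_ncrna, dtype=object)
    rng.shuffle(kinds)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=n)

    placed: list[tuple[int, int, str, str]] = []  # start, end, strand, kind
    for strand in ("+", "-"):
        sel = np.flatnonzero(strands == strand)
        total = int(lengths[sel].sum())
        if total > genome_length:
            raise ValueError(
                f"infeasible packing: {len(sel)} features totalling {total} bp "
                f"exceed genome_length={genome_length} on strand {strand!r}"
            )
        free = genome_length - total
        gaps = rng.multinomial(free, np.full(len(sel) + 1, 1.0 / (len(sel) + 1)))
        cursor = 0
        for i, fi in enumerate(sel):
            cursor += int(gaps[i])
            start = cursor
            end = start + int(lengths[fi])
            placed.append((start, end, strand, str(kinds[fi])))
            cursor = end

    placed.sort(key=lambda t: (t[0], t[2]))
    cat_names: list[str] = []
    cat_probs: np.ndarray | None = None
    if category_scheme:
        cat_names = list(category_scheme)
        shares = np.array([category_scheme[c] for c in cat_names], dtype=float)
        if np.any(shares < 0) or shares.sum() > 1.0 + 1e-9:
            raise ValueError("category shares must be >= 0 and sum to <= 1")
        cat_probs = np.append(shares, max(0.0, 1.0 - shares.sum()))

    features: list[Feature] = []
    n_c = n_s = 0
    for start, end, strand, kind in placed:
        if kind == "coding":
            n_c += 1
            fid = f"g{n_c:04d}"
        else:
            n_s += 1
            fid = f"s{n_s:04d}"
        cats: frozenset = frozenset()
        if kind == "coding" and cat_probs is not None:
            pick = rng.choice(len(cat_names) + 1, p=cat_probs)
            if pick < len(cat_names):
                cats = frozenset({cat_names[pick]})
        features.append(
            Feature(fid, chrom, start, end, strand, kind=kind, categories=cats)
        )
    ann = GenomeAnnotation(features=features, chrom_lengths={chrom: genome_length})
    assert ann.n_coding == n_coding
    return ann


def generate_probe_layout(
    annotation: GenomeAnnotation, resolution: int = 22
) -> ProbeLayout:
    """Tile both strands of every chromosome at fixed ``resolution``."""
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    rows = []
    for chrom in sorted(annotation.chrom_lengths):
        length = annotation.chrom_lengths[chrom]
        positions = np.arange(0, length, resolution, dtype=int)
        for strand in ("+", "-"):
            for pos in positions:
                rows.append((f"{chrom}:{strand}:{pos}", chrom, int(pos), strand))
    probes = pd.DataFrame(rows, columns=["probe_id", "chrom", "position", "strand"])
    layout = ProbeLayout(probes=probes, resolution=resolution)
    layout.validate_spacing()
    return layout


def default_design(replicates: int = 2) -> list[ArrayInfo]:
    """Duplicate-culture depletion design: -inducer vs +inducer."""
    arrays = []
    for rep in range(1, replicates + 1):
        arrays.append(ArrayInfo(f"dep_{rep}", CONDITION_DEPLETED, rep))
    for rep in range(1, replicates + 1):
        arrays.append(ArrayInfo(f"ind_{rep}", "induced", rep))
    return arrays


def simulate_expression(
    annotation: GenomeAnnotation,
    layout: ProbeLayout,
    design: list[ArrayInfo],
    effects: EffectConfig,
) -> ProbeSignalSet:
    """Probe intensities under the planted-effect model.

    probe value = gene baseline + probe affinity + effect * 1[depleted]
    + replicate noise, optionally passed through a per-array affine
    distortion, then clipped at the saturation ceiling. Direct-up genes get
    positive log2 effects, indirect-down genes negative ones; the planted
    effect of every feature is recorded in ``truth``.
    """
    design = validate_design(design)
    conditions = {a.condition for a in design}
    if conditions != {"depleted", "induced"}:
        raise ValueError("design needs >=1 array in each of the two conditions")

    n_feat = len(annotation)
    fids = annotation.ids
    seed = effects.seed
    rng_base = _stage_rng(seed, _STAGE_EXPRESSION, 0)
    rng_assign = _stage_rng(seed, _STAGE_EXPRESSION, 1)
    rng_affinity = _stage_rng(seed, _STAGE_EXPRESSION, 2)
    rng_noise = _stage_rng(seed, _STAGE_EXPRESSION, 3)
    rng_distort = _stage_rng(seed, _STAGE_EXPRESSION, 4)

    baseline = rng_base.normal(effects.baseline_mean, effects.baseline_sd, n_feat)

    planted = np.zeros(n_feat)
    n_up = int(np.floor(effects.frac_direct_up * n_feat + 0.5))
    n_down = int(np.floor(effects.frac_indirect_down * n_feat + 0.5))
    chosen = rng_assign.choice(n_feat, size=n_up + n_down, replace=False) if n_feat else []
    up_idx = np.asarray(chosen[:n_up], dtype=int)
    down_idx = np.asarray(chosen[n_up:], dtype=int)
    planted[up_idx] = np.abs(
        rng_assign.normal(effects.up_log2_mean, effects.up_log2_sd, n_up)
    )
    planted[down_idx] = -np.abs(
        rng_assign.normal(-effects.down_log2_mean, effects.down_log2_sd, n_down)
    )

    probe_feature = assign_probes(layout, annotation)
    fid_index = {fid: i for i, fid in enumerate(fids)}
    feat_of_probe = np.array(
        [fid_index.get(f, -1) for f in probe_feature.to_numpy()], dtype=int
    )
    in_gene = feat_of_probe >= 0
    n_probes = len(layout)

    probe_mu = np.full(n_probes, effects.background_mean)
    probe_mu[in_gene] = baseline[feat_of_probe[in_gene]]
    probe_effect = np.zeros(n_probes)
    probe_effect[in_gene] = planted[feat_of_probe[in_gene]]
    affinity = rng_affinity.normal(0.0, effects.noise_sd_probe_affinity, n_probes)

    columns = {}
    for a in design:
        v = probe_mu + affinity
        if a.condition == CONDITION_DEPLETED:
            v = v + probe_effect
        v = v + rng_noise.normal(0.0, effects.noise_sd_replicate, n_probes)
        slope = 1.0 + rng_distort.normal(0.0, effects.array_slope_sd)
        offset = rng_distort.normal(0.0, effects.array_offset_sd)
        v = slope * v + offset
        columns[a.array_id] = np.minimum(v, effects.saturation_ceiling)

    values = pd.DataFrame(columns, index=layout.probes["probe_id"].to_numpy())
    truth = pd.Series(planted, index=pd.Index(fids, name="id"), name="log2_effect")
    logger.info(
        "simulated %d probes x %d arrays (%d up, %d down planted)",
        n_probes,
        len(design),
        n_up,
        n_down,
    )
    return ProbeSignalSet(layout=layout, arrays=design, values=values, truth=truth)


#: sentinel accepted by simulate_decay for non-decaying transcripts
STABLE = "stable"


def simulate_decay(
    half_life,
    times,
    i0: float = 100.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    transcript_id: str = "tx",
    condition: str = CONDITION_DEPLETED,
) -> DecaySeries:
    """Exponential decay series with multiplicative log-normal noise.

    E[I(t)] = i0 * 2^(-t / half_life); the sentinel ``"stable"`` gives a
    constant expectation. ``noise_cv`` is the coefficient of variation of the
    multiplicative noise, whose mean is exactly 1.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if half_life == STABLE:
        expected = np.full_like(times, float(i0))
    else:
        hl = float(half_life)
        if hl <= 0:
            raise ValueError("half_life must be > 0 (or the 'stable' sentinel)")
        expected = i0 * np.power(2.0, -times / hl)
    if noise_cv > 0:
        rng = _stage_rng(seed, _STAGE_DECAY)
        sigma2 = np.log1p(noise_cv**2)
        noise = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), len(times)))
        expected = expected * noise
    return DecaySeries(
        transcript_id=transcript_id,
        condition=condition,
        times=times,
        intensities=expected,
    )
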