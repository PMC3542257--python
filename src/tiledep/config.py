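"""Pipeline configuration: one YAML file, defaults matching the published
thresholds (lfdr 0.1, amplitude 1.6x, kernel bandwidth 0.5, uniform
comparison cut-off 1.5x)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import EffectConfig


@dataclass
class SimulationConfig:
    n_coding: int = 300
    n_ncrna: int = 30
    genome_length: int = 450_000
    resolution: int = 22
    replicates: int = 2
    category_scheme: dict = field(default_factory=dict)
    effects: EffectConfig = field(default_factory=EffectConfig)


@dataclass
class PipelineConfig:
    seed: int = 0
    lvs_fraction: float = 0.4
    lfdr_max: float = 0.1
    amplitude_min: float | str = 1.6  # number or "auto" (break-point detection)
    grid: str = "1.0:4.0:0.05"
    bandwidth: float = 0.5
    bh_q: float = 0.05
    slope_min: float = 1e-4
    uniform_cutoff: float = 1.5
    var_floor: float = 1e-8
    # input paths; unset entries are skipped or simulated
    probes: str | None = None
    annotation: str | None = None
    annotation_sidecar: str | None = None
    design: str | None = None
    categories: str | None = None
    simulation: SimulationConfig | None = None

    def grid_values(self):
        lo, hi, step = (float(x) for x in self.grid.split(":"))
        from .threshold import default_grid

        return default_grid(lo, hi, step)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            effects = EffectConfig(**sim.pop("effects", {}))
            cfg.simulation = SimulationConfig(effects=effects, **sim)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Planted-effect demonstration: an excess of up-effects above the knee,
    indirect down-effects, probe/replicate noise, affine array distortions
    and saturation clipping."""
    effects = EffectConfig(
        frac_direct_up=0.20,
        frac_indirect_down=0.06,
        up_log2_mean=1.6,
        up_log2_sd=0.6,
        down_log2_mean=-1.0,
        down_log2_sd=0.4,
        noise_sd_probe_affinity=0.25,
        noise_sd_replicate=0.10,
        saturation_ceiling=16.0,
        baseline_mean=10.0,
        baseline_sd=1.5,
        array_slope_sd=0.02,
        array_offset_sd=0.10,
        seed=seed,
    )
    sim = SimulationConfig(
        n_coding=300,
        n_ncrna=30,
        genome_length=450_000,
        resolution=22,
        replicates=2,
        category_scheme={
            "prophage": 0.05,
            "iron": 0.05,
            "translation": 0.10,
            "stress": 0.10,
        },
        effects=effects,
    )
    return PipelineConfig(seed=seed, simulation=sim)
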