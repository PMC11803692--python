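"""Serializable pipeline configuration.

Every run writes its effective configuration next to its outputs, so any
result directory is self-describing and re-runnable. All randomness flows
from the single root seed through named per-stage substreams.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as eio

__all__ = ["PipelineConfig", "stage_rng"]

# fixed substream labels: changing one stage's parameters leaves the draws
# of the other stages untouched
STAGE_NAMES = ("cohort", "wave", "echo", "dwi", "histo")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run"

    # cohort / phantom
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"treatment_control": 2, "radiotherapy": 2, "sham": 2}
    )
    grid_shape: tuple[int, int, int] = (64, 64, 9)
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 0.3)

    # acquisition
    frequency_hz: float = 900.0
    target_phase_rad: float = 3.5  # peak encoded phase; > pi so wrapping occurs
    phase_noise_sd_rad: float = 0.0
    compressional_amplitude_frac: float = 0.0  # relative to shear amplitude
    echo_s0: float = 1000.0
    echo_noise_sd: float = 10.0
    dwi_s0: float = 1000.0
    dwi_noise_sd: float = 0.0
    bvalue: float = 1500.0

    # reconstruction / fitting
    density_kg_m3: float = 1000.0
    smooth_sigma_vox: float = 0.0
    combine: str = "least_squares"
    t2_threshold_multiplier: float = 4.0
    t2_filter_mode: str = "sample"

    # statistics
    alpha: float = 0.05  # significance level of the reported comparisons
    welch: bool = False

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        if stage not in STAGE_NAMES:
            raise KeyError(f"unknown stage '{stage}'")
        return np.random.SeedSequence(self.seed, spawn_key=(STAGE_NAMES.index(stage),))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing_mm"] = list(self.spacing_mm)
        eio.save_yaml(path, d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = eio.load_yaml(path) or {}
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "spacing_mm" in d:
            d["spacing_mm"] = tuple(d["spacing_mm"])
        return cls(**d)


def stage_rng(config: PipelineConfig, stage: str, key: int = 0) -> np.random.Generator:
    """Generator for one stage (and optionally one item within the stage)."""
    ss = config.stage_seed(stage)
    return np.random.default_rng(np.random.SeedSequence(
        ss.entropy, spawn_key=ss.spawn_key + (key,)
    ))
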