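"""Pipeline configuration.

A single document of the constants the analysis depends on; the
defaults reproduce the standard study conditions (768 px canvas,
1-cycle annular bins, 25% first-harmonic threshold, preferred
numerosities restricted to 1.05-6.95, 0.2 deg eccentricity bins, 1000
bootstrap resamples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    canvas_px: int = 768
    px_per_degree: float = 350.0 / 0.75
    contrast_mode: str = "binary_mask"
    psd_definition: str = "magnitude"
    f1_psd_fraction: float = 0.25
    hrf_peak_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    mu_grid_size: int = 60
    sigma_grid_size: int = 40
    mu_range: tuple[float, float] = (1.05, 6.95)
    ecc_bin_width_deg: float = 0.2
    n_bootstrap: int = 1000
    seed: int = 0
    n_voxels: int = 500
    out_dir: str = "results"
    # simulation sizes (kept modest so a full run takes minutes)
    numerosity_repeats: int = 5
    configuration_repeats: int = 3
    contrast_displays: int = 80

    def validate(self) -> None:
        if self.canvas_px % 2 or self.canvas_px < 32:
            raise ValueError("canvas_px must be even and >= 32")
        if not (0 < self.f1_psd_fraction < 1):
            raise ValueError("f1_psd_fraction must be in (0, 1)")
        if self.mu_range[0] >= self.mu_range[1]:
            raise ValueError("mu_range must be increasing")


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "mu_range" in data:
        data["mu_range"] = tuple(data["mu_range"])
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["mu_range"] = list(d["mu_range"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
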