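"""Synthetic voxel populations with known ground truth.

Generates per-voxel BOLD cycles with the same structure as the averaged
numerosity-experiment data (44 TRs per cycle, split-half replicates,
eccentricity labels): each voxel responds monotonically (increasing or
decreasing) or with logarithmic-Gaussian tuning, the response is
HRF-convolved, and white Gaussian noise (optionally AR(1)) is added.
Cohorts impose an eccentricity profile on achievable model fits by
scaling each voxel's noise so that the expected variance explained
follows a generating curve -- sigmoid declines for early visual maps,
flat or quadratic profiles for association maps.  Everything is
reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .response_models import (
    CYCLE_LEN,
    StimulusSequence,
    VoxelTimeSeries,
    default_design_labels,
    hrf_kernel,
    predicted_timecourse,
    tuned_amplitudes,
)

__all__ = [
    "SyntheticVoxelSpec",
    "SyntheticCohort",
    "simulate_voxel",
    "simulate_cohort",
    "sigmoid_profile",
    "quadratic_profile",
    "cohort_to_frame",
]

ModelKind = Literal["monotonic_increasing", "monotonic_decreasing", "tuned"]

ECC_MAX_DEG = 5.5


@dataclass
class SyntheticVoxelSpec:
    model_kind: ModelKind
    beta: float = 1.0
    baseline: float = 0.0
    mu: float | None = None
    sigma: float | None = None
    amplitude: float = 1.0
    eccentricity_deg: float = 0.0
    map_label: str = "V1"
    hemisphere: str = "L"
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.model_kind == "tuned" and (self.mu is None or self.sigma is None):
            raise ValueError("tuned voxels need mu and sigma")


@dataclass
class SyntheticCohort:
    voxels: list[SyntheticVoxelSpec]
    profile_by_map: dict[str, Callable[[np.ndarray], np.ndarray]] = field(
        default_factory=dict)


def _neural_amplitudes(spec: SyntheticVoxelSpec, labels: np.ndarray) -> np.ndarray:
    x = np.asarray(labels, dtype=float)
    if spec.model_kind == "tuned":
        return spec.amplitude * tuned_amplitudes(x, spec.mu, spec.sigma)
    amp = spec.beta * np.log(x)
    if spec.model_kind == "monotonic_decreasing":
        amp = -amp
    return amp


def noiseless_prediction(spec: SyntheticVoxelSpec,
                         labels: np.ndarray | None = None,
                         hrf: np.ndarray | None = None) -> np.ndarray:
    if labels is None:
        labels = default_design_labels()
    amp = _neural_amplitudes(spec, labels)
    return spec.baseline + predicted_timecourse(amp, hrf)


def simulate_voxel(spec: SyntheticVoxelSpec,
                   labels: np.ndarray | None = None,
                   rng: np.random.Generator | None = None,
                   n_cycles: int = 1,
                   ar1_phi: float = 0.0) -> VoxelTimeSeries:
    """One synthetic BOLD cycle (or several concatenated cycles):
    model prediction plus additive noise with the spec's SD."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pred = noiseless_prediction(spec, labels)
    bold = np.tile(pred, n_cycles)
    if spec.noise_sd > 0:
        eps = rng.standard_normal(bold.size)
        if ar1_phi:
            for i in range(1, eps.size):
                eps[i] = ar1_phi * eps[i - 1] + math.sqrt(1 - ar1_phi**2) * eps[i]
        bold = bold + spec.noise_sd * eps
    return VoxelTimeSeries(bold, spec.eccentricity_deg, spec.map_label,
                           spec.hemisphere)


# ----------------------------------------------------------------------
# eccentricity profiles
# ----------------------------------------------------------------------

def sigmoid_profile(inflection_deg: float = 1.5, slope_deg: float = 0.5,
                    ve_max: float = 0.6, ve_min: float = 0.0
                    ) -> Callable[[np.ndarray], np.ndarray]:
    """Cumulative-Gaussian decline of variance explained with
    eccentricity (early-visual pattern: best fits at fixation)."""
    from scipy.stats import norm

    def profile(ecc: np.ndarray) -> np.ndarray:
        ecc = np.asarray(ecc, dtype=float)
        return ve_min + (ve_max - ve_min) * (
            1.0 - norm.cdf((ecc - inflection_deg) / slope_deg))

    return profile


def quadratic_profile(intercept: float = 0.3, slope: float = 0.0,
                      quad: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """Quadratic (possibly flat) profile: association-map pattern with
    no necessary eccentricity dependence."""

    def profile(ecc: np.ndarray) -> np.ndarray:
        ecc = np.asarray(ecc, dtype=float)
        return np.clip(intercept + slope * ecc + quad * ecc**2, 0.0, 1.0)

    return profile


def _noise_sd_for_ve(signal: np.ndarray, target_ve: float) -> float:
    """Noise SD making the expected variance explained equal the
    target: VE = var(signal) / (var(signal) + noise_var)."""
    sig_var = float(np.var(signal))
    ve = float(np.clip(target_ve, 1e-3, 1 - 1e-6))
    return math.sqrt(sig_var * (1.0 - ve) / ve)


def simulate_cohort(n_voxels: int,
                    profiles: dict[str, Callable[[np.ndarray], np.ndarray]] | None = None,
                    rng: np.random.Generator | None = None,
                    model_kind: ModelKind = "monotonic_increasing",
                    mu_range: tuple[float, float] = (1.5, 6.0),
                    sigma_range: tuple[float, float] = (0.1, 1.0),
                    ) -> tuple[SyntheticCohort, pd.DataFrame]:
    """A cohort of synthetic voxels with split-half replicate cycles.

    Eccentricities are uniform on [0, 5.5] deg; each voxel's noise SD is
    set so its expected VE follows the map's generating profile.  The
    returned table holds one voxel per row: metadata columns followed by
    the 44 odd-half and 44 even-half BOLD samples.
    """
    if n_voxels < 1:
        raise ValueError("need at least one voxel")
    if rng is None:
        rng = np.random.default_rng()
    if profiles is None:
        profiles = {"V1": sigmoid_profile()}
    labels = default_design_labels()
    hrf = hrf_kernel()
    voxels: list[SyntheticVoxelSpec] = []
    rows = []
    maps = sorted(profiles)
    for vid in range(n_voxels):
        map_label = maps[vid % len(maps)]
        ecc = float(rng.uniform(0.0, ECC_MAX_DEG))
        if model_kind == "tuned":
            spec = SyntheticVoxelSpec(
                "tuned",
                mu=float(rng.uniform(*mu_range)),
                sigma=float(rng.uniform(*sigma_range)),
                amplitude=1.0,
                eccentricity_deg=ecc, map_label=map_label,
                hemisphere="L" if vid % 2 == 0 else "R")
        else:
            spec = SyntheticVoxelSpec(
                model_kind, beta=1.0, eccentricity_deg=ecc,
                map_label=map_label,
                hemisphere="L" if vid % 2 == 0 else "R")
        signal = noiseless_prediction(spec, labels, hrf)
        target = float(profiles[map_label](np.array([ecc]))[0])
        spec.noise_sd = _noise_sd_for_ve(signal, target)
        voxels.append(spec)
        odd = signal + spec.noise_sd * rng.standard_normal(CYCLE_LEN)
        even = signal + spec.noise_sd * rng.standard_normal(CYCLE_LEN)
        rows.append({
            "voxel_id": vid, "map_label": map_label,
            "hemisphere": spec.hemisphere, "eccentricity_deg": ecc,
            "model_kind": model_kind, "noise_sd": spec.noise_sd,
            "target_ve": target,
            **{f"odd_{t}": odd[t] for t in range(CYCLE_LEN)},
            **{f"even_{t}": even[t] for t in range(CYCLE_LEN)},
        })
    return SyntheticCohort(voxels, dict(profiles)), pd.DataFrame(rows)


def cohort_to_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Ground-truth parameter table of a cohort (one row per voxel)."""
    rows = []
    for vid, v in enumerate(cohort.voxels):
        rows.append({
            "voxel_id": vid, "model_kind": v.model_kind, "beta": v.beta,
            "mu": v.mu, "sigma": v.sigma, "noise_sd": v.noise_sd,
            "eccentricity_deg": v.eccentricity_deg, "map_label": v.map_label,
            "hemisphere": v.hemisphere,
        })
    return pd.DataFrame(rows)
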