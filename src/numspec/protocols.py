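"""Simulation protocols: how aggregate Fourier power behaves under
numerosity, size, spacing, shape, contrast, and connectedness
manipulations.

Each function generates the displays of one manipulation, runs the
spectral statistic, and returns a tidy table or summary dict.  These are
the building blocks the analysis scripts and the acceptance checks
drive; display geometry follows the generator defaults in
:mod:`numspec.stimuli`.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import stimuli
from .spectral import (
    aggregate_power,
    compute_radial_psd,
    detect_first_harmonic,
    normalize_image,
    orientation_resolved_power,
    second_harmonic_power,
)
from .stimuli import (
    Configuration,
    DisplaySpec,
    PairConnection,
    make_configuration_display,
    make_dot_pair_display,
    make_generalization_series,
    make_seven_circle_group,
    render,
)

__all__ = [
    "power_of_displays",
    "power_vs_numerosity",
    "fit_power_law",
    "single_circle_size_series",
    "seven_circle_spacing_series",
    "shape_series",
    "configuration_power_table",
    "mixed_black_white_contrast",
    "contrast_range_experiment",
    "connectedness_experiment",
    "GROUP_AREA_RANGE_PX",
]

#: group-area diameter range for the seven-circle displays (px); at the
#: lower end all seven items touch
GROUP_AREA_RANGE_PX = (50.0, 528.0)


def power_of_displays(specs: Sequence[DisplaySpec],
                      contrast_mode: str = "binary_mask") -> np.ndarray:
    return np.array([aggregate_power(render(s), contrast_mode).normalized
                     for s in specs])


# ----------------------------------------------------------------------
# numerosity series and the power law
# ----------------------------------------------------------------------

def power_vs_numerosity(numerosities: Sequence[int] | None = None,
                        n_repeats: int = 10,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Mean aggregate power of fixed-size-item displays as a function of
    numerosity: 16 px circles, >= 24 px edge-to-edge, 700 px diameter
    region."""
    if rng is None:
        rng = np.random.default_rng()
    if numerosities is None:
        numerosities = _log_spaced_numerosities()
    rows = []
    for n in numerosities:
        specs = make_generalization_series("numerosity_1_to_175", rng,
                                           n_repeats=n_repeats,
                                           numerosities=[n])
        powers = power_of_displays(specs)
        rows.append({"numerosity": n, "mean_power": powers.mean(),
                     "sd_power": powers.std(ddof=1) if len(powers) > 1 else 0.0,
                     "n_displays": len(powers)})
    return pd.DataFrame(rows)


def _log_spaced_numerosities(lo: int = 1, hi: int = 175, k: int = 24) -> list[int]:
    ns = np.unique(np.rint(np.geomspace(lo, hi, k)).astype(int))
    return ns.tolist()


def fit_power_law(table: pd.DataFrame) -> tuple[float, float]:
    """Least-squares fit of log(mean power) = a + b log(n); returns
    (exponent b, intercept a)."""
    x = np.log(table["numerosity"].to_numpy(dtype=float))
    y = np.log(table["mean_power"].to_numpy(dtype=float))
    b, a = np.polyfit(x, y, 1)
    return float(b), float(a)


# ----------------------------------------------------------------------
# generalization series
# ----------------------------------------------------------------------

def single_circle_size_series(diameters: Sequence[int] | None = None) -> pd.DataFrame:
    """Aggregate power of one centered circle across diameters."""
    specs = make_generalization_series("single_circle_diameters")
    if diameters is not None:
        want = set(diameters)
        specs = [s for s in specs if round(2 * s.items[0].size) in want]
    rows = [{"diameter_px": round(2 * s.items[0].size),
             "power": aggregate_power(render(s)).normalized} for s in specs]
    return pd.DataFrame(rows)


def seven_circle_spacing_series(n_repeats: int = 18,
                                rng: np.random.Generator | None = None,
                                area_diameters: Sequence[float] | None = None,
                                ) -> pd.DataFrame:
    """Power of the seven-circle group as its area (spacing) varies."""
    if rng is None:
        rng = np.random.default_rng()
    if area_diameters is None:
        area_diameters = range(50, 529, 26)
    rows = []
    for d_area in area_diameters:
        powers = [aggregate_power(render(
            make_seven_circle_group(d_area, rng))).normalized
            for _ in range(n_repeats)]
        rows.append({"area_diameter_px": d_area,
                     "mean_power": float(np.mean(powers)),
                     "sd_power": float(np.std(powers, ddof=1))})
    return pd.DataFrame(rows)


def shape_series() -> pd.DataFrame:
    """Orientation-resolved power of regular polygons (3-10 corners plus
    a circle) and stars; spatial frequency differs with orientation in
    these shapes, so the first-harmonic limit is found per orientation
    sector."""
    rows = []
    for spec in make_generalization_series("polygons"):
        item = spec.items[0]
        nv = item.n_vertices if item.n_vertices else math.inf
        rows.append({"family": "polygon", "n_corners": nv,
                     "power": orientation_resolved_power(render(spec)).normalized})
    for spec in make_generalization_series("stars"):
        rows.append({"family": "star", "n_corners": spec.items[0].n_vertices,
                     "power": orientation_resolved_power(render(spec)).normalized})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# fMRI-style configurations
# ----------------------------------------------------------------------

def configuration_power_table(numerosities: Sequence[int] = range(1, 8),
                              n_repeats: int = 3,
                              rng: np.random.Generator | None = None,
                              configs: Sequence[Configuration] | None = None,
                              with_second_harmonic: bool = False) -> pd.DataFrame:
    """Mean aggregate power (and optionally second-harmonic power) per
    numerosity for each stimulus configuration."""
    if rng is None:
        rng = np.random.default_rng()
    if configs is None:
        configs = [Configuration.CONSTANT_AREA, Configuration.CONSTANT_SIZE,
                   Configuration.CONSTANT_PERIMETER, Configuration.HIGH_DENSITY]
    rows = []
    for config in configs:
        for n in numerosities:
            p1, p2 = [], []
            for _ in range(n_repeats):
                spec = make_configuration_display(config, n, rng=rng)
                img = render(spec)
                ap = aggregate_power(img,
                                     with_second_harmonic=with_second_harmonic)
                p1.append(ap.normalized)
                if with_second_harmonic and ap.second_harmonic_normalized is not None:
                    p2.append(ap.second_harmonic_normalized)
            row = {"configuration": Configuration(config).value, "numerosity": n,
                   "mean_power": float(np.mean(p1)),
                   "sd_power": float(np.std(p1, ddof=1)) if len(p1) > 1 else 0.0}
            if with_second_harmonic:
                row["mean_second_harmonic"] = float(np.mean(p2)) if p2 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# contrast manipulations
# ----------------------------------------------------------------------

def _seven_circle_contrast_display(rng: np.random.Generator,
                                   contrasts: np.ndarray) -> DisplaySpec:
    """Seven-circle display for the contrast manipulations: the group
    area diameter is drawn uniformly from the 50-528 px range used by
    the spacing analysis; items may touch but not overlap (at the 50 px
    minimum area all seven items touch)."""
    d_area = rng.uniform(*GROUP_AREA_RANGE_PX)
    region = d_area / 2.0
    centers = stimuli.place_items(7, 8.0, region, 0.0, rng)
    cx = cy = stimuli.CANVAS_PX / 2.0
    items = [stimuli.ItemSpec(stimuli.Shape.CIRCLE, (cx + x, cy + y), 8.0,
                              weber_contrast=float(c))
             for (x, y), c in zip(centers, contrasts)]
    return DisplaySpec(items, stimuli.CANVAS_PX, region_radius_px=region,
                       numerosity=7)


def mixed_black_white_contrast(n_displays: int = 80,
                               rng: np.random.Generator | None = None) -> dict:
    """Mean power of displays whose items are all black (contrast -1)
    versus a random black/white mixture (+-1), on shared geometries.

    Uses the signed-deviation normalization so that white and black
    items enter with opposite sign.
    """
    if rng is None:
        rng = np.random.default_rng()
    black, mixed = [], []
    for _ in range(n_displays):
        d_area = rng.uniform(*GROUP_AREA_RANGE_PX)
        region = d_area / 2.0
        centers = stimuli.place_items(7, 8.0, region, 0.0, rng)
        signs = rng.choice([-1.0, 1.0], size=7)
        cx = cy = stimuli.CANVAS_PX / 2.0
        for contrasts, out in (([-1.0] * 7, black), (signs, mixed)):
            items = [stimuli.ItemSpec(stimuli.Shape.CIRCLE,
                                      (cx + x, cy + y), 8.0,
                                      weber_contrast=float(c))
                     for (x, y), c in zip(centers, contrasts)]
            spec = DisplaySpec(items, stimuli.CANVAS_PX,
                               region_radius_px=region, numerosity=7)
            out.append(aggregate_power(render(spec),
                                       "signed_deviation").normalized)
    black = np.asarray(black)
    mixed = np.asarray(mixed)
    return {
        "mean_black": float(black.mean()),
        "mean_mixed": float(mixed.mean()),
        "pct_increase": float(100.0 * (mixed.mean() - black.mean())
                              / black.mean()),
        "powers_black": black,
        "powers_mixed": mixed,
    }


def contrast_range_experiment(contrast_ranges: Sequence[float] = (0.1, 0.85),
                              center: float = 0.5,
                              n_displays: int = 80,
                              rng: np.random.Generator | None = None) -> dict:
    """Per-display power when each item's absolute Weber contrast is
    drawn uniformly from ``center +- range/2`` (items dark), for each
    tested range.  Reports across-display means and 95% interval widths
    (2.5-97.5 percentiles) per condition, on shared geometries."""
    if rng is None:
        rng = np.random.default_rng()
    geoms = []
    for _ in range(n_displays):
        d_area = rng.uniform(*GROUP_AREA_RANGE_PX)
        region = d_area / 2.0
        geoms.append((region, stimuli.place_items(7, 8.0, region, 0.0, rng)))
    cx = cy = stimuli.CANVAS_PX / 2.0
    out: dict = {"conditions": {}}
    for crange in contrast_ranges:
        lo, hi = center - crange / 2.0, center + crange / 2.0
        powers = []
        for region, centers in geoms:
            contrasts = -rng.uniform(lo, hi, size=7)
            items = [stimuli.ItemSpec(stimuli.Shape.CIRCLE,
                                      (cx + x, cy + y), 8.0,
                                      weber_contrast=float(c))
                     for (x, y), c in zip(centers, contrasts)]
            spec = DisplaySpec(items, stimuli.CANVAS_PX,
                               region_radius_px=region, numerosity=7)
            powers.append(aggregate_power(render(spec),
                                          "signed_deviation").normalized)
        powers = np.asarray(powers)
        out["conditions"][crange] = {
            "mean": float(powers.mean()),
            "ci_width": float(np.percentile(powers, 97.5)
                              - np.percentile(powers, 2.5)),
            "powers": powers,
        }
    ranges = sorted(out["conditions"])
    narrow, wide = out["conditions"][ranges[0]], out["conditions"][ranges[-1]]
    out["ci_width_pct_increase"] = float(
        100.0 * (wide["ci_width"] - narrow["ci_width"]) / narrow["ci_width"])
    out["mean_pct_increase"] = float(
        100.0 * (wide["mean"] - narrow["mean"]) / narrow["mean"])
    return out


# ----------------------------------------------------------------------
# connectedness
# ----------------------------------------------------------------------

def connectedness_experiment(separation_px: float = 60.0,
                             contrast_mode: str = "binary_mask") -> pd.DataFrame:
    """Aggregate power of dot pairs with connecting bars, rotated-bar
    controls, illusory-contour inducers, and rotated-inducer controls."""
    rows = []
    for conn in PairConnection:
        spec = make_dot_pair_display(conn, separation_px)
        rows.append({"connection": conn.value,
                     "power": aggregate_power(render(spec),
                                              contrast_mode).normalized})
    return pd.DataFrame(rows)
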