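"""Candidate non-numerical display features.

Thirteen scalar features per display (numerosity, per-item and total
area and perimeter, convex-hull geometry, luminance/edge/number density
inside the hull, RMS contrast, aggregate Fourier power) plus two
filter-based statistics of texture-density accounts of numerosity (the
summed response of a high-spatial-frequency Laplacian-of-Gaussian
filter, and the response ratio of a high/low filter pair), and spatial
pRF predictors that follow item luminance or edges.

These are the alternative explanatory variables that monotonic response
models are fit against; analytic circle geometry is used where
available, everything else is measured from the rendered mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.spatial import ConvexHull

from .spectral import aggregate_power, normalize_image
from .stimuli import DisplaySpec, Shape, StimulusImage, PX_PER_DEGREE

__all__ = [
    "FeatureRecord",
    "quantify_features",
    "log_kernel",
    "log_filter_response",
    "response_ratio",
    "spatial_prf_predictor",
    "edge_map",
]

LOG_FILTER_SIGMA_PX = 2.0
RESPONSE_RATIO_SIGMAS = (1.0, 34.0)


@dataclass
class FeatureRecord:
    numerosity: int
    item_area: float
    item_perimeter: float
    total_area: float
    total_perimeter: float
    hull_area: float
    hull_perimeter: float
    luminance_density: float
    edge_density: float
    number_density: float
    rms_contrast_display: float
    rms_contrast_hull: float
    aggregate_fourier_power: float
    log_filter_response: float
    response_ratio: float
    configuration: str = "custom"
    seed: int | None = None


def edge_map(mask: np.ndarray) -> np.ndarray:
    """Item boundary pixels: the mask minus its erosion by one pixel."""
    mask = mask.astype(bool)
    return mask & ~ndimage.binary_erosion(mask)


def _hull_of_pixels(mask: np.ndarray) -> ConvexHull | None:
    ys, xs = np.nonzero(mask)
    if len(xs) < 3:
        return None
    pts = np.c_[xs, ys].astype(float)
    try:
        return ConvexHull(pts)
    except Exception:
        return None


def _hull_mask(hull: ConvexHull, shape: tuple[int, int]) -> np.ndarray:
    from matplotlib.path import Path

    verts = hull.points[hull.vertices]
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return Path(verts).contains_points(
        np.c_[xx.ravel(), yy.ravel()], radius=1e-9
    ).reshape(shape)


def quantify_features(spec: DisplaySpec, img: StimulusImage,
                      contrast_mode: str = "binary_mask") -> FeatureRecord:
    """Measure the full feature battery for one display.

    Circle area and perimeter are analytic; the convex hull is computed
    over item pixel coordinates; RMS contrast is the standard deviation
    of pixel luminance (over the whole display, and restricted to the
    hull).  For a one-item display the hull degenerates to the item's
    own footprint.
    """
    mask = normalize_image(img, "binary_mask").astype(bool)
    n = spec.numerosity

    circles = [it for it in spec.items if it.shape is Shape.CIRCLE]
    if len(circles) == len(spec.items) and circles:
        total_area = sum(it.area() for it in circles)
        total_perimeter = sum(it.perimeter() for it in circles)
    else:
        total_area = float(mask.sum())
        total_perimeter = float(edge_map(mask).sum())
    item_area = total_area / max(n, 1)
    item_perimeter = total_perimeter / max(n, 1)

    hull = _hull_of_pixels(mask)
    if hull is not None:
        hull_area = float(hull.volume)      # 2-D: volume is the area
        hull_perimeter = float(hull.area)   # 2-D: area is the perimeter
        hmask = _hull_mask(hull, mask.shape)
    else:  # tiny or degenerate item footprint
        hull_area = float(mask.sum())
        hull_perimeter = float(edge_map(mask).sum())
        hmask = mask
    hull_area = max(hull_area, 1.0)

    lum_dev = np.abs(normalize_image(img, "signed_deviation"))
    luminance_density = float(lum_dev[hmask].sum()) / hull_area
    edge_density = float(edge_map(mask)[hmask].sum()) / hull_area
    number_density = n / hull_area

    px = img.pixels
    rms_display = float(px.std())
    rms_hull = float(px[hmask].std()) if hmask.any() else 0.0

    power = aggregate_power(img, contrast_mode=contrast_mode).normalized

    return FeatureRecord(
        numerosity=n,
        item_area=item_area,
        item_perimeter=item_perimeter,
        total_area=total_area,
        total_perimeter=total_perimeter,
        hull_area=hull_area,
        hull_perimeter=hull_perimeter,
        luminance_density=luminance_density,
        edge_density=edge_density,
        number_density=number_density,
        rms_contrast_display=rms_display,
        rms_contrast_hull=rms_hull,
        aggregate_fourier_power=power,
        log_filter_response=log_filter_response(img, LOG_FILTER_SIGMA_PX),
        response_ratio=response_ratio(img, *RESPONSE_RATIO_SIGMAS),
        configuration=spec.configuration.value,
        seed=spec.seed,
    )


def log_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Sampled Laplacian-of-Gaussian center-surround kernel, truncated
    at ``truncate`` standard deviations and shifted to exact zero mean."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = max(int(math.ceil(truncate * sigma)), 1)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    q = (xx**2 + yy**2) / (2.0 * sigma**2)
    k = (q - 1.0) / (math.pi * sigma**4) * np.exp(-q)
    return k - k.mean()


def log_filter_response(img: StimulusImage | np.ndarray, sigma: float,
                        rectify: str = "abs") -> float:
    """Summed response of a zero-mean Laplacian-of-Gaussian filter.

    The filter is convolved with the zero-background-normalized field
    and the response is summed over all image locations after
    rectification (``abs``; ``square`` sums response energy instead).
    An unrectified sum of a zero-mean filter response would be
    identically zero.
    """
    if isinstance(img, StimulusImage):
        field = normalize_image(img, "signed_deviation")
    else:
        field = np.asarray(img, dtype=float)
    if sigma >= field.shape[0] / 4:
        raise ValueError("sigma too large relative to the canvas")
    resp = signal.fftconvolve(field, log_kernel(sigma), mode="same")
    if rectify == "abs":
        return float(np.abs(resp).sum())
    if rectify == "square":
        return float((resp**2).sum())
    raise ValueError(f"unknown rectification: {rectify}")


def response_ratio(img: StimulusImage | np.ndarray, sigma_hi: float = 1.0,
                   sigma_lo: float = 34.0) -> float:
    """Ratio of summed high- to low-spatial-frequency filter responses
    (a density-sensitive alternative statistic; defaults sigma 1 and 34
    px)."""
    if sigma_hi > sigma_lo:
        raise ValueError("sigma_hi must not exceed sigma_lo")
    hi = log_filter_response(img, sigma_hi)
    lo = log_filter_response(img, sigma_lo)
    if lo == 0.0:
        raise ZeroDivisionError("low-frequency filter response is zero")
    return hi / lo


def spatial_prf_predictor(displays: list[tuple[DisplaySpec, StimulusImage]],
                          prf_center_deg: tuple[float, float],
                          prf_size_deg: float,
                          source: str = "luminance",
                          px_per_degree: float = PX_PER_DEGREE,
                          ) -> dict[int, float]:
    """Predictor of a visual position selective pRF.

    A 2-D Gaussian pRF (center and size in degrees relative to the
    display center) weights either the item luminance-deviation map or
    the edge map of each display; weighted sums are accumulated across
    all displays of the same numerosity, yielding one predictor value
    per numerosity.
    """
    if not displays:
        raise ValueError("need at least one display")
    out: dict[int, float] = {}
    for spec, img in displays:
        n = spec.canvas_px
        cx = n / 2.0 + prf_center_deg[0] * px_per_degree
        cy = n / 2.0 + prf_center_deg[1] * px_per_degree
        sd = prf_size_deg * px_per_degree
        yy, xx = np.mgrid[0:n, 0:n]
        w = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sd**2)))
        if source == "luminance":
            m = np.abs(normalize_image(img, "signed_deviation"))
        elif source == "edges":
            m = edge_map(normalize_image(img, "binary_mask").astype(bool)).astype(float)
        else:
            raise ValueError(f"unknown source: {source}")
        out[spec.numerosity] = out.get(spec.numerosity, 0.0) + float((w * m).sum())
    return out
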