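"""Parametric numerosity displays and their rasterization.

Displays are sets of items (circles, regular polygons, stars, bars,
illusory-contour inducers) on a mid-gray background, described by a
:class:`DisplaySpec` and rendered to a grayscale :class:`StimulusImage`.
Four families of displays mirror a standard numerosity-fMRI design:
constant total item area, constant individual item size, constant total
item perimeter, and a high-density grouping.  Further generator series
(single circles of varying diameter, a seven-circle group of varying
spacing, numerosities 1-175, regular polygons and stars, connected dot
pairs) support generalization analyses of the aggregate-Fourier-power
statistic.

Geometry is in pixels throughout.  Visual-degree quantities are mapped
through ``PX_PER_DEGREE`` (chosen so that the 0.75 deg stimulus-region
radius equals 350 px on the default 768 px canvas).  Rendering uses
pixel-center membership with no anti-aliasing, so the same spec always
rasterizes to a bit-identical image.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Shape",
    "Configuration",
    "PairConnection",
    "ItemSpec",
    "DisplaySpec",
    "StimulusImage",
    "PackingError",
    "place_items",
    "make_configuration_display",
    "render",
    "make_generalization_series",
    "make_dot_pair_display",
    "CANVAS_PX",
    "PX_PER_DEGREE",
    "REGION_RADIUS_PX",
]

# Default evaluation resolution and degree->pixel mapping.  The stimulus
# region spans 0.75 deg of visual angle; at the default mapping this is a
# 350 px radius on a 768 px canvas.
CANVAS_PX = 768
REGION_RADIUS_PX = 350.0
PX_PER_DEGREE = REGION_RADIUS_PX / 0.75

#: default minimum edge-to-edge gap inside the four fMRI-style
#: configurations (not stated by the design; 2 px prevents item fusion)
DEFAULT_MIN_GAP_PX = 2.0

#: dot-pair constants: 30 px dot diameter, 4 px bars, inducers carved
#: 10 px into the dot
DOT_PAIR_DIAMETER_PX = 30.0
BAR_WIDTH_PX = 4.0
INDUCER_DEPTH_PX = 10.0


class Shape(str, Enum):
    CIRCLE = "circle"
    REGULAR_POLYGON = "regular_polygon"
    STAR = "star"
    BAR = "bar"
    ILLUSORY_INDUCER = "illusory_inducer"


class Configuration(str, Enum):
    CONSTANT_AREA = "constant_area"
    CONSTANT_SIZE = "constant_size"
    CONSTANT_PERIMETER = "constant_perimeter"
    HIGH_DENSITY = "high_density"
    CUSTOM = "custom"


class PairConnection(str, Enum):
    DOTS_ONLY = "dots_only"
    BAR = "bar"
    ROTATED_BAR = "rotated_bar"
    ILLUSORY = "illusory"
    ROTATED_ILLUSORY = "rotated_illusory"


class PackingError(RuntimeError):
    """Raised when items cannot be placed under the spacing constraints."""


@dataclass
class ItemSpec:
    """One display item.

    ``size`` is the primary radius in px for circles/polygons/stars and
    the half-length for bars and inducers.  ``weber_contrast`` is signed:
    -1 is black on the mid-gray background, +1 is white, 0 matches the
    background (used for carving illusory-contour inducers).
    """

    shape: Shape
    center: tuple[float, float]
    size: float
    n_vertices: int | None = None
    inner_radius: float | None = None
    orientation: float = 0.0
    weber_contrast: float = -1.0
    width: float | None = None  # bars / inducers only

    def __post_init__(self) -> None:
        self.shape = Shape(self.shape)
        if self.size <= 0:
            raise ValueError(f"item size must be positive, got {self.size}")
        if abs(self.weber_contrast) > 1 + 1e-12:
            raise ValueError("weber_contrast must lie in [-1, 1]")

    # -- analytic geometry (circles only; other shapes fall back to
    #    rasterized measures in the feature module) --------------------
    def area(self) -> float:
        if self.shape is Shape.CIRCLE:
            return math.pi * self.size**2
        raise NotImplementedError(f"analytic area for {self.shape}")

    def perimeter(self) -> float:
        if self.shape is Shape.CIRCLE:
            return 2.0 * math.pi * self.size
        raise NotImplementedError(f"analytic perimeter for {self.shape}")


@dataclass
class DisplaySpec:
    items: list[ItemSpec]
    canvas_px: int = CANVAS_PX
    background_level: float = 0.5
    region_radius_px: float = REGION_RADIUS_PX
    configuration: Configuration = Configuration.CUSTOM
    numerosity: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.configuration = Configuration(self.configuration)
        if self.numerosity == 0:
            self.numerosity = len(self.items)

    def to_json(self) -> str:
        d = asdict(self)
        d["configuration"] = self.configuration.value
        for it in d["items"]:
            it["shape"] = Shape(it["shape"]).value
            it["center"] = list(it["center"])
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "DisplaySpec":
        d = json.loads(text)
        items = [ItemSpec(**{**it, "center": tuple(it["center"])}) for it in d.pop("items")]
        return cls(items=items, **d)


@dataclass
class StimulusImage:
    """Grayscale luminance image; values are fractions in [0, 1]."""

    pixels: np.ndarray
    canvas_px: int
    background_level: float = 0.5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (self.canvas_px, self.canvas_px):
            raise ValueError("pixel array does not match canvas size")


# ----------------------------------------------------------------------
# item placement
# ----------------------------------------------------------------------

def _pairwise_min_dist(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return math.inf
    d = pts[:, None, :] - pts[None, :, :]
    dist = np.hypot(d[..., 0], d[..., 1])
    np.fill_diagonal(dist, np.inf)
    return float(dist.min())


def _rejection_place(n: int, radius: float, region_radius: float, min_gap: float,
                     rng: np.random.Generator, max_retries: int = 10_000) -> np.ndarray | None:
    mind = 2 * radius + min_gap
    reff = region_radius - radius
    pts: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(max_retries):
            ang = rng.uniform(0.0, 2 * math.pi)
            rad = reff * math.sqrt(rng.uniform())
            p = np.array([rad * math.cos(ang), rad * math.sin(ang)])
            if all(np.hypot(*(p - q)) >= mind for q in pts):
                pts.append(p)
                break
        else:
            return None
    return np.asarray(pts)


def _relaxation_place(n: int, radius: float, region_radius: float, min_gap: float,
                      rng: np.random.Generator, max_iter: int = 2000) -> np.ndarray | None:
    """Random starts pushed apart pairwise (Gauss-Seidel) until the
    spacing constraint holds.  Reaches packing densities where
    sequential rejection sampling jams, while keeping the arrangement
    disordered (no lattice structure in the spectrum)."""
    mind = 2 * radius + min_gap
    reff = region_radius - radius
    if reff <= 0:
        return None
    target = mind * 1.001
    ang = rng.uniform(0.0, 2 * math.pi, n)
    rad = reff * np.sqrt(rng.uniform(size=n))
    pts = np.c_[rad * np.cos(ang), rad * np.sin(ang)]
    for _ in range(max_iter):
        d = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(dist, np.inf)
        ii, jj = np.nonzero(np.triu(dist < mind, 1))
        if len(ii) == 0:
            return pts
        for k in rng.permutation(len(ii)):
            i, j = ii[k], jj[k]
            v = pts[i] - pts[j]
            dd = math.hypot(*v)
            if dd < 1e-9:
                v = rng.standard_normal(2)
                dd = math.hypot(*v)
            if dd >= target:
                continue
            shift = 0.5 * (target - dd) * v / dd
            pts[i] += shift
            pts[j] -= shift
            for q in (i, j):
                rr = math.hypot(*pts[q])
                if rr > reff:
                    pts[q] *= reff / rr
    return None


def place_items(n: int, item_radii: float | Sequence[float], region_radius: float,
                min_gap: float, rng: np.random.Generator) -> np.ndarray:
    """Place ``n`` item centers uniformly in a circular region with a
    minimum edge-to-edge gap.

    Returns centers relative to the region center, shape ``(n, 2)``.
    Placement is rejection sampling for sparse displays and collision
    relaxation for dense ones (rejection sampling cannot reach the
    required packing fraction for e.g. 175 items at a 24 px gap).

    Raises :class:`PackingError` if the constraint cannot be satisfied.
    """
    if n < 1:
        raise ValueError("need at least one item")
    radii = np.atleast_1d(np.asarray(item_radii, dtype=float))
    radius = float(radii.max())
    if radius > region_radius:
        raise PackingError(
            f"item radius {radius} exceeds region radius {region_radius}")
    mind = 2 * radius + min_gap
    reff = max(region_radius - radius, 1e-9)
    coverage = n * (mind / 2.0) ** 2 / (reff + mind / 2.0) ** 2
    if coverage < 0.3:
        for _ in range(5):
            pts = _rejection_place(n, radius, region_radius, min_gap, rng)
            if pts is not None:
                return pts
    for _ in range(10):
        pts = _relaxation_place(n, radius, region_radius, min_gap, rng)
        if pts is not None:
            return pts
    raise PackingError(
        f"could not place n={n} items of radius {radius} with gap "
        f"{min_gap} inside region radius {region_radius}")


# ----------------------------------------------------------------------
# configuration displays
# ----------------------------------------------------------------------

# Conservation constants for the four fMRI-style families, chosen so that
# displays resemble the published examples: the reference is a single
# circle of 160 px diameter (~0.34 deg).  Constant-size items are 56 px
# in diameter (~0.12 deg).
TOTAL_AREA_PX2 = math.pi * 80.0**2
TOTAL_PERIMETER_PX = 2 * math.pi * 80.0
CONSTANT_SIZE_RADIUS_PX = 28.0


def _config_radius(config: Configuration, n: int) -> float:
    if config is Configuration.CONSTANT_SIZE:
        return CONSTANT_SIZE_RADIUS_PX
    if config in (Configuration.CONSTANT_AREA, Configuration.HIGH_DENSITY):
        return math.sqrt(TOTAL_AREA_PX2 / (n * math.pi))
    if config is Configuration.CONSTANT_PERIMETER:
        return TOTAL_PERIMETER_PX / (2 * math.pi * n)
    raise ValueError(f"no size rule for configuration {config}")


def make_configuration_display(config: Configuration | str, n: int,
                               canvas: int = CANVAS_PX,
                               rng: np.random.Generator | None = None,
                               region_radius: float = REGION_RADIUS_PX,
                               min_gap: float = DEFAULT_MIN_GAP_PX,
                               seed: int | None = None) -> DisplaySpec:
    """Build one display of ``n`` black circles under a conservation rule.

    ``constant_area`` holds summed item area fixed, ``constant_size``
    holds the item diameter fixed, ``constant_perimeter`` holds summed
    circumference fixed, and ``high_density`` uses the constant-area
    sizes but groups all items in a half-radius sub-region that is
    itself randomly positioned inside the stimulus region.
    """
    config = Configuration(config)
    if rng is None:
        rng = np.random.default_rng(seed)
    if n < 1:
        raise ValueError("numerosity must be >= 1")
    radius = _config_radius(config, n)
    cx = cy = canvas / 2.0
    if config is Configuration.HIGH_DENSITY:
        sub_radius = region_radius / 2.0
        max_off = region_radius - sub_radius
        ang = rng.uniform(0.0, 2 * math.pi)
        off = max_off * math.sqrt(rng.uniform())
        sub_center = np.array([off * math.cos(ang), off * math.sin(ang)])
        centers = place_items(n, radius, sub_radius, min_gap, rng) + sub_center
    else:
        centers = place_items(n, radius, region_radius, min_gap, rng)
    items = [ItemSpec(Shape.CIRCLE, (cx + x, cy + y), radius) for x, y in centers]
    return DisplaySpec(items=items, canvas_px=canvas,
                       region_radius_px=region_radius, configuration=config,
                       numerosity=n, seed=seed)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _item_mask_into(img: np.ndarray, item: ItemSpec, value: float) -> None:
    """Paint an item into ``img`` (painter's order) using pixel-center
    membership tests restricted to the item's bounding box."""
    n = img.shape[0]
    cx, cy = item.center
    if item.shape in (Shape.BAR, Shape.ILLUSORY_INDUCER):
        half_diag = math.hypot(item.size, (item.width or BAR_WIDTH_PX) / 2.0)
    elif item.shape is Shape.STAR or item.shape is Shape.REGULAR_POLYGON:
        half_diag = item.size
    else:
        half_diag = item.size
    x0 = max(int(math.floor(cx - half_diag)) - 1, 0)
    x1 = min(int(math.ceil(cx + half_diag)) + 2, n)
    y0 = max(int(math.floor(cy - half_diag)) - 1, 0)
    y1 = min(int(math.ceil(cy + half_diag)) + 2, n)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("item lies outside the canvas")
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    if item.shape is Shape.CIRCLE:
        mask = dx * dx + dy * dy <= item.size**2
    elif item.shape is Shape.REGULAR_POLYGON:
        mask = _convex_polygon_mask(dx, dy, _polygon_vertices(item))
    elif item.shape is Shape.STAR:
        mask = _simple_polygon_mask(dx, dy, _star_vertices(item))
    elif item.shape in (Shape.BAR, Shape.ILLUSORY_INDUCER):
        c, s = math.cos(item.orientation), math.sin(item.orientation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        w = (item.width or BAR_WIDTH_PX) / 2.0
        eps = 1e-9  # rotation round-off must not shave boundary pixels
        mask = (np.abs(u) <= item.size + eps) & (np.abs(v) <= w + eps)
    else:  # pragma: no cover
        raise NotImplementedError(item.shape)
    img[y0:y1, x0:x1][mask] = value


def _polygon_vertices(item: ItemSpec) -> np.ndarray:
    if not item.n_vertices or item.n_vertices < 3:
        raise ValueError("polygon needs n_vertices >= 3")
    ang = item.orientation + 2 * math.pi * np.arange(item.n_vertices) / item.n_vertices
    return np.c_[item.size * np.cos(ang), item.size * np.sin(ang)]


def _star_vertices(item: ItemSpec) -> np.ndarray:
    if not item.n_vertices or item.n_vertices < 3:
        raise ValueError("star needs n_vertices >= 3")
    if not item.inner_radius:
        raise ValueError("star needs an inner_radius")
    k = item.n_vertices
    ang = item.orientation + math.pi * np.arange(2 * k) / k
    rad = np.where(np.arange(2 * k) % 2 == 0, item.size, item.inner_radius)
    return np.c_[rad * np.cos(ang), rad * np.sin(ang)]


def _convex_polygon_mask(dx: np.ndarray, dy: np.ndarray, verts: np.ndarray) -> np.ndarray:
    mask = np.ones(dx.shape, dtype=bool)
    m = len(verts)
    for i in range(m):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % m]
        # CCW vertex order: interior is the non-negative cross-product side
        mask &= (x2 - x1) * (dy - y1) - (y2 - y1) * (dx - x1) >= 0
    return mask


def _simple_polygon_mask(dx: np.ndarray, dy: np.ndarray, verts: np.ndarray) -> np.ndarray:
    from matplotlib.path import Path

    pts = np.c_[dx.ravel(), dy.ravel()]
    return Path(verts).contains_points(pts).reshape(dx.shape)


def render(spec: DisplaySpec) -> StimulusImage:
    """Rasterize a display spec to a grayscale image.

    Items are painted in list order; a pixel belongs to an item if its
    center lies inside the analytic shape.  Item pixels are set to
    ``background_level * (1 + weber_contrast)``, clipped to [0, 1].
    """
    img = np.full((spec.canvas_px, spec.canvas_px), spec.background_level, dtype=float)
    for item in spec.items:
        value = spec.background_level * (1.0 + item.weber_contrast)
        _item_mask_into(img, item, float(np.clip(value, 0.0, 1.0)))
    return StimulusImage(img, spec.canvas_px, spec.background_level)


# ----------------------------------------------------------------------
# generalization series
# ----------------------------------------------------------------------

def make_generalization_series(kind: str, rng: np.random.Generator | None = None,
                               canvas: int = CANVAS_PX,
                               n_repeats: int = 1,
                               numerosities: Sequence[int] | None = None,
                               ) -> list[DisplaySpec]:
    """Displays probing how aggregate power generalizes over item size,
    spacing, count, and shape.

    kinds:
      ``single_circle_diameters``  one centered circle, diameters 1-240 px
      ``seven_circle_spacing``     seven 16 px circles in areas of 50-528 px
                                   diameter (spacing scales with the area)
      ``numerosity_1_to_175``      16 px circles, >= 24 px edge-to-edge,
                                   700 px diameter region
      ``polygons``                 regular 3-10-gons at 30 px vertex radius,
                                   plus a circle
      ``stars``                    3-10-point stars, 30 px outer / 10 px
                                   inner radius
    """
    if rng is None:
        rng = np.random.default_rng()
    cx = cy = canvas / 2.0
    specs: list[DisplaySpec] = []

    if kind == "single_circle_diameters":
        for d in range(1, 241):
            items = [ItemSpec(Shape.CIRCLE, (cx, cy), d / 2.0)]
            specs.append(DisplaySpec(items, canvas, numerosity=1))
    elif kind == "seven_circle_spacing":
        for d_area in range(50, 529, 26):
            for _ in range(n_repeats):
                specs.append(make_seven_circle_group(d_area, rng, canvas))
    elif kind == "numerosity_1_to_175":
        ns = numerosities if numerosities is not None else range(1, 176)
        for n in ns:
            for _ in range(n_repeats):
                centers = place_items(n, 8.0, 350.0, 24.0, rng)
                items = [ItemSpec(Shape.CIRCLE, (cx + x, cy + y), 8.0)
                         for x, y in centers]
                specs.append(DisplaySpec(items, canvas, region_radius_px=350.0,
                                         numerosity=n))
    elif kind == "polygons":
        for nv in range(3, 11):
            items = [ItemSpec(Shape.REGULAR_POLYGON, (cx, cy), 30.0, n_vertices=nv)]
            specs.append(DisplaySpec(items, canvas, numerosity=1))
        specs.append(DisplaySpec([ItemSpec(Shape.CIRCLE, (cx, cy), 30.0)],
                                 canvas, numerosity=1))
    elif kind == "stars":
        for nv in range(3, 11):
            items = [ItemSpec(Shape.STAR, (cx, cy), 30.0, n_vertices=nv,
                              inner_radius=10.0)]
            specs.append(DisplaySpec(items, canvas, numerosity=1))
    else:
        raise ValueError(f"unknown series kind: {kind}")
    return specs


def make_seven_circle_group(area_diameter_px: float, rng: np.random.Generator,
                            canvas: int = CANVAS_PX,
                            contrasts: Sequence[float] | None = None) -> DisplaySpec:
    """Seven 16 px diameter circles spaced randomly but evenly inside a
    circular area of the given diameter.  The minimum center-to-center
    distance scales with the area diameter, so that at 50 px all items
    touch."""
    region = area_diameter_px / 2.0
    mind = 16.0 * (area_diameter_px / 50.0)
    gap = max(mind - 16.0, 0.0)
    centers = place_items(7, 8.0, region, gap, rng)
    cx = cy = canvas / 2.0
    if contrasts is None:
        contrasts = [-1.0] * 7
    items = [ItemSpec(Shape.CIRCLE, (cx + x, cy + y), 8.0, weber_contrast=c)
             for (x, y), c in zip(centers, contrasts)]
    return DisplaySpec(items, canvas, region_radius_px=region, numerosity=7)


# ----------------------------------------------------------------------
# connected dot pairs
# ----------------------------------------------------------------------

def make_dot_pair_display(connection: PairConnection | str, separation: float,
                          rng: np.random.Generator | None = None,
                          canvas: int = CANVAS_PX,
                          rotation: float = math.pi / 2.0) -> DisplaySpec:
    """Two 30 px dots at the given edge-to-edge separation, optionally
    joined by a 4 px bar or by illusory-contour inducers carved 10 px
    into each dot.  ``rotated_*`` variants split the element at the
    midpoint and rotate each half about its dot center, changing each
    dot identically while breaking the connection."""
    connection = PairConnection(connection)
    if separation <= 0:
        raise ValueError("separation must be positive")
    r = DOT_PAIR_DIAMETER_PX / 2.0
    cx = cy = canvas / 2.0
    half_cc = (separation + 2 * r) / 2.0  # center-to-center / 2
    left = (cx - half_cc, cy)
    right = (cx + half_cc, cy)
    items = [ItemSpec(Shape.CIRCLE, left, r), ItemSpec(Shape.CIRCLE, right, r)]

    if connection is PairConnection.BAR:
        items.append(ItemSpec(Shape.BAR, (cx, cy), separation / 2.0,
                              orientation=0.0, width=BAR_WIDTH_PX))
    elif connection is PairConnection.ROTATED_BAR:
        # each half-bar spans [r, r + separation/2] from its dot center
        mid = r + separation / 4.0
        for center, sign in ((left, +1.0), (right, -1.0)):
            ang = rotation if sign > 0 else math.pi - rotation
            bx = center[0] + mid * math.cos(ang)
            by = center[1] + mid * math.sin(ang)
            _check_no_dot_overlap((bx, by), separation / 4.0, ang,
                                  left if sign < 0 else right, r)
            items.append(ItemSpec(Shape.BAR, (bx, by), separation / 4.0,
                                  orientation=ang, width=BAR_WIDTH_PX))
    elif connection is PairConnection.ILLUSORY:
        for center, sign in ((left, +1.0), (right, -1.0)):
            # background-colored notch from the dot edge, 10 px deep
            nx = center[0] + sign * (r - INDUCER_DEPTH_PX / 2.0)
            items.append(ItemSpec(Shape.ILLUSORY_INDUCER, (nx, center[1]),
                                  INDUCER_DEPTH_PX / 2.0, orientation=0.0,
                                  weber_contrast=0.0, width=BAR_WIDTH_PX))
    elif connection is PairConnection.ROTATED_ILLUSORY:
        mid = r - INDUCER_DEPTH_PX / 2.0
        for center, sign in ((left, +1.0), (right, -1.0)):
            ang = rotation if sign > 0 else math.pi - rotation
            nx = center[0] + mid * math.cos(ang)
            ny = center[1] + mid * math.sin(ang)
            items.append(ItemSpec(Shape.ILLUSORY_INDUCER, (nx, ny),
                                  INDUCER_DEPTH_PX / 2.0, orientation=ang,
                                  weber_contrast=0.0, width=BAR_WIDTH_PX))
    return DisplaySpec(items, canvas, numerosity=2)


def _check_no_dot_overlap(bar_center: tuple[float, float], half_len: float,
                          ang: float, other_dot: tuple[float, float],
                          dot_radius: float) -> None:
    ends = []
    for s in (-1.0, 1.0):
        ends.append((bar_center[0] + s * half_len * math.cos(ang),
                     bar_center[1] + s * half_len * math.sin(ang)))
    for ex, ey in ends:
        if math.hypot(ex - other_dot[0], ey - other_dot[1]) < dot_radius:
            raise ValueError("rotated element overlaps the opposite dot")
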