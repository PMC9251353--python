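"""Random-dot stereogram synthesis.

A random-dot stereogram (RDS) hides a figure that is invisible to either
eye alone: both eyes see statistically identical dot fields, and only
the horizontal displacement of the figure region between the two eyes'
images carries the shape.  The construction here is the classic one —
start from a single random dot field, translate the figure region by
half the total pixel shift in opposite directions in the two eyes, and
refill the disoccluded strips with fresh dots drawn at the same density
so no first-order monocular cue (density, contour) survives.

Three stimulus items are provided, mirroring a clinical distance
stereotest: a *teaching* graph (one RDS circle next to a monocularly
visible outline circle of the same physical diameter, so a naive subject
can learn what to look for), a *screening* graph (three concentric
figures at coarse disparities, a "triple-layer cake", to rule out
stereoblindness), and per-level banks of ten figures for the
quantitative test.

Every generated pair carries a ground-truth disparity map: the total
horizontal pixel offset of corresponding content, referenced to left-eye
pixel positions, with refill/occlusion pixels flagged invalid.  This is
what end-to-end verification by independent block matching samples from.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._glyphs import GLYPH_COLS, GLYPH_ROWS, glyph_bitmap
from .geometry import (
    DisplayGeometry,
    DisparitySpec,
    extent_to_visual_angle,
    quantize_disparity,
    visual_angle_to_extent,
)

__all__ = [
    "CatalogueError",
    "EmptyMaskError",
    "GeometryError",
    "LayoutError",
    "ShapeSpec",
    "RDSParams",
    "RDSPair",
    "GEOMETRIC_SHAPES",
    "SHAPE_CATALOGUE",
    "DEFAULT_BANK_SHAPES",
    "make_shape_mask",
    "generate_rds",
    "generate_screening_item",
    "generate_teaching_item",
    "build_level_bank",
]


class CatalogueError(ValueError):
    """A shape id outside the closed stimulus catalogue."""


class EmptyMaskError(ValueError):
    """A shape rasterized to zero pixels (angular size too small)."""


class GeometryError(ValueError):
    """Stimulus does not fit the canvas with room for its shift."""


class LayoutError(ValueError):
    """Multi-region stimulus whose regions fail the required nesting."""


GEOMETRIC_SHAPES = ("circle", "square", "triangle", "rectangle", "cross", "pentagon")
LETTERS = tuple(chr(c) for c in range(ord("A"), ord("Z") + 1))
DIGITS = tuple(str(d) for d in range(10))
SHAPE_CATALOGUE = GEOMETRIC_SHAPES + LETTERS + DIGITS

#: The ten-figure bank used for each quantitative level: six geometric
#: figures, two letters, two digits.
DEFAULT_BANK_SHAPES = (
    "circle",
    "square",
    "triangle",
    "rectangle",
    "cross",
    "pentagon",
    "A",
    "E",
    "3",
    "7",
)


@dataclass(frozen=True)
class ShapeSpec:
    """A figure from the catalogue at an angular size and canvas position.

    ``center`` is in image-fraction coordinates ((0.5, 0.5) = canvas
    centre).  ``angular_size_deg`` is the overall extent (diameter / side
    / glyph height) as a visual angle at the configured distance.
    """

    shape_id: str
    angular_size_deg: float = 1.5
    center: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.shape_id not in SHAPE_CATALOGUE:
            raise CatalogueError(f"unknown shape_id {self.shape_id!r}")
        if self.angular_size_deg <= 0:
            raise ValueError(f"angular_size_deg must be positive, got {self.angular_size_deg}")


@dataclass(frozen=True)
class RDSParams:
    """Dot-field statistics and canvas for stereogram synthesis.

    dot_density is the probability that a dot cell takes the foreground
    value; dot_size the side of one square dot in pixels.  The defaults
    (0.5 density, 2-px black/white dots) maximise per-pixel entropy.
    ``canvas_px`` is (width, height); None means the full display
    resolution of the geometry in use.
    """

    dot_density: float = 0.5
    dot_size: int = 2
    canvas_px: tuple[int, int] | None = None
    background: int = 0
    foreground: int = 255
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dot_density < 1.0:
            raise ValueError(f"dot_density must be in (0, 1), got {self.dot_density}")
        if self.dot_size < 1:
            raise ValueError(f"dot_size must be >= 1, got {self.dot_size}")
        for v in (self.background, self.foreground):
            if not 0 <= v <= 255:
                raise ValueError(f"gray levels must be 8-bit, got {v}")


@dataclass(frozen=True)
class RDSPair:
    """A left/right random-dot image pair with full provenance.

    The metadata is sufficient to regenerate the rasters bit-exactly:
    the shapes, the quantized disparities and the dot parameters
    (including the seed) fully determine the generator's output.
    ``disparity_map``/``valid_map`` give the ground-truth total pixel
    offset at each left-eye pixel (invalid where occlusion refill makes
    disparity undefined).
    """

    left: np.ndarray
    right: np.ndarray
    shapes: tuple[ShapeSpec, ...]
    disparities: tuple[DisparitySpec, ...]
    params: RDSParams
    disparity_map: np.ndarray = field(repr=False, compare=False)
    valid_map: np.ndarray = field(repr=False, compare=False)
    created: str = field(default="", compare=False)

    def metadata(self) -> dict:
        """JSON-serialisable sidecar record for a rendered pair."""
        return {
            "created": self.created,
            "seed": self.params.seed,
            "dot_density": self.params.dot_density,
            "dot_size": self.params.dot_size,
            "canvas_px": list(self.left.shape[::-1]),
            "shapes": [
                {
                    "shape_id": s.shape_id,
                    "angular_size_deg": s.angular_size_deg,
                    "center": list(s.center),
                }
                for s in self.shapes
            ],
            "disparities": [
                {
                    "requested_arcsec": d.disparity_arcsec,
                    "achieved_arcsec": d.achieved_arcsec,
                    "shift_px_applied": d.shift_px_applied,
                    "sign": d.sign,
                    "quantization_warning": d.quantization_warning,
                }
                for d in self.disparities
            ],
        }

    def metadata_json(self) -> str:
        return json.dumps(self.metadata(), indent=2)


# ---------------------------------------------------------------------------
# shape rasterization


def _canvas_size(params: RDSParams, geom: DisplayGeometry) -> tuple[int, int]:
    return params.canvas_px if params.canvas_px is not None else geom.resolution_px


def _size_px(spec: ShapeSpec, geom: DisplayGeometry) -> float:
    size_mm = visual_angle_to_extent(spec.angular_size_deg, geom.viewing_distance_mm)
    return size_mm / geom.pixel_pitch_mm


def _convex_polygon_mask(
    verts: np.ndarray, width: int, height: int
) -> np.ndarray:
    """Rasterize a convex polygon by half-plane tests at pixel centres."""
    yy, xx = np.mgrid[0:height, 0:width]
    mask = np.ones((height, width), dtype=bool)
    n = len(verts)
    # orientation-agnostic: signed area fixes the interior side of each edge
    xs, ys = verts[:, 0], verts[:, 1]
    area2 = np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys)
    interior_sign = -1.0 if area2 < 0 else 1.0
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        cross = (x1 - x0) * (yy - y0) - (y1 - y0) * (xx - x0)
        mask &= interior_sign * cross >= 0
        if not mask.any():
            break
    return mask


def make_shape_mask(
    spec: ShapeSpec,
    geom: DisplayGeometry,
    canvas_px: tuple[int, int] | None = None,
) -> np.ndarray:
    """Rasterize a catalogue shape to a boolean mask on the canvas.

    Geometric figures are analytically rasterized (pixel-centre
    inclusion; squares and rectangles by integer slicing so an n-px
    square covers exactly n^2 pixels).  Letters and digits come from the
    embedded bitmap atlas scaled by whole-pixel replication, so their
    stroke width is size/7 pixels regardless of platform fonts.
    """
    width, height = canvas_px if canvas_px is not None else geom.resolution_px
    size = _size_px(spec, geom)
    if size < 1.0:
        raise EmptyMaskError(
            f"shape {spec.shape_id!r} at {spec.angular_size_deg} deg spans {size:.3f} px "
            "— below one pixel, so its mask would be empty"
        )
    cx, cy = spec.center[0] * width, spec.center[1] * height
    mask = np.zeros((height, width), dtype=bool)
    sid = spec.shape_id

    if sid == "circle":
        r = size / 2.0
        yy, xx = np.mgrid[0:height, 0:width]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    elif sid in ("square", "rectangle"):
        w = int(round(size))
        h = w if sid == "square" else int(round(0.6 * size))
        x0, y0 = int(round(cx - w / 2.0)), int(round(cy - h / 2.0))
        if x0 < 0 or y0 < 0 or x0 + w > width or y0 + h > height:
            raise GeometryError(f"{sid} of {w}x{h} px does not fit the canvas")
        mask[y0 : y0 + h, x0 : x0 + w] = True
    elif sid == "cross":
        arm = int(round(size))
        thick = max(1, int(round(size / 3.0)))
        x0, y0 = int(round(cx - arm / 2.0)), int(round(cy - thick / 2.0))
        mask[y0 : y0 + thick, x0 : x0 + arm] = True
        x0, y0 = int(round(cx - thick / 2.0)), int(round(cy - arm / 2.0))
        mask[y0 : y0 + arm, x0 : x0 + thick] = True
    elif sid == "triangle":
        # equilateral, apex up, height = size
        half_base = size / np.sqrt(3.0)
        verts = np.array(
            [
                (cx, cy - size / 2.0),
                (cx - half_base, cy + size / 2.0),
                (cx + half_base, cy + size / 2.0),
            ]
        )
        mask = _convex_polygon_mask(verts, width, height)
    elif sid == "pentagon":
        r = size / 2.0
        ang = -np.pi / 2.0 + 2.0 * np.pi * np.arange(5) / 5.0
        verts = np.stack([cx + r * np.cos(ang), cy + r * np.sin(ang)], axis=1)
        mask = _convex_polygon_mask(verts, width, height)
    elif sid in LETTERS or sid in DIGITS:
        scale = max(1, int(round(size / GLYPH_ROWS)))
        bitmap = np.kron(glyph_bitmap(sid), np.ones((scale, scale), dtype=bool))
        gh, gw = bitmap.shape
        y0, x0 = int(round(cy - gh / 2.0)), int(round(cx - gw / 2.0))
        if x0 < 0 or y0 < 0 or x0 + gw > width or y0 + gh > height:
            raise GeometryError(f"glyph {sid!r} of {gw}x{gh} px does not fit the canvas")
        mask[y0 : y0 + gh, x0 : x0 + gw] = bitmap
    else:  # pragma: no cover - ShapeSpec already validates
        raise CatalogueError(f"unknown shape_id {sid!r}")

    if not mask.any():
        raise EmptyMaskError(
            f"shape {sid!r} at {spec.angular_size_deg} deg rasterizes to an empty mask"
        )
    ys, xs = np.nonzero(mask)
    if ys[0] == 0 or xs.min() == 0 or ys[-1] == height - 1 or xs.max() == width - 1:
        raise GeometryError(f"shape {sid!r} touches the canvas border")
    return mask


# ---------------------------------------------------------------------------
# dot fields and region shifting


def _random_field(
    height: int, width: int, params: RDSParams, rng: np.random.Generator
) -> np.ndarray:
    """Random dot field with dot_size x dot_size square dots."""
    ds = params.dot_size
    ch, cw = -(-height // ds), -(-width // ds)
    cells = rng.random((ch, cw)) < params.dot_density
    field_ = np.where(cells, params.foreground, params.background).astype(np.uint8)
    if ds > 1:
        field_ = np.repeat(np.repeat(field_, ds, axis=0), ds, axis=1)
    return field_[:height, :width]


def _hshift(arr: np.ndarray, d: int) -> np.ndarray:
    """Shift columns by d (positive = rightward), filling with zeros/False."""
    if d == 0:
        return arr.copy()
    out = np.zeros_like(arr)
    if d > 0:
        out[:, d:] = arr[:, :-d]
    else:
        out[:, :d] = arr[:, -d:]
    return out


_BG, _REFILL = -1, -2


def _compose(
    base: np.ndarray,
    regions: Sequence[tuple[np.ndarray, DisparitySpec]],
    params: RDSParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Apply region shifts (outermost first) to a common base field.

    Returns (left, right, disparity_map, valid_map).  Each region's
    content is sampled from the *base* field at its own absolute
    half-shift, so an inner region overwrites an outer one with its own
    disparity rather than compounding.  Disoccluded pixels in either eye
    are refilled from a fresh, independent dot field of the same
    statistics.
    """
    height, width = base.shape
    left, right = base.copy(), base.copy()
    prov_l = np.full((height, width), _BG, dtype=np.int16)
    prov_r = np.full((height, width), _BG, dtype=np.int16)
    offsets: list[tuple[int, int]] = []

    for i, (mask, disp) in enumerate(regions):
        h = disp.half_shift_px
        direction = 1 if disp.sign == "crossed" else -1
        dl, dr = h * direction, -h * direction
        offsets.append((dl, dr))
        xs = np.flatnonzero(mask.any(axis=0))
        if xs.size and (xs[0] < abs(dl) or xs[-1] >= width - abs(dl)):
            raise GeometryError(
                f"region {i}: shift of {h} px pushes the mask off the canvas"
            )
        for img, prov, d in ((left, prov_l, dl), (right, prov_r, dr)):
            shifted = _hshift(mask, d)
            img[shifted] = _hshift(base, d)[shifted]
            prov[shifted] = i
            holes = mask & ~shifted
            if holes.any():
                fresh = _random_field(height, width, params, rng)
                img[holes] = fresh[holes]
                prov[holes] = _REFILL

    disparity_map = np.zeros((height, width), dtype=float)
    valid = (prov_l == _BG) & (prov_r == _BG)
    for i, (dl, dr) in enumerate(offsets):
        d = dl - dr
        # left pixel x pairs with right pixel x - d
        sel = (prov_l == i) & _hshift(prov_r == i, d)
        disparity_map[sel] = d
        valid |= sel
    return left, right, disparity_map, valid


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def generate_rds(
    mask: np.ndarray,
    disparity: DisparitySpec,
    params: RDSParams,
    shape: ShapeSpec | None = None,
) -> RDSPair:
    """Generate a single-figure stereogram pair from a mask.

    Deterministic in (mask, disparity, params): the same seed always
    yields bit-identical rasters.
    """
    rng = np.random.default_rng(params.seed)
    height, width = mask.shape
    base = _random_field(height, width, params, rng)
    left, right, dmap, valid = _compose(base, [(mask, disparity)], params, rng)
    return RDSPair(
        left=left,
        right=right,
        shapes=(shape,) if shape is not None else (),
        disparities=(disparity,),
        params=params,
        disparity_map=dmap,
        valid_map=valid,
        created=_now(),
    )


#: Default angular sizes (deg) of the screening figures, outermost first.
#: Chosen so circle > square > pentagon nest strictly after rasterization
#: and all three fit a 23-in screen seen at 5 m (about 5.8 x 3.3 deg).
SCREENING_SIZES_DEG = (2.8, 1.9, 1.0)
SCREENING_LEVELS_ARCSEC = (800.0, 1600.0, 2400.0)
SCREENING_SHAPES = ("circle", "square", "pentagon")


def generate_screening_item(
    geom: DisplayGeometry,
    params: RDSParams,
    levels_arcsec: Sequence[float] = SCREENING_LEVELS_ARCSEC,
    sizes_deg: Sequence[float] = SCREENING_SIZES_DEG,
) -> RDSPair:
    """The stereoblindness-screening graph: three concentric figures.

    A large circle, medium square and small pentagon share one centre
    ("triple-layer cake"), at coarse disparities increasing inward
    (defaults 800 / 1,600 / 2,400 arcsec).  Region shifts are applied
    outermost first, each relative to the base field, so each zone
    carries its own disparity.
    """
    if len(levels_arcsec) != 3 or len(sizes_deg) != 3:
        raise ValueError("screening item takes exactly three levels and sizes")
    if not all(a < b for a, b in zip(levels_arcsec, levels_arcsec[1:])):
        raise ValueError(f"screening levels must increase inward: {levels_arcsec}")
    width, height = _canvas_size(params, geom)
    shapes = tuple(
        ShapeSpec(sid, angular_size_deg=sz) for sid, sz in zip(SCREENING_SHAPES, sizes_deg)
    )
    masks = [make_shape_mask(s, geom, (width, height)) for s in shapes]
    for outer, inner, s in zip(masks, masks[1:], shapes[1:]):
        if (inner & ~outer).any() or inner.sum() >= outer.sum():
            raise LayoutError(f"screening figure {s.shape_id!r} is not strictly nested")
    disparities = tuple(quantize_disparity(lv, geom) for lv in levels_arcsec)

    rng = np.random.default_rng(params.seed)
    base = _random_field(height, width, params, rng)
    left, right, dmap, valid = _compose(base, list(zip(masks, disparities)), params, rng)
    return RDSPair(
        left=left,
        right=right,
        shapes=shapes,
        disparities=disparities,
        params=params,
        disparity_map=dmap,
        valid_map=valid,
        created=_now(),
    )


def generate_teaching_item(
    geom: DisplayGeometry,
    params: RDSParams,
    disparity_arcsec: float = 800.0,
    diameter_mm: float = 150.0,
    ring_stroke_px: int = 8,
) -> RDSPair:
    """The teaching graph: an RDS circle beside an outline circle.

    Both circles have the same physical diameter (default 15 cm).  The
    left one is a random-dot figure at the teaching disparity; the right
    one is a monocularly visible contour ring drawn identically into
    both eyes (zero disparity), so the subject knows what size of figure
    to look for before experiencing the stereoscopic one.
    """
    width, height = _canvas_size(params, geom)
    d_px = int(round(diameter_mm / geom.pixel_pitch_mm))
    r = d_px / 2.0
    disp = quantize_disparity(disparity_arcsec, geom)
    cx_rds, cx_ring, cy = width * 0.25, width * 0.75, height * 0.5
    h = disp.half_shift_px
    if (
        cx_rds - r - h < 0
        or cx_rds + r + h > width / 2.0
        or cx_ring + r >= width
        or cy - r < 0
        or cy + r >= height
    ):
        raise GeometryError(
            f"canvas {width}x{height} too small for two {d_px}-px circles side by side"
        )
    angular = extent_to_visual_angle(diameter_mm, geom.viewing_distance_mm)
    rds_shape = ShapeSpec("circle", angular_size_deg=angular, center=(0.25, 0.5))
    mask = make_shape_mask(rds_shape, geom, (width, height))

    rng = np.random.default_rng(params.seed)
    base = _random_field(height, width, params, rng)
    left, right, dmap, valid = _compose(base, [(mask, disp)], params, rng)

    yy, xx = np.mgrid[0:height, 0:width]
    ring = np.abs(np.hypot(xx - cx_ring, yy - cy) - r) <= ring_stroke_px / 2.0
    left[ring] = params.foreground
    right[ring] = params.foreground

    ring_shape = ShapeSpec("circle", angular_size_deg=angular, center=(0.75, 0.5))
    zero = quantize_disparity(0.0, geom)
    return RDSPair(
        left=left,
        right=right,
        shapes=(rds_shape, ring_shape),
        disparities=(disp, zero),
        params=params,
        disparity_map=dmap,
        valid_map=valid,
        created=_now(),
    )


def build_level_bank(
    level_arcsec: float,
    geom: DisplayGeometry,
    params: RDSParams,
    seed: int,
    bank_shapes: Sequence[str] = DEFAULT_BANK_SHAPES,
    angular_size_deg: float = 1.5,
) -> list[RDSPair]:
    """Ten distinct-figure stereograms at one disparity level.

    The figure *set* is fixed by ``bank_shapes`` (ten distinct catalogue
    ids spanning geometric figures, letters and digits); the seed
    controls the presentation order and every pair's dot field.
    """
    if len(bank_shapes) < 10 or len(set(bank_shapes)) != len(bank_shapes):
        raise CatalogueError(
            f"level bank needs >= 10 distinct shapes, got {list(bank_shapes)}"
        )
    for sid in bank_shapes:
        if sid not in SHAPE_CATALOGUE:
            raise CatalogueError(f"unknown shape_id {sid!r} in bank")
    rng = np.random.default_rng(seed)
    order = [bank_shapes[i] for i in rng.permutation(len(bank_shapes))[:10]]
    child_seeds = np.random.SeedSequence(seed).generate_state(10) >> 1  # keep < 2**31
    disp = quantize_disparity(level_arcsec, geom)
    pairs = []
    for sid, child in zip(order, child_seeds):
        shape = ShapeSpec(sid, angular_size_deg=angular_size_deg)
        mask = make_shape_mask(shape, geom, _canvas_size(params, geom))
        p = replace(params, seed=int(child))
        pairs.append(generate_rds(mask, disp, p, shape=shape))
    return pairs
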