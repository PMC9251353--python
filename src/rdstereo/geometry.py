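"""Display and viewing geometry for disparity-based stereotests.

Everything the rest of the package knows about the physical world lives
here: the screen's physical extent, its pixel grid, and the viewing
distance.  Binocular disparity is specified as a visual angle (arcsec);
on a flat display it is realised as a horizontal shift of image content
between the left- and right-eye images.  For a total on-screen shift
``s`` viewed from distance ``D`` the angular disparity is

    eta = 2 * atan(s / (2 * D))

and conversely ``s = 2 * D * tan(eta / 2)``.  The exact ``tan`` form is
used throughout rather than the small-angle approximation; at clinical
scales (tens to thousands of arcsec, metres of viewing distance) the two
agree to well under 0.01%, but the exact form costs nothing.

Because content can only be shifted by whole pixels, a requested
disparity is quantized: the exact real-valued pixel shift is rounded to
the nearest *even* integer so that it splits into an integral per-eye
half-shift, keeping the cyclopean position of the hidden figure fixed.
Both the requested and the achieved (post-quantization) disparity are
carried in :class:`DisparitySpec` so the caller never has to guess which
one a stimulus actually realised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "DisplayGeometry",
    "DisparitySpec",
    "PROFILES",
    "load_geometry",
    "arcsec_to_shift_mm",
    "shift_mm_to_arcsec",
    "shift_mm_to_px",
    "px_to_shift_mm",
    "shift_px_to_arcsec",
    "quantize_disparity",
    "extent_to_visual_angle",
    "visual_angle_to_extent",
]

ARCSEC_PER_RAD = 3600.0 * 180.0 / math.pi

#: Relative quantization error above which a warning flag is raised.
QUANTIZATION_WARN_REL = 0.10


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical and pixel model of a display plus the viewing distance.

    Parameters
    ----------
    diagonal_mm : float
        Physical diagonal of the active area, in mm (23 in = 584.2 mm).
    aspect_ratio : tuple of int
        Width:height aspect, e.g. ``(16, 9)``.
    resolution_px : tuple of int
        Horizontal x vertical pixel counts, e.g. ``(3840, 2160)``.
    viewing_distance_mm : float
        Eye-to-screen distance D, in mm.
    """

    diagonal_mm: float
    aspect_ratio: tuple[int, int] = (16, 9)
    resolution_px: tuple[int, int] = (3840, 2160)
    viewing_distance_mm: float = 5000.0

    def __post_init__(self) -> None:
        if self.diagonal_mm <= 0:
            raise ValueError(f"diagonal_mm must be positive, got {self.diagonal_mm}")
        if any(a <= 0 for a in self.aspect_ratio):
            raise ValueError(f"aspect_ratio components must be positive: {self.aspect_ratio}")
        if any(r <= 0 for r in self.resolution_px):
            raise ValueError(f"resolution_px components must be positive: {self.resolution_px}")
        if self.viewing_distance_mm <= 0:
            raise ValueError(
                f"viewing_distance_mm must be positive, got {self.viewing_distance_mm}"
            )

    @property
    def width_mm(self) -> float:
        aw, ah = self.aspect_ratio
        return self.diagonal_mm * aw / math.hypot(aw, ah)

    @property
    def height_mm(self) -> float:
        aw, ah = self.aspect_ratio
        return self.diagonal_mm * ah / math.hypot(aw, ah)

    @property
    def pixel_pitch_mm(self) -> float:
        """Horizontal pixel pitch (mm per pixel)."""
        return self.width_mm / self.resolution_px[0]

    def pixel_arcsec(self) -> float:
        """Angular subtense of one horizontal pixel at the viewing distance."""
        return shift_mm_to_arcsec(self.pixel_pitch_mm, self.viewing_distance_mm)


@dataclass(frozen=True)
class DisparitySpec:
    """A requested angular disparity and what the pixel grid actually yields.

    ``shift_px_applied`` is always even so each eye receives an integral
    half-shift of ``shift_px_applied // 2`` in opposite directions.
    ``sign`` is 'crossed' (figure floats in front of the screen, the
    default) or 'uncrossed' (behind).
    """

    disparity_arcsec: float
    sign: str
    shift_mm: float
    shift_px_exact: float
    shift_px_applied: int
    achieved_arcsec: float
    quantization_warning: bool = False

    def __post_init__(self) -> None:
        if self.sign not in ("crossed", "uncrossed"):
            raise ValueError(f"sign must be 'crossed' or 'uncrossed', got {self.sign!r}")
        if self.shift_px_applied % 2 != 0:
            raise ValueError("shift_px_applied must be even (it splits per eye)")

    @property
    def half_shift_px(self) -> int:
        return self.shift_px_applied // 2


def arcsec_to_shift_mm(disparity_arcsec: float, viewing_distance_mm: float) -> float:
    """Total on-screen shift s = 2 D tan(eta/2) realising a disparity."""
    if disparity_arcsec < 0:
        raise ValueError(f"disparity must be non-negative, got {disparity_arcsec}")
    if viewing_distance_mm <= 0:
        raise ValueError(f"viewing distance must be positive, got {viewing_distance_mm}")
    eta = disparity_arcsec / ARCSEC_PER_RAD
    return 2.0 * viewing_distance_mm * math.tan(eta / 2.0)


def shift_mm_to_arcsec(shift_mm: float, viewing_distance_mm: float) -> float:
    """Inverse of :func:`arcsec_to_shift_mm`."""
    if viewing_distance_mm <= 0:
        raise ValueError(f"viewing distance must be positive, got {viewing_distance_mm}")
    return 2.0 * math.atan(shift_mm / (2.0 * viewing_distance_mm)) * ARCSEC_PER_RAD


def shift_mm_to_px(shift_mm: float, geom: DisplayGeometry) -> float:
    """Convert a physical horizontal shift to a real-valued pixel count."""
    return shift_mm / geom.pixel_pitch_mm


def px_to_shift_mm(shift_px: float, geom: DisplayGeometry) -> float:
    return shift_px * geom.pixel_pitch_mm


def shift_px_to_arcsec(shift_px: float, geom: DisplayGeometry) -> float:
    return shift_mm_to_arcsec(px_to_shift_mm(shift_px, geom), geom.viewing_distance_mm)


def _nearest_even(x: float) -> int:
    # ties (exact odd integers) round up to the next even
    return 2 * math.floor(x / 2.0 + 0.5)


def quantize_disparity(
    disparity_arcsec: float, geom: DisplayGeometry, sign: str = "crossed"
) -> DisparitySpec:
    """Quantize a requested disparity to the display's pixel grid.

    The exact pixel shift is rounded to the nearest even integer (ties
    round up).  The achieved disparity is recomputed from the applied
    shift, and ``quantization_warning`` is set when the relative error
    exceeds 10% — the signal that this display/distance combination
    cannot meaningfully present the requested level.
    """
    shift_mm = arcsec_to_shift_mm(disparity_arcsec, geom.viewing_distance_mm)
    exact = shift_mm_to_px(shift_mm, geom)
    applied = _nearest_even(exact)
    achieved = shift_px_to_arcsec(applied, geom)
    warn = False
    if disparity_arcsec > 0:
        warn = abs(achieved - disparity_arcsec) / disparity_arcsec > QUANTIZATION_WARN_REL
    return DisparitySpec(
        disparity_arcsec=disparity_arcsec,
        sign=sign,
        shift_mm=shift_mm,
        shift_px_exact=exact,
        shift_px_applied=applied,
        achieved_arcsec=achieved,
        quantization_warning=warn,
    )


def extent_to_visual_angle(size_mm: float, viewing_distance_mm: float) -> float:
    """Visual angle (degrees) subtended by an extent viewed frontally."""
    if size_mm < 0:
        raise ValueError(f"size must be non-negative, got {size_mm}")
    if viewing_distance_mm <= 0:
        raise ValueError(f"viewing distance must be positive, got {viewing_distance_mm}")
    return math.degrees(2.0 * math.atan(size_mm / (2.0 * viewing_distance_mm)))


def visual_angle_to_extent(angle_deg: float, viewing_distance_mm: float) -> float:
    """Physical extent (mm) subtending a visual angle at a distance."""
    if angle_deg < 0:
        raise ValueError(f"angle must be non-negative, got {angle_deg}")
    if viewing_distance_mm <= 0:
        raise ValueError(f"viewing distance must be positive, got {viewing_distance_mm}")
    return 2.0 * viewing_distance_mm * math.tan(math.radians(angle_deg) / 2.0)


# ---------------------------------------------------------------------------
# profile / configuration-file handling

#: Named display profiles shipped with the package.  ``default`` is the
#: 23-in 4K autostereoscopic panel viewed at 5 m; ``laptop`` the 17.3-in
#: full-HD 3D notebook panel the software variant ran on.
PROFILES = {
    "default": "gfdrdss_23in_5m.cfg",
    "laptop": "laptop_17in_fhd.cfg",
}


def _parse_kv(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed geometry config line: {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        out[key] = val
    return out


def load_geometry(source: str | Path) -> DisplayGeometry:
    """Load a :class:`DisplayGeometry` from a profile name or config file.

    The plain-text format is ``key = value`` with ``#`` comments.  The
    screen may be given either as ``diagonal_mm`` + ``aspect_ratio``
    (``16:9``) or as ``width_mm`` + ``height_mm``; ``resolution_px`` is
    ``WxH`` and ``viewing_distance_mm`` a length.
    """
    if isinstance(source, str) and source in PROFILES:
        text = (
            resources.files("rdstereo").joinpath("data/profiles").joinpath(PROFILES[source]).read_text()
        )
    else:
        text = Path(source).read_text()
    kv = _parse_kv(text)

    if "resolution_px" not in kv or "viewing_distance_mm" not in kv:
        raise ValueError("geometry config needs resolution_px and viewing_distance_mm")
    rw, rh = (int(v) for v in kv["resolution_px"].lower().split("x"))
    distance = float(kv["viewing_distance_mm"])

    if "diagonal_mm" in kv:
        diagonal = float(kv["diagonal_mm"])
        aw, ah = (int(v) for v in kv.get("aspect_ratio", "16:9").split(":"))
    elif "width_mm" in kv and "height_mm" in kv:
        w, h = float(kv["width_mm"]), float(kv["height_mm"])
        diagonal = math.hypot(w, h)
        # reduce w:h to an integer ratio for the aspect field
        scale = 1000
        aw, ah = round(w * scale), round(h * scale)
        g = math.gcd(aw, ah)
        aw, ah = aw // g, ah // g
    else:
        raise ValueError("geometry config needs diagonal_mm or width_mm/height_mm")

    return DisplayGeometry(
        diagonal_mm=diagonal,
        aspect_ratio=(aw, ah),
        resolution_px=(rw, rh),
        viewing_distance_mm=distance,
    )
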