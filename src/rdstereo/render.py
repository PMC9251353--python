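"""Viewable stereo output formats for stereogram pairs.

The clinical device separates the two eyes' channels in hardware; on an
ordinary screen the pair has to be packed into a viewable file instead.
All outputs are lossless PNG — the stimulus *is* its dot pattern, so a
lossy format would corrupt it — and a side-by-side file splits back into
the original rasters bit-exactly.  The anaglyph mode is a red/cyan
preview aid (pure channel substitution, no ghosting compensation), not a
calibrated stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .rds import RDSPair

__all__ = [
    "RENDER_MODES",
    "RenderSpec",
    "render",
    "to_side_by_side",
    "to_anaglyph",
    "split_side_by_side",
]

RENDER_MODES = ("side_by_side", "anaglyph_red_cyan", "frame_sequence", "mono_left", "mono_right")


@dataclass(frozen=True)
class RenderSpec:
    """Output mode and path for :func:`render`.

    ``path`` is the target PNG; frame_sequence derives two files with
    ``_L``/``_R`` suffixes from it.  ``downscale`` shrinks both axes by
    an integer factor (aspect preserved) for previews.
    """

    mode: str
    path: str | Path
    downscale: int = 1

    def __post_init__(self) -> None:
        if self.mode not in RENDER_MODES:
            raise ValueError(f"mode must be one of {RENDER_MODES}, got {self.mode!r}")
        if self.downscale < 1:
            raise ValueError(f"downscale must be >= 1, got {self.downscale}")
        if Path(self.path).suffix.lower() != ".png":
            raise ValueError(
                f"only lossless PNG output is supported, got {Path(self.path).suffix!r}"
            )


def to_side_by_side(pair: RDSPair) -> np.ndarray:
    """Left and right rasters packed into one 2W-wide image."""
    return np.hstack([pair.left, pair.right])


def split_side_by_side(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_side_by_side`."""
    if image.shape[1] % 2 != 0:
        raise ValueError("side-by-side image must have even width")
    half = image.shape[1] // 2
    return image[:, :half].copy(), image[:, half:].copy()


def to_anaglyph(pair: RDSPair) -> np.ndarray:
    """Red/cyan packing: left eye in R, right eye in G and B."""
    return np.stack([pair.left, pair.right, pair.right], axis=-1)


def _maybe_downscale(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    return arr[::factor, ::factor]


def render(pair: RDSPair, spec: RenderSpec) -> list[Path]:
    """Write a pair to disk in the requested mode; returns written paths."""
    path = Path(spec.path)
    path.parent.mkdir(parents=True, exist_ok=True)
    f = spec.downscale
    if spec.mode == "side_by_side":
        arrays = {path: _maybe_downscale(to_side_by_side(pair), f)}
    elif spec.mode == "anaglyph_red_cyan":
        arrays = {path: _maybe_downscale(to_anaglyph(pair), f)}
    elif spec.mode == "frame_sequence":
        arrays = {
            path.with_name(path.stem + "_L" + path.suffix): _maybe_downscale(pair.left, f),
            path.with_name(path.stem + "_R" + path.suffix): _maybe_downscale(pair.right, f),
        }
    elif spec.mode == "mono_left":
        arrays = {path: _maybe_downscale(pair.left, f)}
    else:  # mono_right
        arrays = {path: _maybe_downscale(pair.right, f)}

    written = []
    for p, arr in arrays.items():
        Image.fromarray(arr).save(p, format="PNG")
        written.append(p)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(pair.metadata_json())
    return written
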