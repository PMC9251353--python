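"""Brute-force block matching for end-to-end stimulus verification.

The generator claims that a stereogram pair carries a given pixel
disparity inside the figure and zero outside.  This module checks that
claim by means that share nothing with the generator: exhaustive
horizontal sum-of-squared-differences matching between the two rasters.
For a left-eye block centred at (y, x) the recovered disparity is the
lag d minimising SSD between the left block and the right block at
(y, x - d); ties break toward the smallest |d|.

Disparity is undefined where occlusion refill replaced content, so
sampling locations are drawn from regions where the pair's ground-truth
map is valid and constant over the whole block.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import minimum_filter

from .rds import RDSPair

__all__ = ["block_match", "sample_block_centers", "verify_pair"]


def block_match(
    left: np.ndarray,
    right: np.ndarray,
    y: int,
    x: int,
    block: int = 16,
    max_shift: int = 200,
) -> int:
    """Recovered disparity at left-eye position (y, x).

    Convention: left[y, x] corresponds to right[y, x - d]; crossed
    (in-front) figures give d > 0 with the package's sign convention.
    """
    half = block // 2
    y0, y1 = y - half, y - half + block
    x0, x1 = x - half, x - half + block
    height, width = left.shape
    if y0 < 0 or y1 > height or x0 < 0 or x1 > width:
        raise ValueError(f"block at ({y}, {x}) exceeds the image")
    patch = left[y0:y1, x0:x1].astype(np.int32)
    lags = [d for d in range(-max_shift, max_shift + 1) if 0 <= x0 - d and x1 - d <= width]
    if not lags:
        raise ValueError("no admissible lag for this block position")
    best_d, best_ssd = 0, None
    for d in sorted(lags, key=abs):  # ties resolve to the smallest |d|
        cand = right[y0:y1, x0 - d : x1 - d].astype(np.int32)
        ssd = int(((patch - cand) ** 2).sum())
        if best_ssd is None or ssd < best_ssd:
            best_d, best_ssd = d, ssd
    return best_d


def sample_block_centers(
    region: np.ndarray,
    n: int,
    rng: np.random.Generator,
    block: int = 16,
) -> list[tuple[int, int]]:
    """Up to n pixel positions whose full block window lies in ``region``."""
    inner = minimum_filter(region.astype(np.uint8), size=block + 2, mode="constant") > 0
    ys, xs = np.nonzero(inner)
    if ys.size == 0:
        return []
    pick = rng.choice(ys.size, size=min(n, ys.size), replace=False)
    return [(int(ys[i]), int(xs[i])) for i in pick]


def verify_pair(
    pair: RDSPair,
    n_blocks: int = 12,
    block: int = 16,
    seed: int = 0,
    tol_px: int = 1,
) -> dict[float, list[int]]:
    """Block-match a pair at sampled positions for each true disparity.

    Returns {true_disparity_px: [recovered, ...]} over the distinct
    values of the pair's ground-truth map (0 included: the background),
    using only positions where the map is valid and constant across the
    block.  Raises AssertionError if any recovery misses by more than
    ``tol_px``.
    """
    rng = np.random.default_rng(seed)
    max_shift = int(np.abs(pair.disparity_map).max()) + 4
    out: dict[float, list[int]] = {}
    for value in np.unique(pair.disparity_map[pair.valid_map]):
        region = pair.valid_map & (pair.disparity_map == value)
        centers = sample_block_centers(region, n_blocks, rng, block=block)
        recovered = [
            block_match(pair.left, pair.right, y, x, block=block, max_shift=max_shift)
            for y, x in centers
        ]
        for r in recovered:
            if abs(r - value) > tol_px:
                raise AssertionError(
                    f"block matching recovered {r} px where ground truth is {value} px"
                )
        out[float(value)] = recovered
    return out
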