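"""tCENTRIST texture features: local ternary patterns in a census-transform
histogram scheme over a spatial pyramid.

A local ternary pattern compares each interior pixel p with its 8 neighbors
using a dead band of width +-t: a neighbor counts as "upper" when
n >= p + t and as "lower" when n <= p - t. The two resulting binary codes
(bits packed per neighbor) replace the census/LBP code of CENTRIST. The
descriptor is the concatenation, over a spatial pyramid of blocks, of the
L1-normalized 256-bin histograms of the upper and lower code maps.

Neighbor bit assignment (frozen for reproducibility): top-left, top,
top-right, right, bottom-right, bottom, bottom-left, left -> bits 0..7.
Code maps cover interior pixels only, so they are (H-2) x (W-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: (row offset, col offset) per bit, bits 0..7.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


@dataclass
class LTPConfig:
    """threshold: dead-band half width t on the 0-255 intensity scale;
    pyramid_levels: spatial pyramid levels, level l contributing a
    2^l x 2^l block grid."""

    threshold: int = 5
    pyramid_levels: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if len(self.pyramid_levels) == 0:
            raise ValueError("at least one pyramid level is required")
        self.pyramid_levels = tuple(sorted(set(int(l) for l in self.pyramid_levels)))
        if any(l < 0 for l in self.pyramid_levels):
            raise ValueError("pyramid levels must be non-negative")

    @property
    def n_blocks(self) -> int:
        return sum(4**l for l in self.pyramid_levels)

    @property
    def feature_length(self) -> int:
        """512 bins (upper + lower) per block."""
        return 512 * self.n_blocks


@dataclass
class LTPMaps:
    upper_codes: np.ndarray
    lower_codes: np.ndarray


@dataclass
class FeatureVector:
    values: np.ndarray
    block_layout: list[tuple[int, int, int, int]]  # (r0, r1, c0, c1), half-open


def compute_ltp_maps(image: np.ndarray, cfg: LTPConfig | None = None) -> LTPMaps:
    """Upper/lower LTP code maps of an intensity image.

    Thresholding works on differences, so the maps are invariant to a global
    additive intensity shift (absent clipping).
    """
    cfg = cfg or LTPConfig()
    img = np.asarray(image).astype(np.int16)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    t = cfg.threshold
    center = img[1:-1, 1:-1]
    upper = np.zeros(center.shape, dtype=np.uint8)
    lower = np.zeros(center.shape, dtype=np.uint8)
    h, w = img.shape
    for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neigh = img[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc]
        upper |= ((neigh >= center + t).astype(np.uint8)) << bit
        lower |= ((neigh <= center - t).astype(np.uint8)) << bit
    return LTPMaps(upper_codes=upper, lower_codes=lower)


def pyramid_blocks(shape: tuple[int, int], levels=(0, 1, 2)) -> list[tuple[int, int, int, int]]:
    """Block rectangles of the spatial pyramid over a code map of ``shape``.

    Level l is a 2^l x 2^l grid of equal blocks; division remainders are
    absorbed by the last row/column of blocks so every level tiles the map
    exactly. Rectangles are (r0, r1, c0, c1), half-open, level order
    ascending, row-major within a level.
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError("shape must be at least 1x1")
    blocks: list[tuple[int, int, int, int]] = []
    for level in sorted(set(levels)):
        g = 2**level
        if g > rows or g > cols:
            raise ValueError(f"pyramid level {level} needs a map of at least {g}x{g}")
        rstep, cstep = rows // g, cols // g
        for i in range(g):
            r0 = i * rstep
            r1 = rows if i == g - 1 else (i + 1) * rstep
            for j in range(g):
                c0 = j * cstep
                c1 = cols if j == g - 1 else (j + 1) * cstep
                blocks.append((r0, r1, c0, c1))
    return blocks


def block_histograms(maps: LTPMaps, blocks) -> FeatureVector:
    """Concatenated per-block histograms, upper then lower within each block.

    Each 256-bin sub-histogram is L1-normalized independently (an empty
    block would be left all-zero), which makes features comparable across
    unequal block sizes.
    """
    rows, cols = maps.upper_codes.shape
    parts: list[np.ndarray] = []
    for (r0, r1, c0, c1) in blocks:
        if not (0 <= r0 <= r1 <= rows and 0 <= c0 <= c1 <= cols):
            raise ValueError(f"block {(r0, r1, c0, c1)} is out of bounds for map {maps.upper_codes.shape}")
        for codes in (maps.upper_codes, maps.lower_codes):
            hist = np.bincount(codes[r0:r1, c0:c1].ravel(), minlength=256).astype(float)
            total = hist.sum()
            if total > 0:
                hist /= total
            parts.append(hist)
    return FeatureVector(values=np.concatenate(parts), block_layout=list(blocks))


def extract_tcentrist(image: np.ndarray, cfg: LTPConfig | None = None) -> FeatureVector:
    """Full descriptor of one image: LTP maps -> pyramid -> histograms.

    Deterministic; with the default 3-level pyramid (21 blocks) the vector
    has 512 x 21 = 10752 entries.
    """
    cfg = cfg or LTPConfig()
    maps = compute_ltp_maps(image, cfg)
    blocks = pyramid_blocks(maps.upper_codes.shape, cfg.pyramid_levels)
    return block_histograms(maps, blocks)
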