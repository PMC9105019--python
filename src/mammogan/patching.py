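"""Patch extraction, categorization, gradient maps, pyramids and targets.

Mammograms are tiled into fixed-size patches with a sliding window; each
patch is assigned to one of three categories from the fraction of
background in its (full-image OTSU) mask crop:

* background fraction == 1  ->  BACKGROUND (patch lies entirely outside
  the breast),
* background fraction == 0  ->  BREAST (no background at all),
* anything in between       ->  BOUNDARY.

The multi-scale discriminators do not see a patch directly: level l
(l = 1, 2, 3) receives the patch downsampled by 2**(l-1) concatenated with
the Sobel gradient-magnitude map of that downsampled image — the gradient
channel emphasizes weak edges (faded breast boundaries, tiny
calcifications) that a plain intensity critic misses.  Their training
targets are two-channel maps: a constant real/fake label plane and the
breast mask area-downsampled to the critic's output resolution.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import BreastMask, GrayscaleImage

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = SOBEL_X.T

#: Sobel responses are divided by 8 so a unit-slope ramp yields unit
#: magnitude, keeping the gradient channel on the same scale as intensities.
SOBEL_SCALE = 1.0 / 8.0


class PatchCategory(enum.Enum):
    BREAST = "breast"
    BOUNDARY = "boundary"
    BACKGROUND = "background"


@dataclass(frozen=True)
class Patch:
    pixels: np.ndarray
    mask: np.ndarray
    category: PatchCategory
    origin_rc: Tuple[int, int]
    side: int

    def __post_init__(self):
        if self.pixels.shape != (self.side, self.side):
            raise ValueError("patch pixels must be side x side")
        if self.mask.shape != self.pixels.shape:
            raise ValueError("patch mask must align with pixels")


@dataclass(frozen=True)
class ScalePyramid:
    """The three per-level [image, gradient] planes fed to the critics."""

    levels: Tuple[np.ndarray, ...]          # each (2, side/2**(l-1), ...)

    def __post_init__(self):
        if len(self.levels) != 3:
            raise ValueError("a scale pyramid has exactly 3 levels")
        side = self.levels[0].shape[-1]
        for l, lvl in enumerate(self.levels):
            if lvl.shape[0] != 2:
                raise ValueError("each level carries 2 channels")
            if lvl.shape[-1] != side // 2 ** l or lvl.shape[-2] != self.levels[0].shape[-2] // 2 ** l:
                raise ValueError("level sides must halve per level")


@dataclass(frozen=True)
class TargetMap:
    label_plane: np.ndarray
    mask_plane: np.ndarray
    level: int

    def __post_init__(self):
        if self.label_plane.shape != self.mask_plane.shape:
            raise ValueError("target planes must share a shape")
        if np.ptp(self.label_plane) != 0:
            raise ValueError("label plane must be constant")

    def stacked(self) -> np.ndarray:
        return np.stack([self.label_plane, self.mask_plane])


# ---------------------------------------------------------------------------

def background_fraction(patch_mask: np.ndarray) -> float:
    """Fraction of background (0) pixels in a binary mask crop."""
    m = np.asarray(patch_mask)
    return float((m == 0).sum() / m.size)


def categorize_patch(bg_fraction: float) -> PatchCategory:
    if not (0.0 <= bg_fraction <= 1.0):
        raise ValueError(f"background fraction {bg_fraction} outside [0, 1]")
    if bg_fraction == 1.0:
        return PatchCategory.BACKGROUND
    if bg_fraction == 0.0:
        return PatchCategory.BREAST
    return PatchCategory.BOUNDARY


def _anchors(dim: int, side: int, stride: int) -> List[int]:
    """Window anchors covering [0, dim): stride grid + edge-anchored last."""
    xs = list(range(0, dim - side + 1, stride))
    if xs[-1] != dim - side:
        xs.append(dim - side)
    return xs


def tile_sliding_window(img: GrayscaleImage, mask: BreastMask,
                        side: int = 256, stride: int = 256) -> List[Patch]:
    """Tile an image (and its mask) into categorized side x side patches.

    When a dimension is not a multiple of ``stride`` a final row/column of
    patches anchored to the image edge is added so the whole breast is
    covered.
    """
    H, W = img.shape
    if side > H or side > W:
        raise ValueError(f"patch side {side} exceeds image {img.shape}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if mask.mask.shape != img.shape:
        raise ValueError("mask must align with image")
    patches = []
    for r in _anchors(H, side, stride):
        for c in _anchors(W, side, stride):
            mcrop = mask.mask[r:r + side, c:c + side]
            cat = categorize_patch(background_fraction(mcrop))
            patches.append(Patch(img.pixels[r:r + side, c:c + side].copy(),
                                 mcrop.copy(), cat, (r, c), side))
    return patches


def sobel_gradient(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2), replicate borders.

    Scaled by 1/8 so a unit-slope ramp has unit magnitude; output shape
    equals input shape.
    """
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2 or min(a.shape) < 3:
        raise ValueError("sobel_gradient needs a 2-D image of at least 3x3")
    # centring is exact for a zero-sum kernel and keeps a constant image's
    # gradient at exactly zero instead of float residue
    a = a - a.flat[0]
    gx = ndimage.correlate(a, SOBEL_X, mode="nearest") * SOBEL_SCALE
    gy = ndimage.correlate(a, SOBEL_Y, mode="nearest") * SOBEL_SCALE
    return np.hypot(gx, gy)


def downsample_avg(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling by an integer factor (area interpolation)."""
    a = np.asarray(img, dtype=np.float64)
    if factor == 1:
        return a.copy()
    H, W = a.shape
    if H % factor or W % factor:
        raise ValueError(f"shape {a.shape} not divisible by {factor}")
    return a.reshape(H // factor, factor, W // factor, factor).mean(axis=(1, 3))


def downsample_area(mask: np.ndarray, out_shape: Tuple[int, int]) -> np.ndarray:
    """Area-style downsampling of a mask to an arbitrary shape, in [0, 1]."""
    m = np.asarray(mask, dtype=np.float64)
    H, W = m.shape
    oh, ow = out_shape
    if H % oh == 0 and W % ow == 0 and H // oh == W // ow:
        return downsample_avg(m, H // oh)
    zoom = (oh / H, ow / W)
    out = ndimage.zoom(m, zoom, order=1, mode="nearest", grid_mode=True)
    return np.clip(out, 0.0, 1.0)


def build_scale_pyramid(patch_pixels: np.ndarray) -> ScalePyramid:
    """Three [image, gradient] levels at sides s, s/2, s/4.

    The gradient map is computed AFTER downsampling at each level, not
    downsampled from the fine-scale gradient.
    """
    a = np.asarray(patch_pixels, dtype=np.float64)
    if a.shape[-1] % 4 or a.shape[-2] % 4:
        raise ValueError("patch sides must be divisible by 4")
    levels = []
    for l in range(3):
        img_l = downsample_avg(a, 2 ** l)
        levels.append(np.stack([img_l, sobel_gradient(img_l)]))
    return ScalePyramid(tuple(levels))


def make_target_map(i: int, mask: np.ndarray, level: int,
                    out_shape: Tuple[int, int]) -> TargetMap:
    """Two-channel critic target: constant label plane i + downsampled mask.

    ``i`` = 1 for real inputs, 0 for synthesized ones; the mask plane is the
    breast mask of the patch that produced the input (for a synthesized
    patch, the source patch's mask — the only spatially aligned mask there
    is), area-downsampled to the critic's level-``level`` output shape and
    therefore real-valued in [0, 1] at coarse scales.
    """
    if i not in (0, 1):
        raise ValueError("label i must be 0 or 1")
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    mask_plane = downsample_area(np.asarray(mask, dtype=np.float64), out_shape)
    label_plane = np.full(out_shape, float(i))
    return TargetMap(label_plane, mask_plane, level)


# ---------------------------------------------------------------------------
# persistence

def patch_index_frame(patches: Sequence[Patch], source_image: str,
                      domain: str) -> pd.DataFrame:
    rows = [{"origin_row": p.origin_rc[0], "origin_col": p.origin_rc[1],
             "side": p.side, "category": p.category.value,
             "source_image": source_image, "domain": domain}
            for p in patches]
    return pd.DataFrame(rows)


def save_patch_index(frame: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def load_patch_index(path) -> pd.DataFrame:
    return pd.read_csv(path)
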