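"""Whole-mammogram translation with a patch-trained generator.

Because the generator is fully convolutional (and normalization-free), the
weights trained on patches apply directly to whole images: a single forward
pass translates an entire film mammogram.  Sides only need reflect-padding
up to the next multiple of ``2**depth``.  For very large images an
overlap-tiled mode processes the image in tiles and keeps only each tile's
interior, trimming a margin no smaller than the receptive-field radius;
interior pixels agree with the single-pass result by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .autodiff import Tensor
from .image import Domain, GrayscaleImage
from .nn import UNetGenerator


@dataclass(frozen=True)
class CropRecord:
    rows: Tuple[int, int]
    cols: Tuple[int, int]


def pad_to_valid(img: GrayscaleImage, divisor: int):
    """Reflect-pad sides up to the next multiple of ``divisor``.

    Returns (padded image, crop record); cropping with the record inverts
    the padding exactly.
    """
    H, W = img.shape
    ph = (-H) % divisor
    pw = (-W) % divisor
    if ph == 0 and pw == 0:
        return img, CropRecord((0, H), (0, W))
    pixels = np.pad(img.pixels, [(0, ph), (0, pw)], mode="reflect")
    return (GrayscaleImage(pixels, img.spacing_mm, img.domain),
            CropRecord((0, H), (0, W)))


def crop(img: GrayscaleImage, rec: CropRecord) -> GrayscaleImage:
    r0, r1 = rec.rows
    c0, c1 = rec.cols
    return GrayscaleImage(img.pixels[r0:r1, c0:c1], img.spacing_mm, img.domain)


def _forward(gen: UNetGenerator, pixels: np.ndarray) -> np.ndarray:
    out = gen.forward(Tensor(pixels[None, None]))
    return out.data[0, 0]


def generate_sffdm(gen: UNetGenerator, dfm: GrayscaleImage,
                   strict: bool = False, tiled: bool = False,
                   tile: int = 512, margin: int = 64) -> GrayscaleImage:
    """Translate a film mammogram into a synthesized digital one.

    The input must be normalized to the training convention ([-1, 1]); a
    range outside [-1.5, 1.5] raises (strict) or warns.  Output shape,
    spacing and determinism follow the input; the domain tag becomes SFFDM.
    """
    lo, hi = float(dfm.pixels.min()), float(dfm.pixels.max())
    if lo < -1.5 or hi > 1.5:
        msg = (f"input range [{lo:.3g}, {hi:.3g}] outside the normalized "
               "[-1, 1] convention")
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    if abs(dfm.spacing_mm - 0.1) > 1e-9:
        import warnings

        warnings.warn(f"spacing {dfm.spacing_mm} mm differs from the 0.1 mm "
                      "training convention", stacklevel=2)
    div = 2 ** gen.depth
    padded, rec = pad_to_valid(dfm, div)
    if tiled:
        out = _tiled_forward(gen, padded.pixels, div, tile, margin)
    else:
        out = _forward(gen, padded.pixels)
    out = out[rec.rows[0]:rec.rows[1], rec.cols[0]:rec.cols[1]]
    return GrayscaleImage(out, dfm.spacing_mm, Domain.SFFDM)


def _tiled_forward(gen, pixels, div, tile, margin):
    """Overlap-tiled inference on a divisor-aligned canvas.

    Each tile's core is surrounded by at least ``margin`` pixels of real
    context (tile cuts are divisor-aligned and clamp to the canvas border,
    where both passes see the same edge), so with a margin no smaller than
    the receptive-field radius the kept interiors reproduce the single-pass
    output exactly.
    """
    H, W = pixels.shape
    if margin % div:
        margin += div - margin % div
    core = tile - 2 * margin
    if core < div:
        raise ValueError("tile too small for the requested margin")
    out = np.empty_like(pixels)
    for r0 in range(0, H, core):
        for c0 in range(0, W, core):
            r1, c1 = min(r0 + core, H), min(c0 + core, W)
            rs = max(0, r0 - margin) // div * div
            cs = max(0, c0 - margin) // div * div
            re = min(H, r1 + margin)
            re += (-re) % div
            ce = min(W, c1 + margin)
            ce += (-ce) % div
            res = _forward(gen, pixels[rs:re, cs:ce])
            out[r0:r1, c0:c1] = res[r0 - rs:r1 - rs, c0 - cs:c1 - cs]
    return out


def receptive_field_radius(gen: UNetGenerator) -> int:
    """Empirical receptive-field radius of the generator (one-sided).

    Measured by perturbing the centre pixel of a zero canvas and finding
    the farthest output pixel that changes; tile margins should be at
    least this value.
    """
    side = max(128, 2 ** gen.depth * 16)
    base = _forward(gen, np.zeros((side, side)))
    poked = np.zeros((side, side))
    poked[side // 2, side // 2] = 1.0
    diff = np.abs(_forward(gen, poked) - base) > 1e-12
    if not diff.any():
        return 0
    rr, cc = np.nonzero(diff)
    return int(max(np.abs(rr - side // 2).max(), np.abs(cc - side // 2).max()))
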