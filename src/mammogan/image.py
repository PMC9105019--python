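"""Mammogram containers, I/O, resampling, normalization and OTSU masking.

A mammogram here is a 2-D grayscale intensity array with a known isotropic
pixel spacing (mm per pixel edge) and a domain tag saying whether it is a
digitized screen-film mammogram (DFM), a native full-field digital
mammogram (FFDM), a synthesized FFDM, or one of the two phantom renderings.
Film and digital acquisitions differ mainly in contrast, boundary
visibility and edge sharpness; everything downstream (patching, training,
evaluation) consumes these containers.

The breast/background mask is obtained with OTSU thresholding over a
256-bin histogram: the threshold maximizing between-class variance.  The
dark-background convention (breast brighter than background) is asserted by
contract, not auto-detected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage


class Domain(enum.Enum):
    DFM = "dfm"
    FFDM = "ffdm"
    SFFDM = "sffdm"
    PHANTOM_FILM = "phantom_film"
    PHANTOM_DIGITAL = "phantom_digital"


class MetadataError(ValueError):
    """Required image metadata (pixel spacing) missing or unusable."""


class DegenerateInputError(ValueError):
    """Image content cannot support the requested operation."""


@dataclass(frozen=True)
class GrayscaleImage:
    """2-D intensity array + isotropic pixel spacing + domain tag."""

    pixels: np.ndarray
    spacing_mm: float
    domain: Domain = Domain.DFM

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not (self.spacing_mm > 0):
            raise ValueError("spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class BreastMask:
    """Binary breast (1) / background (0) mask aligned with its image."""

    mask: np.ndarray
    spacing_mm: float

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "mask", m.astype(np.uint8))


# ---------------------------------------------------------------------------
# I/O

def read_mammogram(path, format_hint=None, spacing_override=None,
                   domain=Domain.DFM) -> GrayscaleImage:
    """Read a DICOM / PNG / TIFF mammogram.

    Integer inputs of any bit depth are promoted to float64 without
    rescaling, so the full stored dynamic range is preserved.  DICOM files
    must carry ``PixelSpacing`` unless ``spacing_override`` is given;
    anisotropic DICOM spacing is rejected (resample explicitly instead).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = (format_hint or path.suffix.lstrip(".")).lower()
    if suffix in ("dcm", "dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array.astype(np.float64)
        if pixels.ndim != 2:
            raise MetadataError("multi-frame DICOM not supported")
        if spacing_override is not None:
            spacing = float(spacing_override)
        else:
            ps = getattr(ds, "PixelSpacing", None)
            if ps is None:
                raise MetadataError(f"{path} has no PixelSpacing and no "
                                    "override was supplied")
            r, c = float(ps[0]), float(ps[1])
            if abs(r - c) > 1e-9:
                raise MetadataError(
                    f"anisotropic PixelSpacing ({r}, {c}); resample explicitly")
            spacing = r
    else:
        import imageio.v3 as iio

        pixels = np.asarray(iio.imread(path)).astype(np.float64)
        if pixels.ndim == 3:          # collapse grayscale-saved-as-RGB
            pixels = pixels[..., 0]
        if spacing_override is None:
            raise MetadataError(f"{path}: PNG/TIFF carries no spacing; "
                                "supply spacing_override")
        spacing = float(spacing_override)
    return GrayscaleImage(pixels, spacing, domain)


def write_image_16bit(path, img: GrayscaleImage, lo=None, hi=None):
    """Write as 16-bit PNG/TIFF, linearly mapping [lo, hi] to [0, 65535].

    Returns the (lo, hi) window used so the mapping can be inverted.
    """
    import imageio.v3 as iio

    px = img.pixels
    lo = float(px.min()) if lo is None else float(lo)
    hi = float(px.max()) if hi is None else float(hi)
    if hi <= lo:
        hi = lo + 1.0
    scaled = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(Path(path), (scaled * 65535).round().astype(np.uint16))
    return lo, hi


def write_mask_png(path, mask: BreastMask):
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.mask * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# preprocessing

def resample_isotropic(img: GrayscaleImage, target_spacing_mm: float = 0.1
                       ) -> GrayscaleImage:
    """Resample to ``target_spacing_mm`` with bilinear interpolation.

    Output dimensions are ``round(dim * spacing / target)``; masks must go
    through :func:`resample_mask` instead so they stay binary.
    """
    if not (target_spacing_mm > 0):
        raise ValueError("target_spacing_mm must be positive")
    factor = img.spacing_mm / target_spacing_mm
    out_shape = tuple(int(round(d * factor)) for d in img.shape)
    if min(out_shape) < 1:
        raise DegenerateInputError(
            f"resampling {img.shape} by {factor:g} gives degenerate size")
    if out_shape == img.shape and abs(factor - 1.0) < 1e-12:
        return replace(img, spacing_mm=target_spacing_mm)
    zoom = [o / i for o, i in zip(out_shape, img.shape)]
    pixels = ndimage.zoom(img.pixels, zoom, order=1, mode="nearest",
                          grid_mode=True)
    return GrayscaleImage(pixels, target_spacing_mm, img.domain)


def resample_mask(mask: BreastMask, target_spacing_mm: float) -> BreastMask:
    """Nearest-neighbour resampling — masks stay strictly binary."""
    factor = mask.spacing_mm / target_spacing_mm
    out_shape = tuple(int(round(d * factor)) for d in mask.mask.shape)
    if min(out_shape) < 1:
        raise DegenerateInputError("mask resampling gives degenerate size")
    zoom = [o / i for o, i in zip(out_shape, mask.mask.shape)]
    m = ndimage.zoom(mask.mask, zoom, order=0, mode="nearest", grid_mode=True)
    return BreastMask(m, target_spacing_mm)


def normalize_intensity(img: GrayscaleImage, percentiles=(0.0, 100.0),
                        strict=False) -> GrayscaleImage:
    """Linearly map the [p_low, p_high] percentile window onto [-1, 1].

    Values outside the window are clipped.  The default window is min-max;
    tighter percentiles help with specular outliers on film scans.  A
    constant image maps to all zeros unless ``strict``.
    """
    px = img.pixels
    lo, hi = np.percentile(px, percentiles)
    if hi <= lo:
        if strict:
            raise DegenerateInputError("constant image cannot be normalized")
        return GrayscaleImage(np.zeros_like(px), img.spacing_mm, img.domain)
    out = np.clip(2.0 * (px - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    return GrayscaleImage(out, img.spacing_mm, img.domain)


def otsu_threshold(pixels: np.ndarray, nbins: int = 256) -> float:
    """OTSU threshold over ``nbins`` uniform bins spanning the image range.

    Returns the bin-centre threshold t maximizing the between-class
    variance  w0(t) * w1(t) * (mu0(t) - mu1(t))^2 ; pixels strictly above t
    are foreground.
    """
    px = np.asarray(pixels, dtype=np.float64).ravel()
    lo, hi = px.min(), px.max()
    if hi <= lo:
        raise DegenerateInputError("constant image has no OTSU threshold")
    hist, edges = np.histogram(px, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    between[~np.isfinite(between)] = -np.inf
    return float(centers[int(np.argmax(between))])


def otsu_breast_mask(img: GrayscaleImage, keep_largest: bool = True
                     ) -> BreastMask:
    """Breast mask by OTSU thresholding of the whole mammogram.

    Applied to the full (resampled) mammogram before tiling; per-patch
    thresholds would be unstable on background-only patches.  Foreground is
    the above-threshold class — the caller must ensure the dark-background
    convention.  ``keep_largest`` retains only the largest connected
    foreground component (default on), discarding labels, dust and specks
    outside the breast.
    """
    t = otsu_threshold(img.pixels)
    fg = img.pixels > t
    if keep_largest and fg.any():
        labels, n = ndimage.label(fg)
        if n > 1:
            sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
            fg = labels == (1 + int(np.argmax(sizes)))
    return BreastMask(fg.astype(np.uint8), img.spacing_mm)
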