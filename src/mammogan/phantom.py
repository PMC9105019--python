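"""Two-domain mammogram phantoms with ground truth.

Each phantom anatomy is a half-elliptical breast (chest wall at the left
edge, a small nipple bump at the tip) filled with smooth low-frequency
tissue texture, optional soft-edged bright blobs standing in for masses,
and a few 1-3 px bright specks standing in for micro-calcifications.  The
same anatomy is rendered twice:

* film-like: contrast-compressed, Gaussian-blurred, boundary faded into
  the background, correlated film-grain noise — the faded, low-contrast
  look of a digitized screen film;
* digital-like: full contrast, unsharp-mask edge enhancement, mild pixel
  noise — the crisp look of a native digital acquisition.

The realism target is statistical, not anatomical: the two renderings must
differ measurably in foreground contrast and boundary edge energy so the
categorization, pairing, gradient and loss machinery has a real domain gap
to close, while ground-truth masks and lesion coordinates make every
downstream check exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import BreastMask, Domain, GrayscaleImage, normalize_intensity, otsu_breast_mask
from .patching import Patch, tile_sliding_window


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, lesion load and acquisition parameters for one phantom.

    Defaults give a 256x512 canvas at a nominal 0.1 mm spacing; the tiny
    preset (:func:`tiny_spec`) shrinks everything for fast desk-scale
    training runs.  The film contrast scale must stay below the digital one
    — the simulated domain gap encodes that digital acquisitions have the
    better contrast.
    """

    canvas: Tuple[int, int] = (256, 512)
    spacing_mm: float = 0.1
    semi_axes_frac: Tuple[float, float] = (0.42, 0.72)   # of (rows, cols)
    n_masses: Tuple[int, int] = (1, 3)
    mass_radius_px: Tuple[int, int] = (8, 16)
    n_calcs: Tuple[int, int] = (3, 8)
    calc_radius_px: Tuple[int, int] = (1, 3)
    film_contrast: float = 0.45
    film_blur_sigma: float = 1.2
    film_noise_sd: float = 0.02
    film_boundary_fade: float = 2.5
    digital_contrast: float = 1.0
    digital_edge_sharpness: float = 0.8
    digital_noise_sd: float = 0.01
    patch_side: int = 64
    patch_stride: int = 32
    seed: int = 0

    def __post_init__(self):
        if not self.film_contrast < self.digital_contrast:
            raise ValueError("film contrast must be below digital contrast")
        if self.calc_radius_px[0] < 1 or self.calc_radius_px[1] > 3:
            raise ValueError("calcification radius must stay in 1-3 px")


def tiny_spec(**overrides) -> PhantomSpec:
    """Desk-scale preset: 64x128 canvas, 32 px patches."""
    base = dict(canvas=(64, 128), mass_radius_px=(6, 10), n_calcs=(2, 5),
                patch_side=32, patch_stride=16, film_blur_sigma=0.9)
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass(frozen=True)
class PhantomSample:
    film_image: GrayscaleImage
    digital_image: GrayscaleImage
    mask: BreastMask
    mass_polygons: List[np.ndarray]          # each (K, 2) of (row, col)
    mass_disks: List[Tuple[float, float, float]]   # (row, col, radius)
    calc_points: List[Tuple[int, int]]
    anatomy_id: int = 0


def _breast_mask(spec: PhantomSpec, rng) -> np.ndarray:
    rows, cols = spec.canvas
    cy = rows / 2.0 + rng.uniform(-0.03, 0.03) * rows
    a = spec.semi_axes_frac[0] * rows * rng.uniform(0.9, 1.0)
    b = spec.semi_axes_frac[1] * cols * rng.uniform(0.9, 1.0)
    rr, cc = np.mgrid[0:rows, 0:cols]
    ellipse = ((rr - cy) / a) ** 2 + (cc / b) ** 2 <= 1.0
    # nipple: small bump at the ellipse tip
    nip_r = max(2, int(round(0.04 * rows)))
    bump = (rr - cy) ** 2 + (cc - b) ** 2 <= nip_r ** 2
    return (ellipse | bump).astype(np.uint8)


def _place_inside(mask: np.ndarray, margin: int, rng, max_tries=200):
    interior = ndimage.binary_erosion(mask.astype(bool),
                                      iterations=max(1, margin))
    coords = np.argwhere(interior)
    if coords.size == 0:
        raise RuntimeError("phantom lesion placement failed: no interior")
    for _ in range(max_tries):
        r, c = coords[rng.integers(len(coords))]
        return int(r), int(c)
    raise RuntimeError("phantom lesion placement failed")


def make_phantom(spec: PhantomSpec, rng: Optional[np.random.Generator] = None,
                 anatomy_id: int = 0) -> PhantomSample:
    """Render one anatomy in both acquisition domains.

    Deterministic given the generator state: the same seeded ``rng`` gives
    byte-identical samples.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows, cols = spec.canvas
    mask = _breast_mask(spec, rng)

    # smooth tissue texture: low-frequency random field
    texture = ndimage.gaussian_filter(rng.standard_normal((rows, cols)),
                                      sigma=max(rows, cols) / 24.0)
    sd = texture.std()
    texture = 0.12 * texture / (sd if sd > 0 else 1.0)
    anatomy = (0.55 + texture) * mask

    rr, cc = np.mgrid[0:rows, 0:cols]
    mass_polygons, mass_disks = [], []
    n_mass = int(rng.integers(spec.n_masses[0], spec.n_masses[1] + 1))
    for _ in range(n_mass):
        rad = int(rng.integers(spec.mass_radius_px[0], spec.mass_radius_px[1] + 1))
        r, c = _place_inside(mask, rad + 2, rng)
        blob = 0.30 * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * (rad / 2.0) ** 2))
        anatomy += blob * mask
        theta = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        mass_polygons.append(np.stack([r + rad * np.sin(theta),
                                       c + rad * np.cos(theta)], axis=1))
        mass_disks.append((float(r), float(c), float(rad)))

    calc_points = []
    n_calc = int(rng.integers(spec.n_calcs[0], spec.n_calcs[1] + 1))
    for _ in range(n_calc):
        rad = int(rng.integers(spec.calc_radius_px[0], spec.calc_radius_px[1] + 1))
        r, c = _place_inside(mask, rad + 1, rng)
        speck = (rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2
        anatomy[speck] += 0.6
        calc_points.append((int(r), int(c)))

    anatomy = np.clip(anatomy, 0.0, 1.5)

    # digital rendering: full contrast, sharpened edges, mild noise
    sharp = anatomy + spec.digital_edge_sharpness * (
        anatomy - ndimage.gaussian_filter(anatomy, 1.0))
    digital = spec.digital_contrast * sharp \
        + spec.digital_noise_sd * rng.standard_normal((rows, cols))

    # film rendering: compressed contrast, faded boundary, blur, film grain
    fade = ndimage.gaussian_filter(mask.astype(np.float64),
                                   spec.film_boundary_fade)
    film = spec.film_contrast * anatomy * fade
    film = ndimage.gaussian_filter(film, spec.film_blur_sigma)
    grain = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 0.7)
    gsd = grain.std()
    film = film + 0.02 + spec.film_noise_sd * grain / (gsd if gsd > 0 else 1.0)

    return PhantomSample(
        film_image=GrayscaleImage(film, spec.spacing_mm, Domain.PHANTOM_FILM),
        digital_image=GrayscaleImage(digital, spec.spacing_mm,
                                     Domain.PHANTOM_DIGITAL),
        mask=BreastMask(mask, spec.spacing_mm),
        mass_polygons=mass_polygons,
        mass_disks=mass_disks,
        calc_points=calc_points,
        anatomy_id=anatomy_id,
    )


def mass_mask(sample: PhantomSample) -> np.ndarray:
    """Rasterize the mass annotations into a binary lesion mask."""
    rows, cols = sample.mask.mask.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    out = np.zeros((rows, cols), dtype=np.uint8)
    for r, c, rad in sample.mass_disks:
        out[(rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2] = 1
    return out


def foreground_iqr(img: GrayscaleImage, mask: BreastMask) -> float:
    """Interquartile intensity range inside the breast — the contrast
    statistic used to measure the film/digital domain gap."""
    fg = img.pixels[mask.mask.astype(bool)]
    q75, q25 = np.percentile(fg, [75, 25])
    return float(q75 - q25)


@dataclass
class PhantomDataset:
    """Unpaired patch pools plus held-out ground truth.

    Film patches come from the first half of the anatomies and digital
    patches from the second half, so the two pools share no anatomy — the
    same unpaired situation as two disjoint clinical archives.
    """

    samples: List[PhantomSample]
    film_ids: List[int]
    digital_ids: List[int]
    film_pool: List[Patch] = field(default_factory=list)
    digital_pool: List[Patch] = field(default_factory=list)
    film_pool_ids: List[int] = field(default_factory=list)
    digital_pool_ids: List[int] = field(default_factory=list)
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)


def _pool_patches(sample: PhantomSample, which: str, spec: PhantomSpec):
    img = sample.film_image if which == "film" else sample.digital_image
    norm = normalize_intensity(img)
    mask = otsu_breast_mask(norm)
    return tile_sliding_window(norm, mask, side=spec.patch_side,
                               stride=spec.patch_stride)


def make_phantom_dataset(n: int, spec: PhantomSpec, out_dir=None,
                         seed: int = 0) -> PhantomDataset:
    """Generate ``n`` anatomies and build the unpaired training pools.

    Pools use the pipeline's own OTSU masks (not the ground truth) for
    patch categorization, exactly as real mammograms would; ground-truth
    masks and lesion annotations ride along for evaluation.  With
    ``out_dir`` set, images, masks and index/annotation tables are written
    as 16-bit PNGs and CSVs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [make_phantom(spec, rng, anatomy_id=i) for i in range(n)]
    film_ids = list(range(0, n // 2)) if n > 1 else [0]
    digital_ids = list(range(n // 2, n)) if n > 1 else [0]

    ds = PhantomDataset(samples, film_ids, digital_ids)
    for i in film_ids:
        patches = _pool_patches(samples[i], "film", spec)
        ds.film_pool.extend(patches)
        ds.film_pool_ids.extend([i] * len(patches))
    for i in digital_ids:
        patches = _pool_patches(samples[i], "digital", spec)
        ds.digital_pool.extend(patches)
        ds.digital_pool_ids.extend([i] * len(patches))

    rows = []
    for s in ds.samples:
        for (r, c, rad) in s.mass_disks:
            rows.append({"anatomy_id": s.anatomy_id, "kind": "mass",
                         "row": r, "col": c, "radius_px": rad})
        for (r, c) in s.calc_points:
            rows.append({"anatomy_id": s.anatomy_id, "kind": "calcification",
                         "row": r, "col": c, "radius_px": np.nan})
    ds.annotations = pd.DataFrame(rows)

    if out_dir is not None:
        _write_dataset(ds, spec, Path(out_dir))
    return ds


def _write_dataset(ds: PhantomDataset, spec: PhantomSpec, out_dir: Path):
    from .image import write_image_16bit, write_mask_png
    from .patching import patch_index_frame

    out_dir.mkdir(parents=True, exist_ok=True)
    for s in ds.samples:
        write_image_16bit(out_dir / f"anatomy{s.anatomy_id:03d}_film.png",
                          s.film_image)
        write_image_16bit(out_dir / f"anatomy{s.anatomy_id:03d}_digital.png",
                          s.digital_image)
        write_mask_png(out_dir / f"anatomy{s.anatomy_id:03d}_mask.png", s.mask)
    ds.annotations.to_csv(out_dir / "annotations.csv", index=False)
    frames = []
    for pool, ids, dom in ((ds.film_pool, ds.film_pool_ids, "phantom_film"),
                           (ds.digital_pool, ds.digital_pool_ids,
                            "phantom_digital")):
        for p, aid in zip(pool, ids):
            frames.append(patch_index_frame([p], f"anatomy{aid:03d}", dom))
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / "patch_index.csv", index=False)
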