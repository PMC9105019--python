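"""I/O, resampling, normalization and OTSU masking."""

import numpy as np
import pytest

from mammogan.image import (BreastMask, DegenerateInputError, Domain,
                            GrayscaleImage, MetadataError, normalize_intensity,
                            otsu_breast_mask, otsu_threshold, read_mammogram,
                            resample_isotropic, resample_mask,
                            write_image_16bit)


def _brute_force_otsu(pixels, nbins=256):
    """Exhaustive search over all bin-centre thresholds, maximizing the
    between-class variance computed directly (no cumulative-sum shortcut)."""
    px = pixels.ravel()
    hist, edges = np.histogram(px, bins=nbins, range=(px.min(), px.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = hist.sum()
    best_t, best_v = None, -np.inf
    for i in range(nbins):
        n0 = hist[:i + 1].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[:i + 1] * centers[:i + 1]).sum() / n0
        mu1 = (hist[i + 1:] * centers[i + 1:]).sum() / n1
        v = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[i]
    return best_t


class TestOtsu:
    def test_matches_exhaustive_search_on_random_images(self, rng):
        for _ in range(50):
            px = rng.uniform(0, rng.uniform(1, 4096), size=(64, 64))
            assert otsu_threshold(px) == pytest.approx(
                _brute_force_otsu(px), abs=1e-12)

    def test_two_population_image_separates_exactly(self, rng):
        px = np.full(1000, 10.0)
        px[:400] = 200.0
        rng.shuffle(px)
        img = GrayscaleImage(px.reshape(25, 40), 0.1)
        mask = otsu_breast_mask(img, keep_largest=False)
        np.testing.assert_array_equal(mask.mask, (img.pixels > 10).astype(np.uint8))

    def test_recovers_disk_foreground(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = ((rr - 32) ** 2 + (cc - 32) ** 2 <= 20 ** 2)
        img = GrayscaleImage(disk * 1.0, 0.1)
        mask = otsu_breast_mask(img)
        np.testing.assert_array_equal(mask.mask, disk.astype(np.uint8))

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_breast_mask(GrayscaleImage(np.ones((8, 8)), 0.1))

    def test_keep_largest_drops_specks(self):
        px = np.zeros((32, 32))
        px[4:20, 4:20] = 1.0      # breast
        px[28, 28] = 1.0          # dust
        mask = otsu_breast_mask(GrayscaleImage(px, 0.1), keep_largest=True)
        assert mask.mask[28, 28] == 0 and mask.mask[10, 10] == 1

    def test_bright_background_still_selects_above_threshold(self):
        # documented behavior: foreground is always the above-threshold class
        px = np.full((16, 16), 200.0)
        px[4:12, 4:12] = 10.0
        mask = otsu_breast_mask(GrayscaleImage(px, 0.1))
        assert mask.mask[0, 0] == 1 and mask.mask[8, 8] == 0


class TestResample:
    def test_factor_two_arithmetic(self):
        img = GrayscaleImage(np.zeros((400, 300)), 0.05)
        out = resample_isotropic(img, 0.1)
        assert out.shape == (200, 150) and out.spacing_mm == 0.1

    def test_identity_spacing_is_noop(self, rng):
        img = GrayscaleImage(rng.normal(size=(37, 53)), 0.1)
        out = resample_isotropic(img, 0.1)
        assert out.shape == img.shape
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_downsample_to_segmentation_resolution(self):
        img = GrayscaleImage(np.zeros((100, 100)), 0.1)
        assert resample_isotropic(img, 0.4).shape == (25, 25)

    @pytest.mark.parametrize("shape,s0,s1", [
        ((128, 96), 0.1, 0.05), ((50, 70), 0.2, 0.1), ((33, 47), 0.1, 0.07)])
    def test_round_trip_shape_identity(self, rng, shape, s0, s1):
        img = GrayscaleImage(rng.normal(size=shape), s0)
        back = resample_isotropic(resample_isotropic(img, s1), s0)
        assert back.shape == img.shape

    def test_mask_resampling_stays_binary(self, rng):
        m = BreastMask((rng.uniform(size=(40, 40)) > 0.5).astype(np.uint8), 0.1)
        out = resample_mask(m, 0.17)
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_degenerate_target_rejected(self):
        img = GrayscaleImage(np.zeros((4, 4)), 0.1)
        with pytest.raises(DegenerateInputError):
            resample_isotropic(img, 100.0)


class TestNormalize:
    def test_minmax_endpoints(self):
        img = GrayscaleImage(np.array([[0.0, 2000.0], [4095.0, 1000.0]]), 0.1)
        out = normalize_intensity(img)
        assert out.pixels.min() == -1.0 and out.pixels.max() == 1.0

    def test_midpoint_linear(self):
        img = GrayscaleImage(np.array([[0.0, 100.0, 200.0]]), 0.1)
        np.testing.assert_allclose(normalize_intensity(img).pixels,
                                   [[-1.0, 0.0, 1.0]])

    def test_idempotent(self, rng):
        img = GrayscaleImage(rng.uniform(0, 4096, size=(32, 32)), 0.1)
        once = normalize_intensity(img)
        twice = normalize_intensity(once)
        np.testing.assert_allclose(once.pixels, twice.pixels, atol=1e-12)

    def test_constant_image_modes(self):
        img = GrayscaleImage(np.full((4, 4), 7.0), 0.1)
        assert np.all(normalize_intensity(img).pixels == 0.0)
        with pytest.raises(DegenerateInputError):
            normalize_intensity(img, strict=True)

    def test_percentile_window_clips(self, rng):
        px = rng.uniform(0, 100, size=(50, 50))
        px[0, 0] = 1e6                      # specular outlier
        out = normalize_intensity(GrayscaleImage(px, 0.1), percentiles=(1, 99))
        assert out.pixels.max() == 1.0 and out.pixels[0, 0] == 1.0


class TestIO:
    def test_png_16bit_roundtrip_with_spacing_override(self, tmp_path, rng):
        img = GrayscaleImage(rng.uniform(0, 1, size=(20, 30)), 0.05)
        path = tmp_path / "m.png"
        write_image_16bit(path, img)
        back = read_mammogram(path, spacing_override=0.05)
        assert back.spacing_mm == 0.05 and back.shape == (20, 30)
        # 16-bit quantization error only
        scaled = (img.pixels - img.pixels.min()) / np.ptp(img.pixels)
        np.testing.assert_allclose(back.pixels / 65535, scaled, atol=1e-4)

    def test_png_without_spacing_rejected(self, tmp_path, rng):
        img = GrayscaleImage(rng.uniform(size=(8, 8)), 0.1)
        path = tmp_path / "m.png"
        write_image_16bit(path, img)
        with pytest.raises(MetadataError):
            read_mammogram(path)

    def _write_dicom(self, path, spacing):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Rows, ds.Columns = 10, 12
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.arange(120, dtype=np.uint16).tobytes()
        if spacing is not None:
            ds.PixelSpacing = list(spacing)
        ds.save_as(path, enforce_file_format=True)

    def test_dicom_spacing_metadata_copied(self, tmp_path):
        path = tmp_path / "a.dcm"
        self._write_dicom(path, (0.07, 0.07))
        img = read_mammogram(path)
        assert img.spacing_mm == pytest.approx(0.07)
        assert img.pixels[0, 1] == 1.0

    def test_dicom_anisotropic_rejected_without_override(self, tmp_path):
        path = tmp_path / "b.dcm"
        self._write_dicom(path, (0.05, 0.07))
        with pytest.raises(MetadataError):
            read_mammogram(path)
        assert read_mammogram(path, spacing_override=0.05).spacing_mm == 0.05

    def test_dicom_missing_spacing(self, tmp_path):
        path = tmp_path / "c.dcm"
        self._write_dicom(path, None)
        with pytest.raises(MetadataError):
            read_mammogram(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            read_mammogram(tmp_path / "nope.png", spacing_override=0.1)


def test_grayscale_image_invariants():
    with pytest.raises(ValueError):
        GrayscaleImage(np.zeros((0, 4)), 0.1)
    with pytest.raises(ValueError):
        GrayscaleImage(np.zeros((4, 4)), -1.0)
    img = GrayscaleImage(np.zeros((4, 4)), 0.1, Domain.FFDM)
    assert img.domain is Domain.FFDM
    with pytest.raises(ValueError):
        BreastMask(np.full((4, 4), 2), 0.1)
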