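"""ENVI I/O round-trips, empirical-line correction, ROI extraction."""

import numpy as np
import pytest

from hypyield.errors import DataError, DimensionError, FormatError
from hypyield.hsi_io import (
    ElmCoefficients,
    ROPSet,
    SpectralCube,
    empirical_line_correct,
    extract_roi,
    mean_spectrum,
    read_envi_cube,
    read_mask_png,
    read_mask_rle,
    rop_features,
    wavelength_to_channel,
    write_envi_cube,
    write_mask_png,
    write_mask_rle,
)


def _cube(rng, shape=(4, 5, 6), dtype=np.float32, unit="dn"):
    values = rng.random(shape).astype(dtype)
    wl = np.linspace(400, 1000, shape[2])
    return SpectralCube(values=values, wavelengths=wl, unit_state=unit)


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    @pytest.mark.parametrize("dtype", [np.float32, np.uint16])
    def test_round_trip_lossless(self, tmp_path, rng, interleave, dtype):
        values = (rng.random((3, 4, 5)) * 100).astype(dtype)
        cube = SpectralCube(values, np.linspace(400, 1000, 5))
        hdr = tmp_path / f"c_{interleave}.hdr"
        write_envi_cube(cube, hdr, interleave=interleave)
        back = read_envi_cube(hdr)
        assert np.array_equal(back.values, cube.values)
        assert np.allclose(back.wavelengths, cube.wavelengths)
        assert back.unit_state == "dn"

    def test_bsq_and_bil_store_same_array(self, tmp_path, rng):
        cube = _cube(rng)
        write_envi_cube(cube, tmp_path / "a.hdr", interleave="bsq")
        write_envi_cube(cube, tmp_path / "b.hdr", interleave="bil")
        a = read_envi_cube(tmp_path / "a.hdr")
        b = read_envi_cube(tmp_path / "b.hdr")
        assert np.array_equal(a.values, b.values)

    def test_band_count_mismatch_raises(self, tmp_path, rng):
        cube = _cube(rng, shape=(2, 2, 4))
        write_envi_cube(cube, tmp_path / "c.hdr")
        text = (tmp_path / "c.hdr").read_text().replace("bands = 4", "bands = 3")
        # drop one wavelength so the header is self-consistent but disagrees
        # with the binary payload size
        import re

        text = re.sub(r"wavelength = \{[^}]*\}", "wavelength = { 1 , 2 , 3 }", text)
        (tmp_path / "c.hdr").write_text(text)
        with pytest.raises(FormatError):
            read_envi_cube(tmp_path / "c.hdr")

    def test_missing_wavelengths_raises(self, tmp_path, rng):
        cube = _cube(rng)
        write_envi_cube(cube, tmp_path / "c.hdr")
        lines = [
            l for l in (tmp_path / "c.hdr").read_text().splitlines()
            if not l.startswith("wavelength =")
        ]
        (tmp_path / "c.hdr").write_text("\n".join(lines))
        with pytest.raises(FormatError):
            read_envi_cube(tmp_path / "c.hdr")


class TestEmpiricalLine:
    def test_unit_gain_zero_offset_is_identity(self, rng):
        cube = _cube(rng)
        out = empirical_line_correct(cube, ElmCoefficients(gain=1.0, offset=0.0))
        assert np.allclose(out.values, cube.values)
        assert out.unit_state == "reflectance"

    def test_linear_transform_arithmetic(self):
        cube = SpectralCube(np.full((1, 1, 1), 100.0), np.array([500.0]))
        out = empirical_line_correct(cube, ElmCoefficients(gain=0.5, offset=10.0))
        assert out.values[0, 0, 0] == pytest.approx(60.0)

    def test_out_of_range_values_kept_and_counted(self):
        cube = SpectralCube(np.full((1, 1, 1), 40.0), np.array([500.0]))
        out = empirical_line_correct(cube, ElmCoefficients(gain=0.001, offset=-0.05))
        assert out.values[0, 0, 0] == pytest.approx(-0.01)
        assert out.out_of_range_count == 1

    def test_affine_in_gain(self, rng):
        # correcting a cube scaled by s with gain G == correcting the
        # original with gain s*G (offset fixed)
        cube = _cube(rng, dtype=np.float64)
        s = 2.5
        gain = rng.random(6) + 0.5
        offset = rng.random(6)
        scaled = SpectralCube(cube.values * s, cube.wavelengths)
        a = empirical_line_correct(scaled, ElmCoefficients(gain, offset))
        b = empirical_line_correct(cube, ElmCoefficients(gain * s, offset))
        assert np.allclose(a.values, b.values)

    def test_coefficient_length_mismatch_raises(self, rng):
        cube = _cube(rng)
        with pytest.raises(DimensionError):
            empirical_line_correct(cube, ElmCoefficients(gain=np.ones(3)))


class TestRoi:
    def test_single_pixel_mask(self, rng):
        cube = _cube(rng)
        mask = np.zeros((4, 5), dtype=bool)
        mask[2, 3] = True
        rop = extract_roi(cube, mask)
        assert rop.n_pixels == 1
        assert np.array_equal(rop.pixel_spectra[0], cube.values[2, 3])

    def test_pixel_count_matches_mask(self, rng):
        cube = _cube(rng)
        mask = rng.random((4, 5)) > 0.5
        if not mask.any():
            mask[0, 0] = True
        assert extract_roi(cube, mask).n_pixels == mask.sum()

    def test_empty_mask_raises(self, rng):
        with pytest.raises(DataError):
            extract_roi(_cube(rng), np.zeros((4, 5), dtype=bool))

    def test_full_mask_mean_equals_image_mean(self, rng):
        cube = _cube(rng, dtype=np.float64)
        rop = extract_roi(cube, np.ones((4, 5), dtype=bool))
        assert np.allclose(mean_spectrum(rop), cube.values.mean(axis=(0, 1)))

    def test_mean_spectrum_arithmetic(self):
        rop = ROPSet("s", np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([500.0, 600.0]))
        assert np.allclose(mean_spectrum(rop), [2.0, 3.0])

    def test_mean_spectrum_single_pixel_identity(self):
        rop = ROPSet("s", np.array([[1.5, 2.5]]), np.array([500.0, 600.0]))
        assert np.allclose(mean_spectrum(rop), [1.5, 2.5])


class TestRopFeatures:
    def test_identical_pixels_zero_dispersion_and_angle(self):
        px = np.tile([0.2, 0.4, 0.6], (5, 1))
        feats = rop_features(ROPSet("s", px, np.array([500.0, 600.0, 700.0])))
        assert feats[0] == 5
        assert feats[1] == 0.0
        assert feats[2] == pytest.approx(0.4)
        assert feats[3] == pytest.approx(0.0, abs=1e-7)

    def test_scalar_multiple_pixels_have_zero_spectral_angle(self):
        base = np.array([0.1, 0.2, 0.3])
        px = np.vstack([base, 2.0 * base])
        feats = rop_features(ROPSet("s", px, np.array([5.0, 6.0, 7.0])))
        assert feats[3] == pytest.approx(0.0, abs=1e-7)

    def test_single_pixel_components_are_zero(self):
        feats = rop_features(ROPSet("s", np.array([[1.0, 2.0]]), np.array([5.0, 6.0])))
        assert feats[1] == 0.0 and feats[3] == 0.0

    def test_larger_intra_roi_cv_gives_larger_dispersion(self):
        from hypyield.synthetic import SceneConfig, generate_scene

        feats = {}
        for cv in (0.02, 0.10):
            cfg = SceneConfig(n_samples=1, n_bands=32, roi_pixels=50,
                              intra_roi_cv=cv, noise_sd=0.0, seed=12)
            cube, masks, _ = generate_scene(cfg)
            feats[cv] = rop_features(extract_roi(cube, masks[0]))
        assert feats[0.10][1] > feats[0.02][1]


class TestWavelengthLookup:
    def test_grid_endpoints(self):
        wl = np.linspace(400, 1000, 224)
        assert wavelength_to_channel(wl, 400) == 0
        assert wavelength_to_channel(wl, 1000) == 223

    def test_matches_brute_force_argmin(self):
        wl = np.linspace(400, 1000, 224)
        for target in (801, 682, 720, 561, 820, 680, 462, 712, 701):
            brute = min(range(224), key=lambda i: (abs(wl[i] - target), i))
            assert wavelength_to_channel(wl, target) == brute

    def test_tie_breaks_toward_lower_index(self):
        wl = np.array([400.0, 500.0, 600.0])
        assert wavelength_to_channel(wl, 450.0) == 0

    def test_out_of_range_raises(self):
        with pytest.raises(DataError):
            wavelength_to_channel(np.array([400.0, 500.0]), 600.0)


class TestMaskIO:
    def test_rle_round_trip(self, tmp_path, rng):
        mask = rng.random((7, 9)) > 0.6
        write_mask_rle(mask, tmp_path / "m.csv")
        assert np.array_equal(read_mask_rle(tmp_path / "m.csv"), mask)

    def test_png_round_trip(self, tmp_path, rng):
        mask = rng.random((6, 4)) > 0.5
        write_mask_png(mask, tmp_path / "m.png")
        assert np.array_equal(read_mask_png(tmp_path / "m.png"), mask)
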