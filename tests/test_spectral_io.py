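"""Cube I/O, reflectance calibration, ROI masking and spectra tables."""

import numpy as np
import pytest

from fruitspec import (
    HyperspectralCube,
    ReferenceCaptures,
    ROIMask,
    SpectrumSet,
    WavelengthGrid,
    calibrate_reflectance,
    extract_roi_mask,
    mean_spectrum,
    read_envi_cube,
    read_spectra_table,
    write_envi_cube,
    write_spectra_table,
)
from fruitspec.spectral_io import (
    CalibrationError,
    EmptyROIError,
    EnviFormatError,
    SpectraTableError,
)


def _toy_cube(rng, shape=(4, 4, 5)):
    grid = WavelengthGrid.uniform(400.0, 800.0, shape[2])
    return HyperspectralCube(rng.random(shape), grid, kind="raw")


def _naive_decode(binary, header_text):
    """Independent triple-loop byte decoder for ENVI fixtures."""
    import struct

    fields = {}
    for line in header_text.splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            fields[k.strip().lower()] = v.strip()
    lines_, samples, bands = (int(fields[k]) for k in ("lines", "samples",
                                                       "bands"))
    fmt = {"4": "f", "12": "H"}[fields["data type"]]
    endian = "<" if fields.get("byte order", "0") == "0" else ">"
    size = struct.calcsize(fmt)
    raw = binary.read_bytes()
    out = np.zeros((lines_, samples, bands))
    interleave = fields["interleave"].lower()
    idx = 0
    if interleave == "bil":
        for r in range(lines_):
            for b in range(bands):
                for c in range(samples):
                    out[r, c, b] = struct.unpack_from(endian + fmt, raw,
                                                      idx * size)[0]
                    idx += 1
    elif interleave == "bip":
        for r in range(lines_):
            for c in range(samples):
                for b in range(bands):
                    out[r, c, b] = struct.unpack_from(endian + fmt, raw,
                                                      idx * size)[0]
                    idx += 1
    else:
        for b in range(bands):
            for r in range(lines_):
                for c in range(samples):
                    out[r, c, b] = struct.unpack_from(endian + fmt, raw,
                                                      idx * size)[0]
                    idx += 1
    return out


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    @pytest.mark.parametrize("dtype,byte_order", [("float32", 0),
                                                  ("float32", 1),
                                                  ("uint16", 0)])
    def test_round_trip(self, tmp_path, rng, interleave, dtype, byte_order):
        cube = _toy_cube(rng)
        if dtype == "uint16":
            cube = HyperspectralCube((cube.data * 1000).astype(np.uint16),
                                     cube.grid, "raw")
        hdr = tmp_path / "cube.hdr"
        write_envi_cube(hdr, cube, interleave, dtype, byte_order)
        back = read_envi_cube(hdr)
        np.testing.assert_allclose(back.data, cube.data, rtol=1e-6)
        np.testing.assert_allclose(back.grid.values, cube.grid.values,
                                   rtol=1e-6)

    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    def test_agrees_with_naive_decoder(self, tmp_path, rng, interleave):
        grid = WavelengthGrid.uniform(400.0, 800.0, 8)
        cube = HyperspectralCube(rng.random((7, 8, 8)), grid, "raw")
        hdr = tmp_path / "cube.hdr"
        write_envi_cube(hdr, cube, interleave)
        oracle = _naive_decode(tmp_path / "cube.img", hdr.read_text())
        got = read_envi_cube(hdr)
        np.testing.assert_allclose(got.data, oracle, rtol=1e-6)

    def test_band_count_from_header(self, tmp_path, rng):
        grid = WavelengthGrid.default()
        cube = HyperspectralCube(rng.random((2, 2, 462)), grid, "raw")
        hdr = tmp_path / "big.hdr"
        write_envi_cube(hdr, cube)
        assert read_envi_cube(hdr).grid.count == 462

    def test_missing_binary(self, tmp_path):
        hdr = tmp_path / "lonely.hdr"
        hdr.write_text("ENVI\nsamples = 2\nlines = 2\nbands = 3\n"
                       "interleave = bil\ndata type = 4\n")
        with pytest.raises(EnviFormatError, match="companion"):
            read_envi_cube(hdr)

    def test_unsupported_interleave_and_dtype(self, tmp_path, rng):
        cube = _toy_cube(rng)
        hdr = tmp_path / "c.hdr"
        write_envi_cube(hdr, cube)
        text = hdr.read_text()
        hdr.write_text(text.replace("interleave = bil", "interleave = foo"))
        with pytest.raises(EnviFormatError, match="interleave"):
            read_envi_cube(hdr)
        hdr.write_text(text.replace("data type = 4", "data type = 5"))
        with pytest.raises(EnviFormatError, match="data type"):
            read_envi_cube(hdr)

    def test_declared_layout_mismatch(self, tmp_path, rng):
        # header declares more bands than the binary holds
        cube = _toy_cube(rng)
        hdr = tmp_path / "c.hdr"
        write_envi_cube(hdr, cube)
        hdr.write_text(hdr.read_text().replace("bands = 5", "bands = 6")
                       .replace("wavelength", "; wavelength"))
        with pytest.raises(EnviFormatError, match="bands=6"):
            read_envi_cube(hdr)

    def test_default_grid_when_no_wavelengths(self, tmp_path, rng):
        cube = _toy_cube(rng)
        hdr = tmp_path / "c.hdr"
        write_envi_cube(hdr, cube)
        hdr.write_text("\n".join(l for l in hdr.read_text().splitlines()
                                 if not l.startswith("wavelength")))
        back = read_envi_cube(hdr)
        assert back.grid.count == 5
        assert back.grid.values[0] == pytest.approx(386.0)


class TestCalibration:
    def _refs(self, n_bands, rng):
        dark = 80.0 + 10.0 * rng.random(n_bands)
        white = 900.0 + 50.0 * rng.random(n_bands)
        return ReferenceCaptures(white=white, dark=dark)

    @pytest.mark.parametrize("t", [0.0, 0.25, 0.5, 1.0])
    def test_affine_exact(self, rng, t):
        grid = WavelengthGrid.uniform(400, 800, 10)
        refs = self._refs(10, rng)
        raw = np.broadcast_to(refs.dark + t * (refs.white - refs.dark),
                              (3, 3, 10)).copy()
        out = calibrate_reflectance(HyperspectralCube(raw, grid, "raw"), refs)
        np.testing.assert_allclose(out.data, t, atol=1e-12)
        assert out.kind == "reflectance"

    def test_degenerate_band_named(self, rng):
        grid = WavelengthGrid.uniform(400, 800, 5)
        refs = ReferenceCaptures(white=np.array([2.0, 2.0, 3.0, 2.0, 2.0]),
                                 dark=np.array([1.0, 1.0, 3.0, 1.0, 1.0]))
        raw = HyperspectralCube(np.ones((2, 2, 5)), grid, "raw")
        with pytest.raises(CalibrationError, match="band index 2"):
            calibrate_reflectance(raw, refs)

    def test_rejects_already_calibrated(self, random_cube):
        refs = ReferenceCaptures(white=np.ones(6), dark=np.zeros(6))
        with pytest.raises(ValueError, match="already calibrated"):
            calibrate_reflectance(random_cube, refs)

    def test_calibration_commutes_with_masking(self, rng):
        # ROI-mean of calibrated cube == mean of per-pixel calibration
        grid = WavelengthGrid.uniform(400, 800, 8)
        refs = self._refs(8, rng)
        raw = HyperspectralCube(100 + 700 * rng.random((6, 6, 8)), grid, "raw")
        refl = calibrate_reflectance(raw, refs)
        mask = ROIMask(rng.random((6, 6)) > 0.4)
        route_a = mean_spectrum(refl, mask)
        per_pixel = [(raw.data[i, j] - refs.dark) / (refs.white - refs.dark)
                     for i, j in zip(*np.nonzero(mask.mask))]
        route_b = np.mean(per_pixel, axis=0)
        np.testing.assert_allclose(route_a, route_b, atol=1e-10)


class TestROI:
    def test_uniform_cube_fully_retained(self, small_grid):
        data = np.full((5, 5, small_grid.count), 0.4)
        cube = HyperspectralCube(data, small_grid, "reflectance")
        mask = extract_roi_mask(cube, highlight_percentile=0.0,
                                background_threshold=0.1)
        assert mask.mask.all()

    def test_highlight_pixels_excluded_exactly(self, small_grid):
        data = np.full((10, 10, small_grid.count), 0.3)
        inflated = [(0, 0), (3, 7), (5, 5), (9, 9), (2, 4),
                    (6, 1), (7, 8), (8, 2), (1, 9), (4, 6)]  # 10 % of pixels
        for i, j in inflated:
            data[i, j] *= 3.0
        cube = HyperspectralCube(data, small_grid, "reflectance")
        mask = extract_roi_mask(cube, highlight_percentile=0.10,
                                background_threshold=0.1)
        excluded = {tuple(p) for p in np.argwhere(~mask.mask)}
        assert excluded == set(inflated)

    def test_all_zero_cube_raises(self, small_grid):
        cube = HyperspectralCube(np.zeros((4, 4, small_grid.count)),
                                 small_grid, "reflectance")
        with pytest.raises(EmptyROIError, match="background_threshold"):
            extract_roi_mask(cube, 0.05, 0.05)

    def test_provenance_recorded(self, small_grid):
        cube = HyperspectralCube(np.full((4, 4, small_grid.count), 0.5),
                                 small_grid, "reflectance")
        mask = extract_roi_mask(cube, 0.2, 0.01)
        assert mask.provenance == {"highlight_percentile": 0.2,
                                   "background_threshold": 0.01}


class TestMeanSpectrum:
    def test_uniform_cube_returns_pixel_spectrum(self, small_grid, rng):
        spectrum = rng.random(small_grid.count)
        data = np.broadcast_to(spectrum, (4, 4, small_grid.count)).copy()
        cube = HyperspectralCube(data, small_grid, "reflectance")
        mask = ROIMask(np.ones((4, 4), dtype=bool))
        np.testing.assert_allclose(mean_spectrum(cube, mask), spectrum)

    def test_two_pixel_arithmetic_mean(self, small_grid, rng):
        s = rng.random(small_grid.count)
        data = np.zeros((1, 2, small_grid.count))
        data[0, 0], data[0, 1] = s, 3 * s
        cube = HyperspectralCube(data, small_grid, "reflectance")
        mask = ROIMask(np.ones((1, 2), dtype=bool))
        np.testing.assert_allclose(mean_spectrum(cube, mask), 2 * s,
                                   atol=1e-12)

    def test_matches_loop_oracle(self, random_cube, rng):
        mask = ROIMask(rng.random((8, 8)) > 0.3)
        got = mean_spectrum(random_cube, mask)
        for b in range(random_cube.grid.count):
            acc, cnt = 0.0, 0
            for i in range(8):
                for j in range(8):
                    if mask.mask[i, j]:
                        acc += random_cube.data[i, j, b]
                        cnt += 1
            assert got[b] == pytest.approx(acc / cnt, abs=1e-12)


class TestSpectraTable:
    def test_round_trip_with_labels(self, tmp_path, random_set, rng):
        ssc = 7 + 4 * rng.random(random_set.n_samples)
        firm = 6 + 6 * rng.random(random_set.n_samples)
        path = tmp_path / "t.csv"
        write_spectra_table(path, random_set, ssc=ssc, firmness=firm)
        back, labels = read_spectra_table(path)
        np.testing.assert_allclose(back.spectra, random_set.spectra,
                                   atol=1e-12)
        assert back.sample_ids == random_set.sample_ids
        np.testing.assert_allclose(labels["ssc"], ssc, atol=1e-12)
        np.testing.assert_allclose(labels["firmness"], firm, atol=1e-12)

    def test_large_table_round_trip(self, tmp_path, rng):
        grid = WavelengthGrid.default()
        spectra = SpectrumSet(rng.random((200, 462)), grid,
                              [f"x{i}" for i in range(200)])
        path = tmp_path / "big.csv"
        write_spectra_table(path, spectra)
        back, _ = read_spectra_table(path)
        np.testing.assert_allclose(back.spectra, spectra.spectra, atol=1e-12)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,400,500,600\n"
                        "a,0.1,0.2,0.3\n"
                        "b,0.1,0.2\n")
        with pytest.raises(SpectraTableError, match="line 3"):
            read_spectra_table(path)

    def test_non_monotone_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,400,600,500\na,0.1,0.2,0.3\n")
        with pytest.raises(SpectraTableError, match="increasing"):
            read_spectra_table(path)


class TestTypes:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            WavelengthGrid(np.array([3.0, 2.0, 1.0]))

    def test_duplicate_ids_rejected(self, small_grid):
        with pytest.raises(ValueError, match="duplicated"):
            SpectrumSet(np.zeros((2, small_grid.count)), small_grid,
                        ["a", "a"])

    def test_band_dimension_checked(self, small_grid):
        with pytest.raises(ValueError, match="grid"):
            HyperspectralCube(np.zeros((2, 2, 7)), small_grid, "raw")
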