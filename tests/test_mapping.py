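"""Cube I/O, masking and pixel-wise prediction contracts."""

import numpy as np
import pandas as pd
import pytest

import teaspec as ts
from teaspec import mapping as mp
from teaspec import preprocessing as pp
from teaspec import regression as reg
from teaspec.synthetic import _tea_mask


@pytest.fixture(scope="module")
def cube_setup(small_library):
    chem = ts.simulate_kinetics()
    row = chem.data.iloc[4]   # 1 h, middle layer
    noise = ts.NoiseModel(seed=21)
    cube, truth = ts.simulate_cube(row, small_library, noise,
                                   height=32, width=32,
                                   content_jitter_sd=0.05)
    return cube, truth, row


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil"])
    def test_cube_survives_write_read(self, cube_setup, tmp_path, interleave):
        cube, _, _ = cube_setup
        hdr = tmp_path / f"cube_{interleave}.hdr"
        mp.write_envi(cube, str(hdr), interleave=interleave)
        back = mp.read_envi(str(hdr))
        assert back.shape == cube.shape
        np.testing.assert_allclose(back.values, cube.values, atol=1e-6)
        np.testing.assert_allclose(back.grid.wavelengths_nm,
                                   cube.grid.wavelengths_nm, atol=1e-3)

    def test_float64_exact(self, cube_setup, tmp_path):
        cube, _, _ = cube_setup
        hdr = tmp_path / "cube64.hdr"
        mp.write_envi(cube, str(hdr), dtype=np.float64)
        back = mp.read_envi(str(hdr))
        np.testing.assert_array_equal(back.values, cube.values)

    def test_non_envi_header_rejected(self, tmp_path):
        bad = tmp_path / "x.hdr"
        bad.write_text("not a header")
        with pytest.raises(ts.ConfigurationError):
            mp.read_envi(str(bad))


class TestRoiExtraction:
    def test_uniform_cube_all_rois_identical(self, small_grid):
        vals = np.ones((40, 40, len(small_grid))) * 0.5
        cube = ts.HyperCube(vals, small_grid)
        centers = mp.symmetric_roi_centers(40, 40, 10)
        s = mp.extract_roi_spectra(cube, centers, roi_size=5)
        np.testing.assert_allclose(s.values, 0.5, atol=1e-12)

    def test_ten_rois_plus_sample_mean(self, cube_setup):
        cube, _, _ = cube_setup
        centers = mp.symmetric_roi_centers(32, 32, 10)
        s = mp.extract_roi_spectra(cube, centers, roi_size=3)
        assert s.n_samples == 11
        assert (s.meta["roi"] == -1).sum() == 1

    def test_sample_mean_is_mean_of_roi_means(self, cube_setup):
        cube, _, _ = cube_setup
        centers = mp.symmetric_roi_centers(32, 32, 6)
        s = mp.extract_roi_spectra(cube, centers, roi_size=3)
        np.testing.assert_allclose(s.values[-1], s.values[:-1].mean(axis=0),
                                   atol=1e-12)

    def test_out_of_bounds_roi_named(self, cube_setup):
        cube, _, _ = cube_setup
        with pytest.raises(ts.ParameterError, match="ROI 1"):
            mp.extract_roi_spectra(cube, [(16, 16), (1, 1)], roi_size=5)


class TestBackgroundMask:
    def test_noise_free_two_level_cube_recovers_truth(self, small_library):
        chem = ts.simulate_kinetics()
        cube, truth = ts.simulate_cube(chem.data.iloc[0], small_library,
                                       ts.NoiseModel(seed=0).silent(),
                                       height=28, width=28,
                                       content_jitter_sd=0.0)
        mask = mp.background_mask(cube)
        np.testing.assert_array_equal(mask, _tea_mask(28, 28, "ellipse"))

    def test_flat_cube_yields_empty_mask(self, small_grid):
        vals = np.full((20, 20, len(small_grid)), 0.8)
        mask = mp.background_mask(ts.HyperCube(vals, small_grid))
        assert not mask.any()

    def test_mask_partitions_frame(self, cube_setup):
        cube, _, _ = cube_setup
        mask = mp.background_mask(cube)
        assert (mask | ~mask).all()
        assert 0 < mask.sum() < mask.size


@pytest.fixture(scope="module")
def trained_bundle(small_library, small_grid):
    """Train a second-derivative PLS chain on noisy default spectra.

    The derivative pretreatment cancels the per-pixel additive offset and
    linear baseline drift that single-pixel spectra carry, which matters
    when the model is replayed on cube pixels.
    """
    chem = ts.simulate_kinetics()
    spectra = ts.simulate_spectra(chem, small_library, ts.NoiseModel(seed=5),
                                  replicates=6)
    y = spectra.meta.merge(chem.data, on="sample_id",
                           suffixes=("", "_c"))["total"].to_numpy(float)
    from teaspec.selection import kennard_stone, spa_select
    base = spectra.to_absorbance()
    split = kennard_stone(base.values, 0.75)
    chain = pp.PretreatmentChain(
        "d2", params={"window": 7, "polyorder": 2}).fit(
        spectra.subset_rows(split.calibration))
    Xc = chain.transform(spectra.subset_rows(split.calibration)).values
    sel_res = spa_select(Xc, y[split.calibration], kmin=5, kmax=12, seed=0,
                         grid=small_grid)
    cal_scores, _, pca = reg.pca_reduce(Xc, Xc, sel_res.indices,
                                        min(8, sel_res.indices.size))
    model = reg.pls_train(cal_scores, y[split.calibration],
                          min(6, cal_scores.shape[1]))
    return chain, sel_res, pca, model


class TestPredictMap:
    def test_uniform_noise_free_cube_recovers_content(self, small_library,
                                                      trained_bundle):
        chain, sel_res, pca, model = trained_bundle
        chem = ts.simulate_kinetics()
        row = chem.data.iloc[6]
        cube, truth = ts.simulate_cube(row, small_library,
                                       ts.NoiseModel(seed=0).silent(),
                                       height=24, width=24,
                                       content_jitter_sd=0.0)
        mask = _tea_mask(24, 24, "ellipse")
        pmap = mp.predict_map(cube, mask, chain, sel_res, pca, model, "total")
        tea = pmap.values[mask]
        assert np.ptp(tea) < 1e-9          # one spectrum -> one prediction
        assert tea.mean() == pytest.approx(row["total"], rel=0.1)

    def test_background_exactly_zero(self, cube_setup, trained_bundle):
        cube, _, _ = cube_setup
        chain, sel_res, pca, model = trained_bundle
        mask = mp.background_mask(cube)
        pmap = mp.predict_map(cube, mask, chain, sel_res, pca, model, "total")
        assert np.all(pmap.values[~mask] == 0.0)

    def test_pixel_sample_consistency(self, small_library, trained_bundle):
        """Predicting the ROI-mean spectrum through the map path equals the
        scalar model prediction for that spectrum."""
        chain, sel_res, pca, model = trained_bundle
        chem = ts.simulate_kinetics()
        cube, _ = ts.simulate_cube(chem.data.iloc[9], small_library,
                                   ts.NoiseModel(seed=13), height=24, width=24)
        centers = mp.symmetric_roi_centers(24, 24, 4)
        rois = mp.extract_roi_spectra(cube, centers, roi_size=3)
        mean_spec = rois.values[-1][None, :]
        # map path on a 1-pixel cube holding the mean spectrum
        tiny = ts.HyperCube(np.tile(mean_spec[0], (16, 16, 1)), cube.grid)
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        pmap = mp.predict_map(tiny, mask, chain, sel_res, pca, model, "total",
                              clip_negative=False)
        direct = model.predict(pca.transform(
            chain.transform_values(mean_spec, cube.grid)))[0]
        assert pmap.values[8, 8] == pytest.approx(direct, abs=1e-9)

    def test_jittered_cube_truth_correlation(self, small_library,
                                             trained_bundle):
        chain, sel_res, pca, model = trained_bundle
        chem = ts.simulate_kinetics()
        cube, truth = ts.simulate_cube(chem.data.iloc[4], small_library,
                                       ts.NoiseModel(seed=21),
                                       height=32, width=32,
                                       content_jitter_sd=0.12)
        mask = _tea_mask(32, 32, "ellipse")
        den = mp.denoise_cube(cube, mask)
        pmap = mp.predict_map(den, mask, chain, sel_res, pca, model, "total")
        r = np.corrcoef(truth["total"][mask], pmap.values[mask])[0, 1]
        assert r >= 0.9

    def test_grid_mismatch_rejected(self, trained_bundle):
        chain, sel_res, pca, model = trained_bundle
        other_grid = ts.make_wavelength_grid(400, 960, 80)
        shifted = ts.make_wavelength_grid(410, 950, 80)
        cube = ts.HyperCube(np.ones((16, 16, 80)) * 0.4, shifted)
        with pytest.raises(ts.ConfigurationError):
            mp.predict_map(cube, np.ones((16, 16), bool), chain, sel_res,
                           pca, model)


class TestRenderMap:
    @pytest.fixture()
    def pmap(self):
        mask = np.zeros((20, 20), bool)
        mask[4:16, 4:16] = True
        vals = np.zeros((20, 20))
        vals[mask] = np.linspace(1.0, 2.0, mask.sum())
        return mp.PixelMap(vals, mask, "total")

    def test_png_payload_matches_map_size(self, pmap, tmp_path):
        from PIL import Image
        out = tmp_path / "m.png"
        mp.render_map(pmap, str(out))
        with Image.open(out) as im:
            assert im.size == (20, 20)

    def test_rerender_byte_identical(self, pmap, tmp_path):
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        mp.render_map(pmap, str(p1))
        mp.render_map(pmap, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_sidecar_scale_spans_tea_pixels(self, pmap, tmp_path):
        side = mp.render_map(pmap, str(tmp_path / "m.png"))
        assert side["scale"]["min"] == pytest.approx(1.0)
        assert side["scale"]["max"] == pytest.approx(2.0)
        assert side["units"] == "% dry mass"
        assert (tmp_path / "m.json").exists()

    def test_constant_map_single_colour(self, tmp_path):
        mask = np.ones((10, 10), bool)
        pmap = mp.PixelMap(np.full((10, 10), 3.0), mask, "ec")
        from PIL import Image
        out = tmp_path / "c.png"
        mp.render_map(pmap, str(out))
        with Image.open(out) as im:
            assert len(im.getcolors()) == 1

    def test_nonzero_background_rejected_by_contract(self):
        mask = np.zeros((8, 8), bool)
        vals = np.ones((8, 8))
        with pytest.raises(ts.ConfigurationError):
            mp.PixelMap(vals, mask, "total")
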