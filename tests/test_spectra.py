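"""Containers, I/O and the preprocessing chain."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from ramanmf import synthetic
from ramanmf.errors import (
    AxisError,
    CoverageError,
    DegenerateSpectrumError,
    DuplicateNameError,
    MetadataError,
    SpectrumError,
    StageError,
)
from ramanmf.spectra import (
    PreprocessConfig,
    RamanSpectrum,
    SpectralDataset,
    WavenumberAxis,
    asymmetric_least_squares_baseline,
    cosmic_ray_mask,
    default_axis,
    load_dataset,
    load_library,
    normalize_area,
    preprocess_dataset,
    remove_cosmic_rays,
    resample_to_axis,
    save_dataset,
    subtract_baseline,
    write_spectrum_file,
)

from conftest import gaussian_spectrum


class TestWavenumberAxis:
    def test_rejects_decreasing(self):
        with pytest.raises(AxisError):
            WavenumberAxis(np.array([1800.0, 1000.0, 450.0]))

    def test_rejects_short_and_nonfinite(self):
        with pytest.raises(AxisError):
            WavenumberAxis(np.array([450.0]))
        with pytest.raises(AxisError):
            WavenumberAxis(np.array([450.0, np.nan, 1800.0]))

    def test_default_span(self, axis):
        lo, hi = axis.span
        assert lo == 450.0 and hi <= 1800.0


class TestResampling:
    def test_identity_on_equal_axes(self, small_axis):
        spec = gaussian_spectrum(small_axis, [900.0], [1.0])
        out = resample_to_axis(spec, small_axis)
        assert out.intensities is spec.intensities

    def test_exact_on_affine_profile(self):
        src = WavenumberAxis(np.arange(500.0, 701.0, 10.0))
        spec = RamanSpectrum(src, 2.0 * src.values + 1.0)
        target = WavenumberAxis(np.arange(500.0, 696.0, 5.0))
        out = resample_to_axis(spec, target)
        np.testing.assert_allclose(out.intensities, 2.0 * target.values + 1.0,
                                   rtol=1e-12)

    def test_extrapolation_rejected(self, small_axis):
        spec = gaussian_spectrum(small_axis, [900.0], [1.0])
        wider = WavenumberAxis(np.linspace(450.0, 1900.0, 100))
        with pytest.raises(CoverageError):
            resample_to_axis(spec, wider)


class TestDespike:
    def test_no_spikes_output_equals_input(self, small_axis):
        spec = gaussian_spectrum(small_axis, [700.0, 1100.0, 1500.0],
                                 [1.0, 0.5, 0.8])
        out = remove_cosmic_rays(spec)
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_narrow_band_not_flagged(self, axis):
        # FWHM at the sharp end of real Raman bands must survive
        spec = gaussian_spectrum(axis, [900.0, 1300.0], [1.0, 0.6], fwhm=6.0)
        assert not cosmic_ray_mask(spec.intensities).any()

    @pytest.mark.parametrize("spike_pixels", [[300], [300, 301]])
    def test_planted_spikes_detected_exactly(self, axis, spike_pixels):
        # spike planted in a quiet region between the two bands
        spec = gaussian_spectrum(axis, [700.0, 1200.0], [1.0, 0.7])
        y = spec.intensities.copy()
        local = max(np.median(y), 0.01)
        planted = np.zeros(len(axis), dtype=bool)
        for px in spike_pixels:
            y[px] += 50.0 * local
            planted[px] = True
        mask = cosmic_ray_mask(y)
        np.testing.assert_array_equal(mask, planted)

    @pytest.mark.parametrize("spike_pixel", [137, 340, 600])
    def test_spike_on_raw_spectrum_with_background(self, axis, spike_pixel):
        # raw spectra carry a fluorescence background that lifts the
        # median; a 50x-median cosmic ray is then detected anywhere,
        # including on a band flank
        rng = np.random.default_rng(spike_pixel)
        t = np.linspace(0.0, 1.0, len(axis))
        background = 0.3 + 0.4 * t + 0.2 * t ** 2
        y = gaussian_spectrum(axis, [700.0, 1200.0], [1.0, 0.7]).intensities \
            + background + rng.normal(0.0, 0.003, len(axis))
        planted = np.zeros(len(axis), dtype=bool)
        planted[spike_pixel] = True
        y[spike_pixel] += 50.0 * np.median(y)
        mask = cosmic_ray_mask(y)
        np.testing.assert_array_equal(mask, planted)

    def test_repair_leaves_offmask_bitwise_unchanged(self, axis):
        spec = gaussian_spectrum(axis, [800.0], [1.0])
        y = spec.intensities.copy()
        y[300] += 5.0
        out = remove_cosmic_rays(RamanSpectrum(axis, y, "raw"))
        mask = cosmic_ray_mask(y)
        assert mask[300]
        np.testing.assert_array_equal(out.intensities[~mask], y[~mask])

    def test_window_larger_than_spectrum(self):
        tiny = WavenumberAxis(np.linspace(450, 470, 5))
        spec = RamanSpectrum(tiny, np.ones(5))
        with pytest.raises(SpectrumError):
            remove_cosmic_rays(spec, window=11)

    def test_requires_raw_stage(self, small_axis):
        spec = gaussian_spectrum(small_axis, [900.0], [1.0], stage="baselined")
        with pytest.raises(StageError):
            remove_cosmic_rays(spec)


class TestBaseline:
    def test_all_zero_in_all_zero_out(self, small_axis):
        base = asymmetric_least_squares_baseline(np.zeros(len(small_axis)))
        np.testing.assert_allclose(base, 0.0, atol=1e-12)

    def test_linear_ramp_removed(self, axis):
        ramp = np.linspace(0.0, 10.0, len(axis))
        spec = RamanSpectrum(axis, ramp, "despiked")
        out = subtract_baseline(spec)
        assert np.abs(out.intensities).max() < 0.01 * 10.0

    def test_peaks_recovered_over_quadratic_background(self, axis):
        t = np.linspace(0.0, 1.0, len(axis))
        background = 2.0 + 3.0 * t + 1.5 * t ** 2
        peaks = gaussian_spectrum(axis, [700.0, 1100.0, 1500.0],
                                  [5.0, 4.0, 6.0], fwhm=15.0).intensities
        spec = RamanSpectrum(axis, background + peaks, "despiked")
        out = subtract_baseline(spec)
        for center, height in ((700.0, 5.0), (1100.0, 4.0), (1500.0, 6.0)):
            px = int(np.argmin(np.abs(axis.values - center)))
            assert abs(out.intensities[px] - height) < 0.05 * height

    def test_nonpositive_smoothness_rejected(self, small_axis):
        spec = gaussian_spectrum(small_axis, [900.0], [1.0], stage="despiked")
        with pytest.raises(ValueError):
            subtract_baseline(spec, smoothness=0.0)


class TestNormalizeArea:
    def test_unit_area_and_idempotent(self, small_axis):
        spec = gaussian_spectrum(small_axis, [700.0, 1200.0], [2.0, 1.0],
                                 stage="baselined")
        out = normalize_area(spec)
        area = np.trapezoid(out.intensities, small_axis.values)
        assert abs(area - 1.0) < 1e-12
        again = normalize_area(out)
        np.testing.assert_array_equal(again.intensities, out.intensities)

    def test_scale_invariance(self, small_axis):
        spec = gaussian_spectrum(small_axis, [800.0], [1.0], stage="baselined")
        scaled = RamanSpectrum(small_axis, 7.0 * spec.intensities, "baselined")
        np.testing.assert_allclose(normalize_area(spec).intensities,
                                   normalize_area(scaled).intensities,
                                   rtol=1e-12)

    def test_negative_values_clipped_first(self, small_axis):
        y = gaussian_spectrum(small_axis, [800.0], [1.0]).intensities - 0.05
        out = normalize_area(RamanSpectrum(small_axis, y, "baselined"))
        assert (out.intensities >= 0).all()

    def test_all_zero_rejected(self, small_axis):
        spec = RamanSpectrum(small_axis, np.zeros(len(small_axis)), "baselined")
        with pytest.raises(DegenerateSpectrumError):
            normalize_area(spec)

    def test_raw_stage_rejected(self, small_axis):
        spec = gaussian_spectrum(small_axis, [800.0], [1.0], stage="raw")
        with pytest.raises(StageError):
            normalize_area(spec)


class TestFileIO:
    def test_dataset_roundtrip(self, tmp_path, small_axis):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 1.0, size=(3, len(small_axis)))
        X /= np.trapezoid(X, small_axis.values, axis=1)[:, None]
        meta = pd.DataFrame({
            "cell_line": ["H460"] * 3, "dose_gy": [0.0, 2.0, 4.0],
            "day": [1, 1, 1], "replicate": ["r1"] * 3,
            "cell_id": ["a", "b", "c"],
        })
        ds = SpectralDataset(X, small_axis, meta)
        save_dataset(ds, tmp_path / "m.csv", tmp_path / "meta.csv",
                     header="roundtrip")
        back = load_dataset(tmp_path / "m.csv", tmp_path / "meta.csv")
        np.testing.assert_allclose(back.X, ds.X, rtol=1e-9)
        assert list(back.meta["cell_id"]) == ["a", "b", "c"]

    def test_metadata_row_mismatch(self, tmp_path, small_axis):
        X = np.ones((2, len(small_axis)))
        pd.DataFrame(X, columns=[f"{w:.4f}" for w in small_axis.values]).to_csv(
            tmp_path / "m.csv", index=False)
        meta = pd.DataFrame({
            "cell_line": ["a"] * 3, "dose_gy": [0.0] * 3, "day": [1] * 3,
            "replicate": ["r1"] * 3, "cell_id": list("abc"),
        })
        meta.to_csv(tmp_path / "meta.csv", index=False)
        with pytest.raises(MetadataError):
            load_dataset(tmp_path / "m.csv", tmp_path / "meta.csv")

    def test_decreasing_header_rejected(self, tmp_path):
        with open(tmp_path / "m.csv", "w") as fh:
            fh.write("1800,1000,450\n1,2,3\n")
        pd.DataFrame({
            "cell_line": ["a"], "dose_gy": [0.0], "day": [1],
            "replicate": ["r1"], "cell_id": ["x"],
        }).to_csv(tmp_path / "meta.csv", index=False)
        with pytest.raises(AxisError):
            load_dataset(tmp_path / "m.csv", tmp_path / "meta.csv")

    def test_missing_metadata_column(self, tmp_path, small_axis):
        X = np.ones((1, len(small_axis)))
        pd.DataFrame(X, columns=[f"{w:.4f}" for w in small_axis.values]).to_csv(
            tmp_path / "m.csv", index=False)
        pd.DataFrame({"cell_line": ["a"]}).to_csv(tmp_path / "meta.csv",
                                                  index=False)
        with pytest.raises(MetadataError):
            load_dataset(tmp_path / "m.csv", tmp_path / "meta.csv",
                         stage="raw")


class TestLoadLibrary:
    def _write_spectra(self, tmp_path, axis, m):
        paths = []
        rng = np.random.default_rng(5)
        for j in range(m):
            y = gaussian_spectrum(
                axis, rng.uniform(500, 1700, 4), rng.uniform(0.2, 1.0, 4),
            ).intensities
            path = tmp_path / f"chem_{j}.txt"
            write_spectrum_file(path, axis.values, y)
            paths.append(path)
        return paths

    def test_thirty_files_unit_area(self, tmp_path, axis):
        paths = self._write_spectra(tmp_path, axis, 30)
        lib = load_library(paths, [f"c{j}" for j in range(30)], axis)
        assert lib.m == 30
        areas = np.trapezoid(lib.B, axis.values, axis=1)
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_duplicate_name_rejected(self, tmp_path, axis):
        paths = self._write_spectra(tmp_path, axis, 2)
        with pytest.raises(DuplicateNameError):
            load_library(paths, ["glycogen", "glycogen"], axis)

    def test_axis_coverage_gap_rejected(self, tmp_path, axis):
        short = WavenumberAxis(np.linspace(450.0, 1500.0, 300))
        y = gaussian_spectrum(short, [900.0], [1.0]).intensities
        path = tmp_path / "short.txt"
        write_spectrum_file(path, short.values, y)
        with pytest.raises(CoverageError):
            load_library([path], ["short"], axis)


class TestPreprocessDataset:
    def test_ten_raw_spectra_all_unit_area(self, axis, library):
        design = synthetic.generate_design(
            lines=("H460",), doses=(0.0, 2.0), days=(1,), replicates=1,
            cells_per_sample=5)
        truth = synthetic.simulate_score_trends(
            design, library, synthetic.TrendConfig(), noise_cv=0.05, seed=1)
        raw = synthetic.synthesize_spectra(truth, raw=True)
        out = preprocess_dataset(raw)
        assert out.n_spectra == 10
        areas = np.trapezoid(out.X, axis.values, axis=1)
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)
        assert out.stage == "normalized"

    def test_end_to_end_tracks_truth_mixtures(self, analog_bundle):
        dataset, truth, library = analog_bundle
        out = preprocess_dataset(dataset)
        clean = truth.true_scores @ library.B
        target = clean / np.trapezoid(clean, library.axis.values,
                                      axis=1)[:, None]
        # per-spectrum shape agreement with the planted mixtures
        cors = [pearsonr(out.X[i], target[i])[0] for i in range(out.n_spectra)]
        assert min(cors) > 0.995
        rel = np.linalg.norm(out.X - target) / np.linalg.norm(target)
        assert rel < 0.10

    def test_corrupt_spectrum_identified(self, small_axis):
        X = np.vstack([
            gaussian_spectrum(small_axis, [900.0], [1.0]).intensities,
            np.zeros(len(small_axis)),
        ])
        meta = pd.DataFrame({
            "cell_line": ["H460", "H460"], "dose_gy": [0.0, 2.0],
            "day": [1, 1], "replicate": ["r1", "r1"],
            "cell_id": ["ok", "bad"],
        })
        ds = SpectralDataset(X, small_axis, meta, stage="raw")
        with pytest.raises(SpectrumError) as err:
            preprocess_dataset(ds)
        assert "bad" in str(err.value)

    def test_requires_raw_stage(self, small_axis):
        X = np.ones((1, len(small_axis)))
        meta = pd.DataFrame({
            "cell_line": ["a"], "dose_gy": [0.0], "day": [1],
            "replicate": ["r1"], "cell_id": ["x"],
        })
        ds = SpectralDataset(X, small_axis, meta, stage="baselined")
        with pytest.raises(StageError):
            preprocess_dataset(ds)
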