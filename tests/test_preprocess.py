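"""Normalization, peak finding/alignment and peak-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msirisk import preprocess, synth
from msirisk.io_formats import MSIDataset
from msirisk.preprocess import (
    PeakMatrix,
    align_peaks,
    build_peak_matrix,
    find_peaks,
    ion_image,
    tic_normalize,
)


def _dataset_from_rows(masses, rows, group="unknown"):
    n = len(rows)
    pixels = np.array([[i, 0] for i in range(n)])
    return MSIDataset(
        pixels,
        [np.asarray(masses, float)] * n,
        [np.asarray(r, np.float32) for r in rows],
        group=group,
    )


class TestTicNormalize:
    def test_every_pixel_reaches_the_common_tic(self):
        ds = _dataset_from_rows([1000.0, 2000.0], [[1, 2], [10, 20], [5, 45]])
        out = tic_normalize(ds)
        tics = out.tic()
        assert np.allclose(tics, tics[0], rtol=1e-6)
        assert tics[0] == pytest.approx(np.mean(ds.tic()), rel=1e-6)

    def test_idempotent_on_uniform_tic(self):
        ds = _dataset_from_rows([1000.0, 2000.0], [[4, 6], [7, 3], [1, 9]])
        out = tic_normalize(ds)
        again = tic_normalize(out)
        for a, b in zip(out.intensities, again.intensities):
            assert np.allclose(a, b, rtol=1e-6)

    def test_zero_tic_pixel_flagged_not_scaled(self):
        ds = _dataset_from_rows([1000.0], [[5.0], [0.0], [15.0]])
        with pytest.warns(UserWarning, match="zero-TIC"):
            out = tic_normalize(ds)
        assert out.metadata["zero_tic_pixels"] == [1]
        assert out.intensities[1][0] == 0.0

    def test_all_zero_dataset_is_an_error(self):
        ds = _dataset_from_rows([1000.0], [[0.0], [0.0]])
        with pytest.raises(ValueError, match="zero total ion count"):
            tic_normalize(ds)

    def test_restores_planted_fold_change_under_tic_variation(self):
        """Per-pixel multiplicative variation is removed: the group-mean ratio
        of a planted peak returns to the configured effect size."""
        cfg = synth.SynthConfig(seed=9, noise_sd=0.0, tic_variation=(0.3, 3.0))
        datasets, truth = synth.generate_msi_dataset(cfg)
        norm = [tic_normalize(d) for d in datasets]
        intervals = align_peaks(truth.all_mz())
        rois = [truth.roi_for(d.sample_id) for d in datasets]
        pm = build_peak_matrix(norm, intervals, rois).subset(
            build_peak_matrix(norm, intervals, rois).roi_mask(synth.TUMOR_LABEL)
        )
        g = pm.pixel_table["group"].to_numpy()
        for mz, direction in truth.discriminative_mz:
            k = pm.interval_index(mz)
            ratio = pm.matrix[g == "HR", k].mean() / pm.matrix[g == "nHR", k].mean()
            if direction == "down":
                ratio = 1 / ratio
            assert ratio == pytest.approx(cfg.effect_size, rel=0.05)


class TestFindPeaks:
    def test_single_planted_peak_found_within_tolerance(self):
        ds = _dataset_from_rows([1234.56], [[50.0]] * 5)
        centers = find_peaks(ds)
        assert len(centers) == 1
        assert abs(centers[0] - 1234.56) < 0.15

    def test_two_peaks_ten_dalton_apart(self):
        ds = _dataset_from_rows([1000.0, 1010.0], [[40.0, 60.0]] * 5)
        centers = find_peaks(ds)
        assert len(centers) == 2

    def test_infinite_snr_gives_empty_list(self):
        ds = _dataset_from_rows([1000.0], [[50.0]] * 3)
        assert len(find_peaks(ds, snr_threshold=np.inf)) == 0

    def test_nonpositive_snr_rejected(self):
        ds = _dataset_from_rows([1000.0], [[50.0]] * 3)
        with pytest.raises(ValueError, match="snr"):
            find_peaks(ds, snr_threshold=0)

    def test_planted_peak_count_recovered(self, clean_study):
        """Noiseless study with well-separated peaks: the pipeline finds one
        interval per planted peak."""
        truth = clean_study["truth"]
        assert clean_study["pm"].n_intervals == len(truth.all_mz())


class TestAlignPeaks:
    def test_close_centers_merge_to_weighted_mean(self):
        intervals = align_peaks(np.array([1000.00, 1000.10]), 0.3, weights=np.array([1.0, 3.0]))
        assert len(intervals) == 1
        assert intervals[0, 0] == pytest.approx((1000.00 * 1 + 1000.10 * 3) / 4)

    def test_distant_centers_stay_separate(self):
        intervals = align_peaks(np.array([1000.00, 1000.40]), 0.3)
        assert len(intervals) == 2

    def test_chained_merge_is_transitive(self):
        # consecutive gaps below the width collapse into one interval
        intervals = align_peaks(np.array([1000.0, 1000.2, 1000.4]), 0.3)
        assert len(intervals) == 1

    @given(
        st.lists(st.floats(min_value=800, max_value=3200), min_size=1, max_size=30),
        st.floats(min_value=0.05, max_value=2.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_intervals_never_overlap(self, centers, width):
        intervals = align_peaks(np.sort(np.array(centers)), width)
        c, hw = intervals[:, 0], intervals[:, 1]
        assert np.all(np.diff(c) >= width - 1e-9)
        assert np.all(hw == width / 2)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            align_peaks(np.array([1000.0]), 0.0)


class TestBuildPeakMatrix:
    def test_interval_value_is_the_maximum(self):
        ds = _dataset_from_rows([1000.00, 1000.10, 1500.0], [[5.0, 7.0, 2.0]])
        pm = build_peak_matrix(ds, np.array([[1000.05, 0.15], [1500.0, 0.15]]))
        assert pm.matrix[0, 0] == 7.0  # max of {5, 7} inside the window
        assert pm.matrix[0, 1] == 2.0

    def test_empty_interval_is_zero(self):
        ds = _dataset_from_rows([1000.0], [[5.0]])
        pm = build_peak_matrix(ds, np.array([[1000.0, 0.15], [2000.0, 0.15]]))
        assert pm.matrix[0, 1] == 0.0

    def test_roi_restriction_drops_rows(self, clean_study):
        pm = clean_study["pm"]
        tumor = pm.subset(pm.roi_mask(synth.TUMOR_LABEL))
        stroma = pm.subset(pm.roi_mask(synth.STROMA_LABEL))
        assert tumor.n_pixels + stroma.n_pixels == pm.n_pixels
        assert 0 < tumor.n_pixels < pm.n_pixels

    def test_values_bounded_by_raw_maximum(self, clean_study):
        """Max semantics: matrix entries never exceed the pixel's raw peak max."""
        pm = clean_study["pm"]
        assert np.all(pm.matrix >= 0)
        datasets = clean_study["datasets"]
        global_max = max(float(i.max()) for d in datasets for i in d.intensities)
        # TIC normalization rescales; bound within the normalization factor range
        assert pm.matrix.max() <= global_max * 10

    def test_overlapping_intervals_rejected(self):
        ds = _dataset_from_rows([1000.0], [[5.0]])
        with pytest.raises(ValueError, match="overlap"):
            build_peak_matrix(ds, np.array([[1000.0, 0.2], [1000.3, 0.2]]))

    def test_normalize_then_matrix_invariant_to_pixel_rescaling(self, rng):
        """TIC normalization followed by interval maxima is invariant (up to a
        single global factor) to arbitrary per-pixel multiplicative rescaling."""
        masses = np.sort(rng.uniform(900, 1100, 10))
        rows = rng.uniform(1, 100, size=(6, 10))
        ds = _dataset_from_rows(masses, rows)
        scales = rng.uniform(0.1, 10.0, size=6)
        ds_scaled = _dataset_from_rows(masses, rows * scales[:, None])
        intervals = align_peaks(masses)
        m1 = build_peak_matrix(tic_normalize(ds), intervals).matrix
        m2 = build_peak_matrix(tic_normalize(ds_scaled), intervals).matrix
        factor = m2.sum() / m1.sum()
        assert np.allclose(m2, m1 * factor, rtol=1e-5)


class TestIonImage:
    def test_constant_peak_gives_constant_image(self):
        ds = _dataset_from_rows([1000.0], [[5.0]] * 4)
        pm = build_peak_matrix(ds, np.array([[1000.0, 0.15]]))
        img = ion_image(pm, 0, ds.sample_id)
        assert np.allclose(img[np.isfinite(img)], 5.0)

    def test_missing_pixels_are_nan_not_zero(self):
        pm = PeakMatrix(
            np.array([[1000.0, 0.15]]),
            np.array([[0.0], [3.0]]),
            pd.DataFrame({"x": [0, 2], "y": [0, 0], "sample": "s", "roi": "", "group": "unknown"}),
        )
        img = ion_image(pm, 0, "s")
        assert img[0, 0] == 0.0  # measured zero
        assert np.isnan(img[0, 1])  # unmeasured pixel
        assert img[0, 2] == 3.0

    def test_image_matches_matrix_column(self, clean_study):
        pm = clean_study["pm"]
        sample = pm.pixel_table["sample"].iloc[0]
        img = ion_image(pm, 3, sample)
        sub = (pm.pixel_table["sample"] == sample).to_numpy()
        vals = img[pm.pixel_table.loc[sub, "y"], pm.pixel_table.loc[sub, "x"]]
        assert np.allclose(vals, pm.matrix[sub, 3])

    def test_bad_index_rejected(self, clean_study):
        with pytest.raises(IndexError):
            ion_image(clean_study["pm"], 10_000, "HR01")
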