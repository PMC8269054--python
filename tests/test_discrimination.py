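"""Per-peak screening statistics against brute-force oracles, plus
planted-effect recovery and type-I control on synthetic data."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msirisk import discrimination, preprocess, synth
from msirisk.discrimination import (
    balanced_subsample,
    candidates_frame,
    pc_score_image,
    pca_candidates,
    roc_auc,
    roc_screen,
    screen_candidates,
)


def pairwise_auc(pos, neg):
    """Oracle: count wins and half-ties over all (pos, neg) pairs."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def permutation_rank_sum_p(pos, neg):
    """Oracle: exact two-sided permutation p for the rank-sum statistic."""
    from scipy.stats import rankdata

    pooled = np.concatenate([pos, neg])
    n_pos = len(pos)

    def stat(idx):
        ranks = rankdata(pooled)
        return ranks[list(idx)].sum()

    observed = stat(range(n_pos))
    mean = n_pos * (len(pooled) + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_pos):
        total += 1
        if abs(stat(idx) - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


class TestRocAuc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([2, 3], [0, 1], 1.0),
            ([0, 1], [2, 3], 0.0),
            ([1, 2], [1, 2], 0.5),
            ([1, 2, 2], [2, 3], (0 + 2 * 0.5) / 6),  # 0 wins + 2 ties of 6 pairs
        ],
    )
    def test_known_values(self, pos, neg, expected):
        assert roc_auc(pos, neg) == pytest.approx(expected)

    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=20),
        st.lists(st.integers(0, 20), min_size=1, max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_pairwise_counting_oracle(self, pos, neg):
        assert roc_auc(pos, neg) == pytest.approx(pairwise_auc(pos, neg))

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=15),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, pos, neg):
        assert roc_auc(pos, neg) + roc_auc(neg, pos) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 30)
        base = roc_auc(pos, neg)
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v + 2):
            assert roc_auc(f(pos), f(neg)) == pytest.approx(base)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestWilcoxon:
    @pytest.mark.parametrize("seed", range(6))
    def test_p_close_to_exact_permutation(self, seed):
        """The reported p is within 0.01 of the exhaustive permutation p for
        small groups (n <= 8 per group, tie-free intensities)."""
        rng = np.random.default_rng(seed)
        pos = rng.normal(1, 2, rng.integers(4, 9))
        neg = rng.normal(0, 2, rng.integers(4, 9))
        reported = discrimination._rank_sum_p(pos, neg)
        exact = permutation_rank_sum_p(pos, neg)
        assert reported == pytest.approx(exact, abs=0.01)

    @pytest.mark.parametrize("seed", range(4))
    def test_tied_data_falls_back_to_corrected_approximation(self, seed):
        """With ties the asymptotic tie-corrected p tracks the permutation p."""
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 6, 8).astype(float)
        neg = rng.integers(0, 6, 8).astype(float)
        reported = discrimination._rank_sum_p(pos, neg)
        exact = permutation_rank_sum_p(pos, neg)
        assert reported == pytest.approx(exact, abs=0.08)

    def test_identical_groups_give_p_one(self):
        v = np.array([3.0, 3.0, 3.0])
        assert discrimination._rank_sum_p(v, v) == 1.0

    def test_separated_large_groups_significant(self, rng):
        pos, neg = rng.normal(10, 1, 100), rng.normal(0, 1, 100)
        assert discrimination._rank_sum_p(pos, neg) < 1e-10


def _matrix_with_groups(rng, n_per_group=60, n_intervals=6, shift=0.0):
    X = rng.lognormal(3, 0.5, size=(2 * n_per_group, n_intervals))
    X[:n_per_group, 0] *= np.exp(shift)
    table = pd.DataFrame(
        {
            "x": np.arange(2 * n_per_group) % 40,
            "y": np.arange(2 * n_per_group) // 40,
            "sample": "s",
            "roi": "tumor_rich",
            "group": ["HR"] * n_per_group + ["nHR"] * n_per_group,
        }
    )
    centers = 1000.0 + np.arange(n_intervals)
    return preprocess.PeakMatrix(np.column_stack([centers, np.full(n_intervals, 0.15)]), X, table)


class TestBalancedSubsample:
    def test_equal_rows_per_group(self, rng):
        pm = _matrix_with_groups(rng)
        sub = balanced_subsample(pm, 10, seed=1)
        counts = sub.pixel_table["group"].value_counts()
        assert counts["HR"] == counts["nHR"] == 10

    def test_reproducible_under_seed(self, rng):
        pm = _matrix_with_groups(rng)
        s1 = balanced_subsample(pm, 15, seed=3)
        s2 = balanced_subsample(pm, 15, seed=3)
        assert np.array_equal(s1.matrix, s2.matrix)

    def test_oversampling_without_replacement_rejected(self, rng):
        pm = _matrix_with_groups(rng, n_per_group=5)
        with pytest.raises(ValueError, match="replace"):
            balanced_subsample(pm, 10, seed=0)
        sub = balanced_subsample(pm, 10, seed=0, replace=True)
        assert sub.n_pixels == 20

    def test_missing_group_rejected(self, rng):
        pm = _matrix_with_groups(rng)
        pm.pixel_table["group"] = "HR"
        with pytest.raises(ValueError, match="nHR"):
            balanced_subsample(pm, 5, seed=0)


class TestScreen:
    def test_auc_prefilter_masks_p_values(self, rng):
        pm = _matrix_with_groups(rng, shift=2.0)
        table = roc_screen(pm)
        assert np.isfinite(table.loc[0, "p_value"])  # shifted interval tested
        middling = table["auc"].between(0.3, 0.7)
        assert table.loc[middling, "p_value"].isna().all()

    def test_null_auc_never_flagged(self, rng):
        pm = _matrix_with_groups(rng, shift=0.0)
        cands = screen_candidates(pm)
        flagged = [c for c in cands if c.passes_screen]
        assert all(abs(c.auc - 0.5) > 0.2 for c in flagged)

    def test_sorted_by_discriminatory_power(self, rng):
        pm = _matrix_with_groups(rng, shift=1.5)
        cands = screen_candidates(pm)
        strength = [abs(c.auc - 0.5) for c in cands]
        assert strength == sorted(strength, reverse=True)

    def test_planted_peaks_recovered_in_noisy_study(self):
        """Power: with a 2-fold planted effect and moderate noise, at least
        95% of planted discriminative peaks pass the candidate screen, with
        AUC on the planted side of 0.5."""
        cfg = synth.SynthConfig(seed=21)  # defaults: effect 2, noise 5, TIC varied
        datasets, truth = synth.generate_msi_dataset(cfg)
        norm = [preprocess.tic_normalize(d) for d in datasets]
        intervals = preprocess.align_peaks(truth.all_mz())
        rois = [truth.roi_for(d.sample_id) for d in datasets]
        pm = preprocess.build_peak_matrix(norm, intervals, rois)
        pm = pm.subset(pm.roi_mask(synth.TUMOR_LABEL))
        cands = {round(c.mz, 4): c for c in screen_candidates(pm)}
        hits = 0
        for mz, direction in truth.discriminative_mz:
            c = cands[round(pm.centers[pm.interval_index(mz)], 4)]
            if c.passes_screen and ((c.auc > 0.5) == (direction == "up")):
                hits += 1
        assert hits / len(truth.discriminative_mz) >= 0.95

    def test_type_one_error_controlled_on_null_data(self):
        """Null study (no planted effect, single subclone): the fraction of
        intervals reaching p < 0.001 stays at or below 0.005."""
        rng = np.random.default_rng(17)
        n_intervals, n_per_group = 2500, 200
        X = rng.lognormal(3, 0.6, size=(2 * n_per_group, n_intervals))
        table = pd.DataFrame(
            {
                "x": np.arange(2 * n_per_group) % 100,
                "y": np.arange(2 * n_per_group) // 100,
                "sample": "s",
                "roi": "tumor_rich",
                "group": ["HR"] * n_per_group + ["nHR"] * n_per_group,
            }
        )
        centers = 800.0 + np.arange(n_intervals) * 0.5
        pm = preprocess.PeakMatrix(
            np.column_stack([centers, np.full(n_intervals, 0.15)]), X, table
        )
        cands = screen_candidates(pm)
        false_rate = np.mean([c.passes_screen for c in cands])
        assert false_rate <= 0.005

    def test_invalid_thresholds_rejected(self, rng):
        pm = _matrix_with_groups(rng)
        with pytest.raises(ValueError):
            screen_candidates(pm, auc_lo=0.8, auc_hi=0.2)


class TestPca:
    def test_loadings_equal_direct_eigendecomposition(self):
        """Oracle: loadings of a 5x4 toy matrix equal the eigenvectors of the
        level-scaled covariance, up to sign."""
        X = np.array(
            [
                [4.0, 2.0, 1.0, 7.0],
                [5.0, 1.0, 2.0, 6.0],
                [6.0, 3.0, 1.5, 5.0],
                [4.5, 2.5, 1.2, 8.0],
                [5.5, 1.5, 2.2, 6.5],
            ]
        )
        pm = preprocess.PeakMatrix(
            np.column_stack([1000.0 + np.arange(4), np.full(4, 0.15)]),
            X,
            pd.DataFrame({"x": range(5), "y": 0, "sample": "s", "roi": "", "group": "HR"}),
        )
        res = pca_candidates(pm, n_components=3)
        scaled = (X - X.mean(0)) / X.mean(0)
        cov = np.cov(scaled - scaled.mean(0), rowvar=False)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for j in range(3):
            dot = abs(res.loadings[:, j] @ v[:, j])
            assert dot == pytest.approx(1.0, abs=1e-9)
        assert res.explained_variance_ratio == pytest.approx(w[:3] / w.sum(), abs=1e-12)

    def test_variance_fractions_monotone_and_bounded(self, rng):
        pm = _matrix_with_groups(rng, n_per_group=50, n_intervals=8)
        res = pca_candidates(pm, n_components=5)
        evr = res.explained_variance_ratio
        assert np.all(evr >= 0) and np.all(evr <= 1)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_dominant_group_direction_loads_on_pc1(self, rng):
        pm = _matrix_with_groups(rng, n_per_group=80, n_intervals=6, shift=0.0)
        g = pm.pixel_table["group"] == "HR"
        pm.matrix[g.to_numpy()] *= 3.0  # one dominant direction
        res = pca_candidates(pm)
        assert res.explained_variance_ratio[0] > res.explained_variance_ratio[1:].max()
        scores = res.scores[:, 0]
        assert abs(np.mean(scores[g]) - np.mean(scores[~g])) > np.std(scores) / 2

    def test_zero_mean_interval_dropped_with_warning(self, rng):
        pm = _matrix_with_groups(rng)
        pm.matrix[:, 2] = 0.0
        with pytest.warns(UserWarning, match="zero-mean"):
            res = pca_candidates(pm)
        assert len(res.kept_centers) == pm.n_intervals - 1

    def test_fewer_intervals_than_components_truncates(self, rng):
        pm = _matrix_with_groups(rng, n_intervals=3)
        with pytest.warns(UserWarning, match="truncating"):
            res = pca_candidates(pm, n_components=5)
        assert res.loadings.shape[1] == 3

    def test_score_image_matches_projection(self, rng):
        pm = _matrix_with_groups(rng, n_per_group=20)
        res = pca_candidates(pm, n_components=2)
        img = pc_score_image(res, 0, "s")
        xs = res.pixel_table["x"].to_numpy()
        ys = res.pixel_table["y"].to_numpy()
        assert np.allclose(img[ys, xs], res.scores[:, 0])
        with pytest.raises(IndexError):
            pc_score_image(res, 5, "s")


def test_candidates_frame_round_trip(rng):
    pm = _matrix_with_groups(rng, shift=1.0)
    cands = screen_candidates(pm)
    df = candidates_frame(cands)
    assert len(df) == pm.n_intervals
    assert {"mz", "auc", "p_value", "passes_screen"} <= set(df.columns)
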