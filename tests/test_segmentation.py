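"""TFT tensor, feature extraction, and constrained clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score

import tftseg as T
from tftseg.io import EEGRecording
from tftseg.segmentation import _labels_from_merges


def naive_constrained_ward(X, k):
    """O(n^3) reference: recompute every within-cluster SSE from scratch."""
    X = np.asarray(X, float)
    clusters = [[i] for i in range(len(X))]

    def sse(idx):
        pts = X[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    while len(clusters) > k:
        best_d, best_p = None, None
        for p in range(len(clusters) - 1):
            merged = clusters[p] + clusters[p + 1]
            d = sse(merged) - sse(clusters[p]) - sse(clusters[p + 1])
            if best_d is None or d < best_d:
                best_d, best_p = d, p
        clusters[best_p:best_p + 2] = [clusters[best_p] + clusters[best_p + 1]]
    labels = np.empty(len(X), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


class TestComputeTFT:
    def test_zero_input_gives_zero_tensor(self):
        rec = EEGRecording(("a", "b"), 128.0, np.zeros((2, 1280)))
        assert np.all(T.compute_tft(rec).power == 0)

    def test_pure_tone_peaks_at_its_bin(self):
        t = np.arange(128 * 20) / 128.0
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = EEGRecording(("a", "b", "c"), 128.0, np.tile(x, (3, 1)))
        tensor = T.compute_tft(rec)
        expected_bin = int(np.argmin(np.abs(tensor.freq_axis - 10.0)))
        peak = tensor.power.argmax(axis=1)
        assert np.all(peak == expected_bin)

    def test_band_noise_parseval(self, rng):
        # windowed variance vs integrated in-band PSD, Hann-corrected
        cfg = T.SimConfig(regimes=[T.RegimeSpec(30.0, {(5.0, 45.0): 8.0})],
                          background_psd=0.0, seed=1)
        rec, _ = T.simulate_eeg(cfg)
        tensor = T.compute_tft(rec, fmin=0.0, fmax=64.0)
        df = tensor.freq_axis[1] - tensor.freq_axis[0]
        tensor_power = tensor.power.sum(axis=1).mean() * df
        assert tensor_power == pytest.approx(rec.samples.var(), rel=0.05)

    def test_window_longer_than_record(self):
        rec = EEGRecording(("a",), 128.0, np.zeros((1, 64)))
        with pytest.raises(ValueError, match="longer"):
            T.compute_tft(rec, window=2.0)

    def test_axes_match_power_shape(self, four_regime_run):
        tensor = four_regime_run["tensor"]
        assert tensor.power.shape == (len(tensor.time_axis),
                                      len(tensor.freq_axis), 14)
        assert tensor.freq_axis.min() >= 2.0
        assert tensor.freq_axis.max() <= 50.0


class TestFeatures:
    def test_shape_is_bins_by_freqs_times_channels(self, four_regime_run):
        tensor = four_regime_run["tensor"]
        X = four_regime_run["features"]
        assert X.shape == (tensor.power.shape[0],
                           len(tensor.freq_axis) * 14)

    def test_zero_power_stays_finite(self):
        rec = EEGRecording(("a", "b"), 128.0, np.zeros((2, 1280)))
        X = T.tft_features(T.compute_tft(rec))
        assert np.all(np.isfinite(X))

    def test_stationary_rows_closer_than_two_regime_rows(self):
        # measured on raw log-power rows: z-scoring fixes the global
        # distance scale, so temporal structure shows up before it
        from scipy.spatial.distance import pdist
        one = T.SimConfig(regimes=[T.RegimeSpec(30.0, {(8.0, 12.0): 10.0})],
                          seed=3)
        two = T.SimConfig(regimes=[T.RegimeSpec(15.0, {(8.0, 12.0): 10.0}),
                                   T.RegimeSpec(15.0, {(18.0, 25.0): 10.0})],
                          seed=3)
        dists = []
        for cfg in (one, two):
            rec, _ = T.simulate_eeg(cfg)
            tensor = T.compute_tft(T.bandpass(rec))
            nt = tensor.power.shape[0]
            logp = np.log(tensor.power + 1e-12).reshape(nt, -1)
            dists.append(pdist(logp).mean())
        assert dists[0] < dists[1]

    def test_fewer_than_two_bins_rejected(self):
        rec = EEGRecording(("a",), 128.0, np.random.default_rng(0)
                           .normal(size=(1, 256)))
        with pytest.raises(ValueError, match="2 time bins"):
            T.tft_features(T.compute_tft(rec, window=2.0, hop=2.0))


class TestConstrainedHCA:
    def test_two_block_boundary_recovered(self, rng):
        X = np.r_[rng.normal(0, 1, (30, 5)), rng.normal(4, 1, (25, 5))]
        lab = T.constrained_hca(X, k=2)
        assert lab.labels[0] != lab.labels[-1]
        boundary = int(np.argmax(np.diff(lab.labels) != 0)) + 1
        assert abs(boundary - 30) <= 1

    def test_k_equals_n_bins_gives_singletons(self, rng):
        X = rng.normal(size=(12, 3))
        lab = T.constrained_hca(X, k=12)
        assert len(np.unique(lab.labels)) == 12

    @pytest.mark.parametrize("n,k", [(10, 2), (25, 3), (50, 4), (50, 7)])
    def test_matches_naive_oracle(self, n, k, rng):
        X = rng.normal(size=(n, 4))
        lab = T.constrained_hca(X, k=k)
        oracle = naive_constrained_ward(X, k)
        assert adjusted_rand_score(lab.labels, oracle) == 1.0

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_matches_sklearn_connectivity_ward(self, k, rng):
        from scipy.sparse import diags
        X = rng.normal(size=(40, 6))
        conn = diags([1.0, 1.0], [-1, 1], shape=(40, 40))
        sk = AgglomerativeClustering(n_clusters=k, linkage="ward",
                                     connectivity=conn).fit(X)
        lab = T.constrained_hca(X, k=k)
        assert adjusted_rand_score(lab.labels, sk.labels_) == 1.0

    def test_segment_count_non_increasing_in_cut_height(self, rng):
        # cutting lower in the dendrogram never yields fewer segments
        X = rng.normal(size=(30, 4))
        ks = [T.constrained_hca(X, k=k).n_segments for k in range(30, 0, -1)]
        assert ks == sorted(ks, reverse=True)
        assert ks[0] == 30 and ks[-1] == 1

    def test_invariant_to_global_amplitude_rescaling(self):
        rec, _ = T.simulate_eeg(T.four_regime_config(seed=5))
        rec2 = EEGRecording(rec.labels, rec.rate, rec.samples * 7.3)
        labs = []
        for r in (rec, rec2):
            tensor = T.compute_tft(T.bandpass(r))
            labs.append(T.constrained_hca(T.tft_features(tensor)).labels)
        np.testing.assert_array_equal(*labs)

    def test_k_larger_than_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            T.constrained_hca(rng.normal(size=(5, 2)), k=6)

    def test_estimator_interface(self, rng):
        X = np.r_[rng.normal(0, 1, (20, 3)), rng.normal(5, 1, (20, 3))]
        est = T.ConstrainedWard().fit(X)
        assert est.n_clusters_ == len(np.unique(est.labels_))
        assert est.fit_predict(X).shape == (40,)


class TestSelectK:
    def test_dominant_jump_returns_its_k(self):
        # 9 merges; a 50x jump between the 3rd-last and 2nd-last merge
        heights = [1, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 80.0, 90.0]
        assert T.select_k(heights) == 3

    def test_uniform_heights_fall_back_to_one(self):
        assert T.select_k([2.0] * 9) == 1

    def test_empty_heights(self):
        assert T.select_k([]) == 1

    @given(st.lists(st.floats(min_value=0, max_value=1e6), max_size=40),
           st.integers(min_value=1, max_value=12))
    @settings(deadline=None, max_examples=100)
    def test_bounded(self, heights, k_max):
        assert 1 <= T.select_k(heights, k_max=k_max) <= k_max


class TestEpochsFromLabels:
    def test_run_length_example(self):
        segs = T.epochs_from_labels([0, 0, 1, 1], [0.5, 1.5, 2.5, 3.5],
                                    duration=4.0)
        assert segs == [(0.0, 2.0, 0), (2.0, 4.0, 1)]

    def test_single_label_spans_record(self):
        segs = T.epochs_from_labels([3, 3, 3], [0.5, 1.5, 2.5], duration=3.0)
        assert segs == [(0.0, 3.0, 3)]

    def test_segments_tile_the_record(self, four_regime_run):
        lab = four_regime_run["labeling"]
        dur = four_regime_run["rec"].duration
        assert lab.segments[0][0] == 0.0
        assert lab.segments[-1][1] == pytest.approx(dur)
        for a, b in zip(lab.segments[:-1], lab.segments[1:]):
            assert a[1] == pytest.approx(b[0])


def test_end_to_end_recovery_single_seed(four_regime_run):
    gt, lab = four_regime_run["gt"], four_regime_run["labeling"]
    tensor, rec = four_regime_run["tensor"], four_regime_run["rec"]
    idx = (tensor.time_axis * rec.rate).astype(int)
    ari = adjusted_rand_score(gt.regime_id[idx], lab.labels)
    assert lab.n_segments == 4
    assert ari >= 0.8
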