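"""Filtering, ICA, and ADJUST-style artifact detection."""

import numpy as np
import pytest
from scipy import signal
from scipy.optimize import linear_sum_assignment

import tftseg as T
from tftseg.io import EEGRecording, STUDY_CHANNELS
from tftseg.preprocess import ICADecomposition, _design_bandpass


def _sine_rec(freq, rate=128.0, seconds=8.0, n_chan=2):
    t = np.arange(int(rate * seconds)) / rate
    x = np.sin(2 * np.pi * freq * t)
    return EEGRecording(tuple(f"C{i}" for i in range(n_chan)), rate,
                        np.tile(x, (n_chan, 1)))


class TestBandpass:
    def test_dc_is_removed(self):
        rec = EEGRecording(("A",), 128.0, np.full((1, 1024), 50.0))
        out = T.bandpass(rec)
        assert np.abs(out.samples).max() < 50.0 * 1e-3

    def test_10hz_passes_at_designed_gain(self):
        # oracle: the squared (forward-backward) design response at 10 Hz
        sos = _design_bandpass(2.0, 50.0, 128.0, 8)
        w, h = signal.sosfreqz(sos, worN=[10.0], fs=128.0)
        designed = np.abs(h[0]) ** 2
        out = T.bandpass(_sine_rec(10.0))
        mid = out.samples[0, 256:-256]  # skip edge transients
        measured = np.abs(mid).max()
        assert measured == pytest.approx(designed, abs=0.02)
        assert 0.95 <= measured <= 1.05

    def test_60hz_attenuated_at_least_20db(self):
        sos = _design_bandpass(2.0, 50.0, 128.0, 8)
        w, h = signal.sosfreqz(sos, worN=[60.0], fs=128.0)
        assert np.abs(h[0]) ** 2 < 0.1  # design oracle agrees
        out = T.bandpass(_sine_rec(60.0))
        assert np.abs(out.samples[0, 256:-256]).max() < 0.1

    def test_high_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            T.bandpass(_sine_rec(10.0), low=2.0, high=64.0)

    def test_estimator_matches_function(self, rng):
        X = rng.normal(size=(1024, 3))
        rec = EEGRecording(("a", "b", "c"), 128.0, X.T)
        est = T.BandpassFilter(rate=128.0).fit(X)
        np.testing.assert_allclose(est.transform(X).T,
                                   T.bandpass(rec).samples)


class TestICA:
    def test_reconstruction_is_identity(self, blink_run):
        dec = blink_run["dec"]
        recon = dec.reconstruct()
        scale = np.abs(blink_run["filt"].samples).max()
        err = np.abs(recon - blink_run["filt"].samples).max()
        assert err < 1e-6 * scale

    def test_same_seed_same_mixing(self, blink_run):
        again = T.ica_fit(blink_run["filt"], seed=7)
        np.testing.assert_array_equal(again.mixing, blink_run["dec"].mixing)

    def test_known_sources_recovered(self, rng):
        # 4 independent non-Gaussian sources, random mixing
        n = 128 * 40
        t = np.arange(n) / 128.0
        S = np.stack([
            signal.square(2 * np.pi * 0.7 * t),
            signal.sawtooth(2 * np.pi * 1.3 * t),
            rng.laplace(size=n),
            np.sign(np.sin(2 * np.pi * 0.23 * t)) * rng.uniform(0.5, 1, n),
        ])
        A = rng.normal(size=(6, 4))
        rec = EEGRecording(tuple("abcdef"), 128.0, A @ S)
        dec = T.ica_fit(rec, n_components=4, seed=0)
        C = np.abs(np.corrcoef(dec.sources, S)[:4, 4:])
        rows, cols = linear_sum_assignment(-C)
        assert np.all(C[rows, cols] >= 0.95)

    def test_short_record_rejected(self, rng):
        rec = EEGRecording(("a", "b"), 128.0, rng.normal(size=(2, 128)))
        with pytest.raises(ValueError, match="short"):
            T.ica_fit(rec)

    def test_rank_deficient_rejected(self, rng):
        x = rng.normal(size=128 * 40)
        rec = EEGRecording(("a", "b"), 128.0, np.stack([x, 2 * x]))
        with pytest.raises(ValueError, match="rank"):
            T.ica_fit(rec)


def _flat_decomposition(montage, rng, n_comp=4, seconds=60, rate=128.0):
    n = int(seconds * rate)
    labels = STUDY_CHANNELS
    mixing = rng.normal(size=(14, n_comp))
    mixing[:, 0] = 1.0  # identical weight on every channel
    sources = rng.standard_normal((n_comp, n))
    return ICADecomposition(mixing=mixing, sources=sources,
                            mean=np.zeros(14), labels=labels, rate=rate,
                            seed=0)


class TestAdjustFeatures:
    def test_uniform_topography_has_zero_spatial_features(self, montage, rng):
        feats = T.adjust_features(_flat_decomposition(montage, rng), montage)
        assert feats.loc[0, "SAD"] == pytest.approx(0.0, abs=1e-12)
        assert feats.loc[0, "SED"] == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_has_near_zero_kurtosis(self, montage, rng):
        feats = T.adjust_features(_flat_decomposition(montage, rng), montage)
        assert np.all(np.abs(feats["TK"]) < 0.5)  # 60 one-second epochs

    def test_blink_component_ranks_top_on_sad(self, blink_run):
        feats = blink_run["feats"]
        blink = max(blink_run["flags"])  # the flagged component
        assert feats.loc[blink, "SAD"] > 0
        assert feats.loc[blink, "SAD"] == feats["SAD"].max()

    def test_epoch_longer_than_record(self, montage, rng):
        dec = _flat_decomposition(montage, rng, seconds=2)
        with pytest.raises(ValueError, match="epoch"):
            T.adjust_features(dec, montage, epoch_length=10.0)

    def test_montage_must_cover_channels(self, blink_run, montage):
        dec = blink_run["dec"]
        bad = T.Montage(positions={"AF3": (0.0, 0.5)})
        with pytest.raises(KeyError):
            T.adjust_features(dec, bad)


class TestFlagArtifacts:
    def test_blink_fixture_flags_exactly_the_blink(self, blink_run):
        flags = blink_run["flags"]
        assert list(flags.values()) == ["blink"]

    def test_identical_components_flag_nothing(self):
        import pandas as pd
        feats = pd.DataFrame(
            {k: [1.0] * 8 for k in T.preprocess.FEATURE_NAMES})
        with pytest.warns(UserWarning, match="degenerate"):
            assert T.flag_artifacts(feats) == {}

    def test_flags_are_subset_of_component_ids(self, blink_run):
        assert set(blink_run["flags"]) <= set(range(len(blink_run["feats"])))

    def test_too_few_components_rejected(self, blink_run):
        with pytest.raises(ValueError, match="4 components"):
            T.flag_artifacts(blink_run["feats"].iloc[:3])

    def test_permutation_equivariance(self, blink_run, rng):
        feats = blink_run["feats"]
        perm = rng.permutation(len(feats))
        shuffled = feats.iloc[perm].reset_index(drop=True)
        flags_p = T.flag_artifacts(shuffled, seed=7)
        expect = {int(np.nonzero(perm == k)[0][0]): v
                  for k, v in blink_run["flags"].items()}
        assert flags_p == expect


class TestRemoveComponents:
    def test_empty_flags_is_identity(self, blink_run):
        out = T.remove_components(blink_run["dec"], {})
        scale = np.abs(blink_run["filt"].samples).max()
        assert np.abs(out.samples - blink_run["filt"].samples).max() \
            < 1e-6 * scale

    def test_all_flagged_gives_mean_only(self, blink_run):
        dec = blink_run["dec"]
        out = T.remove_components(dec, set(range(dec.n_components)))
        np.testing.assert_allclose(
            out.samples, np.broadcast_to(dec.mean[:, None],
                                         out.samples.shape), atol=1e-9)

    def test_out_of_range_flag_rejected(self, blink_run):
        with pytest.raises(IndexError):
            T.remove_components(blink_run["dec"], {99})

    def test_blink_energy_reduced(self, blink_run):
        gt, filt = blink_run["gt"], blink_run["filt"]
        clean = T.remove_components(blink_run["dec"], blink_run["flags"])
        sos = signal.butter(4, [0.5, 4.0], btype="band", output="sos",
                            fs=filt.rate)
        i = filt.labels.index("AF3")
        w = int(0.3 * filt.rate)

        def energy(x):
            xb = signal.sosfiltfilt(sos, x)
            return sum(np.sum(xb[int(t * filt.rate):
                                 int(t * filt.rate) + w] ** 2)
                       for t in gt.blink_times)

        assert energy(clean.samples[i]) < 0.2 * energy(filt.samples[i])


def test_filter_then_ica_reconstruction_is_identity(blink_run):
    """The pipeline must not silently distort data when nothing is removed."""
    X = blink_run["filt"].samples.T
    est = T.ICAArtifactRemover(random_state=7).fit(X)
    est.flags_ = {}
    np.testing.assert_allclose(est.transform(X), X, atol=1e-6)
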