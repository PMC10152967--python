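"""EEG preprocessing: band-pass filtering, ICA, and artifact rejection.

The cleaning pipeline mirrors common EEG practice: a 2-50 Hz zero-phase
band-pass (covering the rhythms associated with cognitive activity while
excluding mains interference), ICA decomposition, and a reduced
reimplementation of the ADJUST artifact classifier, which combines
stereotyped spatial features of each component's topography (SAD, SED,
GDSF) with temporal features of its source signal (TK, MEV) to flag
blinks, eye movements and generic discontinuities.  Flagged components
are zeroed before reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.mixture import GaussianMixture

from .io import EEGRecording, Montage, STUDY_CHANNELS, STUDY_RATE, default_montage

FEATURE_NAMES = ("SAD", "SED", "TK", "MEV", "GDSF")
ARTIFACT_CLASSES = ("blink", "vertical", "horizontal", "discontinuity")

#: electrodes closest to the eyes in this montage, used by SED
LEFT_EYE_AREA = ("AF3", "F7")
RIGHT_EYE_AREA = ("AF4", "F8")

#: minimum record length (s) for a stable unmixing
MIN_ICA_DURATION = 30.0


def _design_bandpass(low: float, high: float, rate: float, order: int = 8):
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= rate / 2:
        raise ValueError(f"high={high} Hz is at or above Nyquist ({rate / 2} Hz)")
    return signal.butter(order, [low, high], btype="band", output="sos", fs=rate)


def bandpass(rec: EEGRecording, low: float = 2.0, high: float = 50.0,
             order: int = 8) -> EEGRecording:
    """Zero-phase Butterworth band-pass, default 2-50 Hz.

    Forward-backward filtering (``sosfiltfilt``) keeps segment timing
    undistorted; the effective magnitude response is the squared design
    response.
    """
    sos = _design_bandpass(low, high, rec.rate, order)
    y = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return EEGRecording(rec.labels, rec.rate, y, rec.start_time)


@dataclass
class ICADecomposition:
    """Result of a deterministic fixed-point ICA on a filtered recording.

    ``mixing @ sources + mean[:, None]`` reconstructs the input within
    numerical tolerance.
    """

    mixing: np.ndarray        # (n_channels, n_components)
    sources: np.ndarray       # (n_components, n_times)
    mean: np.ndarray          # (n_channels,)
    labels: tuple[str, ...]
    rate: float
    seed: int

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self, drop=()) -> np.ndarray:
        """Channel-space signal with the components in ``drop`` zeroed."""
        drop = set(drop)
        bad = [i for i in drop if not 0 <= i < self.n_components]
        if bad:
            raise IndexError(f"component ids out of range: {bad}")
        keep = [i for i in range(self.n_components) if i not in drop]
        return self.mixing[:, keep] @ self.sources[keep] + self.mean[:, None]


def ica_fit(rec: EEGRecording, n_components: int | None = None,
            seed: int = 0) -> ICADecomposition:
    """Deflationary FastICA decomposition of a (filtered) recording.

    Deterministic for a given ``seed``.  Requires at least 30 s of signal
    for a stable unmixing and a full-rank channel covariance.
    """
    if rec.duration < MIN_ICA_DURATION:
        raise ValueError(
            f"record too short for stable ICA: {rec.duration:.1f} s < "
            f"{MIN_ICA_DURATION:.0f} s")
    X = rec.samples.T  # (n_times, n_channels)
    k = n_components or rec.n_channels
    if np.linalg.matrix_rank(np.cov(rec.samples)) < k:
        raise ValueError("rank-deficient input: fewer independent channels "
                         "than requested components")
    ica = FastICA(n_components=k, algorithm="deflation",
                  whiten="unit-variance", max_iter=2000, tol=1e-8,
                  random_state=seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        S = ica.fit_transform(X)  # (n_times, k), unit-variance sources
    return ICADecomposition(mixing=ica.mixing_.copy(), sources=S.T,
                            mean=ica.mean_.copy(), labels=rec.labels,
                            rate=rec.rate, seed=seed)


# ---------------------------------------------------------------------------
# ADJUST-style component features

def _epoch_view(x: np.ndarray, samples_per_epoch: int) -> np.ndarray:
    n = (x.shape[-1] // samples_per_epoch) * samples_per_epoch
    if n == 0:
        raise ValueError("epoch longer than the record")
    return x[..., :n].reshape(*x.shape[:-1], -1, samples_per_epoch)


def adjust_features(decomp: ICADecomposition, montage: Montage | None = None,
                    epoch_length: float = 1.0) -> pd.DataFrame:
    """Spatial and temporal artifact features per independent component.

    Columns: SAD (spatial average difference, mean |anterior| - mean
    |posterior| topography weight), SED (spatial eye difference between
    the left and right eye-area electrodes), TK (mean temporal kurtosis
    over epochs), MEV (max/mean epoch variance), GDSF (generic
    discontinuity spatial feature: largest deviation of an electrode
    weight from the distance-weighted mean of the others).
    """
    montage = montage or default_montage()
    labels = decomp.labels
    missing = [l for l in labels if l not in montage.positions]
    if missing:
        raise KeyError(f"montage does not cover channels: {missing}")
    ant = np.array([montage.anterior.get(l, False) for l in labels])
    pos = montage.coords(labels)
    le = np.array([l in LEFT_EYE_AREA for l in labels])
    re = np.array([l in RIGHT_EYE_AREA for l in labels])

    spe = int(round(epoch_length * decomp.rate))
    epochs = _epoch_view(decomp.sources, spe)           # (k, n_ep, spe)
    ep_var = epochs.var(axis=2)
    tk = stats.kurtosis(epochs, axis=2, fisher=True).mean(axis=1)
    mev = ep_var.max(axis=1) / np.maximum(ep_var.mean(axis=1), 1e-300)

    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    w = np.exp(-d)
    np.fill_diagonal(w, 0.0)
    rows = []
    for k in range(decomp.n_components):
        a = decomp.mixing[:, k]
        sad = np.abs(a[ant]).mean() - np.abs(a[~ant]).mean()
        sed = abs(a[le].mean() - a[re].mean())
        gdsf = np.max(a - (w @ a) / w.sum(axis=1))
        rows.append((sad, sed, tk[k], mev[k], gdsf))
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


def _gmm_high_set(values: np.ndarray, seed: int = 0) -> set[int]:
    """Indices above an automatic threshold from a two-Gaussian split.

    The threshold is the equal-posterior point between the two fitted
    Gaussians.  A degenerate fit (no spread, or overlapping components)
    yields an empty set.
    """
    v = np.asarray(values, float)
    if np.std(v) < 1e-12:
        return set()
    # standardized scale; EM initialized at the bulk (median) and the top
    # value, with a covariance floor so neither component can collapse
    # onto a single point
    z = (v - np.median(v)) / np.std(v)
    gmm = GaussianMixture(n_components=2, random_state=seed,
                          reg_covar=0.01,
                          means_init=[[0.0], [z.max()]])
    gmm.fit(z.reshape(-1, 1))
    mus = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    lo, hi = np.argsort(mus)
    if mus[hi] - mus[lo] < max(sds[lo], sds[hi]):
        return set()  # the two components overlap: no separable split
    grid = np.linspace(mus[lo], mus[hi], 512).reshape(-1, 1)
    post = gmm.predict_proba(grid)
    cross = np.nonzero(post[:, hi] >= 0.5)[0]
    thr = grid[cross[0], 0] if len(cross) else (mus[lo] + mus[hi]) / 2
    return set(np.nonzero(z > thr)[0].tolist())


def flag_artifacts(features: pd.DataFrame, seed: int = 0) -> dict[int, str]:
    """Classify artifact components from their features.

    Per-feature thresholds are set automatically by a two-component
    Gaussian-mixture split.  Classes (first match wins): blink = SAD & TK
    high; vertical eye movement = SAD & MEV; horizontal eye movement =
    SED & MEV; generic discontinuity = GDSF & MEV.
    """
    if len(features) < 4:
        raise ValueError("need at least 4 components to set thresholds")
    if all(features[f].std() < 1e-12 for f in FEATURE_NAMES):
        warnings.warn("degenerate feature variance; nothing flagged")
        return {}
    high = {f: _gmm_high_set(features[f].to_numpy(), seed) for f in FEATURE_NAMES}
    rules = [
        ("blink", ("SAD", "TK")),
        ("vertical", ("SAD", "MEV")),
        ("horizontal", ("SED", "MEV")),
        ("discontinuity", ("GDSF", "MEV")),
    ]
    flags: dict[int, str] = {}
    for comp in range(len(features)):
        for cls, (f1, f2) in rules:
            if comp in high[f1] and comp in high[f2]:
                flags[comp] = cls
                break
    return flags


def remove_components(decomp: ICADecomposition, flags) -> EEGRecording:
    """Reconstruct the recording with the flagged components removed."""
    drop = set(flags.keys()) if isinstance(flags, dict) else set(flags)
    return EEGRecording(decomp.labels, decomp.rate, decomp.reconstruct(drop))


# ---------------------------------------------------------------------------
# Estimator interfaces

class BandpassFilter(TransformerMixin, BaseEstimator):
    """Zero-phase Butterworth band-pass as a transformer.

    Operates on arrays of shape (n_times, n_channels).

    Parameters
    ----------
    low, high : float
        Pass band in Hz (default 2-50).
    rate : float
        Sampling rate in Hz.
    order : int
        Butterworth design order (applied forward and backward).
    """

    def __init__(self, low: float = 2.0, high: float = 50.0,
                 rate: float = STUDY_RATE, order: int = 8):
        self.low = low
        self.high = high
        self.rate = rate
        self.order = order

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("expected (n_times, n_channels)")
        self.sos_ = _design_bandpass(self.low, self.high, self.rate, self.order)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        return signal.sosfiltfilt(self.sos_, X, axis=0)


class ICAArtifactRemover(TransformerMixin, BaseEstimator):
    """ICA + ADJUST-style flagging + component removal as a transformer.

    ``fit`` decomposes the training signal, computes the component
    features and flags artifact components; ``transform`` projects data
    onto the fitted components, zeroes the flagged ones and reconstructs.

    Fitted attributes: ``decomposition_``, ``features_`` (DataFrame with
    an ``artifact_class`` column), ``flags_`` (dict id -> class).
    """

    def __init__(self, rate: float = STUDY_RATE, channels=STUDY_CHANNELS,
                 n_components: int | None = None, epoch_length: float = 1.0,
                 random_state: int = 0):
        self.rate = rate
        self.channels = channels
        self.n_components = n_components
        self.epoch_length = epoch_length
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        rec = EEGRecording(tuple(self.channels), self.rate, X.T)
        self.decomposition_ = ica_fit(rec, self.n_components,
                                      self.random_state)
        feats = adjust_features(self.decomposition_,
                                epoch_length=self.epoch_length)
        self.flags_ = flag_artifacts(feats, seed=self.random_state)
        feats["artifact_class"] = [self.flags_.get(i, "none")
                                   for i in range(len(feats))]
        self.features_ = feats
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        d = self.decomposition_
        # unmix with the fitted model, zero flagged components, remix
        unmix = np.linalg.pinv(d.mixing)
        S = unmix @ (X.T - d.mean[:, None])
        for k in self.flags_:
            S[k] = 0.0
        return (d.mixing @ S + d.mean[:, None]).T
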