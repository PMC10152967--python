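"""Time-Frequency-Topography segmentation into TFT-epochs.

The EEG is projected into a time x frequency x channel power tensor with
the short-time Fourier transform, flattened and standardized into a
per-time-bin feature matrix, and segmented by hierarchical agglomerative
clustering constrained to merge only temporally adjacent clusters.  The
two principles are: *similarity* (Ward's minimum-variance criterion on
the feature rows) and *adjacency* (each cluster is one contiguous time
interval, a TFT-epoch, read as a proxy for a cognitive subprocess).

The number of epochs is either given or chosen at the largest relative
gap between successive dendrogram merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .io import EEGRecording


@dataclass
class TFTTensor:
    """STFT power, time bins x frequency bins x channels (uV^2/Hz)."""

    power: np.ndarray
    window: float
    hop: float
    freq_axis: np.ndarray   # Hz
    time_axis: np.ndarray   # bin centers, s
    duration: float         # source record length, s

    def __post_init__(self):
        if self.power.shape != (len(self.time_axis), len(self.freq_axis),
                                self.power.shape[2]):
            raise ValueError("axis lengths do not match the power array")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SegmentLabeling:
    """Cluster label per time bin plus the derived contiguous segments."""

    labels: np.ndarray                       # per time bin
    segments: list[tuple[float, float, int]] # (start s, end s, cluster id)
    merge_heights: np.ndarray                # Ward increments, merge order
    time_axis: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def compute_tft(rec: EEGRecording, window: float = 2.0, hop: float = 0.5,
                fmin: float = 2.0, fmax: float = 50.0) -> TFTTensor:
    """Magnitude-squared STFT per channel, cropped to the filter band.

    Hann taper, PSD scaling; default 2 s window / 0.5 s hop gives 0.5 Hz
    resolution at 128 Hz with 4x oversampled segment boundaries.
    """
    nperseg = int(round(window * rec.rate))
    nhop = int(round(hop * rec.rate))
    if nperseg < 2:
        raise ValueError("window shorter than 2 samples")
    if nperseg > rec.n_times:
        raise ValueError("window longer than the record")
    if nhop > nperseg:
        raise ValueError("hop must not exceed the window")
    f, t, S = signal.spectrogram(
        rec.samples, fs=rec.rate, window="hann", nperseg=nperseg,
        noverlap=nperseg - nhop, detrend=False, scaling="density",
        mode="psd")
    keep = (f >= fmin) & (f <= fmax)
    power = np.transpose(S[:, keep, :], (2, 1, 0))  # (time, freq, channel)
    return TFTTensor(power=power, window=window, hop=hop,
                     freq_axis=f[keep], time_axis=t + rec.start_time,
                     duration=rec.duration)


def tft_features(tensor: TFTTensor, eps: float = 1e-12) -> np.ndarray:
    """Log-power features, flattened over (frequency, channel), z-scored.

    Each column is standardized to zero mean / unit variance over time so
    that no frequency or channel dominates the clustering distance and
    the segmentation is invariant to global amplitude rescaling.
    """
    nt = tensor.power.shape[0]
    if nt < 2:
        raise ValueError("need at least 2 time bins")
    X = np.log(tensor.power + eps).reshape(nt, -1)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# Adjacency-constrained agglomerative clustering

def _constrained_linkage(X: np.ndarray, linkage: str = "ward"
                         ) -> tuple[np.ndarray, list[int]]:
    """Merge only temporally adjacent clusters; return heights and the
    original-bin boundary removed at each merge (in merge order).

    Ward height = the within-cluster sum-of-squares increment
    n1*n2/(n1+n2) * ||mu1 - mu2||^2; average linkage = mean pairwise
    Euclidean distance.  Ties break toward the earliest left boundary.
    """
    X = np.asarray(X, float)
    n = len(X)
    sizes = np.ones(n)
    means = X.copy()
    D = squareform(pdist(X)) if linkage == "average" else None
    order = list(range(n))          # active cluster ids, temporal order
    start = list(range(n))          # leftmost original bin per cluster id
    removed: list[int] = []
    heights: list[float] = []
    while len(order) > 1:
        ids = np.array(order)
        if linkage == "ward":
            a, b = ids[:-1], ids[1:]
            d = (sizes[a] * sizes[b] / (sizes[a] + sizes[b])
                 * ((means[a] - means[b]) ** 2).sum(axis=1))
        elif linkage == "average":
            d = D[ids[:-1], ids[1:]]
        else:
            raise ValueError(f"unknown linkage: {linkage!r}")
        p = int(np.argmin(d))       # first minimum = earliest left boundary
        i, j = order[p], order[p + 1]
        heights.append(float(d[p]))
        removed.append(start[j])
        if linkage == "average":
            others = [c for c in order if c not in (i, j)]
            if others:
                newd = (sizes[i] * D[i, others] + sizes[j] * D[j, others]) \
                    / (sizes[i] + sizes[j])
                D[i, others] = newd
                D[others, i] = newd
        means[i] = (sizes[i] * means[i] + sizes[j] * means[j]) \
            / (sizes[i] + sizes[j])
        sizes[i] += sizes[j]
        order.pop(p + 1)
    return np.asarray(heights), removed


def _labels_from_merges(n: int, removed: list[int], k: int) -> np.ndarray:
    """Bin labels after undoing the last k-1 merges."""
    cut = sorted(set(range(1, n)) - set(removed[:n - k]))
    labels = np.zeros(n, dtype=int)
    for b in cut:
        labels[b:] += 1
    return labels


def select_k(merge_heights, k_max: int = 10) -> int:
    """Segment count at the largest relative gap in the merge heights.

    Candidate k corresponds to cutting between the k-th-last and the
    (k-1)-th-last merge; the winner maximizes the height ratio across
    that cut.  Uniform heights (no gap) fall back to k = 1.
    """
    h = np.asarray(merge_heights, float)
    m = len(h)
    if m == 0:
        return 1
    best_k, best_ratio = 1, 1.0 + 1e-9
    for k in range(2, min(k_max, m + 1) + 1):
        lo, hi = h[m - k], h[m - k + 1]
        if lo <= 0:
            ratio = np.inf if hi > 0 else 1.0
        else:
            with np.errstate(over="ignore"):
                ratio = hi / lo
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return best_k


def epochs_from_labels(labels, time_axis, duration: float | None = None,
                       start: float = 0.0) -> list[tuple[float, float, int]]:
    """Maximal runs of equal labels as half-open time intervals.

    Interior segment edges fall midway between adjacent bin centers; the
    outer edges are the record span ``[start, start + duration)`` (or an
    extrapolated half-bin when the duration is unknown).  The returned
    segments tile the span without gaps.
    """
    labels = np.asarray(labels)
    t = np.asarray(time_axis, float)
    n = len(labels)
    if n == 0:
        return []
    if n == 1:
        end = start + duration if duration is not None else t[0]
        return [(start, float(end), int(labels[0]))]
    mids = (t[:-1] + t[1:]) / 2.0
    first = start
    last = start + duration if duration is not None else t[-1] + (t[-1] - t[-2]) / 2
    edges = np.concatenate([[first], mids, [last]])
    segs = []
    run_start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[run_start]:
            segs.append((float(edges[run_start]), float(edges[i]),
                         int(labels[run_start])))
            run_start = i
    return segs


def constrained_hca(features: np.ndarray, k: int | None = None,
                    k_max: int = 10, linkage: str = "ward",
                    time_axis=None, duration: float | None = None
                    ) -> SegmentLabeling:
    """Segment the feature rows into contiguous TFT-epochs.

    If ``k`` is not given it is chosen by :func:`select_k` from the merge
    heights.  ``time_axis``/``duration`` (from the TFT tensor) convert
    bin runs into time intervals; without them, bin indices are used.
    """
    X = np.asarray(features, float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 time bins")
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    heights, removed = _constrained_linkage(X, linkage)
    if k is None:
        k = select_k(heights, k_max=k_max)
    labels = _labels_from_merges(n, removed, k)
    if time_axis is None:
        time_axis = np.arange(n, dtype=float) + 0.5
        duration = float(n)
    segments = epochs_from_labels(labels, time_axis, duration=duration)
    return SegmentLabeling(labels=labels, segments=segments,
                           merge_heights=heights,
                           time_axis=np.asarray(time_axis, float))


# ---------------------------------------------------------------------------
# Estimator interfaces

class TFTFeatures(TransformerMixin, BaseEstimator):
    """STFT power tensor + log/z-score feature extraction as a transformer.

    ``transform`` maps a (n_times, n_channels) signal to the
    (n_bins, n_freqs * n_channels) standardized log-power feature matrix;
    the intermediate tensor of the last transform is kept in ``tensor_``.
    """

    def __init__(self, rate: float = 128.0, window: float = 2.0,
                 hop: float = 0.5, fmin: float = 2.0, fmax: float = 50.0,
                 eps: float = 1e-12):
        self.rate = rate
        self.window = window
        self.hop = hop
        self.fmin = fmin
        self.fmax = fmax
        self.eps = eps

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        labels = tuple(f"ch{i}" for i in range(X.shape[1]))
        rec = EEGRecording(labels, self.rate, X.T)
        self.tensor_ = compute_tft(rec, self.window, self.hop,
                                   self.fmin, self.fmax)
        return tft_features(self.tensor_, self.eps)


class ConstrainedWard(ClusterMixin, BaseEstimator):
    """Temporally-constrained agglomerative clustering of feature rows.

    Rows are time bins; only adjacent clusters may merge, so each cluster
    is one contiguous segment.  With ``n_clusters=None`` the cut is
    chosen at the largest relative merge-height gap (up to ``k_max``).

    Fitted attributes: ``labels_``, ``n_clusters_``, ``merge_heights_``.
    """

    def __init__(self, n_clusters: int | None = None, k_max: int = 10,
                 linkage: str = "ward"):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.linkage = linkage

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        res = constrained_hca(X, k=self.n_clusters, k_max=self.k_max,
                              linkage=self.linkage)
        self.labels_ = res.labels
        self.merge_heights_ = res.merge_heights
        self.n_clusters_ = res.n_segments
        self.n_features_in_ = X.shape[1]
        return self
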