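"""Per-segment entropy of the segmented EEG and early/late summaries.

Brain status within each TFT-epoch is quantified by the entropy of its
pooled standardized log-power feature values, estimated with a histogram
plug-in estimator carrying the first-order bias correction
``+(M - 1) / (2N)`` (M occupied bins, N samples) in the tradition of
Moddemeijer's estimator, plus a ``ln(bin width)`` offset for the
differential reading.  Each session is split into an early and a late
stage and the stages are compared with a one-tailed Mann-Whitney U test
(early > late).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import SegmentLabeling
from .stats import MWUResult, mwu

MIN_SAMPLES = 10


def histogram_entropy(samples, n_bins: int | None = None,
                      differential: bool = True) -> float:
    """Bias-corrected histogram entropy of a sample, in nats.

    The plug-in estimate ``-sum p_i ln p_i`` over equal-width bins is
    corrected by ``+(M - 1) / (2N)``; with ``differential=True`` the
    ``ln(bin width)`` offset converts it to a differential-entropy
    reading.  Bin count defaults to ``ceil(sqrt(N))``.  A zero-width
    sample range is degenerate and returns 0.
    """
    x = np.asarray(samples, float).ravel()
    n = x.size
    if n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {n}")
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        return 0.0
    if n_bins is None:
        n_bins = math.ceil(math.sqrt(n))
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / n
    m = p.size
    h = -(p * np.log(p)).sum() + (m - 1) / (2 * n)
    if differential:
        h += math.log((hi - lo) / n_bins)
    return float(h)


def segment_entropy(features: np.ndarray, segmentation) -> np.ndarray:
    """Entropy per segment from pooled feature values.

    For each contiguous segment, its rows' feature values are pooled
    into one sample vector and passed to :func:`histogram_entropy`.
    A segment of identical rows is degenerate (no temporal variability)
    and scores 0.  ``segmentation`` may be a :class:`SegmentLabeling`
    or a per-row label array.
    """
    X = np.asarray(features, float)
    labels = (segmentation.labels if isinstance(segmentation, SegmentLabeling)
              else np.asarray(segmentation))
    if len(labels) != len(X):
        raise ValueError("labels must tile the feature rows")
    out = []
    for a, b in _runs(labels):
        block = X[a:b]
        if np.all(block == block[0]):
            out.append(0.0)
            continue
        pooled = block.ravel()
        if pooled.size < MIN_SAMPLES:
            raise ValueError(
                f"segment [{a}, {b}) pools only {pooled.size} values")
        out.append(histogram_entropy(pooled))
    return np.asarray(out)


def _runs(labels):
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            yield start, i
            start = i


def stage_split(segments, record_duration: float,
                split: float = 0.5) -> list[str]:
    """Assign each (start, end, ...) segment to 'early' or 'late'.

    A segment is early when its midpoint falls before
    ``split * record_duration`` (temporal-midpoint rule).
    """
    stages = []
    for seg in segments:
        start, end = seg[0], seg[1]
        mid = (start + end) / 2.0
        stages.append("early" if mid < split * record_duration else "late")
    return stages


@dataclass
class EntropyReport:
    """Early/late per-segment entropy summary of one session.

    Mirrors the published tables: stage mean +/- SD plus the one-tailed
    Mann-Whitney U comparison (early > late).  A stage with no segments
    leaves its summary undefined (NaN).
    """

    entropies: np.ndarray
    stages: list[str]
    early_mean: float
    early_sd: float
    late_mean: float
    late_sd: float
    test: MWUResult | None

    @property
    def stars(self) -> str:
        from .stats import significance_stars
        return significance_stars(self.test.p) if self.test else ""

    def __str__(self):
        def fmt(m, s):
            return "undefined" if np.isnan(m) else f"{m:.2f} ± {s:.2f}"
        line = (f"early {fmt(self.early_mean, self.early_sd)}, "
                f"late {fmt(self.late_mean, self.late_sd)}")
        if self.test is not None:
            line += f" ({self.test})"
        return line


def entropy_report(entropies, stages) -> EntropyReport:
    """Summarize per-segment entropies by stage.

    SDs use the n-1 denominator; the U test needs both stages non-empty
    (otherwise it is omitted and the empty stage's summary is NaN).
    """
    e = np.asarray(entropies, float)
    if len(e) != len(stages):
        raise ValueError("one stage per segment required")
    early = e[[s == "early" for s in stages]]
    late = e[[s == "late" for s in stages]]

    def summarize(v):
        if v.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        return float(v.mean()), sd

    em, es = summarize(early)
    lm, ls = summarize(late)
    test = (mwu(early, late, alternative="greater", name="early>late")
            if early.size and late.size else None)
    return EntropyReport(entropies=e, stages=list(stages),
                         early_mean=em, early_sd=es,
                         late_mean=lm, late_sd=ls, test=test)


def session_entropy_report(features: np.ndarray,
                           labeling: SegmentLabeling,
                           record_duration: float,
                           split: float = 0.5) -> EntropyReport:
    """Entropy report for one segmented session (convenience wrapper)."""
    e = segment_entropy(features, labeling)
    stages = stage_split(labeling.segments, record_duration, split=split)
    return entropy_report(e, stages)
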