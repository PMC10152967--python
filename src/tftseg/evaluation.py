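"""Benchmark evaluations of the pipeline on ground-truthed synthetic data.

Each function regenerates its inputs from a seed, runs the relevant
stages, and measures recovery against the generator's ground truth:
segmentation accuracy (adjusted Rand index, boundary error), the
early-versus-late entropy direction, blink flagging and removal, the
calibration of the Mann-Whitney contrasts under the null, and the
ordinal behavioral pattern under study-direction effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.metrics import adjusted_rand_score

from .behavior import improvement
from .entropy import histogram_entropy, session_entropy_report
from .preprocess import adjust_features, bandpass, flag_artifacts, ica_fit, \
    remove_components
from .segmentation import compute_tft, constrained_hca, tft_features
from .simulate import EffectConfig, blink_fixture_config, \
    four_regime_config, learning_shaped_config, simulate_cohort, simulate_eeg
from .stats import condition_contrasts


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def segment_recording(rec, window: float = 2.0, hop: float = 0.5):
    """bandpass -> TFT -> features -> constrained clustering."""
    filt = bandpass(rec)
    tensor = compute_tft(filt, window=window, hop=hop)
    X = tft_features(tensor)
    lab = constrained_hca(X, time_axis=tensor.time_axis,
                          duration=tensor.duration)
    return tensor, X, lab


@dataclass
class SegmentationRecovery:
    ari_median: float
    boundary_error_median_s: float   # per-seed mean |recovered - true|, s
    n_seeds: int


def segmentation_recovery(seed: int = 0, n_seeds: int = 20
                          ) -> SegmentationRecovery:
    """Recovery of four >= 10 dB-contrast regimes, end to end.

    Per seed: simulate, run the segmentation stage with the automatic
    cut, and score the bin labeling against the true regime of each bin
    center (ARI) plus the mean distance from each true change point to
    the nearest recovered segment edge.
    """
    aris, berrs = [], []
    for s in _child_seeds(seed, n_seeds):
        rec, gt = simulate_eeg(four_regime_config(seed=s))
        tensor, _, lab = segment_recording(rec)
        idx = (tensor.time_axis * rec.rate).astype(int).clip(0, rec.n_times - 1)
        aris.append(adjusted_rand_score(gt.regime_id[idx], lab.labels))
        edges = [seg[1] for seg in lab.segments[:-1]]
        if edges:
            berrs.append(np.mean([min(abs(b - e) for e in edges)
                                  for b in gt.boundaries]))
        else:
            berrs.append(np.inf)
    return SegmentationRecovery(float(np.median(aris)),
                                float(np.median(berrs)), n_seeds)


def entropy_direction_rate(seed: int = 0, n_seeds: int = 20) -> int:
    """Seeds (out of ``n_seeds``) with early mean entropy > late mean.

    Uses the learning-shaped scenario: spectrally diverse early half,
    single stationary late half.
    """
    wins = 0
    for s in _child_seeds(seed, n_seeds):
        rec, _ = simulate_eeg(learning_shaped_config(seed=s))
        _, X, lab = segment_recording(rec)
        rep = session_entropy_report(X, lab, rec.duration)
        wins += rep.early_mean > rep.late_mean
    return wins


@dataclass
class BlinkRemoval:
    n_flagged: int            # seeds where the blink component was flagged
    n_flagged_as_blink: int   # ... specifically with the blink class
    min_energy_cut: float     # worst-case fraction of event energy removed
    n_seeds: int


def blink_removal(seed: int = 0, n_seeds: int = 20) -> BlinkRemoval:
    """Flag and remove injected blinks; measure frontal event energy.

    Event energy is the 0.5-4 Hz band energy at AF3 summed over windows
    around the known blink onsets, before versus after removal.
    """
    flagged = as_blink = 0
    cuts = []
    for s in _child_seeds(seed, n_seeds):
        rec, gt = simulate_eeg(blink_fixture_config(seed=s))
        filt = bandpass(rec)
        dec = ica_fit(filt, seed=s)
        flags = flag_artifacts(adjust_features(dec), seed=s)
        clean = remove_components(dec, flags)
        flagged += bool(flags)
        as_blink += "blink" in flags.values()
        i_af3 = rec.labels.index("AF3")
        sos = butter(4, [0.5, 4.0], btype="band", output="sos", fs=rec.rate)
        w = int(0.3 * rec.rate)

        def event_energy(x):
            xb = sosfiltfilt(sos, x)
            return sum(float(np.sum(xb[int(t * rec.rate):
                                       int(t * rec.rate) + w] ** 2))
                       for t in gt.blink_times)

        before = event_energy(filt.samples[i_af3])
        after = event_energy(clean.samples[i_af3])
        cuts.append(1.0 - after / before)
    return BlinkRemoval(flagged, as_blink, float(min(cuts)), n_seeds)


def entropy_estimator_errors(seed: int = 0) -> dict[str, float]:
    """Estimator accuracy on closed-form cases.

    Returns the relative error on the Gaussian differential entropy at
    N = 1e5, the absolute error on a discrete uniform over 8 levels, and
    the absolute deviation from the ln|a| scale rule.
    """
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(100_000)
    h_gauss = histogram_entropy(g)
    gauss_true = 0.5 * np.log(2 * np.pi * np.e)
    u = rng.integers(0, 8, size=8000).astype(float)
    h_unif = histogram_entropy(u, n_bins=8, differential=False)
    a = 3.7
    scale_dev = abs(histogram_entropy(a * g) - (h_gauss + np.log(a)))
    return {
        "gaussian_rel_error": abs(h_gauss - gauss_true) / gauss_true,
        "uniform_abs_error": abs(h_unif - np.log(8)),
        "scale_rule_abs_error": scale_dev,
    }


def null_type_i_error(seed: int = 0, n_sims: int = 1000,
                      alpha: float = 0.05) -> float:
    """Empirical rejection rate of the contrasts on null cohorts.

    Pools the p-values of all configured contrasts across ``n_sims``
    cohorts generated with no group differences.
    """
    null = EffectConfig.null()
    rejections = total = 0
    for s in _child_seeds(seed, n_sims):
        cohort = simulate_cohort(effects=null, seed=s)
        for r in condition_contrasts(cohort):
            rejections += r.p < alpha
            total += 1
    return rejections / total


@dataclass
class BehavioralPattern:
    vt_improvement: float
    rt_improvement: float
    la_improvement: float
    ha_improvement: float
    ha_opposite: float
    la_opposite: float

    @property
    def ordinal_ok(self) -> bool:
        return (self.vt_improvement > self.rt_improvement
                and self.la_improvement > self.ha_improvement
                and self.ha_opposite > self.la_opposite)


def behavioral_pattern(seed: int = 0, n_per_group: int = 1000
                       ) -> BehavioralPattern:
    """Group means under study-direction effects at large n."""
    design = dict.fromkeys(("RT-HA", "RT-LA", "VT-HA", "VT-LA"), n_per_group)
    cohort = simulate_cohort(design=design, seed=seed)
    treat = cohort.drop_duplicates("participant") \
        .set_index("participant")["treatment"]
    imp = improvement(cohort)
    opp = cohort[cohort["phase"] == "execution_opposite"] \
        .set_index("participant")["score"]

    def mean_over(series, token):
        return float(series[treat.loc[series.index].str.contains(token)].mean())

    return BehavioralPattern(
        vt_improvement=mean_over(imp, "VT"),
        rt_improvement=mean_over(imp, "RT"),
        la_improvement=mean_over(imp, "LA"),
        ha_improvement=mean_over(imp, "HA"),
        ha_opposite=mean_over(opp, "HA"),
        la_opposite=mean_over(opp, "LA"),
    )
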