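"""Ground-truthed synthetic EEG and behavioral cohorts.

The study's recordings are not deposited, so every pipeline stage is
exercised against simulated inputs with known structure:

* **EEG**: piecewise-stationary multichannel noise.  Each regime is a sum
  of band-limited Gaussian noise shaped to a target power spectral
  density plus a 1/f background, emulating the stationary stretches of
  activity the segmentation stage must find.  Optional blink artifacts
  (frontal-dominant raised-cosine pulses) and mains-frequency line noise.
* **Cohort**: a four-treatment longitudinal design (real/virtual training
  x high/low task abstraction; three training sessions plus an execution
  session) with configurable baseline, per-session gain, opposite-task
  means and workload shifts.
* **NASA-TLX**: pairwise weighting choices plus 21-point-scale ratings.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import TLX_FACTORS, TLXRecord, tlx_weights, tlx_overall
from .io import EEGRecording, Montage, STUDY_CHANNELS, STUDY_RATE, default_montage

TREATMENTS = ("RT-HA", "RT-LA", "VT-HA", "VT-LA")

#: group sizes of the study cohort
STUDY_DESIGN = {"RT-HA": 6, "RT-LA": 6, "VT-HA": 6, "VT-LA": 7}

#: cognitive-task space parameters: geometric shapes x 90-degree rotations
COGNITIVE_SHAPES = 7
COGNITIVE_ROTATIONS = 4

BLINK_DURATION = 0.3     # s, raised-cosine pulse length
BLINK_LAMBDA = 0.4       # spatial decay constant of the blink topography


@dataclass
class RegimeSpec:
    """One stationary stretch: duration and per-band target PSD.

    ``band_power`` maps a frequency interval (Hz, within [2, 50]) to the
    one-sided PSD added on top of the 1/f background, in uV^2/Hz, applied
    identically to every channel.
    """

    duration: float
    band_power: dict[tuple[float, float], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("regime duration must be positive")
        for (lo, hi), p in self.band_power.items():
            if not (2.0 <= lo < hi <= 50.0):
                raise ValueError(f"band ({lo}, {hi}) outside [2, 50] Hz")
            if p < 0:
                raise ValueError("band power must be >= 0")


@dataclass
class SimConfig:
    """Full EEG simulation configuration."""

    regimes: list[RegimeSpec]
    channel_labels: tuple[str, ...] = STUDY_CHANNELS
    rate: float = STUDY_RATE
    background_psd: float = 1.0     # uV^2/Hz at the 10 Hz reference of the 1/f floor
    blink_rate: float = 0.0         # events / minute
    blink_amplitude: float = 100.0  # uV at the frontal pole
    line_noise_amplitude: float = 0.0   # uV at mains frequency
    line_noise_freq: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if not self.regimes:
            raise ValueError("at least one regime is required")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.blink_rate < 0:
            raise ValueError("blink rate must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually produced (the test oracle)."""

    boundaries: np.ndarray      # regime-change times, s, strictly increasing
    regime_id: np.ndarray       # per-sample regime index
    blink_times: np.ndarray     # blink onsets, s


def _colored_noise(n: int, rate: float, psd, rng) -> np.ndarray:
    """Gaussian noise with one-sided PSD ``psd(f)`` (uV^2/Hz)."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    gain = np.sqrt(psd(f) * rate / 2.0)
    gain[0] = 0.0
    return np.fft.irfft(spec * gain, n)


def _regime_psd(regime: RegimeSpec, background_psd: float):
    def psd(f):
        with np.errstate(divide="ignore"):
            s = background_psd * np.where(f > 0, 10.0 / np.maximum(f, 1e-9), 0.0)
        s = np.where(f > 0, s, 0.0)
        for (lo, hi), p in regime.band_power.items():
            s = s + np.where((f >= lo) & (f <= hi), p, 0.0)
        return s
    return psd


def simulate_eeg(config: SimConfig) -> tuple[EEGRecording, GroundTruth]:
    """Piecewise-stationary multichannel EEG with known regime boundaries.

    Within each regime the per-channel band power matches the regime spec
    up to sampling error; channels carry independent noise realizations.
    Deterministic for a given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.rate
    nchan = len(config.channel_labels)
    pieces, regime_id = [], []
    for i, regime in enumerate(config.regimes):
        n = int(round(regime.duration * rate))
        psd = _regime_psd(regime, config.background_psd)
        block = np.stack([_colored_noise(n, rate, psd, rng)
                          for _ in range(nchan)])
        pieces.append(block)
        regime_id.append(np.full(n, i, dtype=int))
    samples = np.concatenate(pieces, axis=1)
    regime_id = np.concatenate(regime_id)
    total = samples.shape[1]

    if config.line_noise_amplitude > 0:
        t = np.arange(total) / rate
        samples += config.line_noise_amplitude * np.sin(
            2 * np.pi * config.line_noise_freq * t)

    durations = np.array([r.duration for r in config.regimes])
    boundaries = np.cumsum(durations)[:-1]

    rec = EEGRecording(tuple(config.channel_labels), rate, samples)
    blink_times = np.array([])
    if config.blink_rate > 0:
        rec, blink_times = inject_blinks(
            rec, default_montage(), config.blink_rate,
            config.blink_amplitude, seed=int(rng.integers(2**31)))
    return rec, GroundTruth(boundaries=boundaries, regime_id=regime_id,
                            blink_times=blink_times)


def cognitive_task_configurations() -> int:
    """Distinct cognitive-task configurations: 7 shapes x 4 rotations = 28."""
    return COGNITIVE_SHAPES * COGNITIVE_ROTATIONS


def blink_topography(montage: Montage, labels) -> np.ndarray:
    """Frontal-dominant per-channel blink weights, max-normalized to 1.

    Weight = exp(-d / lambda) with d the montage distance from the
    AF3-AF4 midpoint, so AF3/AF4 carry the full amplitude and occipital
    electrodes receive a few percent of it.
    """
    coords = montage.coords(labels)
    front = (np.array(montage.positions["AF3"]) +
             np.array(montage.positions["AF4"])) / 2.0
    d = np.linalg.norm(coords - front, axis=1)
    w = np.exp(-d / BLINK_LAMBDA)
    return w / w.max()


def inject_blinks(rec: EEGRecording, montage: Montage, rate: float,
                  amplitude: float, seed: int = 0
                  ) -> tuple[EEGRecording, np.ndarray]:
    """Add raised-cosine blink pulses with frontal topography.

    ``rate`` is in events/minute; the event count over the record is
    Poisson with that intensity.  Returns the augmented recording and
    the blink onset times.
    """
    if rate < 0:
        raise ValueError("blink rate must be >= 0")
    if rate == 0:
        return rec, np.array([])
    rng = np.random.default_rng(seed)
    weights = blink_topography(montage, rec.labels)
    n_template = int(round(BLINK_DURATION * rec.rate))
    tt = np.arange(n_template) / rec.rate
    template = 0.5 * (1 - np.cos(2 * np.pi * tt / BLINK_DURATION))

    duration = rec.duration
    n_events = rng.poisson(rate * duration / 60.0)
    onsets = np.sort(rng.uniform(0, duration - BLINK_DURATION,
                                 size=n_events))
    out = rec.samples.copy()
    for t0 in onsets:
        i0 = int(round(t0 * rec.rate))
        out[:, i0:i0 + n_template] += (
            amplitude * weights[:, None] * template[None, :n_template])
    return EEGRecording(rec.labels, rec.rate, out, rec.start_time), onsets


# ---------------------------------------------------------------------------
# Canned EEG scenarios used throughout the tests

def four_regime_config(seed: int = 0, regime_duration: float = 15.0,
                       band_psd: float = 10.0) -> SimConfig:
    """Four 15 s regimes with distinct dominant bands (>= 10 dB contrast)."""
    bands = [(4.0, 7.0), (8.0, 12.0), (16.0, 24.0), (30.0, 40.0)]
    regimes = [RegimeSpec(regime_duration, {b: band_psd}) for b in bands]
    return SimConfig(regimes=regimes, seed=seed)


def blink_fixture_config(seed: int = 0) -> SimConfig:
    """Alpha-band background with dense, large blinks.

    Blink rate and amplitude are set well clear of the ongoing activity
    so that the blink concentrates into a single independent component
    with strongly separated artifact features.
    """
    return SimConfig(regimes=[RegimeSpec(60.0, {(8.0, 12.0): 5.0})],
                     blink_rate=30.0, blink_amplitude=200.0, seed=seed)


def learning_shaped_config(seed: int = 0) -> SimConfig:
    """Early half: several spectrally distinct regimes; late half: one.

    Emulates a session in which early activity cycles through varied
    spectral states (high cognitive diversity) while late activity has
    settled into a single stationary state.
    """
    early = [
        RegimeSpec(7.5, {(4.0, 7.0): 12.0}),
        RegimeSpec(7.5, {(8.0, 12.0): 12.0}),
        RegimeSpec(7.5, {(16.0, 24.0): 12.0}),
        RegimeSpec(7.5, {(8.0, 12.0): 6.0, (30.0, 40.0): 12.0}),
    ]
    late = [RegimeSpec(30.0, {(8.0, 12.0): 2.0})]
    return SimConfig(regimes=early + late, seed=seed)


# ---------------------------------------------------------------------------
# Behavioral cohort

@dataclass
class EffectConfig:
    """Per-treatment score dynamics and workload shifts.

    ``baseline`` and ``gain`` give the trained-task score mean at session
    1 and its per-session increment; ``opposite_mean`` the score on the
    opposite-abstraction task in the execution session; ``tlx_shift`` the
    mean workload change from session 1 to execution.  Scores are clipped
    to [0, 100] after noise.
    """

    baseline: dict[str, float]
    gain: dict[str, float]
    opposite_mean: dict[str, float]
    noise_sd: float = 12.0
    tlx_base: float = 60.0
    tlx_shift: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(TREATMENTS, 0.0))
    tlx_sd: float = 8.0

    def __post_init__(self):
        for d in (self.baseline, self.gain, self.opposite_mean, self.tlx_shift):
            if set(d) != set(TREATMENTS):
                raise ValueError(f"treatment keys must be {TREATMENTS}")

    @classmethod
    def null(cls) -> "EffectConfig":
        """No group differences: common baseline, zero gains and shifts."""
        return cls(baseline=dict.fromkeys(TREATMENTS, 50.0),
                   gain=dict.fromkeys(TREATMENTS, 0.0),
                   opposite_mean=dict.fromkeys(TREATMENTS, 50.0))

    @classmethod
    def study_effects(cls) -> "EffectConfig":
        """Directions observed in the study cohort.

        Virtual training improves more than real from session 1 to
        execution; low abstraction gains more on the trained task; high
        abstraction scores higher on the opposite-abstraction task;
        workload drops under virtual training and high abstraction.
        """
        return cls(
            baseline={"RT-HA": 24.6, "RT-LA": 45.4,
                      "VT-HA": 14.3, "VT-LA": 16.1},
            gain={"RT-HA": -2.0 / 3, "RT-LA": 20.0 / 3,
                  "VT-HA": 8.0 / 3, "VT-LA": 28.0 / 3},
            opposite_mean={"RT-HA": 35.0, "RT-LA": 18.0,
                           "VT-HA": 35.0, "VT-LA": 18.0},
            tlx_shift={"RT-HA": -1.0, "RT-LA": 6.0,
                       "VT-HA": -9.0, "VT-LA": 2.5},
        )


def _draw_session(rng, mean: float, sd: float) -> tuple[int, int, float]:
    """Draw (hits, attempts, score) around a target mean score."""
    raw = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
    attempts = int(rng.integers(30, 61))
    hits = int(round(raw / 100.0 * attempts))
    return hits, attempts, 100.0 * hits / attempts


def simulate_cohort(design: dict[str, int] | None = None,
                    effects: EffectConfig | None = None,
                    n_sessions: int = 3, seed: int = 0) -> pd.DataFrame:
    """Longitudinal behavioral records for a four-treatment cohort.

    Returns one row per participant x session: three training sessions
    plus an execution session contributing an ``execution_same`` and an
    ``execution_opposite`` row.  Workload (NASA-TLX overall) is recorded
    at session 1 and at execution of the trained task.
    """
    design = design or dict(STUDY_DESIGN)
    effects = effects or EffectConfig.study_effects()
    if any(n < 1 for n in design.values()):
        raise ValueError("group sizes must be >= 1")
    for name, d in (("baseline", effects.baseline),
                    ("opposite_mean", effects.opposite_mean)):
        for t, m in d.items():
            if not 0 <= m <= 100:
                warnings.warn(f"{name}[{t}]={m} outside [0, 100]; "
                              "generated scores will be clipped")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for treat, n in design.items():
        b, g = effects.baseline[treat], effects.gain[treat]
        for _ in range(n):
            pid += 1
            tlx1 = float(np.clip(rng.normal(effects.tlx_base,
                                            effects.tlx_sd), 0, 100))
            for s in range(1, n_sessions + 1):
                hits, att, score = _draw_session(
                    rng, b + g * (s - 1), effects.noise_sd)
                rows.append((f"P{pid:04d}", treat, s, "training",
                             hits, att, score,
                             tlx1 if s == 1 else np.nan))
            hits, att, score = _draw_session(
                rng, b + g * n_sessions, effects.noise_sd)
            tlx_exec = float(np.clip(
                tlx1 + rng.normal(effects.tlx_shift[treat], effects.tlx_sd),
                0, 100))
            rows.append((f"P{pid:04d}", treat, n_sessions + 1,
                         "execution_same", hits, att, score, tlx_exec))
            hits, att, score = _draw_session(
                rng, effects.opposite_mean[treat], effects.noise_sd)
            rows.append((f"P{pid:04d}", treat, n_sessions + 1,
                         "execution_opposite", hits, att, score, np.nan))
    return pd.DataFrame(rows, columns=[
        "participant", "treatment", "session", "phase",
        "hits", "attempts", "score", "tlx"])


def simulate_tlx(n: int, condition_shift: float = 0.0,
                 seed: int = 0) -> list[TLXRecord]:
    """Random NASA-TLX responses: 15 pairwise choices + 6 ratings.

    Ratings sit on the 21-point scale (0-100 in steps of 5) around
    ``50 + condition_shift``.
    """
    if n <= 0:
        raise ValueError("need n >= 1 participants")
    rng = np.random.default_rng(seed)
    pairs = [(TLX_FACTORS[i], TLX_FACTORS[j])
             for i in range(6) for j in range(i + 1, 6)]
    records = []
    for _ in range(n):
        choices = [(a, b, a if rng.random() < 0.5 else b) for a, b in pairs]
        weights = tlx_weights(choices)
        ratings = np.clip(np.round(
            rng.normal(50 + condition_shift, 15, size=6) / 5) * 5, 0, 100)
        ratings = tuple(float(r) for r in ratings)
        records.append(TLXRecord(ratings=ratings, weights=weights,
                                 choices=choices,
                                 overall=tlx_overall(ratings, weights)))
    return records
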