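"""Configured end-to-end runs: EEG -> preprocess -> segment -> entropy,
plus behavioral summaries and group contrasts.

A :class:`PipelineConfig` (validated by pydantic, loadable from YAML)
fixes every tunable and the seed; :func:`run` executes the stages and
writes the artifact files into a run directory, each stamped with the
hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import behavior  # noqa: F401  (re-exported for CLI convenience)
from .entropy import session_entropy_report
from .io import EEGRecording, read_eeg, write_eeg
from .preprocess import adjust_features, bandpass, flag_artifacts, ica_fit, \
    remove_components
from .segmentation import compute_tft, constrained_hca, tft_features
from .simulate import SimConfig, blink_fixture_config, four_regime_config, \
    learning_shaped_config, simulate_cohort, simulate_eeg
from .stats import condition_contrasts, group_summary, significance_stars

log = logging.getLogger("tftseg")

SCENARIOS = {
    "four_regime": four_regime_config,
    "learning_shaped": learning_shaped_config,
    "blink": blink_fixture_config,
}


class FilterConfig(BaseModel):
    low: float = 2.0
    high: float = 50.0
    order: int = 8


class STFTConfig(BaseModel):
    window: float = 2.0
    hop: float = 0.5


class ClusterConfig(BaseModel):
    linkage: str = "ward"
    k: int | None = None        # None -> automatic merge-height gap rule
    k_max: int = 10


class EntropyConfig(BaseModel):
    split: float = 0.5          # early/late boundary as fraction of record
    n_bins: int | None = None


class EEGSource(BaseModel):
    path: str | None = None     # EDF or headered CSV; None -> simulate
    scenario: str = "four_regime"


class CohortSource(BaseModel):
    path: str | None = None     # cohort CSV; None -> simulate


class PipelineConfig(BaseModel):
    """Everything a run depends on, including the seed."""

    eeg: EEGSource = Field(default_factory=EEGSource)
    cohort: CohortSource = Field(default_factory=CohortSource)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    stft: STFTConfig = Field(default_factory=STFTConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    entropy: EntropyConfig = Field(default_factory=EntropyConfig)
    ica: bool = True
    seed: int = 0
    output_dir: str = "tftseg_out"

    def resolved_hash(self) -> str:
        # output_dir does not affect results, so it is not part of the hash
        payload = self.model_dump(exclude={"output_dir"})
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("load-eeg")
def _load_eeg(config: PipelineConfig) -> EEGRecording:
    if config.eeg.path:
        return read_eeg(config.eeg.path)
    if config.eeg.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {config.eeg.scenario!r}; "
                         f"choose from {sorted(SCENARIOS)}")
    sim = SCENARIOS[config.eeg.scenario](seed=config.seed)
    rec, _ = simulate_eeg(sim)
    return rec


@_stage("preprocess")
def _preprocess(config: PipelineConfig, rec: EEGRecording) -> EEGRecording:
    filt = bandpass(rec, config.filter.low, config.filter.high,
                    config.filter.order)
    if not config.ica:
        return filt
    dec = ica_fit(filt, seed=config.seed)
    flags = flag_artifacts(adjust_features(dec), seed=config.seed)
    log.info("flagged components: %s", flags or "none")
    return remove_components(dec, flags)


@_stage("segment")
def _segment(config: PipelineConfig, rec: EEGRecording):
    tensor = compute_tft(rec, config.stft.window, config.stft.hop,
                         config.filter.low, config.filter.high)
    X = tft_features(tensor)
    labeling = constrained_hca(X, k=config.cluster.k,
                               k_max=config.cluster.k_max,
                               linkage=config.cluster.linkage,
                               time_axis=tensor.time_axis,
                               duration=tensor.duration)
    return tensor, X, labeling


@_stage("cohort")
def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if config.cohort.path:
        return pd.read_csv(config.cohort.path, comment="#")
    return simulate_cohort(seed=config.seed)


def run(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Writes: the resolved config (YAML, with its hash), segment table
    (CSV), label sequence (JSON), entropy report (CSV + JSON), behavioral
    summary (CSV), contrast table (CSV), and a log with stage timings.
    Deterministic for a fixed seed: rerunning a config reproduces the
    CSV/JSON artifacts byte for byte.
    """
    import yaml

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.resolved_hash()
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        log.info("config hash %s", cfg_hash)
        resolved = config.model_dump()
        resolved["config_hash"] = cfg_hash
        (out / "config.yaml").write_text(yaml.safe_dump(resolved,
                                                        sort_keys=True))
        rec = _load_eeg(config)
        clean = _preprocess(config, rec)
        tensor, X, labeling = _segment(config, clean)
        seg_df = pd.DataFrame(labeling.segments,
                              columns=["start_s", "end_s", "cluster_id"])
        _write_csv(seg_df, out / "segments.csv", cfg_hash)
        with open(out / "labels.json", "w") as jf:
            json.dump({"config": cfg_hash,
                       "time_axis": np.round(tensor.time_axis, 6).tolist(),
                       "labels": labeling.labels.tolist()}, jf, indent=1)

        report = session_entropy_report(X, labeling, clean.duration,
                                        split=config.entropy.split)
        ent_df = pd.DataFrame({
            "start_s": [s[0] for s in labeling.segments],
            "end_s": [s[1] for s in labeling.segments],
            "stage": report.stages,
            "entropy_nats": np.round(report.entropies, 6),
        })
        _write_csv(ent_df, out / "entropy.csv", cfg_hash)
        ent_summary = {
            "config": cfg_hash,
            "early_mean": report.early_mean, "early_sd": report.early_sd,
            "late_mean": report.late_mean, "late_sd": report.late_sd,
            "U": None if report.test is None else report.test.u_min,
            "p_one_tailed": None if report.test is None else report.test.p,
            "significance": report.stars,
        }
        with open(out / "entropy_summary.json", "w") as jf:
            json.dump(ent_summary, jf, indent=1, allow_nan=True)
        log.info("entropy: %s", report)

        cohort = _load_cohort(config)
        _write_csv(group_summary(cohort), out / "behavior_summary.csv",
                   cfg_hash)
        results = condition_contrasts(cohort)
        con_df = pd.DataFrame([{
            "contrast": r.name, "U": r.u, "U_min": r.u_min, "p": r.p,
            "n1": r.n1, "n2": r.n2, "method": r.method,
            "alternative": r.alternative,
            "significance": significance_stars(r.p),
        } for r in results])
        _write_csv(con_df, out / "contrasts.csv", cfg_hash)
        for r in results:
            log.info("%s", r)
        return out
    except Exception:
        (out / "INCOMPLETE").write_text("run aborted; artifacts partial\n")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def write_eeg_fixture(sim: SimConfig, out_dir, stem: str = "eeg") -> dict:
    """Simulate EEG and write EDF + CSV + ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, gt = simulate_eeg(sim)
    paths = {
        "edf": write_eeg(rec, out / f"{stem}.edf"),
        "csv": write_eeg(rec, out / f"{stem}.csv"),
    }
    sidecar = {
        "boundaries_s": gt.boundaries.tolist(),
        "blink_times_s": np.round(gt.blink_times, 6).tolist(),
        "rate_hz": sim.rate,
        "seed": sim.seed,
    }
    gt_path = out / f"{stem}_ground_truth.json"
    gt_path.write_text(json.dumps(sidecar, indent=1))
    paths["ground_truth"] = gt_path
    return paths
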