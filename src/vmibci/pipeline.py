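"""End-to-end orchestration: simulate -> preprocess -> features ->
classify -> stats, with one declarative configuration and a JSON run
report.

A single top-level seed deterministically derives the per-stage seeds
(simulation, ICA, cross-validation), so each stage is independently
reproducible and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import group_stats as gs
from . import io as vio
from . import synth
from .preprocess import preprocess_session

__all__ = ["PipelineConfig", "run_all", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = seed & 0x7FFFFFFF
    for ch in stage:
        h = (h * 1000003 + ord(ch)) % (2**31)
    return h


@dataclass
class PipelineConfig:
    """Everything a full run needs; unknown keys in a config file are
    rejected rather than silently ignored."""

    out_dir: str = "vmi_run"
    seed: int = 0
    # simulation
    simulate: bool = True
    n_subjects: int = 3
    n_blocks: int = 10
    fs: float = 250.0
    alpha_freq: float = 10.0
    effect_scale: float = 1.0
    alpha_amp: float = 5.0
    noise_sd: float = 10.0
    drift_amp: float = 20.0
    blink_rate: float = 6.0
    # input when not simulating: list of (edf, events-tsv) path pairs
    recordings: list[list[str]] = field(default_factory=list)
    # preprocessing
    band_low: float = 8.0
    band_high: float = 13.0
    use_ica: bool = True
    ica_stage: str = "post-band"
    t_start: float = 1.0
    t_end: float = 4.0
    # features
    k_imfs: int = 3
    ar_order: int = 6
    ar_target: str = "envelope"
    # classification
    svm_c: float = 1.0
    folds: int = 10
    # stage toggles
    run_classify: bool = True
    run_stats: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(
            n_subjects=self.n_subjects,
            n_blocks=self.n_blocks,
            fs=self.fs,
            alpha_freq=self.alpha_freq,
            effect_scale=self.effect_scale,
            alpha_amp=self.alpha_amp,
            noise_sd=self.noise_sd,
            drift_amp=self.drift_amp,
            blink_rate=self.blink_rate,
            seed=stage_seed(self.seed, "simulate"),
        )


def _load_inputs(config: PipelineConfig, out: Path):
    sessions = []
    if config.simulate:
        cfg = config.synth_config()
        for s in range(config.n_subjects):
            rec, events = synth.generate_session(cfg, subject=s)
            vio.write_edf(out / f"sub-{s:02d}.edf", rec)
            vio.write_events(out / f"sub-{s:02d}_events.tsv", events)
            sessions.append((rec, events))
    else:
        if not config.recordings:
            raise FileNotFoundError(
                "no input recordings configured and the simulate stage is "
                "disabled; set `recordings` or `simulate: true`"
            )
        for edf_path, ev_path in config.recordings:
            for p in (edf_path, ev_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input file: {p}")
            sessions.append(
                (vio.read_edf(edf_path), vio.read_events(ev_path))
            )
    return sessions


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"stages": {}}

    def _stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    t0 = _stage("simulate/load")
    sessions = _load_inputs(config, out)
    report["stages"]["input"] = {
        "n_subjects": len(sessions),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = _stage("preprocess")
    all_epochs = []
    for rec, events in sessions:
        all_epochs.extend(
            preprocess_session(
                rec,
                events,
                band=(config.band_low, config.band_high),
                use_ica=config.use_ica,
                ica_stage=config.ica_stage,
                seed=stage_seed(config.seed, "ica"),
                t_start=config.t_start,
                t_end=config.t_end,
            )
        )
    vio.save_epochs(out / "epochs.npz", all_epochs)
    report["stages"]["preprocess"] = {
        "n_epochs": len(all_epochs),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    t0 = _stage("features")
    from .features import extract_feature_table

    feats = extract_feature_table(
        all_epochs,
        k_imfs=config.k_imfs,
        order=config.ar_order,
        ar_target=config.ar_target,
    )
    vio.write_features(out / "features.tsv", feats)
    report["stages"]["features"] = {
        "n_vectors": len(feats),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    if config.run_classify:
        t0 = _stage("classify")
        table = clf.pairwise_task_table(
            feats,
            k=config.folds,
            seed=stage_seed(config.seed, "cv"),
            C=config.svm_c,
        )
        df = table.to_frame()
        df.to_csv(out / "task_pairs.tsv", sep="\t", index=False)
        report["stages"]["classify"] = {
            "n_pairs": len(table.rows),
            "grand_mean_pct": round(table.grand_mean, 4),
            "grand_sd_pct": round(table.grand_sd, 4),
            "seconds": round(time.perf_counter() - t0, 3),
        }

    if config.run_stats:
        t0 = _stage("stats")
        tm = gs.trial_mean_table(all_epochs)
        anova = gs.lead_anova(tm)
        anova.per_lead.to_csv(out / "anova.tsv", sep="\t", index=False)
        gs.descriptives(tm).to_csv(
            out / "descriptives.tsv", sep="\t", index=False
        )
        n_sig = int(anova.per_lead["significant"].sum())
        conn_strongest = {}
        for task in gs.TASKS:
            conn = gs.connectivity(all_epochs, task)
            conn.to_frame().to_csv(out / f"connectivity_{task}.tsv", sep="\t")
            conn_strongest[task] = list(gs.strongest_pair(conn))
        report["stages"]["stats"] = {
            "n_leads": int(anova.per_lead.shape[0]),
            "n_significant_fdr": n_sig,
            "strongest_pair": conn_strongest,
            "seconds": round(time.perf_counter() - t0, 3),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
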