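"""End-to-end orchestration: simulate -> detect -> analyze -> decode ->
tuning -> specificity.

``run_pipeline`` executes the full analysis on one synthetic session and
returns (and optionally writes) a JSON-serializable report; the numbered
scripts under ``analysis/`` are thin drivers over this module. Every
stochastic stage draws its generator from one spawned seed sequence, so a
fixed config reproduces the report bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import assemblies as asm
from . import decoder, specificity, tuning
from .events import DetectionConfig, detect_population_events, evoked_assembly, event_stats
from .preprocess import SpikeRaster
from .synthetic import (SESSION_BLOCK_LAYOUT, SimulationConfig, StimulusProtocol,
                        make_protocol, simulate_raster)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "collect_evoked_trials"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    mode: str = "awake"
    seed: int = 0
    n_sounds: int = 50
    n_reps: int = 12
    sound_dur_s: float = 0.5
    isi_s: float = 1.0
    block_layout: tuple[tuple[str, float], ...] = SESSION_BLOCK_LAYOUT
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    granularity: int | None = None       # ongoing-assembly clusters; default n_sounds // 2
    neuron_granularity: int = 27
    alpha: float = 0.01
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_layout"] = [list(b) for b in self.block_layout]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["sim"] = SimulationConfig(**d.get("sim", {}))
        d["detection"] = DetectionConfig(**d.get("detection", {}))
        d["block_layout"] = tuple((k, float(s)) for k, s in d["block_layout"])
        return cls(**d)


def validate_inputs(raster: SpikeRaster, protocol: StimulusProtocol) -> list[dict]:
    """Structural checks on a raster/protocol pair; returns issue records."""
    issues: list[dict] = []
    uniq = np.unique(raster.spikes)
    if not np.isin(uniq, [0, 1]).all():
        issues.append({"kind": "type", "message": "raster entries not binary"})
    if raster.frame_rate != protocol.frame_rate:
        issues.append({"kind": "frame_rate",
                       "message": f"raster {raster.frame_rate} Hz vs protocol "
                                  f"{protocol.frame_rate} Hz"})
    if protocol.n_frames != raster.n_frames:
        issues.append({"kind": "bounds",
                       "message": f"protocol spans {protocol.n_frames} frames, "
                                  f"raster has {raster.n_frames}"})
    for row in protocol.trials.itertuples(index=False):
        if row.offset_frame > raster.n_frames or row.onset_frame < 0:
            issues.append({"kind": "bounds", "row": int(row.trial),
                           "message": f"trial {row.trial} outside recording"})
        if row.offset_frame <= row.onset_frame:
            issues.append({"kind": "protocol", "row": int(row.trial),
                           "message": f"trial {row.trial} has non-positive duration"})
    return issues


def collect_evoked_trials(
    raster: SpikeRaster,
    protocol: StimulusProtocol,
    window_ms: float = 500.0,
) -> dict[int, list[np.ndarray | None]]:
    """Single-trial evoked assembly vectors grouped by sound id."""
    out: dict[int, list[np.ndarray | None]] = {}
    for row in protocol.trials.itertuples(index=False):
        vec = evoked_assembly(raster, protocol, int(row.trial), window_ms)
        out.setdefault(int(row.sound_id), []).append(vec)
    return out


def _split_events(events, protocol):
    """Partition detected events into pre-stim, stim and post-stim segments."""
    stim_blocks = [(a, b) for k, a, b in protocol.blocks if k == "stim"]
    if stim_blocks:
        stim_start = min(a for a, _ in stim_blocks)
        stim_end = max(b for _, b in stim_blocks)
    else:
        stim_start = stim_end = protocol.n_frames
    pre, stim, post = [], [], []
    for ev in events:
        if ev.end < stim_start:
            pre.append(ev)
        elif ev.start >= stim_end:
            post.append(ev)
        else:
            stim.append(ev)
    return pre, stim, post


def _similarity_block(sound_trials, ongoing_events, granularity):
    """Cluster one segment's ongoing assemblies and compute S/R statistics."""
    vectors = np.vstack([ev.assembly for ev in ongoing_events])
    granularity = min(granularity, len(ongoing_events))
    labels = asm.cluster_assemblies(vectors, granularity)
    table, c_matrix = asm.similarity_reproducibility(sound_trials, vectors, labels)
    valid = table.dropna(subset=["S", "R"])
    stat = {
        "median_S": float(valid["S"].median()),
        "median_R": float(valid["R"].median()),
        "n_sounds_used": int(len(valid)),
        "n_assemblies": len(ongoing_events),
        "n_clusters": int(len({l for l in labels if l >= 0})),
    }
    if len(valid) >= 5:
        try:
            w = scipy.stats.wilcoxon(valid["S"], valid["R"])
            stat["wilcoxon_p"] = float(w.pvalue)
        except ValueError:
            stat["wilcoxon_p"] = float("nan")
    return table, labels, vectors, stat


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on one synthetic session and return the report.

    When ``config.out_dir`` is set, per-stage tables (TSV), the protocol, the
    config and the JSON report are written beneath it.
    """
    t0 = time.time()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_protocol, rng_sim, rng_detect, rng_models = map(np.random.default_rng, seeds)
    report: dict = {"mode": config.mode, "seed": config.seed,
                    "config_hash": config.config_hash(), "stages": {}}

    def _stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)
        report["stages"][name] = round(time.time() - t0, 2)

    # --- simulate -----------------------------------------------------------
    _stage("simulate")
    protocol = make_protocol(config.n_sounds, config.n_reps, config.sound_dur_s,
                             config.isi_s, config.sim.frame_rate,
                             config.block_layout, rng_protocol)
    sim = dataclasses.replace(config.sim, mode=config.mode)
    raster, truth = simulate_raster(sim, protocol, rng_sim)
    issues = validate_inputs(raster, protocol)
    if issues:
        raise RuntimeError(f"stage simulate produced invalid inputs: {issues}")

    # --- detect -------------------------------------------------------------
    _stage("detect")
    events, rate = detect_population_events(raster, config.detection, rng_detect)
    pre, stim, post = _split_events(events, protocol)
    spont_dur_s = sum((b - a) for k, a, b in protocol.blocks if k == "spont") \
        / protocol.frame_rate
    report["events"] = event_stats(pre + post, raster.n_neurons, spont_dur_s)

    # --- analyze: similarity vs reproducibility ----------------------------
    _stage("analyze")
    sound_trials = collect_evoked_trials(raster, protocol,
                                         config.detection.evoked_window_ms)
    granularity = config.granularity or max(2, config.n_sounds // 2)
    sr = {}
    tables = {}
    for segment, segment_events in (("pre", pre), ("post", post)):
        if len(segment_events) < 4:
            sr[segment] = {"error": "too few ongoing assemblies"}
            continue
        table, labels, vectors, stat = _similarity_block(
            sound_trials, segment_events, granularity)
        sr[segment] = stat
        tables[segment] = (table, labels, vectors)
    report["similarity"] = sr

    # --- decode -------------------------------------------------------------
    _stage("decode")
    dec = decoder.template_match_classify(sound_trials)
    report["decoding"] = {"accuracy_pct": dec.accuracy_pct,
                          "chance_pct": dec.chance_pct,
                          "n_trials": dec.n_trials}

    # --- tuning -------------------------------------------------------------
    _stage("tuning")
    profiles = tuning.response_profile(raster, protocol,
                                       config.detection.evoked_window_ms)
    usable = profiles.loc[profiles.std(axis=1) > 0]
    tuning_report: dict = {"n_neurons_tuned": int(len(usable))}
    if len(usable) > config.neuron_granularity:
        labels, _, _ = tuning.cluster_neurons(usable, config.neuron_granularity)
        spars = []
        for c in sorted(c for c in np.unique(labels) if c >= 0):
            mean_profile = usable.to_numpy()[labels == c].mean(axis=0)
            if mean_profile.std() > 0:
                spars.append(tuning.sparseness(mean_profile))
        tuning_report["mean_cluster_sparseness"] = float(np.mean(spars))
        tuning_report["n_clusters"] = int(len(spars))
    report["tuning"] = tuning_report

    # --- specificity --------------------------------------------------------
    _stage("specificity")
    spont_events = pre + post
    spec_report: dict = {}
    if spont_events:
        records = specificity.participation_probs(
            raster, spont_events, protocol, config.detection.evoked_window_ms)
        labels_cls, fractions = specificity.classify_neurons(records)
        spec_report["class_fractions"] = fractions
        spec_report["regression_mad_observed"] = specificity.regression_mad(records)
        params = specificity.SurrogateModelParams(
            n_neurons=len(records),
            n_spont_events=max(1, len(spont_events)),
            n_evoked_trials=protocol.n_trials)
        indep = specificity.model_independent(records, rng_models)
        equal = specificity.model_equal(params, rng_models)
        common = specificity.model_common_specific(params, rng_models)
        spec_report["diff_mad"] = {
            "observed": specificity.mad(records["diff"]),
            "independent": specificity.mad(indep["diff"]),
            "equal": specificity.mad(equal["diff"]),
            "common_specific": specificity.mad(common["diff"]),
        }
    report["specificity"] = spec_report
    report["elapsed_s"] = round(time.time() - t0, 2)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        protocol.to_tsv(out / "protocol.tsv")
        ev_rows = [(i, e.start, e.end, e.peak, e.duration_ms,
                    e.size_pct(raster.n_neurons)) for i, e in enumerate(events)]
        pd.DataFrame(ev_rows, columns=["event_id", "start_frame", "end_frame",
                                       "peak_frame", "duration_ms", "size_pct"]
                     ).to_csv(out / "events.tsv", sep="\t", index=False)
        for segment, (table, labels, _) in tables.items():
            table.to_csv(out / f"similarity_{segment}.tsv", sep="\t")
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
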