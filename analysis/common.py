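"""Shared plumbing for the numbered analysis drivers.

Each driver simulates or reloads the two reference sessions (awake-mode and
anesthesia-mode, 1,000 neurons by default, the standard 50-sound x 12-rep
protocol over 300-s blocks) and writes its tables under results/.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
import yaml

from popassembly.preprocess import SpikeRaster
from popassembly.synthetic import (SESSION_BLOCK_LAYOUT, GroundTruth,
                                   SimulationConfig, StimulusProtocol,
                                   make_protocol, simulate_raster)

RESULTS = Path(__file__).resolve().parent.parent / "results"
MODES = ("awake", "anesthesia")


def parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--n-neurons", type=int, default=1000)
    p.add_argument("--n-sounds", type=int, default=50)
    p.add_argument("--n-reps", type=int, default=12)
    p.add_argument("--results", type=Path, default=RESULTS)
    return p


def session_dir(results: Path, mode: str) -> Path:
    d = results / "sessions" / mode
    d.mkdir(parents=True, exist_ok=True)
    return d


def build_session(args, mode: str, write: bool = False):
    """Simulate one session deterministically from the CLI seed."""
    seeds = [int(s % (2 ** 31))
             for s in np.random.SeedSequence([args.seed, MODES.index(mode)])
             .generate_state(2)]
    protocol = make_protocol(args.n_sounds, args.n_reps, 0.5, 1.0, 30.0,
                             SESSION_BLOCK_LAYOUT, rng=seeds[0])
    cfg = SimulationConfig(n_neurons=args.n_neurons, mode=mode, seed=seeds[1])
    raster, truth = simulate_raster(cfg, protocol)
    if write:
        d = session_dir(args.results, mode)
        raster.to_hdf5(d / "raster.h5")
        truth.to_hdf5(d / "raster.h5")
        protocol.to_tsv(d / "protocol.tsv")
        (d / "blocks.json").write_text(json.dumps(protocol.blocks))
        (d / "sim_config.yaml").write_text(
            yaml.safe_dump({"mode": mode, "seed": cfg.seed,
                            "n_neurons": cfg.n_neurons}))
    return protocol, raster, truth


def load_session(args, mode: str):
    """Load the session written by 01_simulate_sessions, or rebuild it."""
    d = session_dir(args.results, mode)
    raster_path = d / "raster.h5"
    if not raster_path.exists():
        return build_session(args, mode, write=True)
    raster = SpikeRaster.from_hdf5(raster_path)
    truth = GroundTruth.from_hdf5(raster_path)
    blocks = [tuple(b) for b in json.loads((d / "blocks.json").read_text())]
    protocol = StimulusProtocol.from_tsv(d / "protocol.tsv", raster.frame_rate,
                                         blocks)
    return protocol, raster, truth
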