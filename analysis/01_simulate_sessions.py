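#!/usr/bin/env python
"""Simulate the two reference sessions (awake-mode, anesthesia-mode).

Writes rasters + ground truth (HDF5), protocols (TSV) and summary counts
under results/sessions/, and prints the basic session statistics.
"""

import json

from common import MODES, build_session, parser


def main() -> None:
    args = parser(__doc__).parse_args()
    summary = {}
    for mode in MODES:
        protocol, raster, truth = build_session(args, mode, write=True)
        info = {
            "n_neurons": raster.n_neurons,
            "n_frames": raster.n_frames,
            "n_trials": protocol.n_trials,
            "total_spikes": int(raster.spikes.sum()),
            "true_ongoing_events": int(len(truth.event_intervals)),
            "true_event_rate_hz": round(
                len(truth.event_intervals) / raster.duration_s, 3),
        }
        summary[mode] = info
        print(f"{mode}: {info['n_neurons']} neurons x {info['n_frames']} frames, "
              f"{info['n_trials']} trials, {info['true_ongoing_events']} ongoing "
              f"events ({info['true_event_rate_hz']} Hz)")
    (args.results / "sessions" / "summary.json").write_text(
        json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
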