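#!/usr/bin/env python
"""Decode sound identity from single-trial evoked assembly vectors.

Leave-one-out template matching with the correlation distance, in both
sessions, plus a label-permutation chance control. Writes accuracies and
confusion matrices under results/decoding/.
"""

import json

import numpy as np
import pandas as pd

from common import MODES, load_session, parser
from popassembly.decoder import template_match_classify
from popassembly.pipeline import collect_evoked_trials


def main() -> None:
    args = parser(__doc__).parse_args()
    out = args.results / "decoding"
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for mode in MODES:
        protocol, raster, _ = load_session(args, mode)
        trials = collect_evoked_trials(raster, protocol)
        res = template_match_classify(trials)
        rng = np.random.default_rng(args.seed + 300)
        vectors = [v for s in sorted(trials) for v in trials[s] if v is not None]
        labels = [s for s in sorted(trials) for v in trials[s] if v is not None]
        perm = rng.permutation(len(labels))
        shuffled = {}
        for vec, j in zip(vectors, perm):
            shuffled.setdefault(labels[j], []).append(vec)
        null = template_match_classify(shuffled)
        summary[mode] = {"accuracy_pct": res.accuracy_pct,
                         "chance_pct": res.chance_pct,
                         "permuted_accuracy_pct": null.accuracy_pct,
                         "n_trials": res.n_trials}
        pd.DataFrame(res.confusion, index=res.sounds, columns=res.sounds) \
            .to_csv(out / f"confusion_{mode}.tsv", sep="\t")
        print(f"{mode}: accuracy {res.accuracy_pct:.1f}% "
              f"(chance {res.chance_pct:.1f}%, permuted labels "
              f"{null.accuracy_pct:.1f}%)")
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
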