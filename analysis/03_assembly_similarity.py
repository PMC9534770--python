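#!/usr/bin/env python
"""Compare sound-evoked responses with ongoing assembly clusters.

For each session, clusters the ongoing assemblies of the pre- and
post-stimulation segments (complete linkage on correlation distance),
computes per-sound similarity S_i and combined reproducibility R_i, the
neuron-identity shuffle null, and a PCA state-space embedding of all
vectors. Writes per-sound tables and the embedding under
results/similarity/, and prints the median S vs R contrast per state.
"""

import numpy as np
import pandas as pd
import scipy.stats

from common import MODES, load_session, parser
from popassembly import assemblies as asm
from popassembly.events import DetectionConfig, detect_population_events
from popassembly.pipeline import collect_evoked_trials


def main() -> None:
    args = parser(__doc__).parse_args()
    out = args.results / "similarity"
    out.mkdir(parents=True, exist_ok=True)
    embedding_rows = []
    for mode in MODES:
        protocol, raster, _ = load_session(args, mode)
        events, _ = detect_population_events(
            raster, DetectionConfig(seed=args.seed + 100))
        stim = protocol.frames_of_kind("stim")
        trials = collect_evoked_trials(raster, protocol)
        granularity = max(2, protocol.n_sounds // 2)
        for segment in ("pre", "post"):
            if segment == "pre":
                seg_events = [e for e in events if not stim[e.peak]
                              and e.end < np.flatnonzero(stim)[0]]
            else:
                seg_events = [e for e in events if not stim[e.peak]
                              and e.start > np.flatnonzero(stim)[-1]]
            if len(seg_events) < 4:
                print(f"{mode}/{segment}: too few ongoing assemblies")
                continue
            vectors = np.vstack([e.assembly for e in seg_events])
            labels = asm.cluster_assemblies(
                vectors, min(granularity, len(seg_events)))
            table, _ = asm.similarity_reproducibility(trials, vectors, labels)
            null = asm.shuffled_similarity(trials, vectors, labels,
                                           n_shuffles=20,
                                           rng=args.seed + 200)
            table = table.join(null)
            table.to_csv(out / f"{mode}_{segment}.tsv", sep="\t")
            valid = table.dropna(subset=["S", "R"])
            w = scipy.stats.wilcoxon(valid["S"], valid["R"])
            print(f"{mode}/{segment}: median S={valid['S'].median():.3f} "
                  f"median R={valid['R'].median():.3f} "
                  f"(Wilcoxon p={w.pvalue:.2g}; shuffle null "
                  f"{valid['null_mean'].median():.3f})")
            for i, ev in enumerate(seg_events):
                embedding_rows.append((f"{mode}_{segment}", ev.assembly))
        for sound, tv in trials.items():
            for v in tv:
                if v is not None:
                    embedding_rows.append((f"{mode}_evoked", v))
    provenance = [p for p, _ in embedding_rows]
    emb = asm.pca_embed(np.vstack([v for _, v in embedding_rows]))
    pd.DataFrame({
        "provenance": provenance,
        "PC1": emb.scores[:, 0], "PC2": emb.scores[:, 1],
        "PC3": emb.scores[:, 2] if emb.scores.shape[1] > 2 else np.nan,
    }).to_csv(out / "embedding.tsv", sep="\t", index=False)
    print("explained variance (first PCs):",
          np.round(emb.explained_variance_ratio, 3))


if __name__ == "__main__":
    main()
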