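"""Template-matching sound decoder with leave-one-out crossvalidation.

Each held-out single-trial response vector is compared, via the correlation
distance ``1 - r``, with every other single-trial response in the session;
it is assigned to the sound whose remaining trials have the smallest mean
distance to it. Chance level for ``n`` sounds is ``100 / n`` percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .assemblies import pairwise_corr

logger = logging.getLogger(__name__)

__all__ = ["DecodingResult", "template_match_classify", "chance_level"]


@dataclass
class DecodingResult:
    accuracy_pct: float
    per_sound_accuracy: dict[int, float]
    confusion: np.ndarray          # (n_sounds, n_sounds) row-normalized
    sounds: list[int]
    chance_pct: float
    n_trials: int


def chance_level(n_sounds: int) -> float:
    """Chance decoding accuracy in percent: 100 / n_sounds."""
    if n_sounds < 1:
        raise ValueError("need at least one sound")
    return 100.0 / n_sounds


def template_match_classify(
    sound_trials: dict[int, list[np.ndarray | None]],
) -> DecodingResult:
    """Leave-one-out template-matching classification of trial vectors.

    Absent (``None``) or constant trial vectors are skipped; sounds with no
    usable trial are excluded entirely (logged). Ties in mean distance break
    to the lowest sound id.
    """
    sounds, vectors, labels = [], [], []
    for sound in sorted(sound_trials):
        usable = [np.asarray(v, dtype=float) for v in sound_trials[sound]
                  if v is not None and np.asarray(v).std() > 0]
        if not usable:
            logger.warning("sound %s has no usable trials; excluded", sound)
            continue
        sounds.append(sound)
        vectors.extend(usable)
        labels.extend([sound] * len(usable))
    if len(sounds) < 2:
        raise ValueError("need at least two sounds with usable trials")
    x = np.vstack(vectors)
    y = np.asarray(labels)
    n = x.shape[0]
    dist = 1.0 - pairwise_corr(x, x)

    sound_index = {s: i for i, s in enumerate(sounds)}
    onehot = np.zeros((n, len(sounds)))
    onehot[np.arange(n), [sound_index[s] for s in y]] = 1.0
    group_sums = dist @ onehot                     # (n, n_sounds)
    group_counts = onehot.sum(axis=0)              # trials per sound
    # leave-one-out: remove self-distance (0) from the own-sound mean
    counts = np.broadcast_to(group_counts, group_sums.shape).copy()
    counts[np.arange(n), [sound_index[s] for s in y]] -= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dist = group_sums / counts
    mean_dist[~np.isfinite(mean_dist)] = np.inf    # sounds left with 0 train trials
    pred_idx = np.argmin(mean_dist, axis=1)        # argmin -> lowest index on ties
    pred = np.asarray(sounds)[pred_idx]

    correct = pred == y
    confusion = np.zeros((len(sounds), len(sounds)))
    for true, p in zip(y, pred):
        confusion[sound_index[true], sound_index[p]] += 1
    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(row_sums > 0, confusion / row_sums, 0.0)
    per_sound = {
        s: float(correct[y == s].mean()) * 100.0 for s in sounds
    }
    return DecodingResult(
        accuracy_pct=float(correct.mean()) * 100.0,
        per_sound_accuracy=per_sound,
        confusion=confusion,
        sounds=sounds,
        chance_pct=chance_level(len(sounds)),
        n_trials=n,
    )
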