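"""Single-neuron sound tuning: response profiles, clustering, sparseness.

A neuron's response profile is the count, per sound, of trials on which it
fired at least one spike in the 500-ms response window. Profiles are
clustered (complete linkage on correlation distance), per-cluster response
significance is evaluated against instance-shuffled surrogates with a
one-way ANOVA followed by Tukey's multiple-comparison test, and lifetime
sparseness is quantified as the kurtosis of the response distribution
across sounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform

from .assemblies import correlation_matrix
from .preprocess import SpikeRaster
from .synthetic import StimulusProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "response_profile",
    "cluster_neurons",
    "significant_sounds",
    "sparseness",
    "state_distance",
    "filter_terminals",
]


def response_profile(
    raster: SpikeRaster,
    protocol: StimulusProtocol,
    window_ms: float = 500.0,
) -> pd.DataFrame:
    """Per-(neuron, sound) response counts over the trial repetitions.

    Returns a neurons x sounds DataFrame of integer counts (0..n_reps); the
    response-probability profile is ``counts / n_reps``.
    """
    window = int(round(window_ms / 1000.0 * raster.frame_rate))
    sounds = np.unique(protocol.sound_ids)
    counts = np.zeros((raster.n_neurons, sounds.size), dtype=int)
    col = {s: i for i, s in enumerate(sounds)}
    for row in protocol.trials.itertuples(index=False):
        onset = int(row.onset_frame)
        end = min(onset + window, raster.n_frames)
        responded = raster.spikes[:, onset:end].any(axis=1)
        counts[:, col[int(row.sound_id)]] += responded
    return pd.DataFrame(counts, columns=sounds,
                        index=pd.RangeIndex(raster.n_neurons, name="neuron"))


def cluster_neurons(
    profiles: pd.DataFrame | np.ndarray,
    granularity: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-linkage clustering of neurons by response-profile correlation.

    Constant profiles (no variance across sounds) are excluded with a logged
    warning and labelled -1. Returns ``(labels, ordered_corr, order)`` where
    ``ordered_corr`` is the profile correlation matrix reordered by cluster
    and ``order`` the corresponding neuron permutation (excluded neurons
    omitted).
    """
    x = np.asarray(profiles, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two neurons")
    r, kept = correlation_matrix(x)
    if granularity > kept.size:
        raise ValueError("granularity exceeds number of usable neurons")
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(squareform(dist, checks=False), method="complete")
    labels_kept = sch.fcluster(link, t=granularity, criterion="maxclust") - 1
    labels = np.full(x.shape[0], -1, dtype=int)
    labels[kept] = labels_kept
    order_within = np.argsort(labels_kept, kind="stable")
    ordered_corr = r[np.ix_(order_within, order_within)]
    return labels, ordered_corr, kept[order_within]


def significant_sounds(
    profiles: pd.DataFrame,
    labels: np.ndarray,
    n_reps: int,
    n_instances: int | None = None,
    n_shuffle: int = 100,
    alpha: float = 0.01,
    rng: np.random.Generator | int | None = 0,
) -> dict[int, list[int]]:
    """Sounds with responses above instance-shuffled chance, per cluster.

    For every neuron of a cluster, its per-sound response counts are
    redistributed over all stimulation instances (``n_instances``, default
    the actual ``n_sounds * n_reps``); the number of nonzero responses among
    ``n_reps`` randomly chosen instances, averaged over the cluster's
    neurons, forms the surrogate sample. A one-way ANOVA across the
    per-sound observed samples and the surrogate sample, followed by Tukey's
    multiple-comparison test against the surrogate group, yields the sounds
    with significantly higher responses at ``alpha``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = np.asarray(profiles, dtype=float)
    sounds = list(profiles.columns)
    n_sounds = len(sounds)
    if n_instances is None:
        n_instances = n_sounds * n_reps
    if n_instances < n_reps:
        raise ValueError("n_instances must be >= n_reps")
    out: dict[int, list[int]] = {}
    for cluster in sorted(c for c in np.unique(labels) if c >= 0):
        members = np.flatnonzero(labels == cluster)
        sub = counts[members]                       # (m, n_sounds)
        if sub.sum() == 0:
            out[int(cluster)] = []
            continue
        # surrogate: redistribute each neuron's responses over all instances,
        # draw n_reps instances, count nonzero, average over neurons
        surrogate = np.empty(n_shuffle)
        m = sub.shape[0]
        total = sub.sum(axis=1).astype(int)         # responses per neuron
        for b in range(n_shuffle):
            vals = np.empty(m)
            for i in range(m):
                instances = np.zeros(n_instances, dtype=np.int8)
                pos = rng.choice(n_instances, size=min(total[i], n_instances),
                                 replace=False)
                instances[pos] = 1
                pick = rng.choice(n_instances, size=n_reps, replace=False)
                vals[i] = instances[pick].sum()
            surrogate[b] = vals.mean()
        observed = [sub[:, k] for k in range(n_sounds)]
        groups = observed + [surrogate]
        try:
            _, p_global = scipy.stats.f_oneway(*groups)
        except ValueError:
            out[int(cluster)] = []
            continue
        sig: list[int] = []
        if np.isfinite(p_global) and p_global < alpha:
            tukey = scipy.stats.tukey_hsd(*groups)
            surr_idx = n_sounds
            surr_mean = surrogate.mean()
            for k in range(n_sounds):
                if (tukey.pvalue[k, surr_idx] < alpha
                        and observed[k].mean() > surr_mean):
                    sig.append(sounds[k])
        out[int(cluster)] = sig
    return out


def sparseness(profile: np.ndarray) -> float:
    """Lifetime sparseness: Pearson (non-excess) kurtosis across sounds.

    Heavy concentration of responses on few sounds yields large kurtosis;
    a uniform profile yields 1.8, Gaussian-like profiles ~3.
    """
    x = np.asarray(profile, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 sounds")
    if x.std() == 0:
        logger.warning("constant profile: sparseness undefined")
        return float("nan")
    return float(scipy.stats.kurtosis(x, fisher=False, bias=True))


def state_distance(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    metric: str = "correlation",
) -> float:
    """Distance between mean response profiles of two brain states.

    Default is the correlation distance ``1 - r`` (0 identical, 2 perfectly
    anti-correlated); ``metric="euclidean"`` gives the L2 alternative.
    Constant profiles make the correlation distance undefined (NaN, logged).
    """
    a = np.asarray(profile_a, dtype=float).ravel()
    b = np.asarray(profile_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("profile length mismatch")
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric != "correlation":
        raise ValueError(f"unknown metric {metric!r}")
    if a.std() == 0 or b.std() == 0:
        logger.warning("constant profile: state distance undefined")
        return float("nan")
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def filter_terminals(
    profiles: pd.DataFrame,
    min_responses: int = 2,
    per_sound: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Keep units that responded at least ``min_responses`` times.

    By default the threshold applies to the total response count across all
    sounds; with ``per_sound=True`` a unit must respond at least that often
    to a single sound. Returns the retained sub-table and the retained
    fraction.
    """
    counts = np.asarray(profiles, dtype=float)
    if per_sound:
        keep = (counts >= min_responses).any(axis=1)
    else:
        keep = counts.sum(axis=1) >= min_responses
    fraction = float(keep.mean()) if counts.shape[0] else 0.0
    return profiles.loc[keep], fraction
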