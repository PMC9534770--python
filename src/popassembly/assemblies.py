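"""Assembly-level statistics: clustering, similarity vs reproducibility.

Ongoing assemblies are grouped by complete-linkage hierarchical clustering on
the correlation distance between binary population vectors. For every sound
``i`` the similarity ``S_i = max_j C_ij`` is the best mean cross-correlation
between the sound's single-trial response vectors and the assemblies of an
ongoing cluster ``j``; it is compared with the combined reproducibility
``R_i = (A_i + A_{j_i}) / 2`` where ``A_i`` is the mean pairwise correlation
across the sound's trials and ``A_{j_i}`` the mean pairwise correlation
within the best-matching cluster. ``S_i ~ R_i`` indicates that evoked
patterns are drawn from the ongoing repertoire; ``S_i < R_i`` indicates
dedicated evoked assemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_matrix",
    "cluster_assemblies",
    "default_granularity",
    "similarity_reproducibility",
    "shuffled_similarity",
    "pca_embed",
    "StateSpaceEmbedding",
]


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (x - mu) / sd


def pairwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Rows are population vectors over the same neurons; constant rows yield
    NaN columns/rows.
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("vector length mismatch")
    return _standardize_rows(a) @ _standardize_rows(b).T / a.shape[1]


def correlation_matrix(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix between population vectors.

    Constant (all-zero or all-one) vectors have undefined correlation and are
    excluded with a logged warning. Returns ``(matrix, kept_indices)``.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] < 2:
        raise ValueError("need at least two vectors")
    variances = vectors.var(axis=1)
    kept = np.flatnonzero(variances > 0)
    if kept.size < vectors.shape[0]:
        logger.warning("excluding %d constant vectors from correlation matrix",
                       vectors.shape[0] - kept.size)
    if kept.size < 2:
        raise ValueError("fewer than two non-constant vectors")
    r = np.corrcoef(vectors[kept])
    np.fill_diagonal(r, 1.0)
    return r, kept


def default_granularity(n_vectors: int, n_sounds: int) -> int:
    """Default cluster count for ongoing assemblies: min(n, n_sounds/2)."""
    return max(1, min(n_vectors, n_sounds // 2))


def cluster_assemblies(vectors: np.ndarray, granularity: int) -> np.ndarray:
    """Complete-linkage clustering of assembly vectors on distance 1 - r.

    Returns integer labels ``0..granularity-1``; constant vectors (excluded
    before clustering) carry the label ``-1``.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = vectors.shape[0]
    if n < 2:
        raise ValueError("need at least two vectors")
    if granularity > n:
        raise ValueError(f"granularity {granularity} exceeds {n} vectors")
    r, kept = correlation_matrix(vectors)
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = sch.linkage(condensed, method="complete")
    labels_kept = sch.fcluster(link, t=min(granularity, kept.size),
                               criterion="maxclust") - 1
    labels = np.full(n, -1, dtype=int)
    labels[kept] = labels_kept
    return labels


@dataclass
class StateSpaceEmbedding:
    """Leading principal components of pooled assembly/response vectors."""

    scores: np.ndarray                 # (n_vectors, n_components)
    components: np.ndarray             # (n_components, n_neurons)
    explained_variance_ratio: np.ndarray
    n_components_available: int
    degenerate: bool                   # True when < 3 informative dimensions


def pca_embed(vectors: np.ndarray, n_components: int = 3) -> StateSpaceEmbedding:
    """Center and project pooled population vectors onto leading PCs."""
    x = np.atleast_2d(np.asarray(vectors, dtype=float))
    if x.shape[0] < 4:
        raise ValueError("need at least 4 vectors for a state-space embedding")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    k = min(n_components, rank, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    return StateSpaceEmbedding(
        scores=scores,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components_available=k,
        degenerate=k < n_components,
    )


def _usable_trials(trial_vectors: list[np.ndarray | None]) -> list[np.ndarray]:
    return [v for v in trial_vectors
            if v is not None and np.asarray(v).std() > 0]


def similarity_reproducibility(
    sound_trials: dict[int, list[np.ndarray | None]],
    ongoing_vectors: np.ndarray,
    cluster_labels: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sound similarity and reproducibility against ongoing clusters.

    Parameters
    ----------
    sound_trials
        Mapping sound id -> single-trial evoked vectors (``None`` marks an
        absent trial, skipped).
    ongoing_vectors
        Ongoing assembly vectors, one per detected spontaneous event.
    cluster_labels
        Cluster label per ongoing vector (-1 = excluded).

    Returns a per-sound table with columns (S, R, A_sound, A_cluster,
    best_cluster, n_trials) and the full sounds x clusters ``C`` matrix.
    Only clusters with at least two members enter the maximum, so that the
    within-cluster reproducibility of the winner is always defined. Sounds
    with fewer than two usable trials have NaN statistics.
    """
    ongoing_vectors = np.atleast_2d(np.asarray(ongoing_vectors, dtype=float))
    cluster_labels = np.asarray(cluster_labels)
    clusters = [c for c in np.unique(cluster_labels) if c >= 0]
    eligible = [c for c in clusters
                if (cluster_labels == c).sum() >= 2]
    if not eligible:
        raise ValueError("no ongoing cluster with >= 2 members")

    sounds = sorted(sound_trials)
    c_matrix = np.full((len(sounds), len(clusters)), np.nan)
    rows = []
    for si, sound in enumerate(sounds):
        usable = _usable_trials(sound_trials[sound])
        n_used = len(usable)
        if n_used < 2:
            logger.warning("sound %s has %d usable trials; statistics undefined",
                           sound, n_used)
            rows.append((sound, np.nan, np.nan, np.nan, np.nan, -1, n_used))
            continue
        trials = np.vstack(usable)
        rr = pairwise_corr(trials, trials)
        iu = np.triu_indices(n_used, k=1)
        a_sound = float(rr[iu].mean())
        cross = pairwise_corr(trials, ongoing_vectors)
        best_c, best_s = -1, -np.inf
        for ci, c in enumerate(clusters):
            members = cluster_labels == c
            c_ij = float(np.nanmean(cross[:, members]))
            c_matrix[si, ci] = c_ij
            if c in eligible and c_ij > best_s:
                best_s, best_c = c_ij, c
        members = np.flatnonzero(cluster_labels == best_c)
        within = pairwise_corr(ongoing_vectors[members], ongoing_vectors[members])
        iu2 = np.triu_indices(members.size, k=1)
        a_cluster = float(np.nanmean(within[iu2]))
        s_i = best_s
        r_i = (a_sound + a_cluster) / 2.0
        rows.append((sound, s_i, r_i, a_sound, a_cluster, int(best_c), n_used))
    table = pd.DataFrame(
        rows, columns=["sound", "S", "R", "A_sound", "A_cluster",
                       "best_cluster", "n_trials"]
    ).set_index("sound")
    return table, c_matrix


def shuffled_similarity(
    sound_trials: dict[int, list[np.ndarray | None]],
    ongoing_vectors: np.ndarray,
    cluster_labels: np.ndarray,
    n_shuffles: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Null similarity: neuron identities permuted within each evoked vector.

    The permutation preserves every vector's population sum (assembly size)
    while destroying neuron-identity alignment with the ongoing clusters.
    Returns per-sound null mean and the 2.5/97.5% quantiles of ``S_i``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sounds = sorted(sound_trials)
    null = np.full((n_shuffles, len(sounds)), np.nan)
    for b in range(n_shuffles):
        shuffled = {
            sound: [None if v is None else np.asarray(v)[rng.permutation(len(v))]
                    for v in trials]
            for sound, trials in sound_trials.items()
        }
        table, _ = similarity_reproducibility(shuffled, ongoing_vectors,
                                              cluster_labels)
        null[b] = table["S"].to_numpy()
    return pd.DataFrame(
        {
            "null_mean": np.nanmean(null, axis=0),
            "null_q025": np.nanquantile(null, 0.025, axis=0),
            "null_q975": np.nanquantile(null, 0.975, axis=0),
        },
        index=pd.Index(sounds, name="sound"),
    )
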