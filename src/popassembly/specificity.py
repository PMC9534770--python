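"""Single-neuron specificity for ongoing versus evoked activity.

Each neuron is summarized by two probabilities: participating (>= 1 spike)
in a detected spontaneous population event, and responding (>= 1 spike in
the 500-ms window) to any sound presentation. The difference of the two,
bounded by +/- 1 mean absolute deviation around its population mean,
partitions neurons into ongoing-preferring, evoked-preferring and
nonspecific classes. Three surrogate models probe how the two probabilities
relate across the population: fully independent (column shuffle), exactly
equal (estimation noise only), and a common term plus independent specific
terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblies import pairwise_corr
from .events import PopulationEvent
from .preprocess import SpikeRaster
from .synthetic import StimulusProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "SurrogateModelParams",
    "participation_probs",
    "classify_neurons",
    "mad",
    "subset_reproducibility",
    "model_independent",
    "model_equal",
    "model_common_specific",
    "regression_mad",
    "bootstrap_compare",
    "CLASS_LABELS",
]

CLASS_LABELS = ("ongoing-preferring", "evoked-preferring", "nonspecific")


@dataclass
class SurrogateModelParams:
    """Parameters of the surrogate probability models.

    ``equal_mean``/``equal_sd`` define the truncated-normal distribution of
    the true probability in the equal-probabilities model. ``k`` is the scale
    of the common-probability density ``exp(-(x/k)^2)/S`` on [0, 1];
    ``v_sound``/``v_spont`` scale the zero-mean Gaussian specific terms.
    ``v_unit`` selects how the v values are read: ``"scaled_by_k"`` (default)
    takes the specific-term s.d. as ``v * k`` — the reading under which the
    common term and the specific terms live on the same probability scale
    and the model can reproduce a tightly correlated probability cloud —
    while ``"absolute"`` takes ``v`` directly as the s.d. on the probability
    scale. Out-of-range sums are clipped to [0, 1] and the clipping fraction
    logged. ``n_spont_events``/``n_evoked_trials`` are the trial counts used
    for binomial estimation noise in the equal model.
    """

    n_neurons: int = 6310
    equal_mean: float = 0.11
    equal_sd: float = 0.08
    k: float = 0.1
    v_sound: float = 0.85
    v_spont: float = 0.65
    v_unit: str = "scaled_by_k"
    n_spont_events: int = 500
    n_evoked_trials: int = 600

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if min(self.v_sound, self.v_spont) < 0:
            raise ValueError("v parameters must be >= 0")
        if min(self.n_spont_events, self.n_evoked_trials) < 1:
            raise ValueError("trial counts must be >= 1")
        if self.v_unit not in ("scaled_by_k", "absolute"):
            raise ValueError("v_unit must be 'scaled_by_k' or 'absolute'")

    @property
    def sd_sound(self) -> float:
        return self.v_sound * (self.k if self.v_unit == "scaled_by_k" else 1.0)

    @property
    def sd_spont(self) -> float:
        return self.v_spont * (self.k if self.v_unit == "scaled_by_k" else 1.0)


def participation_probs(
    raster: SpikeRaster,
    events: list[PopulationEvent],
    protocol: StimulusProtocol,
    window_ms: float = 500.0,
) -> pd.DataFrame:
    """Per-neuron ongoing and evoked participation probabilities.

    ``p_spont`` is the fraction of detected spontaneous events in which the
    neuron fired; ``p_evoked`` the fraction of sound trials (all sounds
    pooled) with at least one spike in the response window.
    """
    if protocol.n_trials < 1:
        raise ValueError("protocol has no sound trials")
    if not events:
        raise ValueError("no spontaneous events: p_spont undefined")
    n = raster.n_neurons
    spont_counts = np.zeros(n)
    for ev in events:
        member = raster.spikes[:, ev.start:ev.end + 1].any(axis=1)
        spont_counts += member
    p_spont = spont_counts / len(events)

    window = int(round(window_ms / 1000.0 * raster.frame_rate))
    evoked_counts = np.zeros(n)
    for row in protocol.trials.itertuples(index=False):
        onset = int(row.onset_frame)
        end = min(onset + window, raster.n_frames)
        evoked_counts += raster.spikes[:, onset:end].any(axis=1)
    p_evoked = evoked_counts / protocol.n_trials
    return pd.DataFrame(
        {"p_spont": p_spont, "p_evoked": p_evoked,
         "diff": p_spont - p_evoked},
        index=pd.RangeIndex(n, name="neuron"),
    )


def mad(values: np.ndarray) -> float:
    """Mean absolute deviation about the mean."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.abs(x - x.mean()).mean())


def classify_neurons(records: pd.DataFrame) -> tuple[np.ndarray, dict[str, float]]:
    """Three-way specificity partition on the probability difference.

    Neurons whose difference ``p_spont - p_evoked`` lies strictly within
    mean +/- 1 m.a.d. are nonspecific; at or above the upper boundary they
    are ongoing-preferring, at or below the lower boundary evoked-preferring
    (boundary values go to the specific side). Returns the label array and
    the class fractions.
    """
    if len(records) < 2:
        raise ValueError("need at least two neurons")
    diff = records["diff"].to_numpy(dtype=float)
    center = diff.mean()
    spread = mad(diff)
    labels = np.full(diff.size, "nonspecific", dtype=object)
    if spread == 0:
        logger.warning("zero m.a.d.: all neurons classified nonspecific")
    else:
        labels[diff >= center + spread] = "ongoing-preferring"
        labels[diff <= center - spread] = "evoked-preferring"
    fractions = {name: float((labels == name).mean()) for name in CLASS_LABELS}
    return labels.astype(str), fractions


def subset_reproducibility(
    ongoing_vectors: np.ndarray,
    cluster_labels: np.ndarray,
    sound_trials: dict[int, list[np.ndarray | None]],
    keep_mask: np.ndarray,
) -> dict:
    """Reproducibility of assemblies/responses restricted to kept neurons.

    Every population vector is restricted to the neurons selected by
    ``keep_mask``; within-cluster and within-sound mean pairwise Pearson
    correlations are recomputed on the restriction. Vectors that become
    constant are excluded (logged).
    """
    keep_mask = np.asarray(keep_mask, dtype=bool)
    if keep_mask.sum() < 2:
        raise ValueError("kept subset must contain at least two neurons")

    def _mean_pairwise(vectors: list[np.ndarray]) -> float:
        vecs = [v for v in vectors if np.asarray(v).std() > 0]
        if len(vecs) < len(vectors):
            logger.warning("excluding %d constant restricted vectors",
                           len(vectors) - len(vecs))
        if len(vecs) < 2:
            return float("nan")
        x = np.vstack(vecs)
        rr = pairwise_corr(x, x)
        iu = np.triu_indices(len(vecs), k=1)
        return float(np.nanmean(rr[iu]))

    ongoing_vectors = np.atleast_2d(np.asarray(ongoing_vectors))[:, keep_mask]
    cluster_repro = {}
    for c in sorted(c for c in np.unique(cluster_labels) if c >= 0):
        members = ongoing_vectors[np.asarray(cluster_labels) == c]
        if members.shape[0] >= 2:
            cluster_repro[int(c)] = _mean_pairwise(list(members))
    sound_repro = {}
    for sound, trials in sound_trials.items():
        usable = [np.asarray(v)[keep_mask] for v in trials if v is not None]
        sound_repro[sound] = _mean_pairwise(usable)
    def _safe_mean(values: dict) -> float:
        vals = [v for v in values.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return {
        "cluster_reproducibility": cluster_repro,
        "sound_reproducibility": sound_repro,
        "mean_cluster_reproducibility": _safe_mean(cluster_repro),
        "mean_sound_reproducibility": _safe_mean(sound_repro),
        "n_kept": int(keep_mask.sum()),
    }


def model_independent(
    records: pd.DataFrame,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Independence surrogate: probabilities shuffled across cells.

    ``p_spont`` and ``p_evoked`` are permuted independently across neurons,
    preserving both marginals exactly while destroying their coupling.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p_spont = rng.permutation(records["p_spont"].to_numpy())
    p_evoked = rng.permutation(records["p_evoked"].to_numpy())
    return pd.DataFrame({"p_spont": p_spont, "p_evoked": p_evoked,
                         "diff": p_spont - p_evoked})


def model_equal(
    params: SurrogateModelParams,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Equal-probabilities surrogate: spread from estimation noise only.

    A true probability is drawn per neuron from a normal distribution
    (mean ``equal_mean``, s.d. ``equal_sd``, truncated to [0, 1]) and used
    for both ongoing and evoked participation; the observed pair arises from
    binomial estimation with ``n_spont_events`` and ``n_evoked_trials``
    draws. ``n_spont_events=None``-like infinite-trial behaviour can be
    approximated with very large counts, where the difference collapses to 0.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = params.n_neurons
    p = np.empty(n)
    filled = 0
    while filled < n:            # truncated normal by rejection
        draw = rng.normal(params.equal_mean, params.equal_sd, size=n - filled)
        ok = draw[(draw >= 0) & (draw <= 1)]
        p[filled:filled + ok.size] = ok
        filled += ok.size
    p_spont = rng.binomial(params.n_spont_events, p) / params.n_spont_events
    p_evoked = rng.binomial(params.n_evoked_trials, p) / params.n_evoked_trials
    return pd.DataFrame({"p_spont": p_spont, "p_evoked": p_evoked,
                         "diff": p_spont - p_evoked, "p_true": p})


def sample_common_density(
    n: int, k: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample from the density proportional to exp(-(x/k)^2) on [0, 1].

    This is a half-normal with scale ``k / sqrt(2)`` truncated at 1, sampled
    by rejection (resampling the rare draws beyond 1).
    """
    sigma = k / np.sqrt(2.0)
    out = np.abs(rng.normal(0.0, sigma, size=n))
    bad = out > 1.0
    while bad.any():
        out[bad] = np.abs(rng.normal(0.0, sigma, size=int(bad.sum())))
        bad = out > 1.0
    return out


def model_common_specific(
    params: SurrogateModelParams,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Common + specific surrogate.

    ``p_resp = p_common + p_sound_spec`` and ``p_ongoing = p_common +
    p_spont_spec`` with ``p_common`` drawn from ``exp(-(x/k)^2)/S`` on
    [0, 1] and the specific terms from independent zero-mean Gaussians of
    s.d. ``params.sd_sound`` / ``params.sd_spont``; sums are clipped to
    [0, 1] and the clipped fraction logged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = params.n_neurons
    p_common = sample_common_density(n, params.k, rng)
    p_evoked = p_common + rng.normal(0.0, params.sd_sound, size=n) \
        if params.sd_sound > 0 else p_common.copy()
    p_spont = p_common + rng.normal(0.0, params.sd_spont, size=n) \
        if params.sd_spont > 0 else p_common.copy()
    clipped = ((p_evoked < 0) | (p_evoked > 1) | (p_spont < 0) | (p_spont > 1))
    if clipped.any():
        logger.info("common+specific model: clipped %.1f%% of neurons",
                    100.0 * clipped.mean())
    p_evoked = np.clip(p_evoked, 0.0, 1.0)
    p_spont = np.clip(p_spont, 0.0, 1.0)
    return pd.DataFrame({
        "p_spont": p_spont, "p_evoked": p_evoked,
        "diff": p_spont - p_evoked, "p_common": p_common,
        "clipped": clipped,
    })


def regression_mad(
    records: pd.DataFrame,
    residual: str = "vertical",
) -> float:
    """Mean absolute distance of (p_evoked, p_spont) points from the OLS line.

    ``p_spont`` is regressed on ``p_evoked``; the statistic is the mean
    absolute vertical residual (default) or the mean absolute perpendicular
    distance with ``residual="perpendicular"``.
    """
    x = records["p_evoked"].to_numpy(dtype=float)
    y = records["p_spont"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate cloud: p_evoked has no spread")
    slope, intercept = np.polyfit(x, y, deg=1)
    resid = y - (slope * x + intercept)
    if residual == "perpendicular":
        return float(np.abs(resid).mean() / np.sqrt(1.0 + slope ** 2))
    if residual != "vertical":
        raise ValueError(f"unknown residual geometry {residual!r}")
    return float(np.abs(resid).mean())


def bootstrap_compare(
    statistic,
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, float]:
    """Two-sided bootstrap test for a difference in a statistic.

    Resamples both samples with replacement ``n_boot`` times and computes
    the bootstrap distribution of ``statistic(A*) - statistic(B*)``; the
    p-value is twice the smaller tail fraction of that distribution around
    zero (with the +1 resampling floor, so the smallest attainable p is
    ``2 / (n_boot + 1)``). Returns ``(observed_difference, p_value)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = statistic(a) - statistic(b)
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        deltas[i] = (statistic(rng.choice(a, size=a.size, replace=True))
                     - statistic(rng.choice(b, size=b.size, replace=True)))
    lower = (1 + np.sum(deltas <= 0)) / (n_boot + 1)
    upper = (1 + np.sum(deltas >= 0)) / (n_boot + 1)
    p = min(1.0, 2.0 * min(lower, upper))
    return float(observed), float(p)
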