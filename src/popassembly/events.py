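"""Synchronous population-event detection and assembly extraction.

The detector asks when the summed population firing rate exceeds what a
population of independently firing neurons could produce by chance. The null
is built by reshuffling each neuron's inter-spike intervals (preserving its
spike count and interval multiset), the chance level is the average per-frame
99th percentile of the surrogate population rates, and a slowly varying
baseline estimated by asymmetric least squares absorbs drifts in background
rate. Events are the intervals between the local minima flanking each
supra-threshold local maximum of the Savitzky-Golay smoothed rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
from scipy.signal import savgol_filter

from .preprocess import PopulationRateTrace, SpikeRaster, population_rate
from .synthetic import StimulusProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "PopulationEvent",
    "shuffle_isi",
    "asls_baseline",
    "detection_threshold",
    "detect_events",
    "event_assembly",
    "evoked_assembly",
    "event_stats",
    "detect_population_events",
]


@dataclass
class DetectionConfig:
    """Parameters of the population-event detector.

    Defaults follow the standard recipe: 100 interval-shuffle surrogates,
    per-frame 99th percentile, asymmetric least squares baseline with
    asymmetry p = 0.01 and smoothness lambda = 1e8, and Savitzky-Golay
    smoothing of order 3 with frame length 7.
    """

    n_shuffles: int = 100
    percentile: float = 99.0
    asls_p: float = 0.01
    asls_lam: float = 1e8
    asls_iter: int = 10
    sg_order: int = 3
    sg_window: int = 7
    evoked_window_ms: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.asls_p < 1:
            raise ValueError("asls_p must lie in (0, 1)")
        if self.asls_lam <= 0:
            raise ValueError("asls_lam must be positive")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and exceed sg_order")


@dataclass
class PopulationEvent:
    """A detected synchronous event (frames inclusive) and its assembly."""

    start: int
    end: int
    peak: int
    frame_rate: float
    assembly: np.ndarray | None = None   # binary membership vector

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start + 1) / self.frame_rate * 1000.0

    def size_pct(self, n_neurons: int | None = None) -> float:
        if self.assembly is None:
            raise ValueError("assembly not yet extracted")
        n = n_neurons if n_neurons is not None else self.assembly.size
        return 100.0 * float(self.assembly.sum()) / n


def shuffle_isi(
    raster: SpikeRaster,
    n_shuffles: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Population rates of interval-shuffled surrogate rasters.

    For each neuron and surrogate, the multiset of inter-spike intervals is
    randomly permuted; the latency from recording start to the first spike is
    included as an extra interval, so surrogate spike times stay within
    ``[0, last original spike frame]`` and every neuron's spike count is
    preserved exactly. Returns an ``(n_shuffles, n_frames)`` array of
    surrogate population rates (coactive counts per frame).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_frames = raster.n_frames
    row_offset = np.arange(n_shuffles)[:, None] * n_frames
    flat = np.zeros(n_shuffles * n_frames, dtype=np.int64)
    for row in raster.spikes:
        t = np.flatnonzero(row)
        if t.size == 0:
            continue
        if t.size == 1:
            flat[(row_offset[:, 0] + t[0])] += 1
            continue
        # intervals: first-spike latency (from frame -1) then successive ISIs
        intervals = np.diff(t, prepend=-1)
        tiled = np.broadcast_to(intervals, (n_shuffles, intervals.size))
        perm = rng.permuted(tiled, axis=1)
        times = perm.cumsum(axis=1) - 1
        np.add.at(flat, (times + row_offset).ravel(), 1)
    return flat.reshape(n_shuffles, n_frames)


def asls_baseline(
    signal: np.ndarray,
    p: float = 0.01,
    lam: float = 1e8,
    n_iter: int = 10,
    tol: float = 1e-6,
) -> np.ndarray:
    """Asymmetric least squares baseline (Whittaker smoother with
    asymmetric weights).

    Minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2`` where
    ``w_i = p`` for points above the baseline and ``1 - p`` below, iterating
    weights to convergence (or ``n_iter`` rounds). Small ``p`` makes the fit
    hug the lower envelope, which is what a background-rate estimate under a
    signal with positive excursions needs.
    """
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("signal must be 1-D with length >= 3")
    if not np.isfinite(y).all():
        raise ValueError("signal contains non-finite values")
    n = y.size
    d = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = (lam * (d.T @ d)).tocsc()
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        a = (scipy.sparse.diags(w) + penalty).tocsc()
        z = scipy.sparse.linalg.spsolve(a, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    return z


def detection_threshold(
    rate: PopulationRateTrace,
    surrogate_rates: np.ndarray,
    cfg: DetectionConfig | None = None,
) -> np.ndarray:
    """Firing-rate threshold: surrogate offset over an AsLS baseline.

    The per-frame ``cfg.percentile`` of the surrogate ensemble is averaged
    over frames (nearest-rank estimator) and added to the asymmetric least
    squares baseline of the observed population rate.
    """
    cfg = cfg or DetectionConfig()
    counts = np.asarray(rate.counts, dtype=float)
    if surrogate_rates.shape[1] != counts.size:
        raise ValueError("surrogate ensemble not aligned to the rate trace")
    per_frame = np.percentile(surrogate_rates, cfg.percentile, axis=0,
                              method="inverted_cdf")
    offset = float(per_frame.mean())
    baseline = asls_baseline(counts, cfg.asls_p, cfg.asls_lam, cfg.asls_iter)
    rate.baseline = baseline
    threshold = baseline + offset
    rate.threshold = threshold
    return threshold


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima with plateau handling.

    A plateau counts as a single extremum at its midpoint (ties broken
    leftward); the recording boundaries act as candidate minima so every
    interior maximum has flanking minima.
    """
    n = x.size
    if n < 3:
        return np.empty(0, dtype=int), np.asarray([0, n - 1][:n], dtype=int)
    change = np.flatnonzero(np.diff(x) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [n - 1]))
    vals = x[starts]
    maxima, minima = [], []
    for j in range(1, len(starts) - 1):
        mid = (starts[j] + ends[j]) // 2
        if vals[j - 1] < vals[j] > vals[j + 1]:
            maxima.append(mid)
        elif vals[j - 1] > vals[j] < vals[j + 1]:
            minima.append(mid)
    minima = [0] + minima + [n - 1]
    return np.asarray(maxima, dtype=int), np.unique(np.asarray(minima, dtype=int))


def detect_events(
    rate: PopulationRateTrace,
    threshold: np.ndarray,
    cfg: DetectionConfig | None = None,
) -> list[PopulationEvent]:
    """Detect population events on the smoothed rate trace.

    The rate is Savitzky-Golay smoothed; local maxima whose smoothed value
    exceeds the threshold at the peak frame are retained, and the adjacent
    local minima on either side mark event start and end (the recording
    boundary substitutes for a missing flanking minimum). Maxima sharing a
    flanking minimum merge into one event.
    """
    cfg = cfg or DetectionConfig()
    counts = np.asarray(rate.counts, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    if threshold.size != counts.size:
        raise ValueError("threshold length mismatch")
    if counts.size < cfg.sg_window:
        raise ValueError("trace shorter than the smoothing window")
    smoothed = savgol_filter(counts, cfg.sg_window, cfg.sg_order)
    rate.smoothed = smoothed
    maxima, minima = _local_extrema(smoothed)
    keep = maxima[smoothed[maxima] > threshold[maxima]]
    if keep.size == 0:
        return []
    events: list[PopulationEvent] = []
    for m in keep:
        left = minima[minima < m]
        right = minima[minima > m]
        start = int(left[-1]) if left.size else 0
        end = int(right[0]) if right.size else counts.size - 1
        if events and start <= events[-1].end:
            prev = events[-1]
            prev.end = max(prev.end, end)
            if smoothed[m] > smoothed[prev.peak]:
                prev.peak = int(m)
            continue
        events.append(PopulationEvent(start=start, end=end, peak=int(m),
                                      frame_rate=rate.frame_rate))
    return events


def event_assembly(raster: SpikeRaster, event: PopulationEvent) -> np.ndarray:
    """Binary assembly vector: neurons with >= 1 spike in [start, end]."""
    if event.start < 0 or event.end >= raster.n_frames:
        raise ValueError("event outside raster bounds")
    vec = (raster.spikes[:, event.start:event.end + 1].any(axis=1)).astype(np.uint8)
    event.assembly = vec
    return vec


def evoked_assembly(
    raster: SpikeRaster,
    protocol: StimulusProtocol,
    trial: int,
    window_ms: float = 500.0,
) -> np.ndarray | None:
    """Evoked assembly for one trial: membership over the response window.

    Counted over ``[onset, onset + window)`` regardless of whether a
    population event was detected. Returns ``None`` (absent) when not a
    single spike occurred across the population in the window.
    """
    row = protocol.trials.loc[protocol.trials["trial"] == trial]
    if row.empty:
        raise KeyError(f"trial {trial} not in protocol")
    onset = int(row["onset_frame"].iloc[0])
    window = int(round(window_ms / 1000.0 * raster.frame_rate))
    end = onset + window
    if end > raster.n_frames:
        logger.warning("trial %d window truncated at recording end", trial)
        end = raster.n_frames
    vec = raster.spikes[:, onset:end].any(axis=1).astype(np.uint8)
    if vec.sum() == 0:
        return None
    return vec


def event_stats(
    events: list[PopulationEvent],
    n_neurons: int,
    duration_s: float,
) -> dict:
    """Descriptive statistics over a list of detected events."""
    out = {"n_events": len(events),
           "rate_hz": len(events) / duration_s if duration_s > 0 else float("nan")}
    if not events:
        out.update(duration_mean_ms=float("nan"), duration_sd_ms=float("nan"),
                   size_mean_pct=float("nan"))
        return out
    durs = np.array([e.duration_ms for e in events])
    out["duration_mean_ms"] = float(durs.mean())
    out["duration_sd_ms"] = float(durs.std(ddof=1)) if durs.size > 1 else 0.0
    sizes = [e.size_pct(n_neurons) for e in events if e.assembly is not None]
    out["size_mean_pct"] = float(np.mean(sizes)) if sizes else float("nan")
    return out


def detect_population_events(
    raster: SpikeRaster,
    cfg: DetectionConfig | None = None,
    rng: np.random.Generator | None = None,
    extract_assemblies: bool = True,
) -> tuple[list[PopulationEvent], PopulationRateTrace]:
    """Full detection pass: surrogates, threshold, events, assemblies."""
    cfg = cfg or DetectionConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rate = population_rate(raster)
    surrogates = shuffle_isi(raster, cfg.n_shuffles, rng)
    threshold = detection_threshold(rate, surrogates, cfg)
    events = detect_events(rate, threshold, cfg)
    if extract_assemblies:
        for ev in events:
            event_assembly(raster, ev)
    return events, rate
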