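"""Preprocessing of two-photon calcium-imaging derived activity.

The pipeline consumes spike onset times (or binary rasters) produced by an
upstream spike-inference step; this module provides the thin preprocessing
layer around them: neuropil correction of raw fluorescence, binarization of
spike onsets into a neurons x frames raster, and construction of the
instantaneous population firing rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "SpikeRaster",
    "PopulationRateTrace",
    "neuropil_correct",
    "mean_neuropil",
    "bin_spikes",
    "population_rate",
]


@dataclass
class SpikeRaster:
    """Binary spike-onset raster.

    Attributes
    ----------
    spikes : ndarray of uint8, shape (n_neurons, n_frames)
        Entry 1 marks a spike onset of a neuron in a frame.
    frame_rate : float
        Acquisition rate in Hz; a frame spans ``[k/fs, (k+1)/fs)``.
    neuron_ids : ndarray, optional
        Labels of the rows; defaults to ``arange(n_neurons)``.
    """

    spikes: np.ndarray
    frame_rate: float
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("raster must be 2-D (neurons x frames)")
        uniq = np.unique(self.spikes)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("raster entries must be binary")
        self.spikes = self.spikes.astype(np.uint8, copy=False)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.n_neurons)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.spikes.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def onset_times(self) -> list[np.ndarray]:
        """Per-neuron spike onset times in seconds (frame left edges)."""
        return [np.flatnonzero(row) / self.frame_rate for row in self.spikes]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("spikes", data=self.spikes, compression="gzip")
            f.create_dataset("frame_rate", data=float(self.frame_rate))
            f.create_dataset("neuron_ids", data=np.asarray(self.neuron_ids))

    @classmethod
    def from_hdf5(cls, path) -> "SpikeRaster":
        with h5py.File(path, "r") as f:
            return cls(
                spikes=f["spikes"][()],
                frame_rate=float(f["frame_rate"][()]),
                neuron_ids=f["neuron_ids"][()],
            )


@dataclass
class PopulationRateTrace:
    """Per-frame count of coactive neurons and derived quantities."""

    counts: np.ndarray  # integer counts per frame
    frame_rate: float
    smoothed: np.ndarray | None = None
    baseline: np.ndarray | None = None
    threshold: np.ndarray | None = None

    @property
    def rate_hz(self) -> np.ndarray:
        """Population firing rate in Hz (coactive count x frame rate)."""
        return self.counts * self.frame_rate


def neuropil_correct(
    f_measured: np.ndarray, f_neuropil: np.ndarray, coeff: float = 0.7
) -> np.ndarray:
    """Subtract scaled neuropil contamination from measured fluorescence.

    Implements ``F_corrected(t) = F_measured(t) - coeff * F_neuropil(t)``
    with the conventional coefficient of 0.7 for GCaMP somatic ROIs.
    """
    f_measured = np.asarray(f_measured, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_measured.shape[-1] != f_neuropil.shape[-1]:
        raise ValueError(
            f"trace length mismatch: {f_measured.shape[-1]} vs {f_neuropil.shape[-1]}"
        )
    return f_measured - coeff * f_neuropil


def mean_neuropil(neuropil_traces: np.ndarray) -> np.ndarray:
    """Average per-ROI neuropil traces into a single population trace."""
    traces = np.atleast_2d(np.asarray(neuropil_traces, dtype=float))
    if traces.size == 0:
        raise ValueError("need at least one neuropil trace")
    return traces.mean(axis=0)


def bin_spikes(
    onset_times: list[np.ndarray] | list[list[float]],
    n_frames: int,
    frame_rate: float,
) -> SpikeRaster:
    """Binarize spike onset times into a neurons x frames raster.

    Frame assignment is ``floor(t * frame_rate)`` (frames are half-open
    ``[k/fs, (k+1)/fs)``). Multiple onsets falling into one frame collapse
    to a single 1: the raster is strictly binary.
    """
    spikes = np.zeros((len(onset_times), n_frames), dtype=np.uint8)
    for i, times in enumerate(onset_times):
        t = np.asarray(times, dtype=float)
        if t.size == 0:
            continue
        if (t < 0).any():
            raise ValueError(f"neuron {i}: negative spike times")
        frames = np.floor(t * frame_rate).astype(np.int64)
        if (frames >= n_frames).any():
            raise ValueError(f"neuron {i}: spike time beyond recording end")
        spikes[i, frames] = 1
    return SpikeRaster(spikes=spikes, frame_rate=frame_rate)


def population_rate(raster: SpikeRaster) -> PopulationRateTrace:
    """Sum the raster columns: number of coactive neurons per frame."""
    if raster.n_neurons == 0:
        raise ValueError("empty raster")
    counts = raster.spikes.sum(axis=0).astype(np.int64)
    return PopulationRateTrace(counts=counts, frame_rate=raster.frame_rate)
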