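"""Synthetic population rasters with embedded neuronal assemblies.

Generates binary spike rasters (neurons x frames at ~30 Hz) that carry the
statistical structure the downstream analyses assume: sparse background
spiking, recurring template assemblies producing brief synchronous population
events, and sound-evoked assemblies that are either dedicated (awake mode) or
drawn from the ongoing repertoire (anesthesia mode). Every neuron belongs to
one of three specificity classes (ongoing-preferring, evoked-preferring,
nonspecific) that modulates its participation in the two event types.

The generator is the test bed of the whole pipeline: its defaults encode the
stimulation design (50 sounds x 12 repetitions of 500-ms sounds in 300-s
blocks) and awake-like event statistics (ongoing events at ~0.42 Hz lasting
~330 ms, sound-evoked responses on about half of the trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import SpikeRaster

__all__ = [
    "StimulusProtocol",
    "SimulationConfig",
    "GroundTruth",
    "FluorescenceSet",
    "make_protocol",
    "spontaneous_protocol",
    "simulate_raster",
    "simulate_fluorescence",
    "SESSION_BLOCK_LAYOUT",
]

# Session layout: two stimulation-free 300-s blocks, three 300-s blocks with
# sound stimulation, then two more stimulation-free 300-s blocks.
SESSION_BLOCK_LAYOUT: tuple[tuple[str, float], ...] = (
    ("spont", 300.0),
    ("spont", 300.0),
    ("stim", 300.0),
    ("stim", 300.0),
    ("stim", 300.0),
    ("spont", 300.0),
    ("spont", 300.0),
)

# Neuron specificity classes (integer codes used in GroundTruth.neuron_class).
CLASS_ONGOING = 0
CLASS_EVOKED = 1
CLASS_NONSPECIFIC = 2
CLASS_NAMES = {CLASS_ONGOING: "ongoing-preferring",
               CLASS_EVOKED: "evoked-preferring",
               CLASS_NONSPECIFIC: "nonspecific"}


@dataclass
class StimulusProtocol:
    """Trial table plus block structure of a stimulation session.

    ``trials`` has columns (trial, sound_id, onset_frame, offset_frame,
    block); sound ids run 1..n_sounds, each appearing exactly ``n_reps``
    times. ``blocks`` is a list of (kind, start_frame, end_frame) with kind
    in {"spont", "stim"} and end exclusive.
    """

    trials: pd.DataFrame
    frame_rate: float
    blocks: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        onsets = self.trials["onset_frame"].to_numpy()
        if len(onsets) > 1 and not (np.diff(onsets) > 0).all():
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_sounds(self) -> int:
        return int(self.trials["sound_id"].max()) if self.n_trials else 0

    @property
    def n_frames(self) -> int:
        return self.blocks[-1][2]

    @property
    def sound_ids(self) -> np.ndarray:
        return self.trials["sound_id"].to_numpy()

    def frames_of_kind(self, kind: str) -> np.ndarray:
        """Boolean mask over frames belonging to blocks of the given kind."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for k, a, b in self.blocks:
            if k == kind:
                mask[a:b] = True
        return mask

    def to_tsv(self, path) -> None:
        self.trials.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, frame_rate: float,
                 blocks: list[tuple[str, int, int]]) -> "StimulusProtocol":
        trials = pd.read_csv(path, sep="\t")
        required = {"trial", "sound_id", "onset_frame", "offset_frame", "block"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"protocol TSV missing columns: {sorted(missing)}")
        return cls(trials=trials, frame_rate=frame_rate, blocks=blocks)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic session generator.

    Rates are per-neuron (background) or population-wide (events), durations
    in ms. ``mode`` selects whether sound-evoked templates are dedicated
    ("awake") or reuse the ongoing repertoire ("anesthesia"). ``None`` for
    ``background_rate_hz`` / ``evoked_response_fraction`` resolves to a
    mode-dependent default (awake: 0.05 Hz and 0.5; anesthesia: 0.01 Hz and
    0.75 — the anesthetized cortex is near-silent between events and recruits
    its stereotyped templates more reliably).
    """

    n_neurons: int = 1000
    frame_rate: float = 30.0
    mode: str = "awake"
    background_rate_hz: float | None = None
    event_rate_hz: float = 0.42
    event_dur_mean_ms: float = 330.0
    event_dur_sigma: float = 0.35          # log-normal shape parameter
    event_dur_range_ms: tuple[float, float] = (100.0, 1500.0)
    n_templates: int = 10
    class_fractions: tuple[float, float, float] = (1 / 6, 1 / 6, 2 / 3)
    membership_preferred: float = 0.35
    membership_nonspecific: float = 0.15
    membership_nonpreferred: float = 0.05
    # awake sound tuning: neurons come in tuning groups, each preferring a
    # small random set of sounds; evoked templates are gated by preference
    n_tuning_groups: int = 20
    sounds_per_group: tuple[int, int] = (4, 10)
    evoked_member_preferred: float = 0.9
    evoked_member_nonspecific: float = 0.5
    evoked_member_nonpreferred: float = 0.15
    # anesthetized up-state events recruit the population more broadly:
    # template inclusion probabilities are scaled up in anesthesia mode
    anesthesia_membership_scale: float = 2.0
    participation_preferred: float = 0.85
    participation_nonspecific: float = 0.45
    participation_nonpreferred: float = 0.15
    evoked_response_fraction: float | None = None
    evoked_window_ms: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("awake", "anesthesia"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        for name in ("event_rate_hz", "frame_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_rate_hz is not None and self.background_rate_hz < 0:
            raise ValueError("background_rate_hz must be >= 0")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")

    @property
    def resolved_background_rate(self) -> float:
        if self.background_rate_hz is not None:
            return self.background_rate_hz
        return 0.05 if self.mode == "awake" else 0.01

    @property
    def resolved_response_fraction(self) -> float:
        if self.evoked_response_fraction is not None:
            return self.evoked_response_fraction
        return 0.5 if self.mode == "awake" else 0.75


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must rediscover."""

    ongoing_templates: np.ndarray          # (K, n_neurons) uint8
    evoked_templates: np.ndarray           # (n_sounds, n_neurons) uint8
    neuron_class: np.ndarray               # (n_neurons,) int codes
    event_intervals: np.ndarray            # (n_events, 2) start/end frames, inclusive
    event_template: np.ndarray             # (n_events,) ongoing template index
    trial_engaged: np.ndarray              # (n_trials,) True if the trial evoked a response
    trial_template: np.ndarray             # (n_trials,) ongoing template engaged (anesthesia), -1 otherwise
    p_spont_true: np.ndarray               # (n_neurons,) expected ongoing participation
    p_evoked_true: np.ndarray              # (n_neurons,) expected evoked participation

    @property
    def p_common(self) -> np.ndarray:
        return np.minimum(self.p_spont_true, self.p_evoked_true)

    @property
    def p_spont_spec(self) -> np.ndarray:
        return self.p_spont_true - self.p_common

    @property
    def p_sound_spec(self) -> np.ndarray:
        return self.p_evoked_true - self.p_common

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "a") as f:
            if "truth" in f:
                del f["truth"]
            g = f.create_group("truth")
            for name in ("ongoing_templates", "evoked_templates", "neuron_class",
                         "event_intervals", "event_template", "trial_engaged",
                         "trial_template", "p_spont_true", "p_evoked_true"):
                g.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, path) -> "GroundTruth":
        import h5py
        with h5py.File(path, "r") as f:
            g = f["truth"]
            return cls(**{name: g[name][()] for name in (
                "ongoing_templates", "evoked_templates", "neuron_class",
                "event_intervals", "event_template", "trial_engaged",
                "trial_template", "p_spont_true", "p_evoked_true")})


@dataclass
class FluorescenceSet:
    """Raw + neuropil fluorescence traces for the correction step."""

    f_measured: np.ndarray   # (n_rois, n_frames)
    f_neuropil: np.ndarray   # (n_rois, n_frames)
    frame_rate: float
    f_corrected: np.ndarray | None = None


def make_protocol(
    n_sounds: int,
    n_reps: int,
    sound_dur_s: float = 0.5,
    isi_s: float = 1.0,
    frame_rate: float = 30.0,
    block_layout: tuple[tuple[str, float], ...] = SESSION_BLOCK_LAYOUT,
    rng: np.random.Generator | int | None = 0,
) -> StimulusProtocol:
    """Build a randomized stimulation protocol over a block layout.

    Each sound is presented ``n_reps`` times in total, spread as evenly as
    possible over the stimulation blocks; within every block the trial order
    is randomized. Successive onsets are separated by
    ``sound_dur_s + isi_s`` (offset-to-next-onset gap of ``isi_s``).

    Raises ``ValueError`` if the stimulation blocks cannot hold all trials.
    """
    if n_sounds < 2:
        raise ValueError("need at least 2 sounds")
    if n_reps < 1:
        raise ValueError("need at least 1 repetition per sound")
    if sound_dur_s <= 0 or isi_s <= 0:
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    period_s = sound_dur_s + isi_s
    sound_len = int(round(sound_dur_s * frame_rate))

    blocks: list[tuple[str, int, int]] = []
    start = 0
    for kind, dur_s in block_layout:
        n = int(round(dur_s * frame_rate))
        blocks.append((kind, start, start + n))
        start += n

    stim_blocks = [b for b in blocks if b[0] == "stim"]
    capacities = [int((b[2] - b[1]) / frame_rate // period_s) for b in stim_blocks]
    total_trials = n_sounds * n_reps
    if not stim_blocks or total_trials > sum(capacities):
        raise ValueError(
            f"block layout holds {sum(capacities)} trials, "
            f"but {total_trials} requested"
        )

    # Assign each sound's repetitions round-robin over stimulation blocks,
    # then randomize trial order inside each block.
    per_block: list[list[int]] = [[] for _ in stim_blocks]
    b = 0
    for rep in range(n_reps):
        for sound in range(1, n_sounds + 1):
            placed = False
            for _ in range(len(stim_blocks)):
                if len(per_block[b]) < capacities[b]:
                    per_block[b].append(sound)
                    placed = True
                    b = (b + 1) % len(stim_blocks)
                    break
                b = (b + 1) % len(stim_blocks)
            if not placed:  # pragma: no cover - guarded by capacity check
                raise ValueError("block layout too short to fit all trials")

    rows = []
    trial = 0
    for (kind, bstart, bend), sounds in zip(stim_blocks, per_block):
        order = rng.permutation(np.asarray(sounds, dtype=int))
        for j, sound in enumerate(order):
            onset = bstart + int(np.floor(j * period_s * frame_rate))
            rows.append((trial, int(sound), onset, onset + sound_len,
                         blocks.index((kind, bstart, bend))))
            trial += 1
    trials = pd.DataFrame(
        rows, columns=["trial", "sound_id", "onset_frame", "offset_frame", "block"]
    )
    return StimulusProtocol(trials=trials, frame_rate=frame_rate, blocks=blocks)


def spontaneous_protocol(duration_s: float, frame_rate: float = 30.0) -> StimulusProtocol:
    """A trial-less protocol: one stimulation-free block (for calibration runs)."""
    n = int(round(duration_s * frame_rate))
    trials = pd.DataFrame(
        columns=["trial", "sound_id", "onset_frame", "offset_frame", "block"]
    ).astype(int)
    return StimulusProtocol(trials=trials, frame_rate=frame_rate,
                            blocks=[("spont", 0, n)])


def _membership_probs(cfg: SimulationConfig, template_kind: str) -> np.ndarray:
    """Per-class template inclusion probability for one template kind."""
    p = np.empty(3)
    p[CLASS_NONSPECIFIC] = cfg.membership_nonspecific
    if template_kind == "ongoing":
        p[CLASS_ONGOING] = cfg.membership_preferred
        p[CLASS_EVOKED] = cfg.membership_nonpreferred
    else:
        p[CLASS_EVOKED] = cfg.membership_preferred
        p[CLASS_ONGOING] = cfg.membership_nonpreferred
    if cfg.mode == "anesthesia":
        p = np.minimum(p * cfg.anesthesia_membership_scale, 0.95)
    return p


def _participation_probs(cfg: SimulationConfig, event_kind: str) -> np.ndarray:
    """Per-class firing probability given template membership, by event kind."""
    p = np.empty(3)
    p[CLASS_NONSPECIFIC] = cfg.participation_nonspecific
    if event_kind == "ongoing":
        p[CLASS_ONGOING] = cfg.participation_preferred
        p[CLASS_EVOKED] = cfg.participation_nonpreferred
    else:
        p[CLASS_EVOKED] = cfg.participation_preferred
        p[CLASS_ONGOING] = cfg.participation_nonpreferred
    return p


def _draw_evoked_templates_awake(
    cfg: SimulationConfig, n_sounds: int, classes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-sound evoked templates structured by neuron tuning groups.

    Every neuron belongs to one tuning group; each group prefers a random
    subset of sounds (narrow tuning). The template for a sound gates on
    group preference, then includes gated neurons with a class-dependent
    membership probability — so awake sound responses are sparse, dedicated
    and shared within tuning families, independent of the ongoing templates.
    """
    member_p = np.empty(3)
    member_p[CLASS_EVOKED] = cfg.evoked_member_preferred
    member_p[CLASS_NONSPECIFIC] = cfg.evoked_member_nonspecific
    member_p[CLASS_ONGOING] = cfg.evoked_member_nonpreferred
    groups = rng.integers(0, cfg.n_tuning_groups, size=cfg.n_neurons)
    lo, hi = cfg.sounds_per_group
    prefers = np.zeros((cfg.n_tuning_groups, n_sounds), dtype=bool)
    for g in range(cfg.n_tuning_groups):
        size = min(int(rng.integers(lo, hi + 1)), n_sounds)
        prefers[g, rng.choice(n_sounds, size=size, replace=False)] = True
    gate = prefers[groups].T                      # (n_sounds, n_neurons)
    coins = rng.random((n_sounds, cfg.n_neurons)) < member_p[classes]
    return (gate & coins).astype(np.uint8)


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_neurons
    counts = [int(round(f * n)) for f in cfg.class_fractions[:2]]
    counts.append(n - sum(counts))
    classes = np.repeat([CLASS_ONGOING, CLASS_EVOKED, CLASS_NONSPECIFIC], counts)
    return rng.permutation(classes)


def _draw_templates(cfg: SimulationConfig, n_templates: int, kind: str,
                    classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    incl = _membership_probs(cfg, kind)[classes]
    return (rng.random((n_templates, cfg.n_neurons)) < incl).astype(np.uint8)


def _draw_durations(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal event durations (seconds), clipped to the configured range."""
    sigma = cfg.event_dur_sigma
    mu = np.log(cfg.event_dur_mean_ms / 1000.0) - sigma ** 2 / 2
    durs = rng.lognormal(mu, sigma, size=n)
    lo, hi = cfg.event_dur_range_ms
    return np.clip(durs, lo / 1000.0, hi / 1000.0)


def _event_times(cfg: SimulationConfig, duration_s: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Hard-core renewal process: event onsets and durations (seconds).

    Inter-onset gaps are event duration plus an exponential waiting time whose
    mean is adjusted so the overall event rate matches ``event_rate_hz``.
    """
    if cfg.event_rate_hz <= 0:
        return np.empty(0), np.empty(0)
    mean_period = 1.0 / cfg.event_rate_hz
    mean_dur = cfg.event_dur_mean_ms / 1000.0
    mean_gap = max(mean_period - mean_dur, 0.05)
    onsets, durs = [], []
    t = rng.exponential(mean_gap)
    while True:
        d = float(_draw_durations(cfg, 1, rng)[0])
        if t + d >= duration_s:
            break
        onsets.append(t)
        durs.append(d)
        t += d + rng.exponential(mean_gap)
    return np.asarray(onsets), np.asarray(durs)


def _place_event_spikes(spikes: np.ndarray, members: np.ndarray,
                        fire_prob: np.ndarray, start: int, end: int,
                        rng: np.random.Generator) -> None:
    """One spike per participating member, clustered around the event peak."""
    active = np.flatnonzero(members & (rng.random(members.shape) < fire_prob))
    if active.size == 0:
        return
    width = end - start + 1
    center = start + (width - 1) / 2.0
    frames = np.rint(rng.normal(center, max(width / 5.0, 0.6), size=active.size))
    frames = np.clip(frames, start, end).astype(np.int64)
    spikes[active, frames] = 1


def simulate_raster(
    cfg: SimulationConfig,
    protocol: StimulusProtocol,
    rng: np.random.Generator | None = None,
) -> tuple[SpikeRaster, GroundTruth]:
    """Simulate a full session: background + ongoing events + sound responses.

    Ongoing events occur throughout the recording at ``event_rate_hz``; each
    activates one ongoing template whose members fire with class-dependent
    probability, with spikes clustered around the event peak. During sound
    trials an evoked template is activated within the 500-ms response window:
    in awake mode a dedicated per-sound template on a fraction of trials
    (silent failures otherwise); in anesthesia mode an ongoing template — the
    sound's associated one on ``resolved_response_fraction`` of trials and a
    random one otherwise (the anesthetized cortex answers with stereotyped
    events from its spontaneous repertoire rather than with silence).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if protocol.frame_rate != cfg.frame_rate:
        raise ValueError("protocol and config frame rates differ")
    n_frames = protocol.n_frames
    n = cfg.n_neurons
    fr = cfg.frame_rate
    window = int(round(cfg.evoked_window_ms / 1000.0 * fr))
    if protocol.n_trials and protocol.trials["onset_frame"].max() + window > n_frames:
        raise ValueError("evoked window of final trial exceeds the frame budget")

    classes = _assign_classes(cfg, rng)
    ongoing_templates = _draw_templates(cfg, cfg.n_templates, "ongoing", classes, rng)

    n_sounds = protocol.n_sounds
    if cfg.mode == "awake":
        evoked_templates = _draw_evoked_templates_awake(cfg, n_sounds, classes, rng)
        sound_to_ongoing = np.full(n_sounds, -1, dtype=int)
    else:
        sound_to_ongoing = rng.integers(0, cfg.n_templates, size=n_sounds)
        evoked_templates = ongoing_templates[sound_to_ongoing].copy()

    spikes = np.zeros((n, n_frames), dtype=np.uint8)

    # Background: independent Poisson spiking, binarized per frame.
    bg = cfg.resolved_background_rate
    if bg > 0:
        p_frame = 1.0 - np.exp(-bg / fr)
        spikes |= (rng.random((n, n_frames)) < p_frame).astype(np.uint8)

    # Ongoing population events.
    onsets_s, durs_s = _event_times(cfg, n_frames / fr, rng)
    part_ongoing = _participation_probs(cfg, "ongoing")[classes]
    intervals, event_template = [], []
    for t0, d in zip(onsets_s, durs_s):
        start = int(np.floor(t0 * fr))
        end = min(int(np.floor((t0 + d) * fr)), n_frames - 1)
        k = int(rng.integers(cfg.n_templates))
        _place_event_spikes(spikes, ongoing_templates[k].astype(bool),
                            part_ongoing, start, end, rng)
        intervals.append((start, end))
        event_template.append(k)

    # Sound-evoked responses.
    resp_frac = cfg.resolved_response_fraction
    evoked_kind = "evoked" if cfg.mode == "awake" else "ongoing"
    part_evoked = _participation_probs(cfg, evoked_kind)[classes]
    n_trials = protocol.n_trials
    trial_engaged = np.zeros(n_trials, dtype=bool)
    trial_template = np.full(n_trials, -1, dtype=int)
    for idx, row in enumerate(protocol.trials.itertuples(index=False)):
        onset = int(row.onset_frame)
        end = min(onset + window - 1, n_frames - 1)
        sound = int(row.sound_id) - 1
        engaged = rng.random() < resp_frac
        trial_engaged[idx] = engaged
        if engaged:
            template = evoked_templates[sound]
            trial_template[idx] = sound_to_ongoing[sound]
        elif cfg.mode == "anesthesia":
            k = int(rng.integers(cfg.n_templates))
            template = ongoing_templates[k]
            trial_template[idx] = k
        else:
            continue  # awake failure: background only
        _place_event_spikes(spikes, template.astype(bool), part_evoked,
                            onset, end, rng)

    # Expected participation probabilities (class- and template-realized).
    mean_membership_ong = ongoing_templates.mean(axis=0)
    p_spont_true = mean_membership_ong * part_ongoing
    if n_sounds:
        p_evoked_true = (evoked_templates.mean(axis=0) * part_evoked
                         * resp_frac)
        if cfg.mode == "anesthesia":
            p_evoked_true = p_evoked_true + (1 - resp_frac) * mean_membership_ong * part_evoked
    else:
        p_evoked_true = np.zeros(n)

    truth = GroundTruth(
        ongoing_templates=ongoing_templates,
        evoked_templates=evoked_templates,
        neuron_class=classes,
        event_intervals=np.asarray(intervals, dtype=int).reshape(-1, 2),
        event_template=np.asarray(event_template, dtype=int),
        trial_engaged=trial_engaged,
        trial_template=trial_template,
        p_spont_true=p_spont_true,
        p_evoked_true=p_evoked_true,
    )
    raster = SpikeRaster(spikes=spikes, frame_rate=fr)
    return raster, truth


def simulate_fluorescence(
    raster: SpikeRaster,
    tau_s: float = 1.7,
    amplitude: float = 1.0,
    neuropil_trace: np.ndarray | None = None,
    noise_sd: float = 0.0,
    neuropil_coeff: float = 0.7,
    rng: np.random.Generator | int | None = 0,
) -> FluorescenceSet:
    """Forward model of somatic fluorescence from a spike raster.

    Each spike contributes an exponential calcium transient with decay time
    ``tau_s`` (default 1.7 s, typical of GCaMP6s) and peak ``amplitude``; the
    measured trace adds ``neuropil_coeff`` times a shared neuropil trace plus
    Gaussian noise. The inverse of this model is
    :func:`popassembly.preprocess.neuropil_correct`.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fr = raster.frame_rate
    n_frames = raster.n_frames
    kernel_len = min(n_frames, max(1, int(np.ceil(8 * tau_s * fr))))
    kernel = amplitude * np.exp(-np.arange(kernel_len) / (tau_s * fr))
    somatic = np.apply_along_axis(
        lambda row: np.convolve(row, kernel)[:n_frames], 1,
        raster.spikes.astype(float),
    )
    if neuropil_trace is None:
        neuropil_trace = np.zeros(n_frames)
    neuropil_trace = np.asarray(neuropil_trace, dtype=float)
    if neuropil_trace.shape[0] != n_frames:
        raise ValueError("neuropil trace length mismatch")
    f_neuropil = np.broadcast_to(neuropil_trace, somatic.shape).copy()
    f_measured = somatic + neuropil_coeff * f_neuropil
    if noise_sd > 0:
        f_measured = f_measured + rng.normal(0.0, noise_sd, size=somatic.shape)
    return FluorescenceSet(f_measured=f_measured, f_neuropil=f_neuropil,
                           frame_rate=fr)
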