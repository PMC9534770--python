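# Methods

This note documents the models and procedures implemented in `popassembly`,
the choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish about real recordings.

## Input model

The substrate of every analysis is a binary spike-onset raster
(neurons × frames, default 30 Hz; frames are half-open intervals
`[k/fs, (k+1)/fs)`, onsets assigned by `floor(t·fs)`). Spike inference from
fluorescence is an interface boundary: the pipeline consumes onset times or
rasters produced upstream. The only fluorescence-level step included is
neuropil correction, `F_corrected = F_measured − 0.7·F_neuropil`, with the
coefficient exposed as a parameter; `synthetic.simulate_fluorescence`
provides the matching forward model (exponential transients, default decay
1.7 s typical of GCaMP6s) used to test the correction round-trip.

## Population-event detection

1. **Surrogates.** Each neuron's inter-spike intervals are permuted
   independently, 100 times (`DetectionConfig.n_shuffles`). The latency from
   recording start to the first spike is included in the permuted multiset,
   so surrogate spikes stay within `[0, last spike frame]` and per-neuron
   spike counts are conserved exactly. Edge handling is a design choice; the
   alternative (cyclic wrap) changes nothing detectable at these rates.
2. **Threshold.** Per frame, the 99th percentile (nearest-rank estimator;
   with 100 surrogates, the 99th order statistic) of the surrogate
   population rates; its across-frame mean is added to an asymmetric least
   squares baseline of the observed rate (Whittaker smoother with asymmetric
   weights, p = 0.01, λ = 1e8, ≤ 10 reweighting iterations, weight-change
   tolerance 1e−6, solved on the sparse pentadiagonal system). The baseline
   is fitted on the raw, unsmoothed population rate.
3. **Events.** The rate is Savitzky–Golay smoothed (order 3, window 7).
   Local extrema use strict neighbor comparison with plateaus collapsed to
   their midpoint (ties leftward). Supra-threshold maxima are kept
   (smoothed value > threshold at the peak frame); flanking minima mark
   start/end, the recording boundary substituting for a missing minimum;
   maxima sharing a flanking minimum merge into one event. Boundary frames
   are inclusive when extracting the event's assembly (any spike ⇒ member).

Note that event boundaries at flanking minima systematically extend beyond
the frames in which member spikes are concentrated, so detected durations
(~440–520 ms on the synthetic sessions) exceed the generator's nominal
330 ms mean; rates and assemblies are unaffected.

Evoked responses are counted in a 500-ms window from sound onset on every
trial, whether or not an event was detected; a trial is "absent" only when
not a single spike occurred population-wide in the window.

## Assembly statistics

Pearson correlation between binary population vectors is the similarity
metric throughout (point-biserial form; constant vectors are excluded with a
logged warning). Ongoing assemblies are clustered per segment (pre- and
post-stimulation separately) by complete-linkage hierarchical clustering on
1 − r, cut at a granularity defaulting to `n_sounds / 2` (the statistics are
robust over a wide granularity range; the default sits near the response
dimensionality ceiling imposed by the stimulus set size). Only clusters with
≥ 2 members can win the similarity maximum, so the winner's within-cluster
reproducibility is always defined. The shuffle control permutes neuron
identities independently within each evoked vector — it preserves assembly
sizes while destroying identity alignment; no canonical definition of
this null exists, and this is one defensible choice. PCA state-space embeddings are computed on the pooled,
centered (unscaled) vectors.

## Decoder

Leave-one-out template matching: each held-out trial vector is assigned to
the sound whose remaining trials have the smallest mean correlation distance
(1 − r). Ties break to the lowest sound id. Absent trials are skipped;
sounds with no usable trial are excluded and logged.

## Tuning

Response profiles are per-(neuron, sound) counts of trials with ≥ 1 spike in
the response window. Neuron clustering mirrors assembly clustering (complete
linkage, correlation distance). Response significance per cluster compares,
for each sound, the members' observed counts with surrogate counts obtained
by redistributing each neuron's total responses over all stimulation
instances (default: the session's actual `n_sounds × n_reps`) and drawing
`n_reps` instances; a one-way ANOVA over the per-sound groups plus the
surrogate group is followed by Tukey's multiple-comparison test against the
surrogate group. Lifetime sparseness is the Pearson (non-excess) kurtosis of
the response values across sounds (uniform → 1.8, Gaussian → 3, a single
large response among ~50 → of order the number of sounds). The
awake-vs-anesthesia profile distance defaults to 1 − r between mean
profiles, with a Euclidean alternative behind a flag, since no standard
definition exists for this quantity. The axonal-terminal filter keeps units
with total response count ≥ 2 by default ("responded at least twice" read as
a total; a per-sound reading is available via `per_sound=True`).

## Specificity

`p_spont` is the fraction of detected spontaneous events containing the
neuron; `p_evoked` the fraction of all sound trials with ≥ 1 spike in the
window. Classes are cut at mean ± 1 m.a.d. (mean absolute deviation — robust
to the heavy-tailed difference distribution) of `p_spont − p_evoked`;
boundary-equal values go to the specific side (the nonspecific band is the
strict interior). The regression statistic is the mean absolute *vertical*
residual of `p_spont` regressed on `p_evoked` (a perpendicular-distance
option exists). Bootstrap comparisons resample both samples with replacement
(default 1,000 draws) and report a two-sided p with the +1 floor, so the
smallest attainable p is 2/(n_boot + 1).

Surrogate models, at a default population of 6,310 neurons:

- **independent** — both probability columns permuted across neurons
  (marginals exact, coupling destroyed);
- **equal** — one true probability per neuron from a normal distribution
  (mean 0.11, s.d. 0.08) truncated to [0, 1] by rejection (the truncation
  shifts the realized mean up by ~0.013), observed pairs via binomial
  estimation noise with the session's spontaneous-event and sound-trial
  counts — how estimation noise should enter this model is
  underdetermined, so the counts are explicit parameters;
- **common + specific** — `p = p_common + specific` per column, with
  `p_common` from the density ∝ exp(−(x/k)²) on [0, 1] (k = 0.1; a
  half-normal of scale k/√2 truncated at 1) and zero-mean Gaussian specific
  terms. The default scale values v_sound = 0.85, v_spont = 0.65 are read
  as multiples of k (specific-term s.d. = v·k): read as raw probability-scale
  s.d. they exceed the entire [0, 1] range, the clipped distribution bears
  no resemblance to the tight correlated cloud the model is meant to fit,
  and clipping destroys the covariance the common term is there to provide.
  The literal reading remains available (`v_unit="absolute"`). Sums are
  clipped to [0, 1] and the clipped fraction logged.

With the default reading the diff-distribution widths order as
equal < common+specific < independent, which is the model-comparison logic
the specificity analysis rests on.

## Synthetic sessions

The generator emulates the study conditions end to end: 300-s blocks
(2 stimulation-free, 3 stimulation, 2 stimulation-free), 50 sounds ×
12 repetitions of 500-ms sounds with 1-s offsets-to-onset gaps, randomized
within blocks; ongoing events as a hard-core renewal process at 0.42 Hz with
log-normal durations (mean 330 ms, clipped to [100 ms, 1.5 s]); K = 10
ongoing templates with class-dependent inclusion probabilities
(ongoing-preferring 0.35, nonspecific 0.15, evoked-preferring 0.05);
participation per event drawn per member (preferred class 0.85, nonspecific
0.45, non-preferred 0.15), spikes clustered around the event peak; neuron
classes at fractions 1/6 : 1/6 : 2/3.

Awake mode: sound-evoked templates are dedicated and organized in tuning
families — each neuron belongs to one of 20 tuning groups, each group
preferring 4–10 of the 50 sounds — reflecting the clustered response
signatures real awake recordings show; responses occur on half of the trials
(a typical reported event probability in awake recordings), failures being background
only; background Poisson spiking at 0.05 Hz/neuron.

Anesthesia mode: evoked templates are drawn from the ongoing repertoire;
template membership probabilities are doubled (global up-state-like
recruitment, consistent with the slightly larger events reported under
anesthesia and with broader, less specific single-neuron responses); the
sound's own template is recruited on 75 % of trials and a random ongoing
template otherwise — the anesthetized cortex answers sounds with stereotyped
events from its spontaneous repertoire rather than with silence; background
drops to 0.01 Hz/neuron (near-silence between up-states).

What the synthetic bed does **not** model: calcium-indicator nonlinearity,
imaging noise and motion, spike-inference errors, arousal/face-motion drive
of awake ongoing diversity (template count is a free parameter), up/down
spectral structure, and tonotopy. Passing tests therefore establish that the
*pipeline* recovers the planted structure and contrasts under the assumed
statistics — not that real cortex has that structure.

## Problem sizes and numerics

The full-session analyses run at 1,000 neurons × 63,000 frames (35 min at
30 Hz), the scale at which the state contrast is assessed; detector
calibration and ablation analyses use 500-neuron sessions, and oracle
equivalence checks use ≤ 20 neurons × ≤ 600 frames. All randomness flows
through explicitly passed `numpy` generators — no global state; fixed seeds
reproduce every output bit-identically. Degenerate inputs (constant vectors,
empty event lists, zero-m.a.d. difference distributions, sounds with < 2
usable trials) are excluded-and-logged or flagged NaN rather than silently
propagated; errors are reserved for structurally invalid input.

## Known limitations

- Event boundaries inherit the smoothing window's blur; durations are upper
  bounds on the synchronous core.
- The instance-shuffle ANOVA compares per-neuron observed counts against
  cluster-mean surrogates; its pooled-variance assumption is conservative
  for large clusters (type-I control is verified by simulation in the test
  suite).
- `similarity_reproducibility` restricts the maximum to clusters with ≥ 2
  members; with very few detected events this can bias the winner toward
  larger clusters.
- The anesthesia-mode "misattributed response" mechanism is one way to
  realize indistinguishable evoked/ongoing patterns; real anesthetized
  recordings mix it with down-state silence in proportions the generator
  does not fit.
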