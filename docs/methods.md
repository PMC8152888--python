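# Methods

This note documents the models, conventions, and design choices behind
`meterlab`, in the spirit of a package reference: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Rhythm patterns and syncopation

The pattern space is the set of cyclic binary sequences of 12 events
(200 ms each) with 8 sounds and 4 silences. Rotations are identified
(necklace equivalence); enumeration of the 495 raw silence placements
collapses to 43 canonical patterns, each represented by its
lexicographically smallest rotation, with ids assigned in sorted order so
references are stable across runs. The count is cross-checked in the test
suite against an independent Burnside-lemma oracle.

**Metric template.** A template is an ordered set of nested pulse periods
(each divides the next, all divide the cycle). Position *p* receives an
integer weight: 0 at the downbeat, minus one per pulse level (counted from
the slowest) whose grid misses *p*. For periods {2,4,12} on the 12-event
cycle this yields `[0, −3, −2, −3, −1, −3, −2, −3, −1, −3, −2, −3]`.

**Scoring.** In the Longuet-Higgins & Lee tradition, a syncopation arises
when a silence occupies a metrically stronger position than the most recent
sound. For each silent position *r* (scanning backwards cyclically through
any run of silences to the last sounded position *n*) the pair value
*w(r) − w(n)* is formed. The default variant sums the positive pair values;
an alignment in which **no** pair is positive — the rhythm sits fully on the
beat — scores **−1** rather than 0. This convention, found in
implementations of the model, separates "locked to the template" from merely
"unsyncopated" and is what makes the published pattern taxonomy come out:
exactly one necklace attains the maximal score range 9 across the 12
template phases (`.x.x.xxx.xxx`, per-phase scores
`[8,−1,6,−1,8,−1,5,−1,8,−1,5,−1]`), and the other 42 fall into exactly 8
groups with ranges 1–8. Without the −1 convention the maximum is 8 and only
7 groups remain, and a construction target score of −1 would be
unreachable. A plain signed-sum variant (all pair values added) is
selectable via the `variant` argument throughout.

Segment-level scoring of long event windows uses the same pair rule but
linearly: template weights are tiled from the window start, and silences
before the first sound contribute no pair.

## Sequence construction

A sequence concatenates 24 pattern placements: for each syncopation-range
group from 8 down to 1, three patterns are drawn uniformly with replacement
(seeded), giving progressively weaker phase cues to the meter. For each
draw, the placement phase is the one whose syncopation score is closest to
the per-group target `(1, −1, 0, 1, 2, 3, 4, 4)` (groups 8 → 1); exact
matches are taken when the pattern's profile contains the target, otherwise
the nearest achievable score, with ties broken by a seeded uniform draw.
The 288-event core (57.6 s) is padded with two sound events at each end
(58.4 s total), which absorb onset transients and are excluded from
analysis. Each sequence uses a single RNG stream derived from its seed, so
trials are independently reproducible.

Time inversion reverses the core and re-applies the padding. Reversal
leaves the magnitude spectrum of the event-gate envelope untouched
bin-by-bin (a DFT identity, verified to 1e−9 relative tolerance across
seeds), and segment *i* of the inversion is the time reversal of segment
8−*i* of the original.

Audio rendering assigns each sound event a 200-ms 440-Hz pure tone with
10-ms linear onset/offset ramps (identical peak across events, symmetric
envelope); silences are exactly zero. Default rate 44.1 kHz; rates below
8 kHz are refused to keep the carrier well inside Nyquist.

**Segment syncopation.** The core is cut into seven 72-event windows with
50% overlap. Each window is scored linearly under the {2,4} template — the
construction meter without its slowest pulse, since constituent patterns do
not repeat — at window shifts of −2..+2 events (shifted end windows run
into the padding), and the minimum across shifts is kept, on the assumption
that listeners adopt the alignment that minimizes syncopation. Because the
construction targets dip before rising (1, −1, 0, …) and the minimum over
shifts is not reversal-symmetric, the segment scores rise across the
sequence as a strong rank trend rather than monotonically at every adjacent
pair; the alternative nestings {3,6} and {2,6} show no decreasing trend,
i.e. the sequences do not drift into a different meter.

## Frequency-tagging engine

All response modalities share one path:

1. **Segmentation** — seven 14.4-s windows, 7.2-s hop, starting at the core
   onset (0.4 s after trial onset for padded trials). Window and hop are
   rounded to integer samples; at 512 samples/s a window is 7373 samples and
   the spectral resolution is rate/window ≈ 0.06944 Hz (exactly 1/14.4 when
   the window is an integer number of samples, e.g. envelope analyses).
2. **Trial averaging** — element-wise mean in the time domain per
   (direction, segment); phase-locked activity survives, everything else
   cancels ≈ 1/√n.
3. **Spectra** — rectangular-window FFT magnitudes per channel, no zero
   padding, no detrending beyond the upstream high-pass.
4. **Noise subtraction** — at each bin, subtract the mean amplitude of the
   second neighbor on each side (k−2, k+2); boundary bins use the single
   available neighbor. The operation is linear, preserves isolated peaks,
   zeroes locally flat background, and may produce negative values (tracked
   by a flag; double application is refused).
5. **Channel averaging** — noise-subtracted spectra are averaged across
   channels before extraction, avoiding electrode selection bias.
6. **Extraction** — target frequencies are read at their exact bin when
   `f/Δf` is integral (tolerance 1e−9), otherwise as the maximum of the two
   closest bins.
7. **z-scoring** — amplitudes are standardized across the target set using
   the sample (n−1) SD; the toy vector {1,2,3} maps to {−1,0,1}. The mean z
   over the meter subset {1.25, 2.5, 5} Hz is the summary measure; it is
   invariant to overall gain by construction. A zero-variance amplitude
   vector (e.g. from silent input) raises and is surfaced as a missing cell
   by callers.

**Target set.** The default set is the union of harmonics of the 12-event
cycle rate (5/12 Hz) and the 16-event cycle rate (5/16 Hz) up to the 5-Hz
event rate: 24 distinct frequencies, 16 of which are exact-bin at 1/14.4 Hz
resolution. The set is configurable — an explicit frequency list can be
supplied wherever a `TargetFrequencySet` is built — because published work
in this paradigm has also used a 21-frequency variant of the set whose
exclusion rule is not reconstructible from the construction rule alone; all
package defaults use the reproducible 24-frequency union.

**Direction alignment.** For degraded-to-regular signals, segment order is
reversed in comparisons (and reported alongside the raw index) so that
aligned segments share identical stimulus-envelope spectra.

## Auditory periphery control

The control path asks whether early nonlinear auditory processing could
already distinguish a sequence from its inversion. The model is an
ERB-spaced gammatone filterbank (default 100 channels, 50–8000 Hz,
Glasberg–Moore ERB-rate spacing; center frequencies above Nyquist are
refused) followed by a hair-cell stage, with activations downsampled to
512 samples/s (polyphase, exact rational ratio) to match the EEG pipeline
before spectral analysis.

Two hair-cell stages are provided. The default stand-in — half-wave
rectification, square-root compression, and a divisive adaptation loop
(output divided by 1 + k × a 200-ms exponential average of itself,
k = 0.5) — is fully vectorized and processes channels in a streaming loop to
bound memory. Its adaptation constants were set by matching tone-burst
dynamics to the physiological range and to the classic transmitter-reservoir
(Meddis) model that is also included: onset/steady-state ratio ≈ 3 and
recovery on the ~200-ms timescale of the reservoir's replenishment rate.
The Meddis stage integrates the published reservoir equations (constants
A=5, B=300, g=2000, y=5.05, l=2500, r=6580, x=66.31, h=50000, M=1) sample
by sample and is selected via `PeripheryConfig(haircell="meddis")`.

The null control computes per-segment meter prominence for sequence pairs
and tests the (pair × segment) direction differences against zero at 2
standard errors. The cell-level unit of observation mirrors the mixed-model
structure used for such controls, in which the direction effect is judged
against residual variation across segments and trials; collapsing to one
mean per pair first would make the test degenerate for a deterministic
model, since any causal adaptation — including the reference model — leaves
a tiny systematic asymmetry that shrinks proportionally with its own
between-pair variability.

Analyses in the test suite render audio at 8 kHz with 100 channels spanning
50–3500 Hz, sizes chosen to keep the control meaningful while the whole
suite stays quick to run; the model accepts any rate ≥ 8 kHz and channel
layout below Nyquist.

## EEG pipeline

Continuous recordings are high-pass filtered at 0.1 Hz with a 4th-order
Butterworth applied forward-backward (zero phase; this doubles the
effective order, recorded here deliberately), with padding scaled to the
filter's multi-second impulse response so edge transients do not leak into
epochs. Epochs of 57.6 s start 0.4 s after trial onset (skipping the
padding sounds), aligned to the nearest sample without sub-sample
interpolation. Epochs are common-average referenced (≥2 channels), then
segmented and trial-averaged per direction. Artifact handling (ICA,
channel interpolation) is out of scope; `preprocess` accepts hook functions
where such steps would plug in, no-ops by default. Excluded trials drop
their direction-matched twin (same stimulus seed) so averages are always
built from matched pairs; wholly unmatched trials are excluded with a
warning. The pipeline contains no randomness.

## Tapping measures

Tap onsets are samples where the sensor signal is rising (positive first
difference), exceeds a threshold, and respects a refractory gap from the
previous detection (greedy scan). Threshold and refractory are
per-recording parameters, defaulting to 5× the median absolute amplitude
(falling back to half the maximum for silent-floor impulse trains) and
100 ms.

Three measures with deliberately complementary sensitivity:

* **Meter match** — minimum percent difference between the median inter-tap
  interval and the pulse periods of each candidate meter ({2,4}: 200/400/800
  ms; {2,6}: 200/400/1200 ms; {3,6}: 200/600/1200 ms). Percent differences
  use the candidate period as denominator (500 ms → 25% from the 400-ms
  pulse).
* **ITI-error** — within each analysis window, intervals longer than 2 s
  are treated as pauses and removed; the meter period closest to the median
  ITI is the chosen pulse, and the error is the mean percent deviation of
  individual ITIs from it. Invariant to a global time shift of all onsets
  (phase-robust), inflated by period switches; windows with fewer than two
  taps report a missing value.
* **Tapping spectrum** — the continuous sensor signal routed through the
  frequency-tagging engine (trial averaging in the time domain by default;
  period switches among meter pulses keep energy at meter-related
  frequencies, so the spectral measure is period-robust but phase-sensitive
  — the mirror image of ITI-error).

## Synthetic data generator

The EEG generator emulates exactly the structure frequency tagging assumes:
a deterministic sum of cosines at the 24 target frequencies whose phases
are drawn once per virtual participant and reused across trials (so
time-domain averaging preserves the locked component), mixed into 4
channels with a fixed profile `(1.0, 0.6, −0.4, −0.8)`, plus independent
1/f^α background noise per channel and trial (α = 1, RMS 20 — roughly µV-
scale broadband EEG against sub-µV steady-state components). Meter-subset
amplitudes follow a per-segment profile `(1.2 … 0.6)` declining with
degradation for regular-to-degraded sequences and mirrored for the
inversion; meter-unrelated frequencies sit at a constant 0.3. The profile
keeps meter amplitudes above the unrelated floor even in the most degraded
segment — meter prominence declines but does not vanish, as in steady-state
recordings — which also keeps the z-score denominator well conditioned
(amplitude envelopes are interpolated piecewise-linearly between segment
centers, so they cross-fade smoothly at boundaries).

The **context gain** γ multiplies meter-subset amplitudes in chosen
(direction, segment) cells. γ = 1 reproduces a null world in which the two
directions differ only in time order; the injected effect is multiplicative
precisely because the downstream measure is gain-free, making recovery a
nontrivial end-to-end check. Because analysis windows overlap by 50%, a
gain confined to one segment's time span necessarily bleeds at reduced
strength into the two adjacent windows; recovery is therefore assessed at
the flagged segment against the non-adjacent ones. Default cohort size
mirrors a realistic study arm: 16 virtual participants × 15 trials per
direction.

The tapping generator emits one brief raised-cosine pulse (30 ms) per tap
at a base meter period with Gaussian motor jitter (SD 10 ms), and at each
7.2-s analysis boundary may reset phase (uniform within one period) and/or
switch to another pulse period of the induced meter; individual taps may be
missed. These are precisely the failure modes the ITI-error / spectral
dissociation is designed to separate, and the generator reproduces that
dissociation: universal phase resets leave ITI-error low while depressing
spectral meter prominence; universal period switches do the opposite.

What the generator does **not** emulate: volume conduction and realistic
topographies, alpha and other structured rhythms beyond 1/f, nonstationary
artifacts, cognitive strategy differences between musicians and
nonmusicians. Passing recovery tests therefore shows the *pipeline*
faithfully measures what it claims under its own assumptions — not that
real EEG satisfies those assumptions.

## Numerical conventions and degenerate inputs

* Indices are 0-based internally; user-facing tables number segments 1–7.
  Times in seconds, frequencies in Hz, pulse periods in milliseconds.
* Sample-rounding: window/hop/epoch boundaries round to the nearest sample;
  no sub-sample interpolation anywhere.
* All stochastic steps (pattern draws, tie-breaks, synthetic noise) flow
  from explicit integer seeds through `numpy` generators; identical seeds
  give bit-identical outputs, including rendered audio and output tables.
* Degenerate inputs fail loudly and early: non-dividing or non-nested
  template periods, phase out of range, signals too short to segment,
  double noise subtraction, zero-variance z-scoring, frequencies above
  Nyquist, single-channel common-average, sub-8-kHz audio rendering.
* Resampling of periphery activations can ring slightly negative; outputs
  are clipped at zero to honor the non-negativity contract.

## Known limitations

* The 21-frequency variant of the target set is supported only via an
  explicit list; the package cannot derive it from a rule.
* The linear-phase (filtfilt) high-pass and the simplified hair-cell
  stand-in are pragmatic choices; both are swappable (filter parameters,
  `haircell="meddis"`).
* EDF files are read (via `mne`) but not written; synthetic cohorts are
  stored as columnar text.
* The statistics stop at descriptive per-cell summaries and direction
  differences; inferential modeling (mixed models, Bayes factors) is out of
  scope.
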