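# Methods

## Problem and signals

Detecting the onset of the pharyngeal swallowing phase in real time enables
closed-loop interventions (e.g. triggered electrical stimulation) in
dysphagia therapy. Two neck-surface signals carry complementary evidence:

* **Bioimpedance (BI)**, the magnitude of the electrical transfer impedance
  across the larynx, sampled at 4000 Hz in ohm. Laryngeal elevation during
  the pharyngeal phase produces a characteristic *valley*: a small positive
  bump, a fast descent, a minimum, and a recovery.
* **Surface EMG** of the submental/laryngeal muscles (arbitrary units,
  4000 Hz). Muscle activity typically begins about half a second before the
  pharyngeal phase, so EMG is early but unspecific — speech and chewing look
  the same.

The package implements two causal detectors over these signals plus the full
evaluation machinery. Everything is strictly causal (no zero-phase
filtering): the detectors must be deployable online.

## Preprocessing

All filters are Butterworth IIR, applied with `scipy.signal.lfilter` and
first-sample-hold state initialisation, so a constant input produces its
steady-state output from sample 0 and no start-up transient can masquerade
as an onset.

| Stage | Filter | Rates |
|---|---|---|
| BI | 3rd-order low-pass, 15 Hz | 4000 → 100 Hz |
| EMG clean | despike → 3rd-order high-pass 30 Hz → notches 50/150/250 Hz (Q=30) → optional whitening → high-pass 30 Hz → 2nd-order low-pass 300 Hz | 4000 Hz |
| tEMG (trend) | 3rd-order low-pass 10 Hz on the *raw* EMG | 4000 → 1000 Hz |
| eEMG (envelope) | decimate clean EMG, rectify, 3rd-order low-pass 10 Hz | 1000 Hz |

The BI low-pass has a maximum group delay of 0.029 s over 0–100 Hz, within
the 0.03 s budget that keeps the whole chain real-time capable. Decimation is
keep-every-k after the band-limiting low-pass. The notch set targets the odd
mains harmonics (50/150/250 Hz) that dominate power-line interference.
Despiking is a Hampel detector over a trailing 11-sample window (5 scaled
MADs, replacement by the window median); the window trails rather than
centers so the stage stays causal. The whitening stage accepts arbitrary
rational-transfer-function coefficients and defaults to the identity — a
deployment can drop in electrode-specific coefficients without touching the
surrounding band-limits.

## EMG-only detector

The envelope eEMG is compared against a threshold `θ_EMG = θ0·σ0`, where σ0
is an adaptive estimate of the rest-noise standard deviation: the running
minimum of a sliding-window SD (window `Nσ = 250` samples at 1000 Hz,
shift 1). An onset fires at sample `n` when all `w` envelope samples up to
and including `n` exceed the threshold; detection is disabled during the
first `max(w, Nσ)` warm-up samples, and after an onset it re-arms only when
at least 1.0 s has elapsed *and* the envelope has dipped below the threshold
once. σ0 is floored at 1e−12 so a silent channel cannot yield a zero
threshold.

`(θ0, w)` are tuned by exhaustive grid search — θ0 ∈ {1.0, 1.5, …, 7.0},
w ∈ {50, 75, …, 300} samples — maximising pooled F1 subject to the pooled
mean delay staying below `θ_μd` (default 0.05 s; negative delays, i.e. early
triggers on the premonitory EMG, satisfy the bound). If no cell satisfies
the bound the smallest-delay cell is returned flagged. F1 is computed from
confusion counts pooled over the training recordings, not averaged per
recording.

Sample-level true negatives for this detector are
`TN = M − N_skip − N_start − FN − FP − TP`, where `M` is the envelope length,
`N_skip` the disabled samples and `N_start` the warm-up; each counted event
occupies one sample in this accounting.

## BI preselection

A three-sample streaming automaton over the 100 Hz BI: it registers a local
maximum when `BI[m−2] < BI[m−1] > BI[m]` (strict; exact plateaus never
register, which is harmless behind the 15 Hz low-pass) and fires once when
the signal has dropped more than `θ_PS = 0.18 Ω` below the registered
maximum; firing disarms the search until the next local maximum. The
reported *time of interest* is the trigger sample, not the maximum. With
typical valley depths well above 0.18 Ω and drop durations near 0.39 s, the
threshold crossing — and hence the detection delay — lands a few tens of
milliseconds after the true onset.

## Candidate labeling and scores

Candidates are matched to expert reference times by a sequential greedy rule:
references in chronological order each take the unassigned candidate with
the smallest absolute time difference if it is below `θ_LA = 0.5 s`;
equidistant ties go to the earlier candidate (deterministic, and early is
preferable for an intervention). Unmatched candidates are non-swallow
events, except that events falling in `(t_on, t_on + θ_skip]` after a
matched onset (`θ_skip = 1.0 s`) are deleted outright — a triggered
intervention would already be running. Greedy matching, not optimal
bipartite assignment, is deliberate: it mirrors how an online system
consumes detections.

Scores: sensitivity, precision, specificity and F1 from confusion counts;
preselection quality as the true-to-false ratio `Υ = It/If` and sensitivity
`S_PS = It/R`; delay mean and **population** standard deviation (divisor
`1/N`); per-subject scores summarised as median and IQR (linear-interpolation
quantiles).

## Feature vector

For each surviving candidate, 12 features are computed from trailing windows
ending at the candidate sample on BI (100 Hz), clean EMG (1000 Hz) and tEMG
(1000 Hz): window SDs, fractions of samples strictly above the value at the
candidate (reference sample excluded from the count, divisor the full window
length), maxima / argmax / argmin of sub-window SDs, the average absolute
amplitude change, and the SD difference of two consecutive EMG sub-windows
(onset steepness). All SDs use the population divisor; argmax/argmin ties
break to the smallest sub-window index. Sub-window lengths default to 0.1 s
on each channel's own rate (10 samples on BI, 100 on EMG/tEMG) with five
sub-windows; every geometry parameter is configurable per feature, and
candidates without enough history for the largest window are dropped with a
log count.

Feature relevance is the overlap `η(A,B) = ∫ min(f_A, f_B)` of the
class-conditional densities: Gaussian KDE with Silverman bandwidth per
class, integrated on a 2048-point grid spanning the pooled range ±3
bandwidths; integer-valued features (the sub-window-index features) use the
discrete mass overlap `Σ min(p_A, p_B)` instead, as does any zero-variance
sample. The per-feature window optimiser scans sub-window counts n = 2..10
and keeps the count with minimal overlap (ties to the smallest n; counts
with fewer than 10 samples in either class are excluded).

## Classifier and model selection

A scikit-learn `Pipeline(StandardScaler, RandomForestClassifier)` with 100
Gini trees, sqrt feature subsampling, bootstrap bagging, `random_state=1`.
Class weights follow the printed convention of the implemented method,

    ω0 = weight0 · If / (2I),    ω1 = weight1 · It / (2I),

i.e. proportional to each class's own frequency with a tunable multiplier
`weight1 ∈ {0.5, 1.0, …, 3.0}`. Because this direction is the opposite of
the inverse-frequency "balanced" convention, and both conventions circulate
for this method, the package also offers `weighting="inverse_frequency"`;
the proportional form is the default. The scaler is fitted on each training
split only — irrelevant to trees numerically, kept for interface fidelity.

The hyperparameter space is the Cartesian product of the `weight1` grid
(6 values) with uniform random draws of four regularisers: `ccp_alpha ∈ [0,
0.00125]`, `min_impurity_decrease ∈ [0, 0.001]`,
`min_weight_fraction_leaf ∈ [0, 0.0025]`, `max_samples ∈ [0.65, 0.85]`. The
library default is 200 random draws (L = 1200 vectors).

Selection and testing use a nested leave-one-subject-out (LOSO) procedure.
For each held-out test subject, every hyperparameter vector is scored on each
remaining subject (train on the rest), filling an F1 matrix `O` and a
complexity matrix `C` (total leaf count over the forest's trees, averaged
over inner folds for selection). The rule is a correlation-adjusted
one-standard-error rule: take the best row mean, compute its standard error
`σ_se = sd(o_best)/√folds`, shrink it per row by `√(1−ρ)` with ρ the Pearson
correlation to the best row (ρ := 0 for zero-variance rows), and among rows
whose mean lies within that margin of the best, pick the lowest mean
complexity. The winner is refit on all remaining subjects and evaluated once
on the held-out subject.

## Synthetic cohort

The generator emulates the statistical structure of clinical recordings so
the pipeline is testable end to end:

* **Swallows**: BI valley with a pre-valley bump (0.03–0.08 Ω), a descent of
  depth 0.3–1.5 Ω whose duration is Normal(0.39 s, 0.14 s) truncated to
  [0.1, 1.0] s, a total valley duration Normal(0.763 s, 0.205 s) truncated
  to [0.3, 1.5] s, and an EMG burst starting Normal(0.5 s, 0.15 s) before
  the annotated descent start. The descent is a quarter-sine — steep at
  onset, flat at the minimum — because the preselection delays observed
  clinically (tens of milliseconds at θ_PS = 0.18 Ω against a ~0.39 s drop)
  imply the threshold is crossed early in the descent; a symmetric
  raised-cosine start is too flat there to reproduce that timing.
* **Distractors**: head movements (slow raised-cosine BI dips, 0.25–0.8 Ω,
  no EMG burst) and speech/chewing (EMG bursts, no BI valley), cycled per
  subject.
* **Nuisance**: mains sinusoids at 50/150/250 Hz, isolated spikes (Poisson,
  0.2 /s), slow BI drift, white BI and EMG noise. Subject-level parameters
  (baseline 400–600 Ω, EMG burst gain 4–7× the rest noise) are drawn per
  subject.

Events are spaced at least 3 s apart; every annotation coincides with its
descent start. Defaults: 10 subjects, 6 swallows + 6 distractors each,
seeded.

**What passing on this cohort does and does not show.** The generator
reproduces event morphology, timing statistics and interference — not
electrode drift, swallow-to-swallow shape variability of real patients, or
distractors that combine BI dips *with* EMG bursts (head turns while
speaking). Synthetic distractors are therefore more separable than clinical
ones: end-to-end scores here validate the machinery and the expected
*ordering* (BI/EMG above EMG-only, near-exhaustive preselection, small
positive preselection delay), not clinical performance levels.

## Problem sizes and numerical choices

* The desk-scale experiments use 10 synthetic subjects and 8 random
  hyperparameter draws (L = 48 vectors), so the nested LOSO —
  L·(S−1)·S ≈ 4300 forest fits — completes in minutes on one core; the
  library defaults keep the full 200-draw space for larger runs.
* Determinism: all randomness flows from explicit seeds (cohort seed,
  hyperparameter-sampling seed, forest `random_state`); reports serialise
  with sorted keys and are byte-reproducible.
* Degenerate cases: empty delay vectors and 0/0 scores raise or propagate
  NaN rather than silently reporting 0 (except TP = 0 with FP+FN > 0, which
  scores 0); negative TN accounting raises; subjects lacking a class are
  skipped (logged) in nested LOSO.

## Known limitations

* The proportional class-weight convention vs. inverse-frequency ambiguity
  is resolved by a config switch, not by data.
* The whitening stage ships as identity; real deployments should supply
  device-specific coefficients.
* Per-feature window geometries are configurable defaults (0.1 s
  sub-windows, up to 1 s of history), not clinically fitted values.
* The EMG-only detector's sample-level TN accounting treats each event as
  one sample, so specificity is dominated by the recording length; it is
  reported for completeness, and F1 is the score to compare methods on.
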