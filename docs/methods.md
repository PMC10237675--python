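# Methods

## Problem and model

`pulsecap` estimates how much information a pulsatile signaling pathway
transmits per unit time. A cell population is stimulated with a random
train of short light pulses S (on a 1-minute grid) and each cell's
response is read out as a kinase-translocation-reporter (KTR) time
series. The transmitted information rate ("bitrate") is

    i(S, R) = [H(S) − H(S|R)] / Δt = h(S) − h(S|R),

reported in bit/h. The input entropy rate h(S) is known exactly from the
stimulation protocol; the conditional entropy H(S|R) — the information
lost in transmission — is estimated from data. Maximizing the bitrate
over protocols gives a lower bound on the pathway's channel capacity.

### Protocols and input entropy rates

* **Binary encoding.** Equiprobable 0/1 digits in 19 slots spaced
  τ_clock apart; the fixed slot pattern `1011010011110000101` is a
  de Bruijn-type sequence containing every 4-digit word exactly once, and
  experiments pair it with its logic negation so both halves of each
  local context are sampled. Entropy rate: h = 1/τ_clock bit/min.
* **Interval encoding.** Inter-pulse intervals geometric with mean
  τ_geom (rate p = 1/τ_geom), the maximum-entropy discrete renewal
  process; a technical 2-min gap avoids reconstruction ambiguity.
* **Interval encoding with a minimal gap.** A fixed τ_gap is added to
  each geometric draw. Entropy rate:

      h = [τ·log2 τ − (τ−1)·log2(τ−1)] / (τ + τ_gap),  τ = τ_geom,

  i.e. the geometric-distribution entropy per mean inter-pulse interval.
  For a given gap, `optimize_tau_geom` maximizes h over integer τ_geom in
  [1, 120] (ties toward smaller τ_geom). The grid and range are an
  implementation choice: inputs live on a 1-min grid and the relevant
  optima (τ_geom = 10 at τ_gap = 20; 8 at 15; 2 at 0) are small integers.

Realized interval sequences are drawn by quantile matching — the
n = ⌊budget/(τ_geom+τ_gap)⌋ intervals sit at geometric quantiles
(i−½)/n, shifted by τ_gap — and then shuffled with the run seed, so a
single finite experiment reflects the nominal interval distribution as
closely as possible.

## Synthetic data generator

The generator emulates the measured response phenomenology so the whole
analysis chain can be exercised without microscopy data:

* **Response kernel.** Unimodal curve over minutes 0–15 after a pulse:
  a Beta(2, peak/rise) CDF rise on [0, 6] whose density mode is at
  2.5 min (largest discrete increment on the 2→3-min step), then a
  raised-cosine decay with inflection at 10.5 min (largest decrement on
  the 10→11-min step), peak at 6 min, zero at both ends. The measured
  data constrain only these landmarks, not a functional form; any smooth
  curve with the same landmarks would do.
* **Refractoriness.** Each responder cell responds to each pulse
  independently with probability logistic in the preceding inter-pulse
  interval (half-interval 6.86 min, steepness 3.70 min), calibrated so
  the probability is 0.70 at 10 min and 0.90 at 15 min. Refractoriness
  acts on whether a response occurs, not on kernel shape, because the
  measured quantity is a detection fraction.
* **Cell heterogeneity.** Per cell: lognormal response amplitude
  (mean 0.35 of nuclear signal, CV 0.3), a timing offset of −1/0/+1 min
  (probabilities 0.1/0.8/0.1), lognormal baseline intensity (CV 0.2),
  and with probability 0.2 a non-responder phenotype emitting baseline +
  noise only (mimicking cells with a non-functional receptor or
  reporter).
* **Observation model.** Additive i.i.d. Gaussian noise (sd 0.015 per
  minute on the translocation scale; an AR(1) option exists), a
  slow multiplicative exponential drift of the imaging-field intensity
  that also multiplies the nuclear signal (so the first normalization
  step has something to remove), and ≥120 min of pre-stimulation
  history (default 130) for the normalization burn-in.

Noise level and jitter probabilities were fixed once by matching the
reported detection phenomenology of the gap protocol — minute-exact
detections dominating, ~90% of pulses recovered within 1 min — and are
not tuned per experiment. `SimulationParams.noiseless()` switches off
every stochastic element (including refractoriness, which otherwise
never exactly reaches probability 1) for oracle runs in which the
reconstruction must be perfect.

What the generator does **not** model: spatial structure and ERK wave
propagation between cells, cell division/movement/tracking errors,
photobleaching beyond the field drift, broken tracks, and sub-minute
timing. Passing tests therefore show the *estimators* behave correctly
on data with the assumed statistical structure; they do not certify
real-data bitrates.

## Preprocessing

Two-step normalization: (1) divide nuclear intensity by the whole-image
mean at the same time point; (2) divide by the trailing 120-min mean of
the step-1 signal, inclusive of the current time point (the measurement
convention leaves inclusivity open; inclusive is chosen). The
translocation is x_t = 1 − (normalized value), so a constant signal maps
to x ≡ 0. The first 120 points of each track are burn-in and excluded.

Track selection ranks tracks by Σ_t (y_t − y_{t−1})² of the step-1
signal over the analyzed span and rejects the lowest fraction f = 0.2
(ties broken by track id). On synthetic data with 20% non-responders
this removes ≥95% of them at moderate noise.

## Input reconstruction

Slices of ℓ consecutive x-values are represented by their ℓ−1 backward
differences. A kNN classifier (k = 20, Euclidean) predicts per-slice
labels; label ties are broken toward the smaller mean neighbor distance,
then the smaller label (deterministic). Neighbor search is delegated to
scikit-learn's `NearestNeighbors`; voting and tie-breaks are implemented
here.

* **Interval mode.** Slice label = time after pulse (TAP), measured to
  the slice's last point; if that is < 3 min the previous pulse is used.
  Slices predicted TAP ∈ {3, 4, 5} vote for minute (end − TAP); minutes
  with ≥2 of their 3 possible votes become detections; detections within
  2 min after a kept detection are discarded (no two detections in any
  3-minute window).
* **Binary mode.** Three shift-specific classifiers (slices starting 2,
  1, 0 min before the slot) each predict 0/1; a slot is a pulse iff ≥2
  agree.

The decision for a candidate minute t0 uses only x on [t0−2, t0+t_D]
with t_D = 5 by default (8-min window, ℓ = 6). For other decision times
the slice length becomes t_D+1, the voting TAP set {t_D−2, t_D−1, t_D},
and the TAP fallback threshold t_D−2 — at t_D = 5 exactly the standard
rule; the generalization keeps the t_D sweep well-defined below 5.
Slots or candidate minutes whose full window falls outside the
trajectory are not scored.

## Conditional entropy and loss decomposition

Digit probabilities are pooled over time points, tracks and train/test
partitions (population-level channel). For binary protocols H(S_d|R_d)
comes from the 2×2 confusion matrix; for interval protocols
H(S_d|(R_{d−1}, R_d, R_{d+1})) comes from the contingency table of the
input digit against the three surrounding reconstruction digits, which
credits detections that are one minute early or late. Both are upper
bounds on the per-digit conditional entropy of the joint sequence, so
the bitrate is a lower bound; per-cell estimates can be negative.
Boundary digits with truncated neighborhoods are dropped (≤2 digits per
track). Logarithms are base 2 and 0·log 0 ≡ 0 throughout.

Loss decomposition: discrepancies are classified (unambiguously, since
pulses are ≥3 min apart) as false detections, missed pulses, or
inaccurate (±1 min) detections. Each type is corrected in turn —
deleting, inserting, or moving detections — recomputing the pooled table
and bitrate after each step; increments are attributed to the corrected
type and averaged over all correction orders (2 for binary, 6 for
interval). Every order ends with R ≡ S, so the contributions sum exactly
to the total loss. Intermediate states can violate the 3-min spacing, so
the table internally carries all 8 neighborhood patterns; the 4-pattern
restriction is enforced only where the de-duplication precondition
applies.

## Reconstruction-free estimator

Slices of ℓ = 8 points (the span of the three ℓ = 6 decision slices) are
labeled by whether a pulse occurred 5 min before the slice end. For each
slice, the labels of its k = 20 nearest neighbors in the 7-dimensional
difference space (itself included) give a plug-in conditional entropy
with Miller–Madow correction 1/(2k ln 2) applied when both label counts
are nonzero; H(S|R) is the average over slices. Because no classifier
intervenes, this estimate is never below the reconstruction-based one in
expectation; plug-in neighborhood entropies are also biased low at small
k, which contributes to the gap between the two estimators.

## Resampling

Reconstruction-based estimates use 10 random half/half train–test
splits (test tracks never occur in training); the point estimate pools
contingency counts over splits, and the split-wise estimates give the
dispersion. Reconstruction-free estimates use 10 random 50% subsamples.
All randomness derives from a single master seed via independent child
seed streams; a run writes no timestamps, so identical (config, seed)
yields byte-identical reports.

## Problem sizes

Closed-form checks are instantaneous. The stochastic suites use, as this
package's chosen study conditions: 200 deterministic cells over 24 h for
the perfect-channel oracle; 400 default-parameter cells for the
phenomenology checks and for the estimator-ordering comparison (10-h
stimulation span, 10 resamples); and 60–100 cells over 8–15 h for unit
and pipeline tests. The per-digit-bound check enumerates an 8-digit toy
channel exhaustively.

## Known limitations

* The per-digit bounds ignore digit dependencies (refractoriness makes
  even binary digits dependent); the estimate remains a valid lower
  bound.
* Pooling across cells treats cell-to-cell differences (fast/slow cells)
  as noise; per-cell adaptive classifiers are out of scope.
* The experimentally measured bitrates cannot be reproduced without the
  real trajectories; synthetic results characterize the estimators, not
  the pathway.
* Sequences finer than 1-min resolution, light-dose physics, and the
  optional mid-experiment resting period are not modeled (the resting
  period was reported to have no effect and is excluded from analysis
  spans by construction).
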