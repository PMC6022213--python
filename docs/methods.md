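# Methods

This note documents the models implemented in `preictal`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions that matter when reproducing results.

## Windowing and features

All stages operate on non-overlapping windows of `window_length_s`
(default 20 s; configurable 1–100 s for window-size sweeps) starting at
t = 0; a trailing remainder is discarded. Window i covers samples
[i·w, (i+1)·w).

The verbal definitions of the eight time-domain statistics leave several
normalizations open; the concrete formulas are fixed as follows (window
x₁..xₙ, differences dᵢ = xᵢ₊₁ − xᵢ):

| feature | formula | degenerate case |
|---|---|---|
| area | (1/n) Σ\|xᵢ\| | — |
| normalized decay | clip(2·(frac(dᵢ<0) − ½), −1, 1) | 0.5 fraction for n = 1 |
| line length | Σ\|dᵢ\| | — |
| mean energy | (1/n) Σxᵢ² | — |
| peak amplitude | log₁₀(mean xₚ² over peaks) | −12 when no peaks or all-zero |
| valley amplitude | as above, over valleys | −12 |
| normalized peak number | #peaks / (mean\|dᵢ\| + 10⁻¹²) | 0 |
| peak variation | std of successive extremum-to-extremum amplitude differences / window seconds | 0 if < 2 extrema |

A *peak* is a strict sign change of the derivative from negative to
positive, a *valley* the opposite (this is the convention of the source
feature set; flat runs produce neither). All outputs are finite; no NaN is
ever emitted. Under amplitude scaling x → c·x, area and line length scale
linearly, energy quadratically, and the raw peak count is invariant (the
normalized count scales as 1/c) — these are asserted as properties in the
tests.

Band powers use 2nd-order Butterworth filters (low-pass at 4 Hz for
Delta, band-pass otherwise) applied forward–backward. Zero-phase filtering
is a dialect choice: it doubles the effective order and removes phase
distortion; a causal single-pass variant would shift energy slightly
between window boundaries but not change any conclusion here. Squaring and
averaging the filtered signal gives the power (time-domain route; no FFT).
The gamma band (30–100 Hz) requires fs > 200 Hz; lower rates raise an
error naming the band.

Feature columns are channel-major (all features of channel 0, then
channel 1, …); `both` concatenates the full time-domain block before the
band-power block (128 + 80 = 208 for 16 channels).

## Base classifiers

Seven algorithms behind one `train`/`predict` interface, all with
library-default hyperparameters except the SVM (linear kernel, C = 5).
Features are standardized inside the fitted pipeline. Soft labels are the
probability of the predicted class, so v ∈ [0.5, 1]. The SVM's
probabilities come from Platt scaling — a sigmoid on the decision values
fitted by internal cross-validation (up to 5 folds, reduced when a class
has fewer samples; a singleton class is replicated once so two folds
exist, a degenerate case that only arises in tiny pools). The certainty
cutoff for "clear" samples is strict: v must exceed 0.80; v = 0.80
exactly is ambiguous. Both the cutoff and the boundary behaviour are
configurable.

Training requires both classes; callers are expected to balance training
data (1:1 random undersampling, `balance_training_set`) while validating
on the original unbalanced data.

## Bernoulli-Gaussian mixture active learner

The generative model for a window with features x ∈ R^d, hidden class
y = c ∈ {0,1}, and per-round classifier outputs u ∈ {0,1}^K (crisp),
v ∈ [0,1]^K (soft):

    p(x, y=c, u, v) = α_c N(x; μ_c, Σ_c) Π_k B(u_k; π_ck) Π_k N(v_k; λ_{c,m,k}, σ²_{c,m,k}),  m = u_k.

K is the maximum number of expert-query rounds (default 10); history
columns beyond K are frozen. Soft labels are treated as continuous in
[0, 1] (they are probabilities, modelled Gaussian per class and per crisp
value). A switch (`use_soft=False`) drops the soft-label factor entirely.

Estimation is semi-supervised EM: labelled samples keep indicator
responsibilities γ_{j,c} = I(y_j = c); unlabelled samples get the
posterior responsibility T_{j,c} normalized over c. M-step updates are the
responsibility-weighted maximum-likelihood estimates: α_c = Σ_j γ_{j,c}/N,
weighted mean/scatter for μ_c and Σ_c, the weighted crisp-indicator mean
for π_ck, and weighted soft-label moments for λ, σ². The observed-data
log-likelihood is recorded each iteration and asserted non-decreasing
(tolerance 10⁻⁸); convergence is declared when the improvement drops below
`tol` (default 10⁻⁶), and hitting `max_iter` (default 200) returns a state
flagged unconverged rather than raising.

Numerical choices:

* **Covariance mode.** Diagonal covariances by default: the feature
  dimension (128 for 16-channel `set_t`) typically exceeds the per-run
  sample count, where full covariances are singular. Full covariances are
  available (`cov_type="full"`) and used in the low-dimensional
  parameter-recovery tests.
* **Covariance floor.** Instead of adding a ridge proportional to the
  mean variance — which mixes scales across features whose variances span
  eight orders of magnitude (mean energy vs. normalized decay) and breaks
  the EM ascent property — each dimension's variance is floored at 10⁻⁸ of
  its pooled variance (full mode: eigenvalues floored at 10⁻⁸ of the mean
  pooled variance). The floor is constant within a fit, so flooring is the
  constrained M-step argmax and the likelihood trace stays monotone.
* **Bernoulli clipping.** π is clipped to [10⁻⁴, 1 − 10⁻⁴] and soft-label
  variances floored at 10⁻⁴, again as constrained maximization, preventing
  degenerate point masses when histories are unanimous.
* **Initialization.** From labelled per-class moments (proportions → α,
  moments → μ, Σ, history agreement rates → π, λ, σ); classes without
  history fall back to π = 0.5, λ = 0.5, σ² = 1/12 (the uniform-[0,1]
  moments). A 10⁻⁹-scale seeded jitter on μ breaks exact ties.
* **Selection.** Ambiguity is 1 − max_c γ_{j,c}; ties break to the lowest
  index, and a batch exceeding the candidate set returns all candidates
  ambiguity-sorted. When fewer classifier-ambiguous windows exist than the
  batch size, the whole unlabelled set is ranked instead.
* **Stopping.** Querying stops when the last `window` (default 2)
  successive changes of mean confidence are all below `tol` (default
  10⁻³) — the "confidence stays flat" criterion with an explicit,
  configurable tolerance, since none is prescribed.

Two baselines share the loop driver: `random` (passive selection) and
`uncertainty` (smallest classifier soft label).

## Alarm framework

Crisp labels accumulate over disjoint 1 h blocks (the accumulator resets
at block boundaries; a sliding accumulator is a possible variant but the
block reading matches the 180-labels-per-hour bookkeeping). The alarm
fires at the first window where the cumulative pre-ictal count reaches
`ceil(threshold · n_labels)` — 126 of 180 at the default 70 % — which
also defines the alarm time used for prediction horizons. A trailing
partial hour uses a proportionally scaled trigger count. After an
alarm-free block, the block's ambiguous windows become active-learning
candidates; the mixture is fitted on all windows seen so far (no
look-ahead), the expert is queried, and the classifier is retrained on its
original training set plus all expert-labelled windows. With a zero query
budget the run is exactly the static thresholded classifier.

Scoring: a seizure counts as predicted when at least one alarm falls in
[onset − SPH, onset), with SPH defaulting to 1 h (the pre-ictal upper
bound). Each alarm is credited to at most one (nearest) seizure; the
horizon is onset minus the earliest credited alarm. Because the alarm-rate
convention behind a single "FPR" figure is ambiguous, reports carry both
the alarm-level false fraction and FP/h (false alarms per recorded hour),
plus a flag against the 0.15 FP/h clinical-applicability bound. The
Poisson baseline issues alarms at i.i.d. exponential intervals with mean
λ_ran = mean inter-seizure duration.

## Synthetic data

The generator emulates the *structure* of chronic seizure-monitoring
data, not seizure physiology:

* per-channel AR(2) background with a resonant peak (default 6 Hz, pole
  radius 0.97) scaled to 50 µV standard deviation — a stationary stand-in
  for inter-ictal ECoG;
* pre-ictal intervals (default 60 min before each onset) carrying
  additive 10–25 Hz Hann-windowed bursts (rate 0.25 /s) and sparse
  biphasic spikes (rate 0.5 /s, ~60 ms), both with amplitude proportional
  to `effect_size`. `effect_size = 0` leaves the classes statistically
  identical; line length and mean energy of pre-ictal windows increase
  monotonically with it;
* evenly spaced lead-seizure onsets snapped to the window grid, with
  infeasible placements (overlapping pre-ictal intervals) rejected with an
  explicit error;
* a window-class imbalance set by `imbalance_ratio` (inter-ictal :
  pre-ictal), emulating ratios from ~20:1 down to 2:1. When `duration_h`
  is omitted the duration is derived so the emitted ratio is exact; an
  explicit duration takes precedence.

All randomness flows from one seeded generator per recording, so output
is bit-identical across runs. Recordings persist as plain EDF (16-bit,
1 s records, µV) plus CSV sidecars for window labels
(`window_index,start_s,end_s,label`) and seizure onsets; reading a file
with more channels than requested keeps the first n unless an explicit
channel list is given (no principled "most informative channel" selection
rule is implemented — it is configuration).

What passing tests on this data do **not** show: robustness to
non-stationary backgrounds, artefacts, electrode drift, inter-subject
variability, or realistic pre-ictal morphology. The synthetic classes
differ exactly in the statistics the features measure, so absolute
accuracies here are upper bounds with no clinical meaning; only the
*comparative* results (active vs. passive selection, framework vs.
Poisson baseline) and the arithmetic/bookkeeping checks transfer.

## Study conditions and problem sizes

The active-learning studies (`label_complexity_study`,
`noise_sensitivity_study`) use 4-channel recordings with 20-min pre-ictal
blocks at 2:1 imbalance, balanced to ~360-window pools (32-dim `set_t`
features), split 50/50 into query pool and validation set, with a 5 %
(noise study: 10 %) stratified initial labelled set and batch-5 queries up
to the target label fraction. `effect_size = 1.5` gives separable classes
with a genuinely ambiguous boundary — the regime the selector exists for.
Noise sensitivity flips each crisp label feeding the mixture with
probability η; the passive arm ignores those outputs and thus serves as
the η-independent reference the active learner should approach from above
as η grows. The end-to-end demonstration uses 60-min pre-ictal blocks
with an integer imbalance ratio so pre-ictal intervals align with hour
blocks, and `effect_size = 3` ("strong" separability). Ensemble sizes are
20 seeds in the test suite and 10 in the acceptance script.

## Known limitations

* The EDF writer emits a minimal plain-EDF subset (no annotations
  channel, 1 s records, integer sampling rates); it round-trips its own
  output and is cross-read by mne in the tests, but is not a general EDF+
  implementation.
* The mixture assumes Gaussian class-conditional features; heavy-tailed
  feature distributions (e.g. log-scale peak amplitudes with sentinel
  values) are handled in practice by the diagonal covariance but violate
  the model.
* The hourly accumulator is block-based; an alarm exactly at a block
  boundary belongs to the earlier block, and no refractory period beyond
  the block reset is applied after an alarm.
* Expert answers are assumed correct (ground truth in every simulation);
  annotator noise would require a noisy-oracle extension.
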