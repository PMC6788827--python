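# Methods

`confseek` simulates a perceptual decision study with an information-seeking
option and an EEG forward model, and implements the statistical chain used
to ask whether a post-decisional neural correlate of confidence predicts
information-seeking: event-related potential (ERP) contrasts with
cluster-based permutation inference, time-resolved single-trial regression,
and sliding-window multivariate decoding with temporal generalization.
This note documents the models, the parameters that matter, the numerical
conventions, and what the synthetic data can and cannot establish.

## Task model

Each stimulus is eight color values on the red–blue RGB path
`(C, 0, 1 − C)`; the element mean is set by `C` (0.5 = category boundary)
and the element spread by a target variance `V`.  Trials cross mean level
(boundary distance 0.050 = easy "high mean", 0.026 = hard "low mean"),
variance level (`V` = 0.0333 low, 0.1000 high) and color, with exact
per-cell balance inside every 64-trial block; 75% of trials are
free-choice (the observer may pay 1 point to see an easier version:
`C′ = C ± 0.01` away from the boundary, `V′ = V − 0.0167`), 25% are
no-choice.  Element arrays are drawn pseudo-randomly and affinely rescaled
to hit the target moments within 1e-3 (clamped to [0, 1], redrawn on
clamp violations, at most 100 iterations).  Scoring is +5 / −5 points for
correct/wrong final answers, −1 per sample, 650 points to the pound.

Between blocks a staircase compares inverse efficiency (median correct-trial
RT / p(correct)) between the low-mean/low-variance and
high-mean/high-variance cells and moves the low-mean `C` by
0.0025 / 0.0012 / 0.0005 when the absolute gap is ≥ 100 / 50 / 10,
in the direction that shrinks the gap (away from the boundary when the
low-mean cell is less efficient).  The level is clipped to a configurable
interval (default blue-side 0.400–0.499) and every update is logged; the
task description itself leaves both the bound and the direction convention
open, so both are explicit configuration here.

## Observer model

The task specifies no observer, so the simplest model producing the assumed
behavioral structure is used.  On each trial the observer draws one
Gaussian evidence sample

    e ~ Normal(C − 0.5, σ(V)),    σ(V) = sensitivity · √V ,

chooses `sign(e)`, and reports confidence through a noisy saturating map of
the evidence-to-noise ratio:

    conf = 50 · tanh( gain · |e|/σ(V) + ε ),   ε ~ Normal(0, conf_noise),

rounded to the integer scale 1..50 (the rating scale runs −50..50 with the
sign carrying the chosen color; 0 is not a legal response).  Normalizing by
σ(V) is the signal-detection reading — the observer discounts evidence from
a noisier stimulus — and is what makes confidence *fall* with element
variance the way accuracy does; a map of raw `|e|` would inflate confidence
under high variance (folded noise) and invert the variance effects.

On free-choice trials the observer seeks more information iff
`conf + participant_bias + decision_noise < seek_threshold`; on see-again
trials the final choice is `sign(e + e′)` with `e′` drawn from the easier
stimulus, and the final rating uses the combined evidence with its combined
noise level.  RTs are shifted log-normal with location decreasing in `|e|`,
snapped to the EEG sample grid so realignment between event clocks is
sample-exact; the latency from primary response to the information-seeking
confirmation is log-normal (median ≈ 770 ms).

Defaults: `sensitivity` 0.20, `gain` 0.8, `conf_noise` 0.25,
`seek_threshold` 28, between-participant bias sd 8, decision noise sd 7.
These were fixed once so the session-level statistics sit where the task
literature puts them — primary accuracy ≈ 0.80, difficulty-matched
staircase cells, a see-again rate ≈ 0.43–0.45, and a strongly negative
logistic coefficient of seeking on standardized confidence — and were not
revisited afterwards.

## EEG forward model

Thirty-two channels on a schematic 10-20 montage.  Each trial's signal is
synthesized once on a continuous timeline and cut into stimulus-locked
(−100..1000 ms), response-locked (−100..700 ms) and choice-locked
(−700..100 ms) epoch views, so the three views are exact translations of
one underlying signal (realigning one view reproduces another, which the
tests exploit as an oracle).  The signal is

    x(t) = α_P3 · topo_P3 · k_P3(t_stim) + α_Pe · topo_Pe · k_Pe(t_resp) + noise,

with unit-norm Gaussian scalp maps peaking at CPz and Gaussian temporal
kernels hard-limited to 300–600 ms post-stimulus (P3) and 250–700 ms
post-response (Pe).  Amplitudes couple to standardized confidence:

    α_P3 = α0 + a_P3 · z,        α_Pe = α0 − a_Pe · z  (+ confound · difficulty),

so higher confidence means a larger P3 and a *smaller* error positivity.
The coupling uses the z-scored pre-resampling internal confidence: the Pe
is generated right after the primary response, before any resampling, and
coupling to the final rating would erase the seeking signal on see-again
trials.  On no-choice trials — where all confidence analyses run — internal
and reported confidence coincide.  Noise is Gaussian with squared-
exponential spatial correlation over the montage (length scale 0.6) and
AR(1) temporal correlation (ρ = 0.8 at 250 Hz).

Defaults: α0 = 4 µV, a_P3 = 1.5, a_Pe = 2.0 µV per confidence z, noise sd
6 µV, 250 Hz sampling (the hardware-scale 1000 Hz is configurable).  The
SNR was chosen so a single subject's peak decoding Az is ≈ 0.65–0.7 — the
level reported for post-decisional confidence decoding in this literature —
which is what makes the group structure recoverable at the desk-scale
sample sizes below.

## Preprocessing

Baseline correction subtracts the per-trial, per-channel mean over a window
(default −100..0 ms before the alignment event).  Realignment re-cuts
epochs on another event clock from per-trial offsets that must sit on the
sample grid; a previously applied baseline is retained when requested
(pre-stimulus baseline kept after response realignment), and trials whose
new window leaves the available samples are dropped and logged, never
padded.  Artifact screening removes trials containing any |sample| ≥ 200 µV.
Confidence is z-scored per participant × block with the sample (n−1) sd;
degenerate blocks get z = 0 and a flag.  Median splits label values above/
below the sample median and assign ties alternately starting with the
smaller class, so imbalance never exceeds one.  A 10 Hz zero-phase low-pass
exists for waveform display only; every statistic runs on unfiltered data.

## ERP statistics

Condition ERPs are trial means at one electrode (CPz).  The 1-D cluster
permutation test runs a two-tailed paired t per sample, forms maximal runs
of same-sign supra-threshold samples (element p < 0.05), scores each by the
sum of |t| (cluster mass), and compares against the max-mass distribution
under random within-subject condition flips — exhaustive enumeration when
2^n ≤ 4096, otherwise seeded Monte-Carlo with p = (b+1)/(n_perm+1).
Time-resolved regression fits OLS per sample per subject predicting CPz
amplitude from mean, variance, their interaction and binarized confidence
(±0.5 codes); the per-subject t traces enter a group one-sample sign-flip
cluster test.  The group stage for regression t values is not fully pinned
down by common practice descriptions; the one-sample sign-flip reading is
the standard one and is the implemented default.

## Decoding

Features are channel means over sliding windows (106 ms wide, half-open on
the ms grid, default 10 ms steps; a width of one sample interval is the
identity).  The spatial filter is a logistic regression over channels —
implemented in-package as a damped-Newton solver with a small fixed L2
ridge (strength 1/C, default C = 1, intercept unpenalized) so the fit stays
defined on separable data; it matches a long-run reference optimizer to
1e-5 and is ~30× faster, which is what makes the permutation pipeline
tractable.  Performance is Az, the ROC area of the scalar projections (ties
count one half), computed by ranks and verified against O(n²) pair
counting.

Within-condition temporal generalization uses repeated stratified k-fold
CV: per repeat, filters are fitted per training window on k−1 folds,
held-out trials are projected at every test window, projections are pooled
over folds, scored per matrix cell, and Az is averaged over repeats.
Across-condition decoding trains on high/low confidence (no-choice trials,
correct on both decisions) and tests on see-again/respond (free-choice,
correct trials; "respond" coded as the high-confidence-like class so
transfer lands above 0.5), with train and test sets subsampled to equal
class counts on every iteration and Az averaged.  Null matrices rerun the
identical pipeline on shuffled labels and average over iterations.
Stimulus-locked training windows are capped at 400 ms post-stimulus to
avoid post-response leakage on short-RT trials (configurable).

Inference compares true and null matrices per subject with a paired t per
pixel, forms 8-connected clusters above the two-tailed element threshold
(p = 0.01), and tests max cluster mass against the sign-flip null, as in
the 1-D case.  The difficulty control regresses mean, variance and their
interaction out of every channel × time point per subject before decoding;
note that residualizing over the full set can push CV decoding of the
*removed* factor slightly below chance (regression-to-the-mean across
folds), so "removed" means no above-chance decoding, not Az ≡ 0.5.
Peak comparisons select either a matched number of pixels inside the
comparison cluster grown around its peak, or fixed squares (3×3 .. 9×9)
clipped at matrix borders, and run a two-tailed paired t on subject-mean
Az.

Randomness: one master seed fans out via `numpy.random.SeedSequence` to
design, observer, noise, folds, balancing and permutations; identical seeds
give bit-identical tables and epochs.

## Desk-scale problem sizes

The full-scale design (15 subjects × 10 blocks, 1000 Hz, 100 CV repeats,
1000 null/balance/permutation iterations) is configurable but slow; the
shipped analyses and tests run a scaled replica chosen to finish in minutes
on one CPU while keeping every statistical mechanism intact: 8 subjects ×
5 blocks × 64 trials, 250 Hz, 20 ms window steps, 5 CV repeats, 20 null and
50 balance iterations, 200 cluster permutations (sign flips over 8 subjects
enumerate exhaustively, 256 patterns).  Calibration checks use 300
simulated null datasets per test.

## What the synthetic data do and do not show

The generator reproduces the design constants, the behavioral couplings
(difficulty → accuracy/RT/confidence/seeking; confidence → seeking) and the
two confidence-coupled components with realistic spatial/temporal noise
correlations.  It does not emulate eye blinks or non-stationary artifacts
(threshold rejection replaces ICA and visual inspection), volume-conduction
physics beyond smooth scalp maps, latency jitter of the components, serial
dependencies across trials, or individual differences beyond amplitude and
bias scaling.  Passing tests therefore demonstrate that the pipeline
recovers the structure its estimators assume — correct calibration of the
permutation machinery and correct directionality of every coupling — not
that real EEG would yield the same latencies, cluster extents or p-values;
real-data results depend on the recorded data and are out of scope here.

## Known limitations

* The observer is static (no evidence accumulation); RT is a descriptive
  log-normal, not a process model.
* Confidence ratings are generated without post-decisional accumulation;
  the dissociation between matched-difficulty conditions reported in the
  source literature (lower confidence under high variance at equal
  accuracy) appears here only as equal-confidence-at-equal-d′.
* The Pe/P3 kernels are fixed-latency; temporal generalization in the
  simulation is therefore somewhat cleaner (more diagonal-plus-block) than
  in real data.
* Across-condition null matrices shuffle both train and test labels; other
  conventions (train-only shuffling) give indistinguishable chance levels
  here but are not separately exposed.
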