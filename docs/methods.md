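# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the test suite shows.

## Label space and epoching

All staging operates on 30-s epochs of 30-Hz tri-axial acceleration
(900 samples × 3 axes, gravitational units). Five-class AASM labels
(W, N1, N2, N3, R) collapse to wake/NREM/REM by merging N1–N3, and to
sleep/wake by additionally merging REM. Probabilities collapse by
summation *before* the argmax, so the full posterior mass of the merged
stages decides the collapsed call; argmax-then-collapse can differ and is
deliberately not used. Epoch intervals are half-open `[start, start+30 s)`
and timestamps are timezone-naive local time. Daylight-saving crossovers
and shift work are represented only as boolean exclusion flags in
recording metadata, mirroring how cohort pipelines exclude rather than
model them.

## Preprocessing

Raw traces are linearly interpolated onto a uniform 30-Hz grid anchored
at the first timestamp of each contiguous segment; gaps longer than 5 s
are never interpolated across — they split the recording, and each
segment is epoched separately with trailing partial epochs dropped.
Values are clipped to ±3 g. An epoch is *stationary* when the
within-epoch standard deviation of every axis is below 13 mg; maximal
stationary runs strictly longer than 60 min become non-wear. A recording
is excluded when it cannot be parsed, when its mean truncated ENMO
(`max(‖a‖₂ − 1 g, 0)`, reported in mg) over wear epochs exceeds 200 mg,
or when the median vector magnitude over stationary epochs departs from
1 g by more than 30 mg. The 200-mg rule is applied at recording level: a
per-sample bound would reject ordinary movement. Full sphere-fit
autocalibration is out of scope; the magnitude check above only flags
recordings that a calibration tool should have fixed.

## The deep stager

Each epoch is encoded by a pre-activation residual 1-D CNN: a stem
convolution, then one residual block per level (BN → ReLU → stride-2
conv → BN → ReLU → conv, with a 1×1 stride-2 projection shortcut),
then BN → ReLU → global average pooling. Because of the pooling, the
epoch feature width equals the last channel count regardless of depth.
The per-epoch features of a whole night feed one bidirectional LSTM pass
(each night is one sequence; nights are processed individually, so no
padding or masking is needed), then two fully-connected layers produce
five-class logits. Default desk-scale configuration: 4 blocks, channels
(8, 16, 24, 32, 40), kernel 9, LSTM hidden 32, FC (64, 5). A full-scale
preset (`paper_scale_config()`) uses 8 blocks — 17 convolutional layers —
with channels up to 512 and LSTM hidden 128.

Training minimises class-weighted cross-entropy (inverse-frequency
weights normalised to mean 1 over present classes; N2 dominance would
otherwise absorb the minority stages) with Adam. Within a batch of
nights, each night's graph is built and back-propagated separately and
gradients accumulate before the optimiser step, which bounds peak memory
by a single night.

The network runs on an in-repo reverse-mode autodiff engine over NumPy
arrays (float32): broadcasting arithmetic, matmul, reductions, slicing,
a strided conv1d with a hand-written vector-Jacobian product, and fused
softmax/sigmoid cross-entropy losses. Batch normalisation keeps
bias-corrected exponential moving averages of batch statistics; after
the last optimiser step the statistics are reset and recomputed in a
short refresh pass under the final weights, otherwise inference-mode
statistics lag the weights badly on small training sets. All training
randomness derives from a single seed; at a fixed BLAS thread count runs
are bit-reproducible.

### Self-supervised pretraining

The encoder can be pretrained to discriminate three window-level
transformations, each applied independently with probability 0.5:
time-reversal of all axes, permutation of four equal segments (the
non-identity permutation is guaranteed when applied), and time-warping
by a factor drawn from (0.5, 2.0) with centre-crop/edge-pad back to 900
samples. A linear head per task on the encoder output is trained with
summed binary cross-entropies. Time-warp and reversal detection are
learnable on movement-rich (wake-dominated) windows — held-out
accuracies around 0.95 and 0.93 in the test conditions. Permutation
detection stays near chance on this simulator: gravity orientation is
constant within an epoch, so cutting and reordering segments creates
almost no boundary discontinuity. This is a documented limitation of the
movement model, not of the transformation.

## The baseline

Each epoch maps to 28 named features: per-axis mean/sd/range, ENMO
mean/sd/MAD, the three inter-axis Pearson correlations (defined as 0 for
a constant axis), z-angle mean and mean absolute successive difference,
roll/pitch mean and sd, the dominant frequency in 0.3–15 Hz and its
power, total power in 1–3 Hz, spectral entropy, peak-to-peak magnitude,
and the skewness and excess kurtosis of the magnitude. Spectral features
use the sum of per-axis power spectra of mean-removed, Hann-windowed
signals: removing the per-axis mean suppresses the DC/gravity line,
while summing axes keeps oscillations that are orthogonal to gravity and
therefore invisible in the vector magnitude. A 500-tree random forest
(√p features per split, seeded) classifies epochs; its out-of-bag class
probabilities calibrate an HMM emission matrix P(prediction | truth),
the transition matrix comes from add-one-smoothed bigram counts of
training labels, and prediction decodes the Viterbi
maximum-a-posteriori path in the log domain with classifier
probabilities floored at 1e-6. Out-of-bag calibration matters: a
resubstitution confusion matrix is nearly diagonal and would make the
smoother trust the classifier too much.

## Free-living windows and sleep parameters

The two-class baseline output is the time-in-bed proxy. All maximal
sleep runs enter a merge step that unions windows separated by at most
60 min (gap included); merged windows shorter than 30 min are then
discarded. The floor is applied *after* merging: brief within-night wake
bouts fragment a night into short runs, and filtering before merging
truncates the detected window at the first or last long run (measured:
43/100 nights recovered within ±15 min with the floor first, 100/100
with merging first). Each merged window is assigned to the noon-to-noon
interval containing its midpoint; per interval the longest window wins,
ties to the earlier start. Overnight sleep duration is 0.5 min per epoch
staged REM or NREM inside the selected window; unscored (non-wear)
epochs count as wake, and windows with more than 20 % unscored epochs
are flagged low-confidence.

Per-night parameters: TST = 0.5 × #(REM ∪ NREM); sleep efficiency =
100 × TST / window duration; sleep onset = first sleep epoch; WASO
counts wake epochs from onset to the window end (a fixed, auditable
convention — counting only to the final awakening would make WASO depend
on an endpoint that accelerometry estimates poorly); REM/NREM ratios are
percentages of TST. A weekly summary averages days with at least 22 h of
wear and is valid with ≥ 3 such days including ≥ 1 weekday and ≥ 1
weekend day. Duration categories: short < 6 h, normal 6–7.9 h, long
≥ 8 h (the long band is the complement of the printed ones); efficiency
is dichotomised at a configurable split, cohort median by default.

## Validation statistics

Cohen's κ is unweighted, `(p_o − p_e)/(1 − p_e)` with `p_e` from
marginal products; when `p_e = 1` it is defined as 1 if agreement is
perfect and 0 otherwise. Macro-F1 averages per-class F1 over classes
that are present or predicted — a night with no REM neither earns nor
loses credit for REM. Balanced accuracy averages recall over classes
present in the truth. Subject-wise cross-validation partitions subjects
(never nights of one subject across folds) and reports subject-wise
mean ± sd next to pooled epoch-to-epoch values; subjects whose test
epochs contain a single class report a missing κ. Bland-Altman limits
of agreement are bias ± 1.96 × sd (n−1 denominator); the 1.96 normal
quantile is used rather than a t-quantile to match the conventional 95 %
limits. ICC is the two-way, absolute-agreement, single-measure form
ICC(2,1), appropriate for paired measurements of the same quantity;
identical vectors define ICC = 1 and zero variance with unequal pairs is
an error.

The wear-time simulation takes complete 7-day label truths from a
heterogeneous cohort: each subject draws a habitual bed time
(N(23:00, 35 min)) and rise time (N(07:00, 45 min)) once, giving a
between-subject spread of weekly sleep duration of about an hour — the
population variability that ICC measures against, and without which any
censoring noise would collapse the coefficient. The simulation keeps `d`
random days, deletes one contiguous block of `24 − h` hours at a random
offset per kept day (wear gaps are contiguous in practice), recomputes
the weekly mean overnight sleep duration, and reports the ICC against
complete-data means per (h, d) cell, averaged over repetitions. The
minimal criterion is the cell with ICC above 0.75 that minimises total
required wear `h × d`, ties to fewer days.

## The synthetic generator

The hypnogram is a first-order Markov chain over the five stages at
epoch resolution. Default self-transition probabilities encode mean bout
lengths of roughly W 2 min (within the night), N1 1 min, and 10 min for
N2, N3 and REM; the off-diagonal mass follows the usual progression
(W→N1→N2→{N3, R}), and nights start from (0.9 W, 0.1 N1). These are
package fixtures chosen for plausible AASM bout structure, not estimates
of any study population.

Movement is the only stage signature: per stage, wrist acceleration is a
slowly reorienting gravity unit vector (random-walk rotation between
epochs) plus Poisson bursts — exponentially damped (τ = 0.25 s) impulses
with exponential amplitudes in random directions — plus Gaussian noise.
The default profiles encode wake ≫ N1 > (N2 ≈ REM) > N3 in mean ENMO,
with REM distinguished from N2 by many small twitches (5/min at 0.04 g;
muscle atonia with phasic activity) versus few larger repositionings
(1.2/min at 0.15 g). Baseline noise is 14–30 mg so that genuine sleep
never trips the 13-mg stationarity rule — only inserted wear gaps
produce missing data. `StageDynamics.default(contrast=c)` interpolates
every profile toward the pooled mean: at `c = 0` the stages are
statistically identical and any classifier must fall to chance, which
the tests verify.

Free-living simulation runs noon-to-noon days from a fixed Monday, one
overnight in-bed interval per night (bed 23:00 ± 30 min, rise
07:00 ± 30 min, shifted 30 min later on weekend nights), optional
afternoon naps (~14:00, ~45 min, probability 0.15/day), diary entries
jittered N(0, 10 min) around truth, and wear gaps as deleted sample
ranges (0.5/day, 20–120 min by default).

What the generator does *not* emulate: within-epoch gravity drift (hence
the weak permutation pretext task), device-specific noise signatures,
physiological signals beyond movement, circadian misalignment, or the
poor intrinsic separability of real wake-in-bed versus sleep. Passing
the synthetic learning tests therefore shows that the estimators,
training loop and pipeline plumbing work — not that comparable accuracy
would be reached on real polysomnography-labelled recordings, where
agreement is known to be far lower.

## Scaled-down study conditions

The test suite and `scripts/acceptance.py` run on one CPU in minutes, so
the study is scaled down: nights of 240 epochs (2 h), 16 training and 4
test nights, a 3-block encoder with channels (8, 12, 16, 24) and kernel
9, LSTM hidden 16, FC (32, 5), 12 training epochs; self-supervision uses
~2,900 windows for 8 epochs, and the transfer comparison fine-tunes for
3 epochs on 10 nights of 120 epochs over 5 seeds. The wear simulation
uses 16 subjects × 7 days, a 4 × 2 (hours × days) grid and 3
repetitions. These sizes are the package's chosen desk-scale defaults;
all of them are parameters, and larger studies only require changing
them.

## Known limitations

* The NumPy network trains whole nights sequentially; it is CPU-bound
  and not intended for cohort-scale training.
* Permutation self-supervision is uninformative on this simulator (see
  above).
* The HMM smoother assumes stage dynamics are shared across subjects; a
  per-subject transition model is not implemented.
* `detect_time_in_bed` exposes the pre-merge length floor for
  compatibility with its documented contract; end-to-end callers should
  use `time_in_bed_windows`, which merges first.
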