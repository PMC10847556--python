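# Methods

`pcgscreen` implements a screening pipeline that predicts left-sided
valvular heart disease (VHD) from four-position phonocardiograms (PCG). The
pipeline has five stages: audio conditioning, cardiac-cycle segmentation,
MFCC feature extraction, recurrent murmur-grade regression, and
regression-based disease prediction with a cross-validated evaluation
harness. A seeded synthetic cohort generator supplies data with the
statistical structure the analysis assumes, so every stage is testable
without access-restricted clinical recordings.

## Synthetic cohort generator

Each participant receives four ~10 s recordings (aortic, pulmonic,
tricuspid, mitral; 2205 Hz mono, PCM16 on disk), echo labels, and clinical
covariates.

**Disease state.** Aortic stenosis is driven by the aortic valve mean
pressure gradient (AVPGmean): with probability 0.021 the gradient is drawn
from 15 + Exponential(mean 12) mm Hg (truncated at 75), otherwise from a
lognormal centred near 5 mm Hg truncated below 14.5. The stenosis grade is
always the deterministic cutoff function of the gradient (mild ≥ 15,
moderate ≥ 20, severe ≥ 40 mm Hg). Regurgitation grades (AR/MR, 0–4) and
mitral stenosis (0–3) are categorical draws with prevalences matching an
unselected elderly cohort (AR ≥ 3: 7.1%, MR ≥ 3: 13.7%, MS ≥ 1: 0.6%).

**Murmur grades.** True continuous murmur grades per position are the
maximum of disease components: the AS component is monotone in the
gradient, `1 + 2.2·log2(AVPG/15)`, loudest at the aortic/pulmonic
positions; MR contributes a mitral-dominant systolic component; AR and MS
contribute diastolic components; innocent flow murmurs (prevalence 0.16,
grade U(0.5, 3.2), pulmonic-dominant) dominate overall murmur prevalence,
as they do in unselected cohorts — the resulting marginals (~25% of
participants with grade ≥ 1, ~8% with grade ≥ 2) sit near the rates such
cohorts report. Two annotators observe `round(true + N(0, 0.5))` clipped
to 0–6; the recording's label is their mean. Per-position noise-flag
probabilities default to (0.061, 0.053, 0.028, 0.071).

**Audio.** S1 (120 ms) and S2 (90 ms) are Hann-windowed band-limited noise
bursts (40–200 Hz); the systolic interval is a linear function of cycle
length (130 ms + 0.22·cycle); murmurs are band-passed noise (systolic
100–440 Hz with a diamond envelope, diastolic 150–400 Hz decrescendo)
whose RMS relative to S1 is `0.12·grade` — a generator convention placing
grade 1 near the audibility floor and grades 5–6 at murmur-dominant
loudness (clinical grading above 3 reflects loudness only). Cycle lengths
jitter by 1.5%; a noise-flagged recording receives broadband interference
at twice the S1 RMS so "noisy" is physically meaningful. Clinical
covariates shift with disease (age +7 y, heart rate −3 bpm for VHD
subgroups — directions from cohort tables, magnitudes generator knobs) and
are masked at configured missingness rates.

**What the generator does not emulate:** hemodynamics, respiration,
sensor/room acoustics, inter-device variability, or any correlation
structure between murmur quality (pitch, shape) and disease beyond
loudness. Passing tests therefore demonstrate the pipeline's mechanics and
statistical machinery, not clinical performance.

## Audio conditioning

Spike removal partitions the signal into non-overlapping 500 ms windows
(last partial window kept) and, while the maximum per-window maximum
absolute amplitude (MAA) exceeds 3× the median MAA, zeroes the span around
the loudest sample out to the nearest zero-crossings. Zeroed spans are set
to exactly 0 rather than interpolated — the simplest variant and the one
common reference implementations use. The iteration cap is 10× the window
count. Downsampling to the 2205 Hz working rate is polyphase FIR
resampling (deterministic, no IIR transient tuning). Spike removal runs
before downsampling.

## Segmentation

Four envelope features are computed at 50 Hz: homomorphic envelope
(exp of low-passed log analytic amplitude, 8 Hz first-order Butterworth),
analytic-signal magnitude, 40–60 Hz band-power envelope, and a
wavelet-detail envelope (rbio3.9 DWT, coarsest kept detail level
reconstructed). Each is normalized to zero mean and unit variance.

**Heart rate.** The cycle length is the argmax of the mean-removed
normalized autocorrelation of the homomorphic envelope within lags
[0.5 s, 2.0 s] (heart rate forced into 30–120 bpm); the systolic interval
is the argmax within [0.2 s, cycle/2]. For a participant, autocorrelations
of all non-noisy positions are averaged pointwise before peak picking;
with one usable recording this reduces exactly to the single-recording
estimate, and with a corrupted position it is strictly more robust than
that position's own estimate. Averaging autocorrelations (rather than,
say, taking the median of per-recording rates) is a configurable strategy
choice.

**Decoding.** A duration-dependent Viterbi over the cyclic chain
S1 → systole → S2 → diastole. Emissions are per-state diagonal Gaussians
over the four features, fitted on labelled synthetic frames (the emission
model is injected, so a logistic-regression variant can be swapped in).
Duration priors are Gaussian with means S1 = 122 ms, S2 = 92 ms,
systole = systolic interval − S1, diastole = cycle − rest; SDs 22 ms
(50 ms for diastole) — published segmentation defaults, exposed in
configuration. First and last state visits may be truncated; their partial
duration is scored by the same prior. The decoder maximizes total log
probability exactly (verified against an exhaustive dynamic-programming
reference on ≤ 200-frame instances).

**Blocks.** Cycles (S1 onset to S1 onset) are cut into blocks of four with
stride two (50% overlap), at most six blocks per recording (the first six
when more are available). A recording decoding to fewer than four complete
cycles yields one short block rather than being dropped; median
aggregation downstream tolerates it.

## Features

Per block: Hann-windowed spectrogram with a 35 ms window and 25 ms hop
(the window is hop + the 10 ms overlap; at 2205 Hz, 77 and 55 samples), 26
triangular HTK-mel filters from 0 to Nyquist, log energies floored at
1e-10, DCT-II, and the first 13 coefficients (c0 kept; a flag drops it).
The 13 × T matrix is cubically interpolated along time (per-row splines,
not-a-knot ends) to exactly 200 columns, then standardized by the scalar
mean and standard deviation of the whole matrix. Zero-variance blocks are
rejected. Filter count, mel scale, log floor, and c0 are conventions the
framing numbers do not determine; all are exposed as parameters.

## Murmur-grade regressor

A two-layer LSTM (50 units per layer) consumes the 200 timesteps of
13-dim MFCC vectors; the final hidden state feeds a 30-unit fully
connected layer with a rectifier and a linear scalar output. Squared-error
loss; Adam with initial learning rate 0.002 halved every five epochs.
Forward, backpropagation through time, and the optimizer are implemented
directly on numpy arrays (float32 for training; float64 in the gradient
check) — the analytic gradients match central differences to 1e-5.

Training uses only recordings both annotators marked non-noisy, pools all
positions without a position feature, and gives every block its
recording's murmur grade as the label (the only label available per
block). The murmur class (grade ≥ 1) is resampled with replacement to an
approximately 1:1 ratio. Inference is deterministic; a recording's grade
is the median over its block predictions; the participant-level
aggregates are the maximum grade (noisy positions contributing 0) or the
per-position 4-vector plus noise bits.

Default epoch count is 30; the seeded evaluation runs use 15 epochs with
batch size 32 (400 participants), and the per-fold nets inside the
cross-validation harness use 2 epochs with batch size 128 — problem sizes
chosen to keep full runs at desk scale on one core while the loss sits
near its label-noise floor (annotator noise alone bounds the achievable
MSE at about 0.12).

## Aortic-gradient model and screening

The multiposition model is linear in products of murmur-grade factors
(degree ≤ 2) and 0/1 noise indicators; a noisy position's grade is forced
to 0 before evaluation. The published fitted model ships as a preset with
exactly its printed terms (the source equation elides additional terms).
OLS fits report coefficients, standard errors, and two-sided t p-values;
BIC uses the closed form `n·ln(RSS/n) + k·ln(n)` with k counting terms,
intercept, and variance. Stepwise selection starts from the four linear
murmur-grade terms, evaluates all single-term additions (added term must
have p < 0.05) and removals (candidates are terms with p > 0.05) jointly,
and takes the move minimizing BIC until no move improves; ties break
toward the lowest-index candidate, making the search deterministic. A
second phase searches noise-indicator terms the same way; its pool is
kept first-order in noise factors (noise main effects and current-term ×
single-noise interactions, plus the saturated-noise mitral term family the
published model contains) — the full combinatorial pool is intractable
and was not the published procedure's scope either.

Cross-validation is participant-keyed: a ~10% holdout is drawn first,
the rest stratified by AS ≥ 1 into eight folds. Murmur predictions enter
downstream models only out-of-fold; the gradient-model structure is
selected once on pooled out-of-fold predictions and its coefficients are
re-estimated per training split. Decision thresholds maximize
sensitivity + specificity over score midpoints subject to
sensitivity > 50% (ties: higher specificity, then lower threshold). Joint
screening classifies participants positive under three definitions
(grade ≥ 3 regurgitation or any stenosis; grade ≥ 4 or any stenosis;
symptomatic grade ≥ 3 or any stenosis), with "symptomatic" defined as
breathlessness at rest or walking calmly on level ground, or mMRC ≥ 2.
Clinical-variable logistic models per target (AR ≥ 3, MR ≥ 3, AS ≥ 1,
MS ≥ 1) use the covariate sets of the published analysis — the AS model
includes a gender × murmur-grade interaction and takes the multiposition
gradient output as its audio predictor, MR the mitral-position grade, AR
and MS the maximum grade. Missing categorical answers are mode-imputed
before fitting; continuous covariates are untransformed.

## Evaluation statistics

AUC is the Mann–Whitney rank formulation with ties counted ½. Sensitivity
and specificity CIs are exact Clopper–Pearson (beta-quantile inversion).
Fold-level statistics get a t interval with k−1 degrees of freedom over
the k fold values (the fold-iid assumption states no interval form;
small-k practice favours t). Pooled AUC replaces fold AUCs when folds
contain no positives. Interrater agreement is percent agreement and
Cohen's kappa on the binary murmur-present variable. The
symptomatic-subgroup comparison between detected and missed cases is a
two-sided Fisher exact test (counts are small; a chi-square option exists
behind a flag). Threshold-sweep AUCs over gradient cutoffs 7–30 mm Hg get
seeded percentile-bootstrap CIs (1000 replicates).

## Known limitations

- The murmur → loudness mapping is a linear convention; no quantitative
  calibration of clinical murmur grades to RMS ratios exists.
- Whether six blocks per recording were guaranteed in the original
  recordings (10 s needs ≥ 14 cycles) is unknowable; the ≤ 6-block rule is
  a documented choice.
- The per-state Gaussian emission model is simpler than
  logistic-regression emissions; it suffices on synthetic envelopes and is
  injectable.
- Printed coefficient magnitudes of the clinical models are not
  reproduced: their scale/link conventions are under-documented, so only
  the model structure is implemented.
- Automatic noise detection is explicitly out of scope; noise flags are
  taken from the annotations.
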