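# Methods

## Problem setting

The package targets handwriting brain-computer interfaces in which a
paralyzed subject attempts to write characters following a guided-writing
prompt while intracortical activity is recorded. Decoding proceeds in four
stages: (1) render prompt glyphs as 20 Hz velocity/position series, (2)
extract binned neural features from the 30 kHz recording, (3) regress
features onto 2-D pen velocity with a trainable decoder, and (4) translate
decoded velocity into text by template matching. The central methodological
issue is *label misalignment*: the subject's attempted-movement timing
drifts nonuniformly against the prompt, so the kinematic labels are only
shape-correct, not time-correct. The package implements a differentiable
shape/time distortion loss (DILATE) to train decoders under this condition,
alongside the conventional MSE baseline, and the simulation experiments
that isolate the effect.

## Alignment machinery

For sequences y (length m) and z (length n), the cost matrix is
Delta(i,j) = ||y_i - z_j||^2. Hard DTW minimizes <A, Delta> over monotone
paths A from (1,1) to (m,n) with steps down/right/diagonal; backtracking
tie-breaks prefer diagonal, then vertical, then horizontal, which keeps
timing offsets minimal and paths deterministic. Unequal lengths are fully
supported and exact DTW is unwindowed.

Soft-DTW replaces the minimum with softmin_gamma(a) = -gamma log sum
exp(-a/gamma), evaluated with a max-shifted log-sum-exp inside the dynamic
program (cost space, never probability space), so values stay finite for
gamma down to 1e-4 at costs of order 1e3. The *relaxed optimal path*
A*_gamma is the gradient of soft-DTW with respect to Delta, computed by the
standard backward recursion; it equals the Gibbs-probability-weighted
average of path indicator matrices (verified against exhaustive path
enumeration for lengths <= 5 in the tests).

The soft temporal-distortion index is softTDI = <A*_gamma, Omega> with
Omega(i,j) = (i-j)^2, and

    DILATE_{alpha,gamma} = alpha * softDTW + (1-alpha) * softTDI.

Two genuinely open choices were resolved as follows:

- **Omega normalization.** The penalty is divided by m*n by default
  (switchable), which keeps the shape and time terms on comparable scales
  so alpha = 0.5 behaves as a balanced trade-off. Defaults are alpha = 0.5,
  gamma = 0.001; the loss is finite and smooth over alpha in [0.1, 0.9] x
  gamma in [1e-4, 1] on the packaged fixtures.
- **softTDI gradient.** Omega is held constant and the Gibbs weights are
  differentiated. Since <A*(Delta), Omega> is a directional derivative of
  softDTW, its gradient is the Hessian of softDTW applied to Omega; this is
  computed *exactly* by forward-mode differentiation (a JVP in direction
  Omega) threaded through both the forward and backward DP recursions, at
  the cost of one extra pass each — no finite differences. The combined
  gradient is chained through dDelta/dz_j = 2 (z_j - y_i) to the predicted
  sequence.

fastDTW follows the multiscale scheme: halve both sequences by pairwise
averaging, solve recursively, project the coarse path up, and run a
windowed DTW in a corridor of half-width ``radius`` (default 1; recognition
uses 2). The restricted search means fast_dtw >= dtw always, with equality
on smooth inputs at radius >= 2.

Timing statistics use the hard path: index_i = min{j : A(i,j)=1}, offsets
(i - index_i) * 50 ms, with the signed mean, absolute mean, and the SD of
absolute offsets all reported (the within-trial SD is the headline
dispersion statistic).

## Kinematics synthesis

Glyphs are ordered polyline segments labeled stroke or pen-lift; pen lifts
are synthesized as straight movement segments identical to strokes.
Durations are allocated to each straight piece proportionally to its share
of total arclength; within a piece each axis follows the triangular
profile v(t) = a t rising to a peak 2L/T at T/2 and returning to zero, with
a = 4L/T^2 so the profile integrates to the displacement. Total duration
is 4 s for short glyphs up to 8 s for long ones (linear in arclength,
clipped). The sampled velocity at 20 Hz is the exact mean path velocity
over each sample interval (the closed-form position integral differenced),
so integration reproduces the glyph endpoint exactly before smoothing; the
5-point centered moving average (edge-replicated) then perturbs the
endpoint by well under 2 % of the bounding-box diagonal. Coordinates are
x-right/y-up in [0,1]^2; no inter-segment pauses are inserted.

## Neural features

All recipes follow the standard cascades (ESA: 300 Hz first-order
high-pass, rectify, 12 Hz first-order low-pass, 1 kHz; SBP: 300-1000 Hz
second-order band-pass, rectify, 2 kHz; cMUA: 300-6000 Hz third-order
band-pass, square, 100 Hz third-order low-pass, clip negatives, square
root, 1 kHz; LFP: sub-500 Hz low-pass, 2 kHz, +-3 SD clipping, third-order
low-pass; band powers over 1-4 / 3-10 / 12-23 / 27-38 / 50-300 Hz; LMP:
50 ms non-overlapping means; threshold crossings: 250-5000 Hz band-pass,
negative crossings of -k x rms with 1 ms lockout, k in {4.5, 6.25}).
Choices the recipes leave open:

- Filtering is zero-phase (forward-backward) by default for offline parity;
  a causal flag exists for pseudo-online use.
- Downsampling decimates after each recipe's own final low-pass; no extra
  anti-alias stage is added.
- The unstated cutoff of the post-clipping LFP low-pass is 500 Hz,
  consistent with the preceding anti-alias intent.
- rms for threshold detection is computed per channel over the whole
  segment.

Binning averages continuous streams (sums event counts) in overlapping
200 ms windows stepped at 50 ms to match the 20 Hz kinematic grid, with
the feature window ending 300 ms *before* the prompted kinematic sample:
prompted kinematics follow the animation clock, and neural modulation
appears roughly 300 ms after the cue, so a neural event surfaces in the
kinematic bins 300 ms later. Streams must carry at least bin + lag = 500 ms
of pre-trial padding. Channel z-scoring freezes training-fold statistics
for held-out data.

## Decoders

The Kalman filter uses a velocity state augmented with a constant-1 bias
channel; A and H are least-squares fits over stacked training pairs
(ridge fallback on rank deficiency), Q and R residual covariances, B = 0.
The recurrent decoder is a single-layer LSTM (default 512 units; tests and
simulations use far smaller) with an ELU + affine readout to 2-D velocity.
All differentiable training — LSTM backpropagation-through-time, the
windowed linear decoder, the Adam-style optimizer, and the DILATE backward
pass — is implemented in numpy with the dynamic programs JIT-compiled; the
implementation is gradient-checked against central finite differences in
the test suite.

Training is per-trial (batch size 1), learning rate 0.001, dropout 0,
adaptive-moment updates, default 100 epochs with early stop after a
10-epoch plateau of the smoothed loss. For the DILATE loss, model output
and label are z-scored per dimension before the loss, and the gradient is
propagated through the output's own z-scoring (mean and SD treated as
functions of the prediction). Optional noise augmentation adds Gaussian
noise with SD proportional to each channel's SD (factors 0.2-1.0).
Leave-one-character-out cross-validation holds out every repetition of one
character per fold; with 30 characters x 3 repetitions each fold trains on
exactly 87 trials, and a master seed fans out one deterministic child seed
per fold. Position decoding is available as direct regression (a
2-D position target) rather than integration, selectable by passing
position targets.

## Recognition

Decoded velocity is z-scored per dimension and ranked against a library of
z-scored template velocity profiles, by ascending fastDTW distance
(radius 2) or by descending Pearson correlation after linear resampling of
both sequences to the query length with dimensions concatenated; ties
break lexicographically. Comparison happens in velocity space, not
position space. Recognition-rate curves subsample the library at each
size, always forcing inclusion of every query character, with 1000
resamples by default; at the minimal and full sizes the subset is unique
and the SD is zero.

## Simulation experiments

**Timeline resampling.** A trial's trajectory is re-timed by drawing as
many sorted uniform time points as the trajectory has samples over the
whole index range and reading positions off the space-time polyline
(velocity between samples treated as uniform); differencing gives the
"actual" velocity V'. The spatial path is exactly preserved; resampling is
independent per trial and per day.

**Feature generation.** A fixed linear encoder (96 channels, weights drawn
once from N(0, 1/2), shared across trials and days) maps V' to features.
Per-channel observation noise has SD equal to 1.0 x the channel's noiseless
SD — single intracortical channels carry weak kinematic signal, so
channel-level SNR near 1 is the realistic regime. Day drift multiplies
channels by lognormal(0, 0.1) gains and adds normal(0, 0.1 x SD) offsets.

**Misalignment experiment.** Character-level 5-fold cross-validation trains
the simulation decoder against the *prompted* velocity under MSE or DILATE
and evaluates CC and MSE to V' plus the DTW recognition rate. The
simulation decoder is a single linear layer reading a +-8-bin (+-400 ms)
feature window. The window is essential, not cosmetic: a strictly per-bin
linear map can only emit a scalar multiple of V', so *both* losses then
decode a clean time-warped template and the misalignment manipulation has
no observable effect; with temporal context, MSE converges to a smoothing
filter that averages over the incompatible timings of the training trials
(blurred, attenuated velocity lobes) while DILATE retains full-amplitude,
sharp profiles aligned to the subject's actual timing. Scale: 26 glyphs x
2 repetitions, 100 epochs, 3 seeds.

**Toy landscape.** The 1-D reduction uses y = zeros(100) with a triangular
bump y[30..34] = (10, 25, 30, 25, 10) (mean 1) and x the same bump delayed
by 8 samples (non-overlapping), prediction a*x + b over a in [-2, 2] and
b in [-1, 2] at step 0.1, no z-scoring inside the losses (it would erase
the (a, b) dependence), DILATE at alpha = 0.5, gamma = 0.001 with
normalized Omega. The MSE surface is quadratic with its least-squares
optimum rounding to (a, b) = (0, 1) — the flat line at the bump's mean —
while DILATE is minimized at (1, 0), the shape-preserving identity; the
grid argmins are checked against the closed-form least-squares solution in
the tests.

**Multi-day fusion.** Day 0 contributes a fixed test set (every 5th
character); training pools the remaining characters from days 1..D after
per-day, per-channel z-scoring (the per-day statistics are computed on the
whole day, mirroring normalize-then-concatenate practice). Each day
re-times every character afresh through the shared encoder with day drift.
Reported: DTW recognition rate and CC to each test trial's own V' as
functions of D for both losses, 6 days, 3 seeds.

## What the generator does and does not emulate

The synthetic sessions reproduce the *structure* of guided-handwriting
BCI data: shape-correct/time-incorrect labels, a stable low-dimensional
velocity encoding spread over 96 weak channels, day-to-day gain/offset
drift, and trial repetition counts. Raw-signal simulations add
velocity-tuned inhomogeneous spiking with refractory lockout, realistic
biphasic waveforms, and pink+white background at microvolt scales, with
ground-truth spike times retained. Not emulated: nonlinear or
history-dependent neural encoding, non-stationarity within a session,
electrode cross-talk, movement artifacts, or the behavioral variability of
real attempted writing beyond timeline warps. Passing tests therefore
demonstrate correctness of the machinery and the direction of loss-function
effects under the stated generative assumptions — not decoding performance
on real recordings.

A consequence worth stating plainly: with this generator and the
warp-invariant DTW/z-score recognizer, MSE's misalignment-induced
degradation shows up strongly in similarity metrics (CC to V', normalized
DTW) but only mildly in recognition rate on the 26 block-capital corpus,
because template matching that is itself warp- and scale-invariant
forgives much of the blur and attenuation that MSE introduces. Recognition
gaps as large as those reported for external position-space recognizers
should not be expected in this setup.

## Numerical choices and degenerate inputs

- Soft-min over three predecessors uses max-shifted log-sum-exp; border
  cells are +inf in the forward pass and contribute zero weight in the
  backward/JVP passes.
- Zero-variance dimensions z-score to zeros (and pass gradients through
  unscaled); empty sequences, dimension mismatches, gamma <= 0, and
  alpha outside [0,1] raise immediately.
- Hard-DTW backtracking resolves exact cost ties diagonal-first, so
  alignment offsets are minimal and runs are bit-reproducible.
- All stochastic stages consume numpy Generators seeded from explicit
  integers; experiment code fans per-fold/per-day seeds out of a master
  seed via SeedSequence.

## Problem sizes

Packaged experiment defaults are scaled for a single CPU: 26 glyphs with
1-2 repetitions per session, 96 encoder channels, 100 training epochs for
the windowed linear simulation decoder, 3 seeds per directional claim,
6 simulated days, and 4-channel/8-second raw-signal simulations. These
sizes are the package's reference configuration; every knob accepts larger
values.

## Known limitations

- The LSTM trains in interpreted numpy; it is suitable for the packaged
  corpus scales, not for 512-unit multi-session sweeps.
- fastDTW guarantees only an upper bound off the packaged smooth fixtures;
  recognition distances on pathological inputs may exceed exact DTW.
- The Kalman filter assumes the standard linear-Gaussian model; it is the
  baseline decoder, and no nonlinear observation model is provided.
- Per-day z-scoring uses whole-day statistics, so a day's test trials
  contribute to their own day's normalization constants (matching the
  normalize-then-split convention of multi-day fusion).
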