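# Methods

This note documents the models and procedures implemented in `mtpbci`,
the assumptions behind the synthetic data, the numerical choices, and
the limits of what the test suite demonstrates.

## Paradigm and geometry

Two virtual arms rest at home positions in a 3D workspace; three
targets per arm lie at the same unit distance from the home along the
horizontal (X), vertical (Y) and depth (Z) axes.  The offline
calibration part comprises six runs; each run is a 10 s initialization
plus six 28 s blocks (one per arm x target combination, order drawn
independently per run from the seeded generator), each block a 4 s
voice cue plus two identical 12 s movement cycles (sub-blocks):
4 s home-to-target, 2 s pause, 4 s target-to-home, 2 s pause.  With the
40 s inter-run rest after every run the offline part lasts 21.8 min
(reported rounded as 22) and the online part -- runs of at most 190 s
built from cue-limited 30 s blocks -- exactly 23 min.  We apply the
rest after every run including the last because only that convention
reproduces the 23 min online total; the 0.2 min offline rounding
discrepancy is inherent to the protocol arithmetic, not a modeling
choice.

The ideal movement template ramps speed linearly from zero until half
the home-target distance is covered (at 2/3 of the epoch) and then
holds the peak `1.5 * distance / duration`; this is the simplest
integrable profile with the stated "maximal at half way" shape, and
backward movements mirror it.  Positions integrate the profile
analytically, so templates are exact at any sample rate.

## Synthetic EEG

No recordings are publicly available for this protocol, so the
generator is a first-class, tested component that realizes exactly the
relation the decoder assumes:

* **Velocity encoding.**  On designated channels (defaults: C4 carries
  the left arm, C3 the right, contralateral as in sensorimotor
  physiology) a band-limited carrier has amplitude
  `sqrt(2 (c0 + g v(t - delta)))`, so *windowed power* -- not
  amplitude -- is affine in the lagged velocity.  Carrier frequencies
  are the even integer nearest each band center (10, 16, 24, 34 Hz):
  an even-integer carrier places an integer number of half-cycles in
  the 250 ms analysis window (before and after aliasing of the doubled
  frequency at 120 samples/s), which removes quadrature ripple from
  the windowed power and makes the encoding exactly affine.  Defaults:
  baseline power `c0 = 1 uV^2`, gain `g = 2 uV^2 per unit/s`
  (modulation stays positive for the template's 0.375 units/s peak
  speed), encoding lag `delta = 100 ms`.
* **Noise.**  Per-channel 1/f-shaped Gaussian noise (exponent 1,
  broadband std 2 uV), a common-mode 1/f component (1 uV) added to all
  channels to exercise the common-average reference, and 0.5 uV of
  50 Hz line interference.  These are realistic resting-EEG figures;
  at these defaults held-out velocity correlations are roughly
  0.3-0.5 per axis -- decodable but far from trivial -- while the
  noiseless configuration recovers r > 0.99.
* **Class sessions.**  For the discrete comparator, band-limited mu
  rhythms (3 uV resting std on C3 and C4) are attenuated
  multiplicatively during the 12 s movement cycles of one class
  (default factor 0.5 contralateral to the imagined arm), emulating
  event-related desynchronization at a 2x variance ratio.

What the generator does *not* emulate: volume conduction from a
forward model, ocular/muscular artifacts, nonstationary baselines,
inter-subject variability, or any nonlinearity between kinematics and
band power.  Passing tests therefore demonstrate correctness of the
pipeline and its statistics under a correctly specified encoding, not
expected performance on human EEG.

## Preprocessing

Channels failing an automated quality rule (peak |amplitude| above
200 uV or std below 0.01 uV) are dropped -- a deterministic surrogate
for manual inspection.  The common-average reference subtracts the
instantaneous channel mean (idempotent; removes the common-mode
component exactly).  Band-pass filters are linear-phase Kaiser FIR
designs (stop-band 60 dB; transition width `min(2 Hz, 0.8 * low
edge)`, which keeps the 0.5-4 Hz filter-bank band feasible), applied
zero-phase by centered convolution; the first and last half-filter
lengths are transient and fall inside the 10 s run-initialization
periods.  Band power is the mean square in a half-open 250 ms window
stepped by one sample (8.33 ms) at calibration; window timestamps mark
the window *end*, so features are strictly causal.  Standardization
divides by the per-feature standard deviation computed on training
folds only.  A temporal first-difference switch exists ahead of
standardization but defaults to off: the printed scale-only definition
is the concrete one, and both behaviours are available where the
field's descriptions disagree.  Lag embedding concatenates features at
`t, t - Delta, ..., t - L Delta` (embedding dimension `L + 1`) and
drops leading samples without full history.

## Decoder and architecture search

Six independent OLS regressions (2 arms x 3 axes) are solved by
orthogonal decomposition (LAPACK gelsd, minimum-norm on rank
deficiency) with a 1e-8-scaled ridge fallback for pathological
conditioning; predictions are emitted every 25 ms (40 Hz display rate)
and smoothed by a 9-sample (200 ms) centered moving average with
shrunken edge windows.

Model selection runs 6-fold leave-one-run-out cross-validation on the
second sub-block of each block (the cycles without displayed
movement): per fold, sigma is recomputed from the five training runs,
all twelve lag-grid cells (spacings 50/100/200 ms x counts 1/2/4/8)
are fitted, and per-channel scores `R_jnf = sum_k sum_i b^2 / (L+1)`
are averaged over folds and bands; the lowest-scoring channel is
dropped (ties drop the higher montage index, for determinism) and the
loop repeats down to the channel floor.  The selected architecture
minimizes the mean reconstruction error among channel-set sizes 6-12.
Note an identifiability limit of the synthetic encoding: the 100 ms
encoding lag lies inside the 250 ms analysis window, so all lag-grid
cells see the encoded velocity through the current window and their
cross-validated errors are statistically indistinguishable; the grid
machinery is exercised for correctness and determinism, not for lag
recovery.

Trial metrics follow the normalized-velocity scheme: predicted and
target velocities are unit-normalized per sample (near-zero vectors
map to zero and are flagged), converted to relative coordinates by the
within-trial running mean (first sample is the zero reference; under
this scheme a perfect straight reach sits at its target's unit
direction vector), and scored by the mean 3D distance `eps_t`.  Pause
samples never enter `eps_t`; each offline fold contributes twelve
movement trials (six forward, six backward).  A conventional
cumulative-sum integration is available for display only and is never
used for selection.

## Closed loop

The online simulator steps the paradigm clock at 40 Hz.  Displayed
motion integrates the assistance blend at a constant speed scale
(home-target distance per 4 s, the offline template time -- the
protocol normalizes displayed speed without stating the constant, so
the template time is the natural choice), clamps positions to the
workspace box (predicted, unclamped values are logged separately), and
ends a movement epoch early when the hand comes within 20% of the
origin-destination distance of its destination, upon which the 2 s
hold starts immediately and the hand is then relocated to the nominal
endpoint for the 4 s pause.  Blending operates on normalized vectors
throughout, so the displayed speed is independent of the decoder's
output magnitude.  Assistance follows 50% minus 6 points per run
(20% at run six); direct-feedback mode forces 0%.

## Evaluation statistics

Time-varying decoding accuracy classifies each within-trial sample of
the relative-coordinate trajectory by its nearest landmark (the unit
direction vectors of the three targets); ties count as failure
(conservative and deterministic); trials are truncated to their common
length and pooled.  Chance is 100/k % for k balanced classes.  The
permutation null re-assigns whole trajectories to labels (the three
coordinates stay together); per-sample p-values use the add-one
estimator, and global statements use the peak statistic or two-sided
Wilcoxon tests (exact null up to n = 25, normal approximation beyond;
identical paired samples return p = 1 by convention).  How the
original analyses aggregated per-sample p-values is not specified
anywhere authoritative, so the package reports per-sample p and
peak-based summaries without asserting either as canonical.

## FBCSP comparator

Per binary target-vs-rest classifier and per band (0.5-4, 4-8, 8-12,
12-18, 18-28, 28-40 Hz): CSP filters come from the generalized
eigendecomposition of `(C_a, C_a + C_b)` with trace-normalized trial
covariances (a standard conditioning choice) and are taken
alternately from the two ends of the eigenvalue spectrum; features are
sliding-window log-variances (1 s window, 200 ms step, offsets -4 to
+12 s around movement onset, 76 positions); mutual information is
estimated on an equal-frequency-quantized feature space via average
ranks (robust to feature scale; ties collapse to one level so constant
features get exactly zero MI); the top-k features feed an LDA whose
pooled covariance is shrunk toward its scaled identity.  Multi-class
decisions take the argmax of per-class signed hyperplane distances
(ties to the lowest class index).  Hyperparameters -- CSP pairs
{1,2,3}, quantization levels {4,8,16}, k {4,8,16}, shrinkage
{0, 0.1, 0.3, 0.5, 0.9} -- are chosen by inner CV (5 folds inside 6
outer run-folds for single-session analysis; 6 inside 7 session-folds
for multi-session), maximizing peak inner DA; outer test trials never
influence any choice.  Contribution maps average MI weights per band
and offset, and topographies take the MI-weighted CSP filter
magnitudes at the peak-DA offset (magnitude aggregation makes them
invariant to filter sign).

## Problem sizes and tolerances

The test and reference computations run at desk scale: chance-level
simulations use 6000 random-direction trials (the time-averaged DA of
n trials has a standard error of about `sqrt(p(1-p)/n)`, so ~0.6
points at n = 6000); the null FBCSP computation uses a 17-run session
(204 trials) with the reduced hyperparameter grid {1,2} x {4,8} x
{4,8} x {0.1, 0.5}; end-to-end fixtures use 6-run sessions (36
trials/class) and ten generator seeds for the paired comparison of DA
peaks against permutation nulls.  Calibration feature steps of 3-6
samples (25-50 ms) are used where the one-sample default adds cost but
no statistical power.  Numerical floors: velocity normalization treats
norms below 1e-9 of scale as degenerate; log-variance windows are
floored at 1e-12 of the mean variance; OLS falls back to a 1e-8 ridge
only on non-finite solutions.

## Known limitations

* Synthetic EEG only; none of the human-subject accuracy figures are
  reproducible or attempted here.
* The generator's encoding makes the linear model exactly correct;
  model-misspecification behaviour (nonlinear couplings, artifacts) is
  out of scope.
* The online simulator replays decoders against the paradigm clock; it
  does not model reaction times, adaptation or learning across runs.
* EDF files can be read (via mne) but sessions are written as
  tab-separated tables; no EDF writer is bundled.
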