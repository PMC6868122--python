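# mtpbci

Motion-trajectory-prediction (MTP) brain-computer interfacing: decoding
the 3D velocity of imagined arm movements from EEG band power, with a
closed-loop assisted-feedback simulator and a filter-bank CSP
multi-class comparator -- exercised end to end on synthetic EEG with
known ground truth.

## Who this is for

BCI researchers who want a tested, reproducible implementation of the
band-power MTP decoding chain (and its discrete-classification
comparator) without access to proprietary recordings.  Because no
public data exist for this two-arm, six-target virtual-reaching
protocol, the package ships a synthetic-session generator whose
encodings are known exactly, so every stage -- preprocessing, decoding,
architecture search, closed-loop feedback, statistics -- can be
validated against ground truth.

## The model

EEG (16 sensorimotor channels, 120 samples/s) is common-average
referenced, band-pass filtered into mu (8-12 Hz), low beta (12-18 Hz),
high beta (18-28 Hz) and low gamma (28-40 Hz), and reduced to band
power in a 250 ms sliding window.  Standardized, lag-embedded features
feed one ordinary-least-squares regression per arm and axis:

    v_ij[t] = a_ij + sum_n sum_f sum_k  b_ijnfk * S_jnf[t - k] + eps_ij[t]

where `S_jnf` is the band power of channel `n` in band `f` scaled by
its training-fold standard deviation, and `k` indexes `L + 1` time
lags.  The channel subset and lag parameters are chosen by recursive
channel elimination (channels scored by `R_jnf = sum_k sum_i b^2 /
(L+1)`, averaged over folds and bands) under 6-fold leave-one-run-out
cross-validation, scored by the trial-wise trajectory reconstruction
error `eps_t` (mean 3D distance between running-mean relative
coordinates of normalized predicted and target velocities).

Closed-loop feedback blends normalized target and predicted velocities,
`v*_assisted = rho v*_target + (1 - rho) v*_predicted`, with the
assistance fraction dropping from 50% by 6 points per run; trajectory
quality is summarized as time-varying decoding accuracy (DA, nearest
target landmark per within-trial sample) against label-permutation
nulls.  The comparator classifies trials discretely with filter-bank
CSP features, quantized mutual-information selection and regularized
LDA under inner-outer (nested) cross-validation.

## Worked example

```python
import numpy as np
from mtpbci import evaluate, mtp, paradigm, synthgen

layout = paradigm.TargetLayout.default()
schedule = paradigm.build_offline_schedule(layout, n_runs=6, seed=0)
rec, kin = synthgen.synthesize_mtp_session(schedule, layout, seed=0)
ds = mtp.prepare_dataset(rec, schedule, kin, layout, window_step_samples=3)

report = mtp.crossvalidate(ds, lag_spacing=0.1, n_lags=2, arms=("left",))
print(f"mean trajectory reconstruction error eps_t = "
      f"{report.arm_mean_error('left'):.3f}")

forward = [t for t in report.trials("left") if t.direction == "forward"]
landmarks = evaluate.target_landmarks(layout, "left")
perm = evaluate.permutation_null(
    [t.pred_coords for t in forward], [t.target for t in forward],
    landmarks, n_perm=500, seed=0,
)
print(f"time-varying DA peak = {perm.observed.peak:.1f}% "
      f"(permutation-null mean peak = "
      f"{perm.null_curves.max(axis=1).mean():.1f}%, chance = 33.3%)")
```

prints

```
mean trajectory reconstruction error eps_t = 0.896
time-varying DA peak = 94.4% (permutation-null mean peak = 49.8%, chance = 33.3%)
```

The session is one offline calibration block (six runs, six randomized
arm x target blocks each) at the generator's default noise level;
`eps_t` is in normalized-velocity units (a direction-random decoder
scores about 1.0 on forward reaches, a perfect one 0).  The DA peak of 94.4% against a ~50% null
peak shows the decoder recovering the velocity encoding planted on the
contralateral channels.

A command-line pipeline covers the same flow
(`mtpbci simulate | select-architecture | train | cv-report | predict |
simulate-online | evaluate | fbcsp | run-all`); `mtpbci run-all
--seed 1 --out artifacts/` writes per-stage tables, trained-model JSON
and a manifest of seeds and parameters.

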