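# ctlmon — cognitive task-load monitoring and adaptive automation

`ctlmon` is a Python toolkit for physiology-driven operator functional
state monitoring in safety-critical human-machine systems.  It targets the
setting of a simulated process-control task (four coupled air-quality
subsystems, a varying number n(k) of them under manual control) in which
an operator's cognitive task-load (CTL) must be estimated every 10 s from
EEG and ECG recordings and used to reallocate tasks between the operator
and the machine in closed loop.

The package covers the complete chain:

1. **Signal conditioning** — 3rd-order Butterworth low-pass at 40 Hz,
   recursive-least-squares (RLS) cancellation of ocular artifacts against
   the EOG reference channel, non-overlapping 10-s epochs, rectangular
   periodogram band powers (delta/theta/alpha/beta/gamma) for 11 EEG
   channels plus R-peak heart rate: a K x 56 z-scored feature matrix.
2. **Feature pipeline** — adaptive exponential smoothing (gain switching
   among g1/g2/g3 = 0.2/0.1/0.3 by innovation size relative to the series
   s.d.) and one locality preserving projection (LPP) scalar per channel:
   a K x 12 salient feature matrix x'(k).
3. **Dynamic classification** — operator performance

       y(k) = ½ min(s_e, s_t) + ½ (1 − s̃_a) ∈ [0, 1]

   is predicted by a NARX model realized with least-squares support vector
   machines (LSSVM, RBF kernel σ² = 500, regularization γ = 100):

       ỹ(k) = f(x'(k), …, x'(k−d1+1), ỹ(k−1), …, ỹ(k−d2) [, y(k−1), …])

   Variant **LSSVM1** feeds back its own predictions (weights 0.1/0.9);
   variant **LSSVM2** adds a local linear regressor refit at each step on a
   four-sample window of *measured* performance (weights 0.02/0.18/0.8).
   Orders (d1, d2) are selected on the training session by minimizing
   J = 0.8·RMSE + 0.2·n_θ/n_θmax over the grid [1, 15]².  The prediction is
   discretized into five CTL classes (very-low … very-high) by thresholds
   at 1 − σ_o and 1 − z_i·σ_o.
4. **Adaptive automation** — a closed-loop simulator (data generator +
   classifier + controller) with two task-reallocation laws: a
   proportional-plus-threshold controller (Δn = 0/1/2 for the tracking
   error e = 1 − ỹ in [0, 0.2)/[0.2, 0.8)/[0.8, 1]) and a rule-based
   controller that additionally freezes n for two steps (30 s) after every
   reallocation.

Because the study's human recordings are not public, the package ships a
first-class synthetic-operator generator (`ctlmon.synthetic`) reproducing
their key statistics — the 1,3,4,4,3,1 task-load schedule, feature-
performance correlations around |r| ≈ 0.74 for the best EEG channels and
≈ 0.32 for heart rate, AR(1) temporal noise, blink and R-wave structure in
the raw channels — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from ctlmon import (CtlNarx, ParticipantProfile, SessionPool,
                    generate_session_features, run_simulation)
from ctlmon.automation import SIM_SCHEDULE

profile = ParticipantProfile()
feats1, y1, _ = generate_session_features(profile, seed=0)   # training session
feats2, y2, _ = generate_session_features(profile, seed=1)   # test session
sigma_o = float(np.std(np.concatenate([y1, y2])))

model = CtlNarx(y1, feats1.to_numpy(), variant="lssvm2", orders=(3, 5))
res = model.fit()
print(res.summary())

report = res.evaluate(feats2.to_numpy(), y2, sigma_o, profile.z)
print(f"5-class test accuracy: {report.accuracy:.4f}")

pool = SessionPool.from_session(feats2.to_numpy(), y2)
kw = dict(pool=pool, results=res, sigma_o=sigma_o, z=profile.z,
          schedule=SIM_SCHEDULE, runs=10)
without = run_simulation(controller=None, seed=0, **kw)
with_aa = run_simulation(controller="rule", seed=1000, **kw)
print("            n_mean  C_mean  y_mean")
print("without AA  {:.1f}     {:.1f}     {:.4f}".format(*without.summaries().values()))
print("with AA     {:.1f}     {:.1f}     {:.4f}".format(*with_aa.summaries().values()))
```

prints

```
               NARX LSSVM load classifier
==========================================================
variant:            LSSVM2
orders (d1, d2):    (3, 5)
combination weights:(0.02, 0.18, 0.8)
kernel:             RBF(sigma2=500) + linear, gamma=100
training samples:   535 (series length 540)
exogenous dim:      12 (regressors 46)
training RMSE r_e:  0.0588
==========================================================
5-class test accuracy: 0.7444
            n_mean  C_mean  y_mean
without AA  2.7     2.4     0.6873
with AA     1.8     1.7     0.8341
```

The classifier, trained on session 1 and tested on session 2 of the same
synthetic operator, assigns the correct one of five load classes to 74% of
the 540 test epochs (the LSSVM1 variant without measured-performance
feedback reaches 66% on the same data).  In the closed-loop rows, ten
90-step simulation runs show the rule-based controller cutting the mean
number of manual tasks from 2.7 to 1.8, the mean predicted load class from
2.4 to 1.7, and raising mean operator performance from 0.69 to 0.83 —
task reallocation keeps the operator out of the high-load regime.

A `ctl` command-line interface wraps the same stages
(`ctl synth | preprocess | reduce | label | train | evaluate | simulate |
run-all`); see `ctl --help`.

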