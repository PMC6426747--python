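# hystfit

Sigmoid-plus-reuse modelling of **motor hysteresis** in sequential posture
selection, for researchers in computational motor control who study
drawer-opening-style tasks: a participant opens nine drawers mounted at
increasing heights, and the pro/supination angle of the grasp depends not
only on the drawer but also on the *previous* posture — the hallmark of
motor-plan reuse.

## The model

The optimal grasp angle, adopted when a plan is built from scratch, is a
sigmoid function of the drawer number *d*:

```
optimal(d) = y_offset + (range / 2) · tanh( (2·slope / range) · (d − x_offset) )
```

with four parameters: the asymptotic **range** (degrees, lowest to highest
drawer), the steepest **slope** (degrees per drawer, attained at the
inflection), and the **x-** and **y-offset** of the inflection point.  A
fifth parameter, the **reuse** fraction *r* ∈ [0, 1], blends the previous
trial's posture into the next plan:

```
angle(i) = r · angle(i−1) + (1 − r) · optimal(d_i)
```

In ascending sequences the hand lags behind the optimum toward supination,
in descending sequences toward pronation: the difference between the two
directions at the same drawer is the hysteresis effect, and its size across
drawers identifies *r*.  For example, blending a previous posture of 74.0°
with an optimum of 40.0° at 30 % reuse gives 0.3·74.0 + 0.7·40.0 = 50.2°.

The toolkit simulates these tasks, fits the 4-parameter (randomized task)
and 5-parameter (ordered/skipped tasks) models per participant by bounded
multi-start nonlinear least squares, decomposes direction-by-drawer
profiles into factorial variance components, classifies participants into
hysteresis/noise groups, extracts grasp events and pro/supination angles
from marker trajectories, and generates fully synthetic cohorts with known
ground truth.

## Worked example

Fit the five-parameter model to a noiseless ordered-task profile generated
from known parameters:

```python
import numpy as np, pandas as pd
import hystfit as hf

truth = hf.ReuseModelParams.from_values(
    range=131.9, slope=41.2, x_offset=4.4, y_offset=16.5, reuse=0.156)
asc = hf.simulate_sequence(truth, hf.SequenceSpec.ascending())
desc = hf.simulate_sequence(truth, hf.SequenceSpec.descending())
idx = pd.MultiIndex.from_tuples(
    [("ascending", d) for d in range(1, 10)]
    + [("descending", d) for d in range(9, 0, -1)])
profile = hf.ObservedProfile("ordered", pd.Series(np.concatenate([asc, desc]), index=idx))

result = hf.fit_reuse_model(profile)   # or hf.HysteresisGraspModel(profile).fit()
print(result.summary())
```

```
                Grasp-angle model fit
======================================================
Model: 5-par sigmoid + reuse    cells: 18    task: ordered
------------------------------------------------------
parameter                 estimate     std err
range (deg)                131.900       0.000
slope (deg/drawer)          41.200       0.000
x_offset (drawers)           4.400       0.000
y_offset (deg)              16.500       0.000
reuse (%)                   15.600       0.000
------------------------------------------------------
captured variance:  100.00 %    RMSE:   0.00 deg
converged: True    starts: 5    SSR: 2.777e-28
```

All five parameters are recovered exactly (the profile is noiseless, so the
standard errors are zero and the model captures 100 % of the variance); the
reuse fraction 0.156 is reported as 15.6 %.  With the same parameters the
predicted mean hysteresis effect is 4.78° over drawers {1, 3, 5, 7, 9} of
the full ordered task, and 9.34° in the skipped task that visits only those
drawers — larger drawer steps leave a larger residue of the previous plan.

The same operations are available from the shell:

```sh
$ hystfit simulate --range 133.3 --slope 34.769191 --x-offset 5.5 \
      --y-offset 57 --reuse-pct 30 --drawers 6,5
drawer 6: 74.0
drawer 5: 50.2

$ hystfit generate --n 31 --seed 7 --out trials.csv
$ hystfit fit --input trials.csv --out-dir results/
$ hystfit recover --n 20 --seed 2 --noise-sd 0
```

See `docs/methods.md` for the modelling assumptions, estimation details and
limitations.

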