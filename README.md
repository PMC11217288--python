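# eegcpm

Connectome-based predictive modeling (CPM) of individual behavior from
source-space EEG phase-locking networks — the full pipeline from
band-limited regional time series, through sliding-window phase-locking
value (PLV) connectomes, to cross-validated prediction of a behavioral
trait with permutation testing, consensus-network extraction, external
validation, and a dynamic-connectivity (temporal-variance) variant.

It is written for researchers who want to study, stress-test, or extend
EEG-based brain–behavior prediction. Because resting-state EEG cohorts
with behavior inventories are rarely openly deposited, the package
ships a first-class synthetic-data module that emulates the study
regime (68-region parcellation, multi-epoch recordings, five canonical
bands, right-skewed behavior scores) with *planted*, parameterized
brain–behavior structure — so every claim the pipeline makes can be
checked against a known ground truth.

## The method

For subject *s* with connectome edge vector **x**ₛ (the n(n−1)/2 upper-
triangle PLV weights; 2278 edges for 68 ROIs) and behavior score yₛ:

1. z-transform each edge with train-set mean/SD (sample SD, n−1);
2. select edges with Pearson p < 0.01 against y, split by sign into a
   positive ("high") and negative ("low") network;
3. summarize each subject: Σₛ = Σ_{e∈pos} z_{se} − Σ_{e∈neg} z_{se};
4. fit an ε-insensitive RBF-kernel support vector regression Σ → y;
5. validate by leave-one-out (or k-fold) cross-validation; report
   Pearson r with parametric p, MAE, R², plus a score-permutation p
   (5000 full pipeline reruns by default).

Edges selected in ≥ 90% of folds form the consensus networks; the model
refitted on the full cohort with those edges is frozen and applied
unchanged to an external cohort (standardized with the *internal*
cohort's parameters). The dynamic variant replaces each edge's static
PLV with its temporal variance σ² across sliding windows.

See `docs/methods.md` for the complete specification of conventions,
defaults, and the synthetic generators.

## Worked example

The `analysis/` scripts run the whole study on synthetic cohorts:

```bash
python analysis/01_simulate_cohorts.py --seed 0   # n=90 + n=41, 68 ROIs
python analysis/04_internal_validation.py --seed 0 --n-perm 200
python analysis/05_external_validation.py --seed 0
python analysis/06_dynamic_cpm.py --seed 0
```

which prints (seed 0):

```
LOOCV positive : r=0.911 p=1.47e-35 MAE=0.054 R2=0.827
LOOCV negative : r=0.878 p=6.78e-30 MAE=0.062 R2=0.768
LOOCV combined : r=0.980 p=2.61e-63 MAE=0.068 R2=0.791
permutation test (200 shuffles): p_perm=0.0000 (observed r=0.980)
consensus networks: 5 positive / 5 negative edges; recall 1.00, FDP 0.00
external cohort (n=41): r=0.989 p=8.76e-34 MAE=0.061 R2=0.840
dynamic  features: pooled r=0.834, planted-edge recall 1.00, FDP 0.00
static   features: pooled r=0.267, planted-edge recall 0.00, FDP 1.00
```

Reading: the generator planted 5 positively and 5 negatively
behavior-coupled edges among 2278. The combined high+low model predicts
the held-out scores almost perfectly (r = 0.98) and beats both
single-tail models — a per-subject global connectivity offset
contaminates each tail alone but cancels in their difference. The
90%-persistence consensus recovers exactly the 10 planted edges, and the
frozen model transfers to the independent 41-subject cohort. In the
dynamic run the planted effect lives only in how fast coupling switches
between two fixed levels: variance-based CPM recovers all planted edges
(recall 1.00) while static CPM on the same recordings finds none of
them.

A library-level example:

```python
import numpy as np
from eegcpm import synth, cpm

beh = synth.normalize_behavior(synth.generate_behavior(90, seed=1000))
y = beh["c_total"].to_numpy()
planted = synth.PlantedEffect(tuple(range(5)), tuple(range(5, 10)),
                              effect_size=0.2, noise_sd=0.02)
mats = synth.generate_connectomes(90, 68, planted,
                                  synth.standardize_trait(y), seed=0)
report = cpm.run_internal_cv(mats, y, cpm.CVConfig(scheme="loo"))["combined"]
print(report.r, report.mae)          # pooled observed-vs-predicted
```

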