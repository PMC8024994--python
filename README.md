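# tactile-avatar

Personalized tactile-decision modelling: train a machine to reproduce one
person's tactile ranking of texture materials from piezoelectric touch and
slide signals.

## The problem

People rank textures from smooth/soft to rough inconsistently — both
between individuals and across their own repeated trials, especially for
mid-ranked materials that feel alike. A conventional classifier trained on
one-hot material labels learns to name the material and shows none of this
human decision structure. The *tactile avatar* approach instead trains the
network's softmax output to match a specific participant's **decision
histogram** per material (the distribution of ranks they assigned over
repeated trials), so the machine inherits both the person's average
decisions and their confusion pattern.

The package provides, end to end on synthetic data:

- a **simulator** of multiarray piezoelectric recordings for a ranked
  M-material library (touch transient whose initial slope grows with
  durometer hardness; sliding oscillation whose fundamental frequency is
  sliding velocity / surface pattern pitch);
- **feature extraction**: 400-sample touch window, 1–500 Hz sliding
  spectrum, initial-slope and pitch estimators
  (`pitch = velocity × inter-peak interval`, e.g. 4 cm/s × 0.01 s = 400 µm);
- a generative **psychophysics** model of forced full rankings (every trial
  a permutation of 1..M) with the cohort's S/D similar/dissimilar structure
  and decision metrics (per-participant decision RMSE, human–avatar RMSE,
  per-material decision std, histogram kurtosis);
- the dual-branch **network** (3×conv1d kernel 4 → maxpool 4; dense
  400→300 on the spectrum; trunk 400→200; softmax over M rank-sorted
  nodes; SGD momentum 0.9, decay 1e-6) in plain numpy, with histogram-MSE
  and categorical cross-entropy training modes;
- **decision scoring** via the expected-decision rule `round(Σ r·p_r)` and
  tolerance-bounded accuracy/error curves;
- **generalization** tools: leave-one-out prediction of untrained
  materials and convex (simplex-constrained) decomposition of an untrained
  histogram on the trained ones.

## Worked example

```python
from tactile_avatar import (
    SimulationConfig, build_material_library,
    sample_participant, simulate_decision_matrix,
)
from tactile_avatar.model import TactileAvatarModel

library = build_material_library(42, seed=11)          # ranked textures
config = SimulationConfig(seed=12)                     # 42 x 100 trials, 1.2 N, 4 cm/s
participant = sample_participant("S", 42, seed=13)     # a "similar"-group rater
matrix = simulate_decision_matrix(participant, 20)     # 20 full rankings

model = TactileAvatarModel.from_corpus(library, config, matrix)
results = model.fit(mode="histogram", epochs=60, seed=14)
print(results.summary())
```

```
Tactile Avatar Results
==============================================
loss mode                            histogram
materials                                   42
recordings (train/val)                3360/840
epochs                                      60
initial loss                          0.006902
final loss                            0.000036
tolerance                                    2
held-out accuracy                      100.0%
held-out decision error                  0.0%
mean |output - target| rank              0.209
==============================================
```

Reading: the network was fitted on 3360 recordings (80% of the corpus) to
this participant's 42 decision histograms; on the held-out 840 recordings
every expected decision landed within 2 ranks of the participant's mean
decision for that material (decision error 0.0% at tolerance 2), and the
per-material mean of the avatar's output distribution sits 0.24 ranks from
the human mean on average — the avatar reproduces the rater's decisions,
not just the material identities.

The same pipeline is scriptable from a shell (`tactile-avatar simulate`,
`cohort`, `train`, `evaluate`, `loo`, `report`; see `--help`).

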