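# Methods

## Problem and model

A *tactile avatar* is a machine trained to reproduce one person's tactile
rank decisions from sensor signals. The pipeline has four parts:

1. **Signal simulator.** Emulates a 30-cell piezoelectric fingertip sensor
   touched against and slid across each of M fabric-like materials that are
   ordered by a ground-truth smooth/soft → rough rank. The touch channel is
   a transient that rises linearly from contact onset at a slope
   `gain × force × (a + b·durometer)` (affine and increasing in durometer
   hardness, reflecting the measured proportionality between initial slope
   and hardness), peaks at `gain × force` volts, and decays exponentially
   with a configurable time constant (piezoelectric derivative response).
   The slide channel is a sum of a fundamental at `velocity / pitch` (4 cm/s
   over a 400 µm pitch gives 100 Hz), 2–4 overtones with geometrically
   decaying amplitudes, a frozen per-material broadband texture scaled by a
   roughness level that grows with rank, and white measurement noise.
2. **Features.** A 400-sample touch window anchored at contact onset
   (400 ms at 1000 samples/s) and a 500-bin magnitude spectrum of the slide
   trace on integer frequencies 1–500 Hz (demeaned, linearly interpolated,
   max-normalized per recording). Scalar analyses: the least-squares initial
   slope from onset to the first peak, and the pattern pitch as
   `velocity × median inter-peak interval`.
3. **Human ranking model.** A participant ranks M materials per trial by
   sorting latent utilities `true_rank + bias(m) + σ(m)·N(0,1)`, so each
   trial is a full permutation by construction. σ(m) is larger for
   middle-band materials (ranks 11–30 of 42; proportional bands at other M)
   than side-band ones, and "dissimilar" (D) participants have all σ and
   bias scales larger than "similar" (S) participants.
4. **Avatar network.** Dual-branch: touch 400 → three 1D convolutions
   (kernel 4, ReLU) → max-pool 4 → flatten; slide 500 → dense 400 → 300
   (ReLU); concatenated → dense 400 → 200 (ReLU) → dense M with softmax,
   output nodes sorted smooth/soft → rough. SGD with momentum 0.9 and decay
   1e-6. Two loss modes: mean-square error against the participant's
   per-material decision histogram (the avatar), or categorical
   cross-entropy against one-hot labels at the rounded mean decision (the
   conventional baseline).

Decisions are scored with the expected-decision rule
`round(Σ_r r · p_r)` (half away from zero) and tolerance-bounded accuracy:
a decision is correct when within the tolerance (rank units) of the
participant's real-valued mean decision for that material; decision error
is the complement. Generalization to an untrained material is evaluated by
(a) leave-one-out training and reading the held-out output distribution,
and (b) expressing the untrained histogram as the best convex combination
(weights ≥ 0, summing to 1) of trained histograms, scored by RMSE.

## Metrics

With `Tac_i(s, m)` the rank participant `s` assigns material `m` in trial
`i` (I trials, S participants, M materials):

- **Decision RMSE** (per participant): RMS over (m, i) of
  `Tac_i(s,m) − ref(m)`, where `ref(m)` is the grand mean over all
  participants and trials. Participants below the cohort-mean RMSE form
  group S, the rest group D (ties → D).
- **Human–avatar decision RMSE** (per material): RMS across participants of
  the difference between human and avatar trial-mean decisions.
- **Decision std** ("confusion", per participant and material): population
  standard deviation (divisor I) over trials.
- **Kurtosis** of a rank histogram: Pearson convention (normal = 3), the
  fourth standardized moment; undefined (error, not a number) for
  zero-variance histograms.

## Defaults and units

Traces are volts and seconds internally; pitch is µm at the interface.
Study-scale defaults: 42 materials, 100 recordings per material, 1.2 N
contact force, 4 cm/s sliding velocity, 1000 samples/s, 30 sensing cells,
10 participants (7 S / 3 D), 20 ranking trials.

Free parameters chosen once, with rationale:

- **Pitch library**: log-spaced 150–8000 µm (the order-of-magnitude span of
  fabric weave pitches; the two anchor measurements are 400 µm for a fine
  smooth weave and 4 mm for a coarse check). Inter-neighbour gaps in the
  middle band are compressed to 40% so mid-ranked materials are genuinely
  harder to tell apart. Durometer hardness spans 20–90 via a seeded shuffle,
  deliberately not monotone in rank (the measured smooth No. 2 was hard,
  85.1; the rough No. 38 soft, 24.9); the 5 hardness bins are 20–40, 41–50,
  51–60, 61–70, 71–90.
- **Slope map**: a = 2.0, b = 0.2 V/s per (N × gain) per durometer unit —
  arbitrary scale; only positivity of b (monotonicity) matters to any result.
- **Noise**: default measurement noise 0.05 of the signal peak per cell,
  i.i.d. Gaussian, plus 2% per-cell gain heterogeneity fixed per corpus.
  The broadband texture component is frozen per material so that a
  zero-noise corpus is exactly trial-repeatable.
- **Cohort noise geometry**: S-group σ = 0.8 (side) / 2.2 (middle) rank
  units; D multiplies σ by 2.2; bias scales 0.5 (S) / 1.5 (D). These
  reproduce the two robust cohort features: a 7/3 S/D split by RMSE and
  significantly higher middle-band confusion.
- **Network free choices** (the layer table fixes everything else): 8
  channels per conv layer; learning rate 2.0 for histogram-MSE and 0.05 for
  cross-entropy (the MSE loss averages over the M output nodes, so its
  gradient scale is ~M smaller); 60 epochs and batch 32 at study scale
  (the MSE-through-softmax loss plateaus early and converges late, so the
  epoch budget is sized for the late phase); reduced corpora in the
  property checks use proportionally adjusted epochs;
  He-normal initialization (Glorot for the output layer), valid-mode
  convolutions; stratified 80/20 train/validation split per material.
  Training is plain numpy and bit-reproducible from a seed on one thread.

## Numerical choices

- Contact onset: first index exceeding max(5 × leading-50-sample std,
  2% of trace peak) for 5 consecutive samples.
- Slope segment: onset to the first sample reaching 95% of the trace
  maximum (the global argmax wanders on noisy plateaus).
- Peak picking for pitch: scipy prominence ≥ 1 × trace std with a minimum
  separation of 60% of the dominant spectral period (overtones otherwise
  insert sub-period peaks). Sampling quantizes the interval to 1 ms, so at
  4 cm/s the estimate is quantized to 40 µm; recovery within 5% requires a
  pitch ≳ 600 µm (≥ 15 samples per period) at default noise.
- Spectrum: DC excluded; a max-normalization floor treats spectra whose
  peak is at round-off scale as zero rather than amplifying noise.
- Expected decision: the weighted mean is snapped to 9 decimals before
  rounding so an exact .5 boundary (e.g. a uniform distribution) is not
  perturbed by float accumulation; ties round half away from zero.
- Simplex decomposition: SLSQP with analytic gradient, ftol 1e-14; weights
  clipped and renormalized; verified against a dense grid-search oracle.
  RMSE = 0 (within 1e-8) iff the target is in the convex hull.
- Tie conventions: argmax ties take the lowest frequency; group split at
  exactly the mean RMSE assigns D.

## What the generator does and does not emulate

The simulator reproduces the signal-physical relationships the analysis
relies on (slope ∝ hardness, spectral peak at velocity/pitch, rank-graded
broadband roughness, middle-band similarity) and trial noise. It does not
model triboelectric contamination, temperature, finger-pressure variation,
nonstationary sliding velocity, or fabric deformation under shear —
passing tests therefore demonstrate that the pipeline recovers its own
generative structure and mimics the modelled rater, not that the network
would reach the same accuracy on physical sensor data.

Histogram-trained avatars preserve each material's target mean rank within
1 rank on clean corpora. Kurtosis mimicry is asserted within a factor of 2
on middle-band materials only: side-band histograms of a consistent rater
are nearly one-hot, and the fourth moment of a near-degenerate
distribution is ill-conditioned — tiny probability tails move it by orders
of magnitude — so agreement there is not numerically meaningful.

## Problem sizes used in the checks

The headline evaluation (reproducible via `scripts/acceptance.py`) runs
the full study scale: 42 × 100 recordings, one S participant, 60 epochs,
tolerance 2 on the held-out 20%. The property checks run reduced sizes
chosen as the smallest that exercise the effect cleanly: moment mimicry at
12 materials × 10 trials, the entropy contrast over 3 seeds at the same
scale, and leave-one-out over all materials at 14 materials × 8 trials × 5
seeds. The tolerance at which the headline error is quoted is 2, the
worked-example tolerance of the source protocol.

## Known limitations

- The MSE-through-softmax loss plateaus before converging when the number
  of SGD updates is small; reduced corpora need proportionally more epochs.
- Pitch estimation degrades below ~600 µm (sampling quantization) and for
  materials whose strongest overtone rivals the fundamental.
- The unconstrained decomposition variant is provided for sensitivity
  analysis only; its weights are not histograms.
- The 1-year re-test protocol is not modelled; human "prediction" curves
  for the tolerance-gap comparison must be supplied externally (the
  arithmetic itself is implemented and tested).
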