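# Methods

## The problem and the data model

The presomitic mesoderm (PSM) of the zebrafish tailbud is patterned by the
T-box transcription factors *tbxta*, *tbx16* and *tbx6* under the control of
posterior Wnt and FGF signalling. Two complementary data modalities exist:
time-lapse tracking of nuclei (position over ~2 h at 2-min intervals, 61
frames, no expression information) and fixed-sample HCR point clouds
(per-nucleus 3D position plus quantitative expression of all five channels,
no temporal information). `agetkit` combines them into per-cell
**approximated gene expression trajectories (AGETs)** and uses those to fit
a per-cell dynamical model of the T-box network.

Conventions used throughout: positions in µm with the posterior tip of the
PSM at the origin and the anteroposterior (A-P) axis along x; frames
1-based; normalized A-P position 0 = posterior tip, 1 = anterior limit;
channel order (tbxta, tbx16, tbx6, wnt, fgf).

## Expression-cloud processing

Segmented point clouds are post-processed numerically:

* **Thresholding** — per-channel lower bounds set sub-threshold values to 0.
  Threshold choice is data-dependent; a percentile rule (default: 20th
  percentile per channel) is provided as an explicit heuristic, and
  thresholds can be given directly in config.
* **Channel normalization** — each channel is divided by the maximum of its
  Savitzky–Golay-smoothed A-P profile (bin means over 50 bins, window 11
  bins, polynomial order 3), then capped at 1. Normalizing by the *smoothed*
  maximum prevents single bright nuclei from setting the scale. The cap
  keeps the [0, 1] invariant but means the recomputed profile maximum can
  sit slightly below 1 when raw values exceed the smoothed plateau (the
  usual case for monotone profiles); re-normalization drift is bounded by
  the capped mass and is below 0.005 on the synthetic data. Normalization
  is always per sample, never pooled.
* **A-P normalization** — x divided by its maximum, mapping positions to
  [0, 1].

Profiles interpolate interior empty bins linearly up to a run limit
(default 5 bins) and error beyond it.

## Registration

Each source cloud is mapped onto each time-lapse frame independently:

1. **A-P rescaling** — the source is scaled isotropically about the origin
   so its A-P extent matches the target frame's. Isotropic (rather than
   x-only) scaling preserves local neighbourhood geometry.
2. **Coarse initialization** — centroid matching plus principal-axis
   alignment with axes co-oriented against the global frame, so the A-P
   axes of the two clouds agree.
3. **Point-to-plane ICP** — alternating nearest-neighbour correspondence
   (k-d tree) and a linearized least-squares update of the rigid transform
   minimizing residuals along target normals; normals come from a local PCA
   plane fit of each target point's 20 nearest neighbours. Default 50
   iterations, correspondence cutoff 10% of the target A-P length. The
   iteration stops as soon as an update fails to reduce the inlier RMS, so
   the recorded RMS history is non-increasing. The rotation block is
   re-orthonormalized by SVD every update.
4. **Numeric QC** — an alignment is accepted iff inlier RMS ≤ 5% of the
   target A-P length *and* inlier fraction ≥ 0.5. A numeric gate replaces
   visual inspection because reproducibility requires an objective
   criterion; rejected (source, frame) pairs are dropped from expression
   assignment for that frame.

On noiseless 500-point clouds with random rigid perturbations (≤15°,
≤20% of extent), the composed recovered transform is within 1° and 1 µm of
the inverse ground truth in 100/100 trials.

## AGET construction

For each frame, each accepted source is moved by that frame's transform and
every tracked cell receives, per channel, the median of its 5 nearest
source points; the per-source medians are combined across sources by a
second median ("median of medians"). Mean and single-nearest variants are
provided; with `nearest`, the across-source combination takes the value
from the source holding the globally closest point. Distance ties at the
n-th neighbour break deterministically by lowest source-point index. A
frame must retain a configurable minimum number of accepted sources
(default 3, clamped to the number available). Only cells tracked through
every frame of the lapse are fitting-eligible; AGET values inherit the
[0, 1] range of the normalized sources. No temporal smoothing is applied
across frames.

## The GRN model

Each cell runs the same three-gene ODE (see README for the equations) with
24 shared parameters: W (3×3 gene→gene), E (2×3 signal→gene), production
rates R, decay rates λ > 0, and basal thresholds h. Initial gene levels are
the cell's first-frame AGET values; Wnt/FGF inputs are the cell's AGET
signal channels interpolated linearly between frames, making the system
non-autonomous. Signals are inputs only — their dynamics are not modelled —
and the system is deterministic with no cell–cell coupling.

**Integrator** — fixed-step classical RK4 with 10 sub-steps per frame
interval by default (4 in the large fitting runs; halving the step changes
endpoints by < 1e-6). Model time is dimensionless with the whole lapse
spanning 1.0 — the transit time of the fastest cell — which only fixes
units and cancels in recovery experiments as long as generator and fitter
share the grid. RK4 frame samples agree with a 1000-step-per-frame explicit
Euler oracle to < 1e-4 over random parameter draws. States are not clipped:
with g0 ≥ 0, R ≥ 0, λ > 0 trajectories cannot leave
[0, max(g0, R/λ)], which is asserted in tests rather than enforced.

## Inference

* **Likelihood** — Gaussian residuals between target and simulated gene
  values over all fitted cells, frames and genes:
  log L = −½ Σ (T − S)²/σ_a², with σ = (0.2, 0.2, 0.1) for
  (tbxta, tbx16, tbx6). The squared form follows the verbal definition of
  the distance ("squared distance"); a perfect fit scores exactly 0.
* **Priors** — independent uniform on [−200, 200]; R and λ restricted to
  [0, 200] (rates cannot be negative). The restricted set is configurable.
* **Sampler** — emcee's affine-invariant ensemble, vectorized so all
  walkers of a half-ensemble are simulated in one batched RK4 call.
  Defaults: 96 walkers, 10,000 steps, extendable in 10,000-step blocks.
  Walkers start in a small region of support (weights and h in [−1, 1],
  rates in [0.1, 2]) to avoid immediate −∞ at λ = 0. The AGET subset for
  fitting is a uniform random draw of eligible cells whose first-frame
  normalized A-P position is ≤ 0.85 (anterior-most cells are excluded
  because anterior *tbx6* down-regulation involves factors outside the
  model).
* **Convergence** — per-parameter two-sample Kolmogorov–Smirnov tests
  between an early window (steps −10000..−8000) and the final 5000 steps,
  rescaled proportionally for shorter chains; converged when ≥ 20 of 24
  parameters show no shift at p > 0.001. The K-S statistic is verified
  exactly against a brute-force empirical-CDF oracle.
* **Overall scores and MAP** — after convergence the likelihood of the
  final 2000 samples is recomputed against the *full* AGET set so runs
  fitted to different subset sizes are comparable; the MAP network is the
  retained sample with the highest score (ties break earliest).

## Posterior post-processing

Retained samples must come from converged runs, score ≥ −15000 overall, and
keep all 15 interaction weights within ±100. Survivors are z-scaled per
parameter (zero-variance parameters get scale 1) and k-means clustered with
10 restarts; k defaults to the elbow (maximum chord distance) of the
within-cluster sum-of-squares curve over k = 2..15 and is overridable.
Clusters holding < 5% of samples are masked, never relabelled, so
provenance indices survive the whole filter→cluster→prune pipeline.
Interaction-sign consensus reports the fraction of samples with each weight
> 0; exact zeros count as non-positive.

In-silico perturbations clamp one signal channel (e.g. Wnt = 1.5, FGF =
0.01) over the whole simulation and report per-cell final-frame gene
differences (perturbed − unperturbed) and their mean over cells.

## Synthetic embryo design

The generator emulates the pipeline's inputs, not its images:

* **Tissue geometry** — a tapered cylinder (default length 200 µm, radius
  40 µm, radius reduced 30% at the posterior tip). Shape is
  phenomenological; no morphogenesis is modelled.
* **Expression channels** — logistic functions of normalized A-P position:
  tbxta (midpoint 0.35), tbx16 (0.50), Wnt (0.55) and FGF (0.65)
  posterior-high, tbx6 anterior-high (0.55); steepness 8–10; Gaussian noise
  (sd 0.05) clipped to [0, 1]. Multiple source clouds jitter profile
  midpoints (`stage_jitter`) to emulate pooling embryos at nearby somite
  stages.
* **Tracks** — cells advect posteriorly→anteriorly with per-cell speeds
  drawn from N(0.6 L/T, 20%), where T is the lapse duration, plus Gaussian
  positional noise quadrupled inside the posterior 30% of the axis (the
  mixing zone). Cells are clipped to the tube. No division or ingression.
  Speeds and mixing amplitudes are order-of-magnitude choices; the source
  literature does not quantify them.
* **Ground-truth network** — sparse, with four strong interactions
  (Wnt→tbx16 +8, FGF→tbx16 +6, FGF⊣tbxta −8, tbx16→tbx6 +8), R = λ = 2 and
  gating thresholds h = (4, −7, −4) chosen so every gene traverses most of
  [0, 1] as cells transit the tissue. Ground-truth signal rules: Wnt is the
  axial logistic; FGF is additionally modulated by normalized radial
  position (floor 0.35 at the tissue surface scaling to 1 on the axis).
  The radial component exists for identifiability: two signals that are
  both monotone functions of the same axial coordinate are nearly collinear
  across cells, in which case only a linear combination of the E columns is
  constrained and individual signs are unrecoverable in principle. Initial
  gene levels come from a burn-in at frozen first-frame signals (span 5
  model-time units), so targets start on the slow manifold.

What passing recovery tests shows — and does not show: the inference
machinery can identify a sparse network from noiseless, model-generated
trajectories whose inputs vary independently. Real AGETs add measurement
noise, registration error, model misspecification and collinear signalling
gradients; recovery there is necessarily weaker, which is why the posterior
is analysed as filtered ensembles and sign-consensus fractions rather than
single point estimates.

## Problem sizes

Unit and property tests use 21-frame lapses with tens of tracks and
300–500-point clouds. The recovery experiment fits 25 cells × 61 frames
with 64 walkers × 3500 steps (the ensemble sampler needs > 2 × 24 walkers,
so the smallest admissible even count above threshold is used) and 4 RK4
sub-steps per frame. The fitted cells are drawn by the package's own
selection rule restricted to posterior starting positions (normalized A-P
≤ 0.5): those cells transit the signalling gradient during the lapse and
therefore constrain the network, whereas anterior starters experience
near-constant, near-zero signals and carry almost no information. The
acceptance script runs the same sizes end to end.

## Known limitations

* Registration is rigid; tissue deformation between fixed samples and any
  given frame is only absorbed by the A-P rescaling.
* The QC gate's thresholds (5% RMS, 0.5 inliers) are calibrated for frame
  clouds whose density resembles the source clouds; sparse targets need a
  looser config.
* The likelihood treats residuals as independent across frames, ignoring
  temporal autocorrelation of approximation error.
* k-means on z-scaled parameters imposes spherical cluster geometry;
  topology clusters should be read as a coarse partition, not as model
  selection.
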