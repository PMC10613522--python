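# Methods

## Overview

`cineseg` segments the eight blood-filled structures of the heart (LV,
RV, LA, RA, AO, PA, SVC, IVC; label 0 is background) on every frame of
a 4D cine CMR series, supervised only by manual annotations at
end-diastole (ED) and end-systole (ES). The package contains the whole
pipeline — pre-processing, network, propagation, weighted training,
evaluation — plus a synthetic phantom testbed with analytic oracles.

## Pre-processing

Frames are cropped with one shared bounding box (so the series stays a
valid 4D image) and intensity-normalized per frame with a two-anchor
linear map: the 5th percentile of in-box intensities stands in for the
lung signal and the 95th for the blood pool, and are mapped to 0 and 1
respectively, without clipping. The map is monotone and parameter-free;
because both anchors are computed inside the crop box, cropping and
normalization commute. A frame with a degenerate intensity range is
rejected rather than silently normalized.

ED/ES indices cannot be inferred reliably from images alone, so they
are mandatory sidecar inputs for real data; the phantom computes them
analytically (arg-max/arg-min of the combined LV+RV volume curve).

## Network

A 3D U-Net with `n_levels` resolution levels (default 4). Each level
applies two 3×3×3 convolutions, each followed by ReLU and then batch
normalization; levels are connected by 2×2×2 max pooling (encoder) and
nearest-neighbor 2× upsampling plus skip concatenation (decoder); a
1×1×1 convolution and voxel-wise softmax produce the 9 class channels.
With widths 16→32→64→128 the model has 1,461,129 trainable parameters.
Convolutions are "same"-padded so output shape equals input shape;
inputs whose extents are not divisible by 2^(n_levels−1) are
symmetrically zero-padded for prediction and the result cropped back.

Training uses a batch of one volume, so batch normalization reduces to
per-volume (instance-like) statistics. We use those per-volume
statistics at inference as well, which makes prediction deterministic
and independent of any running-average state.

The network, backpropagation, and the AMSGrad optimizer are implemented
directly in numpy. Convolution is evaluated as a sum of 27 shifted
channel-mixing matrix products (fast at small channel counts on CPU);
the backward pass reuses the cached shifted slices. All gradients are
validated against central finite differences in float64
(`tests/test_nn.py`). Weights use He initialization from a seeded
generator; every training entry point is reproducible bit-for-bit from
its seed on a fixed platform.

## Loss and sampling

The cohort-level models (supervised, all-frames baseline, and the final
semi-supervised model) minimize weighted cross-entropy with inverted
class frequencies: `w_c ∝ 1/f_c`, normalized so `Σ w_c = n_classes`,
with `f_c` pooled over the training labels. A class absent from the
pool has its count floored at one voxel (structures can be genuinely
missing in congenital disease) with a warning.

Supervised training samples one subject uniformly, then one of its
labeled frames uniformly, and takes one optimizer step per draw
(AMSGrad; the clinical-scale default learning rate is 3e-4). The
all-frames baseline first trains on ED/ES, then pseudo-labels every
remaining frame with that model (hard argmax), then re-initializes and
retrains with every pooled frame equally likely.

## Label propagation

Frame indices are cyclic. Every frame is claimed by the nearer of the
two anchors (ED or ES; ties go to ED — the canonical 30-frame case with
anchors 15 apart never produces a tie, but general inputs can). Step 1
pseudo-labels all frames at cyclic distance ≤ k (default 3) from their
anchor; step s ≥ 2 extends the radius by `step` (default 2) per side.
Certainty level = 1 for ED/ES, 1+s for frames labeled at step s; for
F = 30 this yields levels of sizes 2/12/8/8. The level count is derived
from F, k and step, not fixed at four.

The per-subject propagator network is, by default, trained from
scratch at every step on all currently labeled frames
(`propagator_iterations` optimizer steps each), keeping the steps
independent of each other's optimization state. A warm-start mode
(`warm_start=True`) instead refines the previous step's weights on the
grown pool (`propagator_refine_iterations` steps per extension), which
at small iteration budgets gives much better pseudo-labels per unit
compute — the desk-scale experiment uses it for exactly that reason
(measured on the phantom: warm-started level-2 pseudo-labels reach
Dice ≈ 0.9 where equally priced from-scratch propagators stay near
0.7).

Two further propagator-specific choices matter at small budgets:

- **Unweighted cross-entropy.** Inverse-frequency weighting leaves
  background false positives almost unpenalized (background carries
  ~95% of voxels, hence a weight near 0.01). An under-converged
  propagator trained that way systematically dilates structures, and
  the dilation compounds across propagation steps — pseudo-labels ended
  up with about three times the true foreground volume in our phantom
  studies. The propagator's task is boundary-accurate reproduction of a
  single subject, not class-imbalance robustness, so it trains with
  uniform class weights. The cohort-level models keep the
  inverse-frequency loss.
- **No augmentation.** The propagator must fit a handful of frames of
  one subject; augmentation slows that convergence considerably and
  adds nothing to within-subject generalization over a few frames of
  smooth motion.

Pseudo-labels are hard argmax maps and are consumed exactly like manual
labels downstream.

## Certainty-weighted semi-supervised training

Each frame's sampling weight is `w(i) = 2^(1−i)` in its certainty level
`i` (configurable; any strictly decreasing positive map is accepted).
Per iteration one subject is drawn uniformly, then two distinct frames
by the level-weighted law, each giving one single-volume optimizer step
(preserving the instance-norm behavior). Loss weights are recomputed
from all frames' labels, manual and pseudo. For the canonical level
sizes (2, 12, 8, 8) the per-frame probabilities are 1/11, 1/22, 1/44,
1/88.

## Evaluation

Dice is `2|A∩B|/(|A|+|B|)` per structure, with the both-empty case
defined as 1 (perfect agreement on absence — relevant when a structure
is genuinely missing); the whole-heart summary is the unweighted mean
over the eight structures. Volumes are voxel counts times voxel volume
(ml); EF is `100·(EDV−ESV)/EDV` with domain checks. Volume-difference
summaries report mean ± SD in ml and in percent of a per-subject
normalizer: the reference EDV for ventricles, the largest reference
volume over the cycle for atria. Paired comparisons screen the
differences with Shapiro-Wilk at α = 0.05 and use a paired two-tailed
t-test for Gaussian-looking differences, otherwise a Wilcoxon
signed-rank test; all-zero differences return p = 1 with a warning
(the signed-rank statistic is undefined there).

Per-structure Dice is reported as the mean of per-frame values. (Frame
pooling before averaging would weight frames by structure size; both
conventions coincide on the phantom to within the reported precision.)

## The phantom

The phantom emulates what the method assumes about real data — cyclic
smooth motion, bright blood pool over dark background, multi-structure
spatial layout — with enough realism to exercise every code path:

- **Geometry.** LV/RV/LA/RA are ellipsoids in two anatomical tiers;
  AO/PA/SVC/IVC are straight capsules (cylinder + hemispherical caps)
  rising from the base, with the RA–SVC/IVC adjacency preserved.
  Analytic gaps guarantee non-overlap at maximal dilation; overlap is
  still checked at voxelization and raises.
- **Motion.** Radii follow `r(t) = r0·(1 − a·(1+cos(2πt/F + φ))/2)`;
  ventricles share φ = 0, atria φ = π (counter-phase filling). Default
  amplitudes ~0.25 (ventricles) and ~0.20 (atria) give an EF near
  1−(1−a)³ ≈ 58%, a realistic value. Vessels are static.
- **Intensity.** Blood 480, background 60, additive Gaussian noise
  σ = 24 (5% of blood), and a smooth multiplicative bias field (±10%)
  from upsampled coarse noise — enough to make the normalization step
  meaningful.
- **Cohorts.** `random_phantom_config` jitters chamber centers (±1% of
  the grid), scales radii (±5%) and draws per-subject motion
  amplitudes, giving anatomically distinct subjects with guaranteed
  non-overlap.

What the phantom does **not** model: myocardium and trabeculation,
valve anatomy, through-plane motion/twist, acquisition physics
(k-space, SENSE artifacts), and pathology (single ventricle, common
atrium, dextrocardia). Passing phantom tests therefore demonstrates the
pipeline's correctness and its behavior under the stated statistical
assumptions, not clinical-grade accuracy on congenital heart disease.

Every chamber has a closed-form volume curve, so voxel-counted
volumetry is testable to voxelization error: ≤ 5% at radii ≥ 6 voxels
(the 48³ configurations), looser at desk-scale 24³ grids.

## Desk-scale experiment

`cineseg.experiment` runs the three arms end to end on a phantom
cohort: 6 training + 2 held-out subjects, 24³ grids, 30 frames, a small
two-level network (base width 6, ~59k parameters), learning rate 2e-2,
260 iterations per cohort training stage, warm-started propagators
(220 + 90 + 90 iterations per subject), and intensity-only augmentation
(scale/shift/noise; geometric augmentation and flips add nothing for a
fixed-chirality phantom cohort at these budgets and slow convergence).
These problem sizes keep a full three-arm, five-seed study within
desk-scale CPU minutes while preserving the method's structure: only
ED and ES carry manual labels, everything else must be earned by
propagation.

The learning rate is deliberately larger than the clinical-scale
default (3e-4): a ~60k-parameter network fitting 24³ volumes within a
few hundred iterations sits in a very different optimization regime
than a 1.5M-parameter model trained for days.

## Numerical and degenerate-input choices

- Normalization anchors equal (constant frame) → error, no fallback.
- Zero-motion phantom: ED/ES fall back to frames 0 and F/2 (the curve
  has no extremes), so the pipeline still runs.
- Both-empty Dice = 1; all-zero paired differences → p = 1 + warning.
- Maxpool ties break toward the first block element (argmax order);
  gradient flows to exactly one voxel per pooled block.
- Softmax is computed with max-subtraction; cross-entropy clamps
  probabilities at 1e-12.
- Schedules: tie frames (equidistant from both anchors) belong to ED.

## Known limitations

- The numpy network trains on CPU only; clinical-resolution volumes
  (~128³ × 1.5M parameters) are out of reach at useful speeds.
- Pseudo-label quality on the phantom decays mildly with propagation
  distance; with warm-started propagators the decay is partly offset by
  the growing training pool, so the level-2 vs level-4 gap is smaller
  than a from-scratch schedule would show.
- The paired-test module implements the comparison recipe but the
  phantom studies mostly exercise its branch selection, not its
  clinical power.
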