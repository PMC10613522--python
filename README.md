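# cineseg

Semi-supervised whole-heart and great-vessel segmentation of 4D (3D +
time) cine cardiac MR images.

## The problem

A 3D cine CMR acquisition yields ~30 isotropic 3D frames covering one
cardiac cycle. Segmenting eight structures — left/right ventricle (LV,
RV), left/right atrium (LA, RA), aorta (AO), pulmonary artery (PA), and
the superior/inferior venae cavae (SVC, IVC) — on every frame enables
full-cycle volumetry and ejection-fraction measurement, but manual
annotation of all frames is prohibitively expensive. In practice only
the end-diastolic (ED) and end-systolic (ES) frames are traced.

`cineseg` implements a semi-supervised pipeline that turns those two
annotated frames into training labels for the whole cycle:

1. **3D U-Net** — a compact encoder–decoder (four resolution levels,
   two 3×3×3 conv → ReLU → batch-norm stages per level, 2×2×2 max
   pooling, nearest-neighbor upsampling, skip concatenations, 1×1×1
   softmax head; ≈1.46 M parameters at the default widths), implemented
   in pure numpy with hand-derived backpropagation and an AMSGrad
   optimizer.
2. **Iterative label propagation** — per subject, a *propagator*
   network is trained on the currently labeled frames and used to
   segment the `k = 3` nearest neighbors of ED and ES (cyclic frame
   distance); those pseudo-labels join the pool and the propagator is
   extended two frames per side per step until the cycle is covered.
   Each frame receives a *certainty level*: 1 for ED/ES, `1 + s` for
   frames labeled at step `s`.
3. **Certainty-weighted training** — the final model trains on all
   frames of all subjects, sampling subjects uniformly and frames with
   probability proportional to `w(level)`, halving per level by
   default, so less reliable pseudo-labels contribute less.
4. **Evaluation** — per-structure, per-frame Dice
   `DSC = 2|A∩B| / (|A|+|B|)`, whole-heart mean over the eight
   structures, chamber volume curves (voxel count × voxel volume),
   ejection fraction `EF = 100·(EDV−ESV)/EDV`, volume-difference
   summaries, and Shapiro-Wilk-gated paired tests (t-test vs Wilcoxon).

Because clinical cine data cannot be redistributed, the package ships a
**synthetic beating-heart phantom**: eight non-overlapping structures
(ellipsoidal chambers, capsule vessels) with cyclic cosine motion —
ventricles and atria in counter-phase — blood-bright intensities,
Gaussian noise and a smooth multiplicative bias field. Every chamber
has a closed-form volume curve, so volumetry and EF have exact oracles.

## Worked example

Generate a phantom subject, propagate its ED/ES labels through the
cycle, and evaluate the pseudo-labels against the phantom ground truth:

```python
from cineseg.cine_io import normalize_intensity
from cineseg.evaluation import dice_per_structure, mean_dice
from cineseg.network import NetworkConfig
from cineseg.phantom import generate_phantom, random_phantom_config
from cineseg.propagation import ScheduleConfig, build_schedule, propagate_labels
from cineseg.train import TrainConfig

series, labels = generate_phantom(random_phantom_config(0, grid_size=24))
series = normalize_intensity(series)

schedule = build_schedule(ScheduleConfig(
    n_frames=30, ed_index=series.ed_index, es_index=series.es_index, k=3, step=2))
print([sorted(s.predict_frames) for s in schedule.steps])

states = propagate_labels(
    series, labels[series.ed_index], labels[series.es_index], schedule,
    NetworkConfig(n_levels=2, base_channels=6, n_classes=9),
    TrainConfig(learning_rate=2e-2, seed=0, augmentation=None,
                propagator_iterations=250, propagator_refine_iterations=100),
    warm_start=True)
for level in (2, 3, 4):
    ds = [mean_dice(dice_per_structure(st.label, labels[st.frame_index]).values())
          for st in states if st.level == level]
    print(f"level {level}: mean pseudo-label Dice {sum(ds)/len(ds):.3f}")
```

With ED at frame 15 and ES at frame 0 (the phantom's analytic extremes)
the schedule prints three steps of 12, 8 and 8 frames, and the
propagation run prints per-level pseudo-label quality, e.g.

```
[[1, 2, 3, 12, 13, 14, 16, 17, 18, 27, 28, 29], [4, 5, 10, 11, 19, 20, 25, 26], [6, 7, 8, 9, 21, 22, 23, 24]]
level 2: mean pseudo-label Dice 0.818
level 3: mean pseudo-label Dice 0.836
level 4: mean pseudo-label Dice 0.849
```

Every frame of the cycle now carries a usable label, earned from just
two annotated frames. The certainty level records how far each label
was propagated; pooled over a multi-subject cohort, level-2 labels
(nearest the anchors) average the highest Dice — propagation error
accumulates with cyclic distance — though warm-started refinement can
locally offset the decay, as on this subject. The full three-arm
comparison
(supervised ED/ES-only vs semi-supervised vs all-frames self-training)
is available as `cineseg run --arm semi ... --out results/` or
programmatically via `cineseg.experiment.run_experiment`.

## Command line

```
cineseg phantom generate --out subj0/ --seed 0 --grid-size 32
cineseg propagate --subject subj0/ --k 3 --step 2 --out labels0/
cineseg evaluate --pred labels0/ --ref subj0/ --out report.csv
cineseg run --seed 0 --out results/        # all three arms + report.json
```

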