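"""Supervised training on annotated frames, plus the all-frames baseline.

Training follows the regime the network was designed for: batches of a
single 3D volume, AMSGrad at learning rate 3e-4, and weighted
cross-entropy whose per-class weights are the inverted pooled class
frequencies of the training labels (small structures get large weights).

`train_all_frames_baseline` is the three-stage self-training comparator:
train on ED/ES, pseudo-label every other frame with that model, then
retrain from scratch on the pooled set with every frame equally likely.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._nn import weighted_cross_entropy
from .cine_io import CineSeries, LabelMap, N_CLASSES
from .network import ModelHandle, NetworkConfig, build_unet, make_optimizer, predict_labels


@dataclass
class AugmentConfig:
    """Random affine + intensity augmentation ranges.

    The same geometric transform is applied to image and label map
    (labels with nearest-neighbor interpolation, so the vocabulary is
    preserved).  All ranges are symmetric around the identity.
    """

    rotation_deg: float = 10.0
    shear: float = 0.1
    translation_vox: float = 5.0
    intensity_scale: float = 0.1
    intensity_shift: float = 0.1
    noise_sigma: float = 0.02
    flip_lr_prob: float = 0.5
    flip_ap_prob: float = 0.5

    def __post_init__(self):
        for p in (self.flip_lr_prob, self.flip_ap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    n_iterations: int = 500
    propagator_iterations: int = 150
    propagator_refine_iterations: int = 100
    seed: int = 0
    augmentation: AugmentConfig | None = field(default_factory=AugmentConfig)
    loss_weights: np.ndarray | None = None
    validation_interval: int = 0


def class_frequency_weights(labelmaps, n_classes: int = N_CLASSES) -> np.ndarray:
    """Inverse-frequency class weights, normalized to sum to ``n_classes``.

    ``w_c`` is proportional to ``1/f_c`` with ``f_c`` the pooled voxel
    fraction of class ``c`` over all given label maps.  A class absent
    from the pool (anatomically possible in congenital disease, e.g. a
    missing chamber) has its count floored at one voxel with a warning.
    """
    counts = np.zeros(n_classes, dtype=np.float64)
    for lm in labelmaps:
        vox = lm.voxels if isinstance(lm, LabelMap) else np.asarray(lm)
        counts += np.bincount(vox.ravel(), minlength=n_classes)[:n_classes]
    absent = counts == 0
    if absent.any():
        warnings.warn(
            f"classes {np.flatnonzero(absent).tolist()} absent from training "
            "labels; flooring their frequency at one voxel",
            stacklevel=2,
        )
        counts[absent] = 1.0
    inv = 1.0 / (counts / counts.sum())
    return inv / inv.sum() * n_classes


def _random_affine_matrix(cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    rot = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg, 3))
    mats = []
    for axis, ang in enumerate(rot):
        c, s = math.cos(ang), math.sin(ang)
        m = np.eye(3)
        i, j = [a for a in range(3) if a != axis]
        m[i, i], m[i, j], m[j, i], m[j, j] = c, -s, s, c
        mats.append(m)
    mat = mats[0] @ mats[1] @ mats[2]
    shear = np.eye(3)
    for i in range(3):
        for j in range(3):
            if i != j:
                shear[i, j] = rng.uniform(-cfg.shear, cfg.shear)
    return mat @ shear


def augment(
    volume: np.ndarray,
    labels: np.ndarray,
    cfg: AugmentConfig,
    draw_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One random augmentation draw, reproducible from ``draw_seed``."""
    if volume.shape != labels.shape:
        raise ValueError("volume and labels must have the same shape")
    rng = np.random.default_rng(draw_seed)
    mat = _random_affine_matrix(cfg, rng)
    shift = rng.uniform(-cfg.translation_vox, cfg.translation_vox, 3)
    if np.allclose(mat, np.eye(3)) and np.allclose(shift, 0.0):
        vol, lab = volume, labels  # identity transform: nothing to resample
    else:
        center = (np.asarray(volume.shape) - 1) / 2.0
        # affine_transform maps output coords through `mat` + offset into input
        offset = center - mat @ center - mat @ shift
        vol = ndimage.affine_transform(
            volume, mat, offset=offset, order=1, mode="nearest"
        )
        lab = ndimage.affine_transform(
            labels, mat, offset=offset, order=0, mode="nearest", output=labels.dtype
        )
    if rng.uniform() < cfg.flip_lr_prob:
        vol, lab = vol[::-1], lab[::-1]
    if rng.uniform() < cfg.flip_ap_prob:
        vol, lab = vol[:, ::-1], lab[:, ::-1]
    scale = 1.0 + rng.uniform(-cfg.intensity_scale, cfg.intensity_scale)
    shift_i = rng.uniform(-cfg.intensity_shift, cfg.intensity_shift)
    vol = vol * scale + shift_i
    if cfg.noise_sigma > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sigma, vol.shape)
    return np.ascontiguousarray(vol, dtype=np.float32), np.ascontiguousarray(lab)


def _training_step(model, opt, volume, labels, weights, aug, draw_seed):
    if aug is not None:
        volume, labels = augment(volume, labels, aug, draw_seed)
    logits = model.net.forward(volume)
    loss, dlogits = weighted_cross_entropy(logits, labels, weights)
    opt.zero_grad()
    model.net.backward(dlogits)
    opt.step()
    return loss


def train_on_frames(
    subjects: list[tuple[CineSeries, dict[int, LabelMap]]],
    net: NetworkConfig,
    cfg: TrainConfig,
    n_iterations: int | None = None,
    model: ModelHandle | None = None,
    rng_seed: int | None = None,
) -> ModelHandle:
    """Train a network on the labeled frames of the given subjects.

    Per iteration one subject is drawn uniformly, then one of its labeled
    frames uniformly; the (augmented) volume/label pair yields a single
    optimizer step.  Volumes are expected to be intensity-normalized.
    Fully reproducible from ``cfg.seed``.

    By default a fresh network is initialized from ``cfg.seed``; passing
    an existing ``model`` continues training it (with a fresh optimizer
    state), which the propagation loop uses to refine a propagator as
    its training set grows.
    """
    labeled = [(s, sorted(lab)) for s, lab in subjects if lab]
    if not labeled or any(not lab for _, lab in subjects):
        raise ValueError("every subject must have at least one labeled frame")
    weights = cfg.loss_weights
    if weights is None:
        weights = class_frequency_weights(
            [lm for _, lab in subjects for lm in lab.values()], net.n_classes
        )
    if model is None:
        model = build_unet(net, cfg.seed)
    opt = make_optimizer(model, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)
    iters = cfg.n_iterations if n_iterations is None else n_iterations
    for _ in range(iters):
        si = rng.integers(len(subjects))
        series, lab = subjects[si]
        fi = sorted(lab)[rng.integers(len(lab))]
        loss = _training_step(
            model, opt, series.frames[fi], lab[fi].voxels,
            weights, cfg.augmentation, int(rng.integers(2 ** 31)),
        )
        model.loss_trace.append(loss)
    return model


def baseline_frame_accounting(
    n_subjects: int, frames_per_subject: int, labeled_per_subject: int = 2
) -> tuple[int, int]:
    """(pseudo-labeled frames, pooled training frames) of the baseline."""
    n_pseudo = n_subjects * (frames_per_subject - labeled_per_subject)
    return n_pseudo, n_pseudo + n_subjects * labeled_per_subject


def train_all_frames_baseline(
    subjects: list[tuple[CineSeries, dict[int, LabelMap]]],
    net: NetworkConfig,
    cfg: TrainConfig,
    stage1_model: ModelHandle | None = None,
) -> tuple[ModelHandle, dict]:
    """Three-stage all-frames self-training baseline.

    Stage 1 trains on the manually labeled (ED/ES) frames; stage 2
    predicts hard pseudo-labels for every remaining frame; stage 3
    re-initializes and trains on the pooled set with uniform per-frame
    sampling and re-inverted class weights.  A pre-trained stage-1 model
    (same config and seed) may be supplied to avoid retraining.
    """
    if stage1_model is None:
        stage1_model = train_on_frames(subjects, net, cfg)
    pooled: list[tuple[int, int, LabelMap, bool]] = []
    n_pseudo = 0
    for si, (series, lab) in enumerate(subjects):
        for fi in range(series.n_frames):
            if fi in lab:
                pooled.append((si, fi, lab[fi], False))
            else:
                pred = predict_labels(stage1_model, series.frames[fi])
                pooled.append((si, fi, LabelMap(pred, series.spacing_mm), True))
                n_pseudo += 1
    accounting = {
        "n_pseudo": n_pseudo,
        "n_pooled": len(pooled),
        "expected": baseline_frame_accounting(
            len(subjects), subjects[0][0].n_frames,
            len(subjects[0][1]),
        ),
    }
    weights = class_frequency_weights([p[2] for p in pooled], net.n_classes)
    model = build_unet(net, cfg.seed + 1)  # "a new network": fresh weights
    opt = make_optimizer(model, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    for _ in range(cfg.n_iterations):
        si, fi, lm, _ = pooled[rng.integers(len(pooled))]
        loss = _training_step(
            model, opt, subjects[si][0].frames[fi], lm.voxels,
            weights, cfg.augmentation, int(rng.integers(2 ** 31)),
        )
        model.loss_trace.append(loss)
    return model, accounting
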