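"""Certainty-weighted semi-supervised training on propagated labels.

After propagation every frame of every subject carries a label and a
certainty level (1 = manual ED/ES, higher = pseudo-labeled further from
the anchors, hence less reliable).  Training compensates for the
accumulated propagation error by sampling frames with probabilities that
decrease with level — the default policy halves the weight per level,
``w(i) = 2**(1 - i)`` — while subjects are drawn uniformly.  Each
iteration samples one subject and two distinct frames from it; every
sampled frame gives one single-volume optimizer step, preserving the
instance-normalization behavior of batch-of-one training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ModelHandle, NetworkConfig, build_unet, make_optimizer
from .propagation import FrameLabelState
from .train import TrainConfig, _training_step, class_frequency_weights


@dataclass
class SamplingPolicy:
    """Level-based frame sampling weights; must strictly decrease."""

    level_weight: dict = field(default_factory=dict)
    frames_per_iteration: int = 2

    def weight(self, level: int) -> float:
        if self.level_weight:
            return float(self.level_weight[level])
        return 2.0 ** (1 - level)

    def validate(self, levels) -> None:
        ws = [self.weight(l) for l in sorted(set(levels))]
        if any(w <= 0 for w in ws):
            raise ValueError("sampling weights must be positive")
        if any(b >= a for a, b in zip(ws, ws[1:])):
            raise ValueError("sampling weights must strictly decrease with level")


def frame_probabilities(
    states: list[FrameLabelState], policy: SamplingPolicy
) -> np.ndarray:
    """Per-frame sampling probabilities ``p(t) = w(level_t) / sum w``."""
    if not states:
        raise ValueError("no frames")
    w = np.array([policy.weight(st.level) for st in states], dtype=np.float64)
    return w / w.sum()


def sample_batch(
    dataset: list[list[FrameLabelState]],
    policy: SamplingPolicy,
    rng: np.random.Generator,
) -> tuple[int, list[int]]:
    """Draw (subject index, frame indices) for one training iteration.

    The subject is uniform over the dataset; frames are drawn without
    replacement within the iteration according to the level weights.
    """
    si = int(rng.integers(len(dataset)))
    states = dataset[si]
    if len(states) < policy.frames_per_iteration:
        raise ValueError("subject has fewer frames than frames_per_iteration")
    p = frame_probabilities(states, policy)
    picks = rng.choice(len(states), size=policy.frames_per_iteration,
                       replace=False, p=p)
    return si, [states[i].frame_index for i in picks]


def train_semisupervised(
    dataset: list[tuple],  # (CineSeries, list[FrameLabelState])
    net: NetworkConfig,
    cfg: TrainConfig,
    policy: SamplingPolicy | None = None,
) -> ModelHandle:
    """Train the final model on all frames with certainty-weighted sampling.

    Loss weights are the inverted class frequencies pooled over *all*
    frames' labels (manual and pseudo).  Reproducible from ``cfg.seed``.
    """
    if policy is None:
        policy = SamplingPolicy()
    for series, states in dataset:
        if len(states) != series.n_frames:
            raise ValueError(
                f"subject {series.subject_id}: {len(states)} labeled frames "
                f"for {series.n_frames} frames — propagation incomplete"
            )
    policy.validate([st.level for _, states in dataset for st in states])
    weights = cfg.loss_weights
    if weights is None:
        weights = class_frequency_weights(
            [st.label for _, states in dataset for st in states], net.n_classes
        )
    model = build_unet(net, cfg.seed)
    opt = make_optimizer(model, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    state_lists = [states for _, states in dataset]
    by_index = [{st.frame_index: st for st in states} for states in state_lists]
    for _ in range(cfg.n_iterations):
        si, frames = sample_batch(state_lists, policy, rng)
        series = dataset[si][0]
        for fi in frames:
            loss = _training_step(
                model, opt, series.frames[fi], by_index[si][fi].label.voxels,
                weights, cfg.augmentation, int(rng.integers(2 ** 31)),
            )
            model.loss_trace.append(loss)
    return model
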