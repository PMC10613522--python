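"""Loss weighting, augmentation, supervised training, and the
all-frames baseline's frame accounting."""

import numpy as np
import pytest

from cineseg.cine_io import LabelMap
from cineseg.network import NetworkConfig
from cineseg.train import (
    AugmentConfig,
    TrainConfig,
    augment,
    baseline_frame_accounting,
    class_frequency_weights,
    train_all_frames_baseline,
    train_on_frames,
)


def _lm(arr):
    return LabelMap(np.asarray(arr, dtype=np.int16), np.ones(3))


class TestClassWeights:
    def test_two_class_worked_example(self):
        """Counts 900/100 -> inverse frequencies normalized to sum 2 give
        weights (0.2, 1.8)."""
        vox = np.concatenate([np.zeros(900), np.ones(100)]).astype(np.int16)
        w = class_frequency_weights([_lm(vox.reshape(10, 10, 10))], n_classes=2)
        assert w == pytest.approx([0.2, 1.8])

    def test_equal_frequencies_give_unit_weights(self):
        vox = np.repeat(np.arange(4), 250).astype(np.int16).reshape(10, 10, 10)
        w = class_frequency_weights([_lm(vox)], n_classes=4)
        assert w == pytest.approx([1, 1, 1, 1])

    def test_three_class_hand_normalization(self):
        counts = (800, 150, 50)
        vox = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        w = class_frequency_weights([_lm(vox.reshape(10, 10, 10).astype(np.int16))],
                                    n_classes=3)
        inv = np.array([1 / 0.8, 1 / 0.15, 1 / 0.05])
        assert w == pytest.approx(inv / inv.sum() * 3)

    def test_weight_times_frequency_is_constant(self, rng):
        vox = rng.integers(0, 5, size=(12, 12, 12)).astype(np.int16)
        w = class_frequency_weights([_lm(vox)], n_classes=5)
        f = np.bincount(vox.ravel(), minlength=5) / vox.size
        prod = w * f
        assert np.allclose(prod, prod[0])

    def test_absent_class_floored_with_warning(self):
        vox = np.zeros((6, 6, 6), dtype=np.int16)
        with pytest.warns(UserWarning, match="absent"):
            w = class_frequency_weights([_lm(vox)], n_classes=3)
        assert np.all(w > 0)
        assert w[0] < w[1]  # missing structures get the largest weights


class TestAugment:
    def _data(self, rng, n=12):
        vol = rng.normal(size=(n, n, n)).astype(np.float32)
        lab = rng.integers(0, 4, size=(n, n, n)).astype(np.int16)
        return vol, lab

    def test_all_ranges_zero_is_identity(self, rng):
        vol, lab = self._data(rng)
        cfg = AugmentConfig(rotation_deg=0, shear=0, translation_vox=0,
                            intensity_scale=0, intensity_shift=0, noise_sigma=0,
                            flip_lr_prob=0, flip_ap_prob=0)
        v2, l2 = augment(vol, lab, cfg, draw_seed=1)
        assert np.allclose(v2, vol)
        assert np.array_equal(l2, lab)

    def test_forced_flip_is_involution(self, rng):
        vol, lab = self._data(rng)
        cfg = AugmentConfig(rotation_deg=0, shear=0, translation_vox=0,
                            intensity_scale=0, intensity_shift=0, noise_sigma=0,
                            flip_lr_prob=1.0, flip_ap_prob=0)
        v1, l1 = augment(vol, lab, cfg, draw_seed=1)
        v2, l2 = augment(v1, l1, cfg, draw_seed=2)
        assert np.allclose(v2, vol)
        assert np.array_equal(l2, lab)

    def test_reproducible_per_draw_seed(self, rng):
        vol, lab = self._data(rng)
        cfg = AugmentConfig()
        a = augment(vol, lab, cfg, draw_seed=42)
        b = augment(vol, lab, cfg, draw_seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = augment(vol, lab, cfg, draw_seed=43)
        assert not np.array_equal(a[1], c[1])

    def test_geometric_transform_keeps_vocabulary_and_alignment(self, rng):
        """Image and labels share one spatial transform: a structure mask
        carried through the intensity channel lands on the transformed
        label mask; nearest-neighbor keeps the label vocabulary."""
        lab = np.zeros((16, 16, 16), dtype=np.int16)
        lab[4:9, 5:10, 6:11] = 2
        vol = (lab == 2).astype(np.float32)
        cfg = AugmentConfig(rotation_deg=20, shear=0.1, translation_vox=3,
                            intensity_scale=0, intensity_shift=0, noise_sigma=0,
                            flip_lr_prob=0.5, flip_ap_prob=0.5)
        v2, l2 = augment(vol, lab, cfg, draw_seed=9)
        assert set(np.unique(l2)) <= {0, 2}
        agreement = ((v2 > 0.5) == (l2 == 2)).mean()
        assert agreement > 0.98

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(np.zeros((4, 4, 4), dtype=np.float32),
                    np.zeros((4, 4, 5), dtype=np.int16), AugmentConfig(), 0)


@pytest.fixture(scope="module")
def tiny_setup(small_phantom_normalized):
    _, series, labels = small_phantom_normalized
    ed, es = series.ed_index, series.es_index
    subjects = [(series, {ed: labels[ed], es: labels[es]})]
    net = NetworkConfig(n_levels=2, base_channels=4, n_classes=9)
    return subjects, net


class TestTrainOnFrames:
    def test_loss_decreases(self, tiny_setup):
        subjects, net = tiny_setup
        cfg = TrainConfig(learning_rate=1e-2, n_iterations=150, seed=0,
                          augmentation=None)
        model = train_on_frames(subjects, net, cfg)
        trace = np.array(model.loss_trace)
        assert trace[-20:].mean() < trace[:5].mean()

    def test_loss_trace_reproducible(self, tiny_setup):
        subjects, net = tiny_setup
        cfg = TrainConfig(learning_rate=1e-2, n_iterations=40, seed=7)
        t1 = train_on_frames(subjects, net, cfg).loss_trace
        t2 = train_on_frames(subjects, net, cfg).loss_trace
        assert t1 == t2

    def test_empty_labeled_set_rejected(self, tiny_setup):
        subjects, net = tiny_setup
        series = subjects[0][0]
        with pytest.raises(ValueError):
            train_on_frames([(series, {})], net, TrainConfig(n_iterations=1))


class TestAllFramesBaseline:
    def test_paper_scale_frame_accounting(self):
        """74 subjects x 30 frames with 2 labels each: 2,072 predicted
        pseudo frames pooled into 2,220 training frames."""
        assert baseline_frame_accounting(74, 30) == (2072, 2220)

    def test_degenerate_two_frame_subject(self):
        assert baseline_frame_accounting(1, 2) == (0, 2)

    def test_three_subjects_ten_frames(self):
        assert baseline_frame_accounting(3, 10) == (24, 30)

    def test_end_to_end_accounting_on_small_cohort(self):
        """Stage 2 of the baseline really predicts every unlabeled frame:
        3 subjects x 10 frames with ED/ES labeled gives 24 pseudo-labeled
        and 30 pooled frames."""
        from cineseg.cine_io import normalize_intensity
        from cineseg.phantom import generate_phantom, random_phantom_config

        subjects = []
        for seed in range(3):
            cfg = random_phantom_config(50 + seed, grid_size=16, n_frames=10)
            series, labels = generate_phantom(cfg)
            series = normalize_intensity(series)
            subjects.append((series, {
                series.ed_index: labels[series.ed_index],
                series.es_index: labels[series.es_index],
            }))
        net = NetworkConfig(n_levels=2, base_channels=2, n_classes=9)
        cfg = TrainConfig(learning_rate=1e-2, n_iterations=20, seed=0,
                          augmentation=None)
        _, accounting = train_all_frames_baseline(subjects, net, cfg)
        assert accounting["n_pseudo"] == 24
        assert accounting["n_pooled"] == 30
        assert accounting["expected"] == (24, 30)
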