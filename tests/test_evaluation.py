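"""Dice, volumetry, ejection fraction, volume-difference summaries,
and the paired-test selection logic."""

import numpy as np
import pytest
from scipy import stats

from cineseg.cine_io import LabelMap
from cineseg.evaluation import (
    STRUCTURE_SET,
    MetricsReport,
    dice,
    dice_per_structure,
    ejection_fraction,
    evaluate_subject,
    mean_dice,
    paired_compare,
    volume_curve,
    volume_difference_summary,
)
from cineseg.phantom import analytic_volume_curve, generate_phantom, label_maps


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.uniform(size=(8, 8, 8)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert dice(a, b) == 0.0

    def test_worked_overlap_example(self):
        """|A|=4, |B|=6, |A∩B|=3: Dice = 2*3/10 = 0.6."""
        a = np.zeros(10, dtype=bool)
        b = np.zeros(10, dtype=bool)
        a[:4] = True
        b[1:7] = True
        assert dice(a.reshape(10, 1, 1), b.reshape(10, 1, 1)) == pytest.approx(0.6)

    def test_symmetry(self, rng):
        a = rng.uniform(size=(6, 6, 6)) > 0.4
        b = rng.uniform(size=(6, 6, 6)) > 0.6
        assert dice(a, b) == dice(b, a)

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert dice(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))


class TestMeanDice:
    def test_all_perfect(self):
        assert mean_dice([1.0] * 8) == 1.0

    def test_half_and_half(self):
        assert mean_dice([1, 1, 1, 1, 0, 0, 0, 0]) == 0.5

    def test_matches_independent_sum(self, rng):
        vals = rng.uniform(size=8)
        assert mean_dice(vals) == pytest.approx(sum(vals) / 8)
        assert min(vals) <= mean_dice(vals) <= max(vals)

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            mean_dice([1.0] * 7)


class TestVolumes:
    def test_unit_spacing_conversion(self):
        vox = np.zeros((10, 10, 10), dtype=np.int16)
        vox[:10, :10, :10][:1000].flat[:1000] = 0
        vox.ravel()[:1000] = 1
        lm = LabelMap(vox, np.ones(3))
        assert volume_curve([lm], np.ones(3), 1)[0] == pytest.approx(1.0)

    def test_anisotropic_spacing_conversion(self):
        vox = np.zeros((10, 10, 10), dtype=np.int16)
        vox.ravel()[:1000] = 1
        spacing = np.array([2.0, 1.0, 1.0])
        assert volume_curve([LabelMap(vox, spacing)], spacing, 1)[0] == pytest.approx(2.0)

    def test_invariant_to_other_structure_relabeling(self, rng):
        vox = rng.integers(0, 4, size=(8, 8, 8)).astype(np.int16)
        v1 = volume_curve([LabelMap(vox, np.ones(3))], np.ones(3), 1)
        relabeled = vox.copy()
        relabeled[relabeled == 3] = 4
        v2 = volume_curve([LabelMap(relabeled, np.ones(3))], np.ones(3), 1)
        assert v1 == pytest.approx(v2)

    def test_unknown_structure_rejected(self):
        lm = LabelMap(np.zeros((2, 2, 2), dtype=np.int16), np.ones(3))
        with pytest.raises(KeyError):
            volume_curve([lm], np.ones(3), 9)

    def test_phantom_curve_matches_closed_form(self, small_phantom):
        cfg, _, labels = small_phantom
        for structure in (1, 2):
            voxel = volume_curve(labels, cfg.spacing_mm, structure)
            analytic = np.array(analytic_volume_curve(cfg, structure))
            assert np.abs(voxel - analytic).max() / analytic.max() < 0.1


class TestEjectionFraction:
    def test_worked_example(self):
        assert ejection_fraction(100, 40) == pytest.approx(60.0)

    def test_no_ejection(self):
        assert ejection_fraction(80, 80) == 0.0

    @pytest.mark.parametrize("edv,esv", [(0, 0), (-1, 0), (50, 60), (50, -1)])
    def test_domain_errors(self, edv, esv):
        with pytest.raises(ValueError):
            ejection_fraction(edv, esv)

    def test_isotropic_shrink_closed_form(self):
        """EF of an isotropically shrinking chamber is 1 - (1-a)^3."""
        a = 0.25
        assert ejection_fraction(1.0, (1 - a) ** 3) == pytest.approx(
            100 * (1 - (1 - a) ** 3))


class TestVolumeDifferenceSummary:
    def test_identical_curves(self):
        ref = [np.array([100.0, 90.0, 80.0])]
        out = volume_difference_summary(ref, [ref[0].copy()],
                                        normalization="edv", ed_indices=[0])
        assert out["mean_diff_ml"] == 0.0
        assert out["mean_diff_pct"] == 0.0

    def test_constant_offset_normalized_to_edv(self):
        ref = [np.array([100.0, 90.0, 80.0])]
        test = [ref[0] + 5.0]
        out = volume_difference_summary(ref, test, "edv", ed_indices=[0])
        assert out["mean_diff_ml"] == pytest.approx(5.0)
        assert out["mean_diff_pct"] == pytest.approx(5.0)

    def test_pooled_mean_over_subjects(self):
        ref = [np.full(3, 50.0), np.full(3, 40.0)]
        test = [ref[0] + 2.0, ref[1] - 4.0]
        out = volume_difference_summary(ref, test, "max")
        assert out["mean_diff_ml"] == pytest.approx(-1.0)
        # percent differences pool (2/50, -4/40) per frame
        assert out["mean_diff_pct"] == pytest.approx(100 * (0.04 - 0.10) / 2)

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError):
            volume_difference_summary([np.zeros(3)], [np.zeros(3)], "max")


class TestPairedCompare:
    def test_identical_samples_degenerate(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero"):
            name, p = paired_compare(x, x)
        assert p == 1.0

    def test_large_gaussian_shift_detected(self, rng):
        """Paired Gaussian data with a 2-sigma shift at n=30 is detected
        essentially always."""
        hits = 0
        for _ in range(100):
            x = rng.normal(0, 1, 30)
            y = x + rng.normal(2, 1, 30)
            _, p = paired_compare(x, y)
            hits += p < 0.05
        assert hits >= 99

    def test_skewed_differences_use_wilcoxon(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.exponential(3.0, 40) ** 2
        name, _ = paired_compare(x, y)
        assert name == "wilcoxon"

    def test_gaussian_differences_use_ttest(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0.5, 1.0, 40)
        name, _ = paired_compare(x, y)
        assert name == "t-test"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0, 2.0], [1.0, 2.5])


class TestEvaluateSubject:
    def test_perfect_prediction_scores_one(self, small_phantom):
        cfg, series, labels = small_phantom
        report = evaluate_subject(labels, labels, cfg.spacing_mm,
                                  subject_id="x", ed_index=series.ed_index,
                                  es_index=series.es_index)
        assert report.overall_mean_dice == pytest.approx(1.0)
        assert set(report.structure_mean_dice()) == set(STRUCTURE_SET)
        df = report.to_frame()
        assert len(df) == 8 * len(labels)
        assert (df["dice"] == 1.0).all()

    def test_ef_from_phantom_volumes_matches_geometry(self, small_phantom):
        """EF computed from voxel-counted LV volumes agrees with the
        closed-form 1-(1-a)^3 of the phantom's motion law."""
        cfg, series, labels = small_phantom
        report = evaluate_subject(labels, labels, cfg.spacing_mm,
                                  ed_index=series.ed_index,
                                  es_index=series.es_index)
        lv_amp = [s.amplitude for s in cfg.structures if s.label == 1][0]
        expected = 100 * (1 - (1 - lv_amp) ** 3)
        assert report.ef("LV") == pytest.approx(expected, rel=0.10)
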