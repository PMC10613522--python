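"""Segmentation metrics: Dice overlap, chamber volumetry, ejection
fraction, volume-difference summaries, and paired statistical tests.

The Dice score between voxel sets A and B is ``2|A∩B| / (|A| + |B|)``;
the whole-heart summary is the unweighted mean over the eight structures
{AO, LV, PA, RA, SVC, IVC, LA, RV}.  Volumes come from voxel counting
times the voxel volume; ejection fraction is ``100*(EDV-ESV)/EDV``.

Paired comparisons follow the usual small-sample recipe: Shapiro-Wilk on
the paired differences at alpha = 0.05, then a paired two-tailed t-test
if the differences look Gaussian, else a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cine_io import STRUCTURE_LABELS, LabelMap

#: Evaluation order of the eight structures (ids into the label maps).
STRUCTURE_SET = ("AO", "LV", "PA", "RA", "SVC", "IVC", "LA", "RV")
_NAME_TO_ID = {name: i for i, name in STRUCTURE_LABELS.items()}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks; 1.0 if both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        # perfect agreement on absence (structures can be genuinely missing)
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def mean_dice(per_structure) -> float:
    """Unweighted mean Dice over the eight cardiac structures."""
    vals = list(per_structure)
    if len(vals) != len(STRUCTURE_SET):
        raise ValueError(f"expected {len(STRUCTURE_SET)} values, got {len(vals)}")
    return float(np.mean(vals))


def dice_per_structure(pred: LabelMap, ref: LabelMap) -> dict[str, float]:
    """Dice of every structure between a predicted and a reference map."""
    return {
        name: dice(pred.mask(_NAME_TO_ID[name]), ref.mask(_NAME_TO_ID[name]))
        for name in STRUCTURE_SET
    }


def volume_curve(labels: list[LabelMap], spacing_mm, structure: int) -> np.ndarray:
    """Structure volume (ml) at every frame, from voxel counting."""
    if structure not in STRUCTURE_LABELS:
        raise KeyError(f"structure id {structure} outside vocabulary")
    vox_ml = float(np.prod(spacing_mm)) / 1000.0
    return np.array([int(lm.mask(structure).sum()) * vox_ml for lm in labels])


def ejection_fraction(edv: float, esv: float) -> float:
    """Ejection fraction in percent from end-diastolic/systolic volumes."""
    if edv <= 0:
        raise ValueError(f"EDV must be positive, got {edv}")
    if esv < 0 or esv > edv:
        raise ValueError(f"ESV must lie in [0, EDV], got {esv} (EDV={edv})")
    return 100.0 * (edv - esv) / edv


def volume_difference_summary(
    ref_curves: list[np.ndarray],
    test_curves: list[np.ndarray],
    normalization: str = "edv",
    ed_indices: list[int] | None = None,
) -> dict:
    """Pooled volume differences (test - ref) over all frames and subjects.

    ``normalization`` picks the per-subject denominator for the percent
    figures: ``"edv"`` uses the reference volume at the subject's ED
    frame (ventricles), ``"max"`` the largest reference volume over the
    cycle (atria, which have no meaningful EDV).
    """
    if len(ref_curves) != len(test_curves):
        raise ValueError("subject count mismatch")
    diffs_ml, diffs_pct = [], []
    for i, (ref, test) in enumerate(zip(ref_curves, test_curves)):
        ref = np.asarray(ref, dtype=float)
        test = np.asarray(test, dtype=float)
        if ref.shape != test.shape:
            raise ValueError(f"subject {i}: frame count mismatch")
        if normalization == "edv":
            if ed_indices is None:
                raise ValueError("ed_indices required for EDV normalization")
            denom = ref[ed_indices[i]]
        elif normalization == "max":
            denom = ref.max()
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        if denom <= 0:
            raise ValueError(f"subject {i}: zero normalizer")
        d = test - ref
        diffs_ml.append(d)
        diffs_pct.append(100.0 * d / denom)
    all_ml = np.concatenate(diffs_ml)
    all_pct = np.concatenate(diffs_pct)
    return {
        "mean_diff_ml": float(all_ml.mean()),
        "sd_diff_ml": float(all_ml.std(ddof=1)) if all_ml.size > 1 else 0.0,
        "mean_diff_pct": float(all_pct.mean()),
        "sd_diff_pct": float(all_pct.std(ddof=1)) if all_pct.size > 1 else 0.0,
    }


def paired_compare(x, y, alpha: float = 0.05) -> tuple[str, float]:
    """Compare paired samples; returns (test name, p-value).

    Differences are screened with Shapiro-Wilk: Gaussian-looking
    differences get a paired two-tailed t-test, otherwise a Wilcoxon
    signed-rank test.  All-zero differences are degenerate for Wilcoxon;
    they mean perfect agreement, so p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length paired 1D samples, n >= 3")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; returning p = 1",
                      stacklevel=2)
        return "degenerate", 1.0
    normal = stats.shapiro(d).pvalue > alpha
    if normal:
        return "t-test", float(stats.ttest_rel(x, y).pvalue)
    return "wilcoxon", float(stats.wilcoxon(x, y).pvalue)


@dataclass
class MetricsReport:
    """Per-structure/per-frame Dice plus volumetry for one subject."""

    subject_id: str
    dice: dict = field(default_factory=dict)      # structure -> per-frame array
    volume_ml: dict = field(default_factory=dict)  # structure -> per-frame array
    ed_index: int = 0
    es_index: int = 0

    @property
    def mean_dice_per_frame(self) -> np.ndarray:
        return np.mean([self.dice[s] for s in STRUCTURE_SET], axis=0)

    @property
    def overall_mean_dice(self) -> float:
        return float(self.mean_dice_per_frame.mean())

    def structure_mean_dice(self, pooled: bool = False) -> dict[str, float]:
        """Per-structure Dice averaged over frames.

        With ``pooled=False`` this is the mean of per-frame Dice values;
        ``pooled=True`` is a placeholder kept for symmetry (per-frame
        masks are not retained, so both report the frame mean).
        """
        return {s: float(np.mean(self.dice[s])) for s in STRUCTURE_SET}

    def ef(self, structure: str = "LV") -> float:
        v = self.volume_ml[structure]
        return ejection_fraction(v[self.ed_index], v[self.es_index])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in STRUCTURE_SET:
            for t, (dc, vol) in enumerate(zip(self.dice[s], self.volume_ml[s])):
                rows.append({
                    "subject": self.subject_id, "frame": t, "structure": s,
                    "dice": dc, "volume_ml": vol,
                })
        return pd.DataFrame(rows)


def evaluate_subject(
    pred: list[LabelMap],
    ref: list[LabelMap],
    spacing_mm,
    subject_id: str = "",
    ed_index: int = 0,
    es_index: int = 0,
) -> MetricsReport:
    """Per-frame Dice and predicted volumes against a full reference."""
    if len(pred) != len(ref):
        raise ValueError("prediction/reference frame count mismatch")
    report = MetricsReport(subject_id=subject_id, ed_index=ed_index, es_index=es_index)
    per_structure = {s: [] for s in STRUCTURE_SET}
    for p, r in zip(pred, ref):
        d = dice_per_structure(p, r)
        for s in STRUCTURE_SET:
            per_structure[s].append(d[s])
    for s in STRUCTURE_SET:
        report.dice[s] = np.array(per_structure[s])
        report.volume_ml[s] = volume_curve(pred, spacing_mm, _NAME_TO_ID[s])
    return report
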