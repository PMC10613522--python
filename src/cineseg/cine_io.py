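"""Reading, writing and pre-processing of 4D cine volumes and label maps.

A cine series is one subject's time-resolved acquisition: ``F`` frames of
3D intensity volumes on a common grid, plus the indices of the
end-diastolic (ED) and end-systolic (ES) frames.  ED/ES cannot be guessed
from the images alone, so they are required sidecar inputs (for phantom
data they are computed analytically from the motion model).

On disk a series is either a single 4D NIfTI file (time as 4th axis) or a
directory of per-frame 3D NIfTI files named ``frame_00.nii.gz`` ...,
accompanied by a YAML sidecar with ``subject_id``, ``ed_index``,
``es_index`` and optionally ``bounding_box``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

#: Integer ids of the eight segmented cardiac structures (0 is background).
STRUCTURE_LABELS = {
    1: "LV", 2: "RV", 3: "LA", 4: "RA", 5: "AO", 6: "PA", 7: "SVC", 8: "IVC",
}
N_CLASSES = 9  # background + 8 structures

SIDECAR_NAME = "series.yaml"


class FormatError(ValueError):
    """Inconsistent on-disk data (mismatched shapes, bad labels)."""


class ConfigurationError(ValueError):
    """Missing or invalid sidecar/configuration information."""


@dataclass
class LabelMap:
    """Integer label volume for one frame; values in {0..8}."""

    voxels: np.ndarray
    spacing_mm: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError("label map must be integer-valued")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        vmin, vmax = int(self.voxels.min()), int(self.voxels.max())
        if vmin < 0 or vmax >= N_CLASSES:
            raise FormatError(
                f"label values must lie in [0, {N_CLASSES - 1}], got [{vmin}, {vmax}]"
            )

    def mask(self, structure: int) -> np.ndarray:
        """Boolean voxel set of one structure (set A or B of the Dice metric)."""
        return self.voxels == structure


@dataclass
class CineSeries:
    """One subject's 4D cine image."""

    subject_id: str
    frames: list  # list of 3D float arrays, all same shape
    spacing_mm: np.ndarray
    ed_index: int
    es_index: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        if len(self.frames) < 2:
            raise FormatError("a cine series needs at least two frames")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent frame shapes: {sorted(shapes)}")
        f = len(self.frames)
        for name, idx in (("ed_index", self.ed_index), ("es_index", self.es_index)):
            if not 0 <= idx < f:
                raise ConfigurationError(f"{name}={idx} outside [0, {f})")
        if self.ed_index == self.es_index:
            raise ConfigurationError("ed_index and es_index must differ")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple:
        return self.frames[0].shape


@dataclass(frozen=True)
class BoundingBox:
    """Half-open voxel-index box: lower inclusive, upper exclusive."""

    lower: tuple
    upper: tuple

    def __post_init__(self):
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise ValueError("bounding box must be 3-dimensional")
        if any(u <= l for l, u in zip(self.lower, self.upper)):
            raise ValueError(f"empty box: lower={self.lower} upper={self.upper}")

    def slices(self) -> tuple:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))

    def check_within(self, shape) -> None:
        for l, u, s in zip(self.lower, self.upper, shape):
            if l < 0 or u > s:
                raise IndexError(
                    f"box [{self.lower}, {self.upper}) exceeds volume shape {tuple(shape)}"
                )


_FRAME_RE = re.compile(r"frame_(\d+)\.nii(\.gz)?$")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_cine(path_spec, sidecar: dict | str | Path | None = None) -> CineSeries:
    """Read a cine series from a 4D file or a directory of frame files.

    ``sidecar`` may be a dict or a YAML path; if omitted, ``series.yaml``
    next to the data is used.  It must provide ``ed_index`` and
    ``es_index`` — the reader fails rather than guessing the cardiac
    phases.
    """
    path = Path(path_spec)
    if sidecar is None:
        cand = (path if path.is_dir() else path.parent) / SIDECAR_NAME
        if not cand.exists():
            raise ConfigurationError(f"no sidecar given and {cand} not found")
        sidecar = cand
    if not isinstance(sidecar, dict):
        with open(sidecar) as fh:
            sidecar = yaml.safe_load(fh)
    for key in ("ed_index", "es_index"):
        if key not in sidecar:
            raise ConfigurationError(f"sidecar missing required key {key!r}")

    if path.is_dir():
        entries = []
        for p in path.iterdir():
            m = _FRAME_RE.search(p.name)
            if m:
                entries.append((int(m.group(1)), p))
        if not entries:
            raise FormatError(f"no frame_NN.nii[.gz] files in {path}")
        entries.sort()
        frames, spacing = [], None
        for _, p in entries:
            img = nib.load(str(p))
            frames.append(np.asarray(img.dataobj, dtype=np.float32))
            spacing = img.header.get_zooms()[:3]
    else:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim != 4:
            raise FormatError(f"expected 4D image, got shape {data.shape}")
        frames = [data[..., t] for t in range(data.shape[-1])]
        spacing = img.header.get_zooms()[:3]

    return CineSeries(
        subject_id=str(sidecar.get("subject_id", path.stem)),
        frames=frames,
        spacing_mm=np.asarray(spacing, dtype=float),
        ed_index=int(sidecar["ed_index"]),
        es_index=int(sidecar["es_index"]),
        metadata=dict(sidecar.get("metadata", {})),
    )


def write_cine(series: CineSeries, out_dir, labels: list[LabelMap] | None = None) -> Path:
    """Write a series (and optional per-frame labels) as per-frame NIfTI files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.spacing_mm)
    for t, frame in enumerate(series.frames):
        nib.save(nib.Nifti1Image(np.asarray(frame, dtype=np.float32), aff),
                 str(out / f"frame_{t:02d}.nii.gz"))
    if labels is not None:
        for t, lm in enumerate(labels):
            nib.save(nib.Nifti1Image(lm.voxels.astype(np.int16), aff),
                     str(out / f"labels_{t:02d}.nii.gz"))
    sidecar = {
        "subject_id": series.subject_id,
        "ed_index": int(series.ed_index),
        "es_index": int(series.es_index),
        "metadata": series.metadata,
    }
    with open(out / SIDECAR_NAME, "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return out


def read_labels(path, spacing_mm=None) -> list[LabelMap]:
    """Read ``labels_NN.nii.gz`` files from a directory, ordered by frame."""
    path = Path(path)
    entries = sorted(
        (int(re.search(r"labels_(\d+)", p.name).group(1)), p)
        for p in path.glob("labels_*.nii*")
    )
    out = []
    for _, p in entries:
        img = nib.load(str(p))
        sp = spacing_mm if spacing_mm is not None else img.header.get_zooms()[:3]
        out.append(LabelMap(np.asarray(img.dataobj).astype(np.int16), np.asarray(sp)))
    return out


def crop(
    series: CineSeries,
    labels: list[LabelMap] | None,
    box: BoundingBox,
) -> tuple[CineSeries, list[LabelMap] | None]:
    """Crop every frame (and label map) of a series with the same box.

    All frames get the same box so the cropped series stays a valid 4D
    image; spacing and label values are unchanged.
    """
    box.check_within(series.frame_shape)
    sl = box.slices()
    new_series = CineSeries(
        subject_id=series.subject_id,
        frames=[f[sl] for f in series.frames],
        spacing_mm=series.spacing_mm.copy(),
        ed_index=series.ed_index,
        es_index=series.es_index,
        metadata=dict(series.metadata),
    )
    new_labels = None
    if labels is not None:
        new_labels = [LabelMap(lm.voxels[sl], lm.spacing_mm.copy()) for lm in labels]
    return new_series, new_labels


def normalize_intensity(
    series: CineSeries, lung_pct: float = 5.0, blood_pct: float = 95.0
) -> CineSeries:
    """Anchor-based intensity normalization, applied per frame.

    In contrast-enhanced cine CMR the blood pool is the brightest tissue
    and lung the darkest, so the low/high percentiles of the cropped frame
    are surrogates for the lung and blood-pool intensities.  Each frame is
    mapped linearly so the lung anchor goes to 0 and the blood anchor to 1
    (no clipping; values outside the anchors stay outside [0, 1]).
    """
    new_frames = []
    for t, frame in enumerate(series.frames):
        lo, hi = np.percentile(frame, [lung_pct, blood_pct])
        if hi <= lo:
            raise ValueError(
                f"frame {t}: degenerate intensity range (anchors {lo} == {hi})"
            )
        new_frames.append(((frame - lo) / (hi - lo)).astype(np.float32))
    return CineSeries(
        subject_id=series.subject_id,
        frames=new_frames,
        spacing_mm=series.spacing_mm.copy(),
        ed_index=series.ed_index,
        es_index=series.es_index,
        metadata=dict(series.metadata),
    )
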