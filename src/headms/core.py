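"""Domain types shared across the pipeline: volumes, labels, subjects, cohorts.

Label coding (fixed convention used by every stage, including the one-hot
channel order of the networks):

====  =======================
code  tissue
====  =======================
0     background
1     right masseter (RM)
2     left masseter (LM)
3     right subcutaneous fat (RSF)
4     left subcutaneous fat (LSF)
5     tongue (T)
====  =======================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_MAP = {
    0: "background",
    1: "right_masseter",
    2: "left_masseter",
    3: "right_subcutaneous_fat",
    4: "left_subcutaneous_fat",
    5: "tongue",
}
#: the five foreground tissues, in label order 1..5
TISSUES = tuple(CLASS_MAP[i] for i in range(1, 6))
TISSUE_LABELS = {name: code for code, name in CLASS_MAP.items() if code > 0}
TISSUE_SHORT = {
    "right_masseter": "RM",
    "left_masseter": "LM",
    "right_subcutaneous_fat": "RSF",
    "left_subcutaneous_fat": "LSF",
    "tongue": "T",
}
N_CLASSES = 6

#: default in-plane pixel spacing: 26 cm field of view over a 256 matrix
DEFAULT_IN_PLANE_MM = 260.0 / 256.0
#: default slice increment (2 mm thickness + 1 mm gap); configurable
DEFAULT_SLICE_INCREMENT_MM = 3.0


def _check_spacing(spacing):
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing}")
    return spacing


@dataclass
class VolumeGrid:
    """3-D intensity array (slices x rows x cols) with physical voxel spacing."""

    voxels: np.ndarray
    spacing: tuple  # (slice_increment_mm, row_mm, col_mm)
    subject_id: str

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (slices, rows, cols)")
        if not np.isfinite(self.voxels).all():
            raise ValueError("intensities must be finite")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class LabelVolume:
    """Integer tissue labels on the same grid as a paired :class:`VolumeGrid`."""

    labels: np.ndarray
    spacing: tuple
    subject_id: str

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise TypeError(f"labels must be integer-typed, got {labels.dtype}")
        if labels.ndim != 3:
            raise ValueError("labels must be 3-D (slices, rows, cols)")
        if labels.min() < 0 or labels.max() >= N_CLASSES:
            raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
        self.labels = labels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self):
        return self.labels.shape

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.labels == TISSUE_LABELS[tissue]


@dataclass
class SubjectRecord:
    """Covariates and generator ground truth for one subject."""

    subject_id: str
    age: float
    sex: str  # "female" | "male"
    bmi: float
    diagnosis: str  # "AD" | "DLB"
    true_region_scales: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.diagnosis not in ("AD", "DLB"):
            raise ValueError(f"diagnosis must be 'AD' or 'DLB', got {self.diagnosis!r}")
        if self.true_region_scales and set(self.true_region_scales) != set(TISSUES):
            raise ValueError("true_region_scales must have exactly the 5 tissue keys")


@dataclass
class CohortManifest:
    """Everything needed to reload or regenerate a phantom cohort."""

    subjects: list
    paths: dict = field(default_factory=dict)  # subject_id -> (image, labels)
    generation_params: dict = field(default_factory=dict)
    volumes: dict = field(default_factory=dict)  # in-memory: sid -> (vol, lab)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    @property
    def subject_ids(self):
        return [s.subject_id for s in self.subjects]

    def record(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)
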