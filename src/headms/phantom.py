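"""Synthetic head-phantom cohort generator.

Each subject is a stack of axial T1-like slices containing five tissues on a
dark background: bilateral masseter ellipses, a subcutaneous-fat crescent
lateral to each masseter, and a central tongue ellipse.  Intensities follow
the T1 contrast ordering background < muscle < fat, with additive Gaussian
noise.  Region geometry is 2-D per slice, replicated across slices with a
parabolic area profile peaking at the central slice — enough structure for
slice selection, segmentation and morphometry, with no claim of 3-D
anatomical realism.

Subject covariates (age, sex, BMI, diagnosis) are drawn from configurable
distributions, and each tissue's linear size is scaled so that its expected
cross-sectional area follows ``base_area * (1 + beta * (BMI - 26))``.  The
default slopes inject a positive BMI effect for the tongue, left masseter
and both fat regions and a null effect for the right masseter, which is what
the downstream regression stage is expected to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_IN_PLANE_MM,
    DEFAULT_SLICE_INCREMENT_MM,
    TISSUE_LABELS,
    TISSUES,
    CohortManifest,
    LabelVolume,
    SubjectRecord,
    VolumeGrid,
)


class PhantomGeometryError(ValueError):
    """Requested scales push a region out of the field of view or into overlap."""

    def __init__(self, tissue, reason):
        self.tissue = tissue
        super().__init__(f"phantom geometry error for tissue {tissue!r}: {reason}")


#: base region geometry in fractional (row, col) coordinates of the slice;
#: radiological convention — the subject's right side is at low column index
_GEOMETRY = {
    "tongue": {"center": (0.44, 0.50), "semi": (0.11, 0.12)},
    "right_masseter": {"center": (0.58, 0.26), "semi": (0.10, 0.050)},
    "left_masseter": {"center": (0.58, 0.74), "semi": (0.10, 0.050)},
    "right_subcutaneous_fat": {
        "center": (0.58, 0.115), "semi": (0.12, 0.050), "notch_shift": +0.030,
    },
    "left_subcutaneous_fat": {
        "center": (0.58, 0.885), "semi": (0.12, 0.050), "notch_shift": -0.030,
    },
}

#: tissue -> T1-like intensity class
_INTENSITY_CLASS = {
    "background": "background",
    "right_masseter": "muscle",
    "left_masseter": "muscle",
    "tongue": "muscle",
    "right_subcutaneous_fat": "fat",
    "left_subcutaneous_fat": "fat",
}


@dataclass
class PhantomParams:
    """Generator configuration; the defaults define the study conditions."""

    image_size: int = 256
    n_slices: int = 7
    in_plane_mm: float = DEFAULT_IN_PLANE_MM
    slice_increment_mm: float = DEFAULT_SLICE_INCREMENT_MM
    intensity_means: dict = field(
        default_factory=lambda: {"background": 0.10, "muscle": 0.50, "fat": 0.90}
    )
    noise_sd: float = 0.05
    #: parabolic area profile: area factor 1 - curvature * u^2, u in [-1, 1]
    slice_profile_curvature: float = 0.3
    #: per-axis multiplicative jitter (relative sd, truncated at 3 sd)
    axis_jitter_sd: float = 0.025
    #: per-region center jitter (fraction of image, truncated at 3 sd)
    center_jitter_sd: float = 0.004
    #: area slope per BMI unit, relative to the base area at BMI 26
    bmi_slopes: dict = field(
        default_factory=lambda: {
            "tongue": 0.02,
            "left_masseter": 0.02,
            "right_masseter": 0.0,
            "left_subcutaneous_fat": 0.02,
            "right_subcutaneous_fat": 0.02,
        }
    )
    bmi_reference: float = 26.0
    #: optional smooth multiplicative intensity inhomogeneity
    bias_field: bool = False
    bias_field_amplitude: float = 0.1
    # covariate distributions
    age_mean: float = 76.0
    age_sd: float = 7.0
    age_min: float = 50.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    bmi_range: tuple = (15.0, 45.0)
    p_male: float = 0.5
    ad_fraction: float = 33.0 / 53.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bmi_range"] = list(d["bmi_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        d = dict(d)
        if "bmi_range" in d:
            d["bmi_range"] = tuple(d["bmi_range"])
        return cls(**d)

    @property
    def spacing(self):
        return (self.slice_increment_mm, self.in_plane_mm, self.in_plane_mm)


def analytic_base_area_cm2(params: PhantomParams, tissue: str) -> float:
    """Continuous-geometry area (cm^2) of a region at unit scale, center slice.

    Ellipses have area pi*a*b; the fat crescent is an ellipse minus its
    intersection with a medially shifted copy (a two-ellipse lens, which maps
    to the two-circle lens under the axis rescaling x -> x/b, y -> y/a).
    The generator's injected BMI slope for a tissue is
    ``analytic_base_area_cm2 * bmi_slopes[tissue]``.
    """
    geom = _GEOMETRY[tissue]
    fov_cm = params.image_size * params.in_plane_mm / 10.0
    a = geom["semi"][0] * fov_cm
    b = geom["semi"][1] * fov_cm
    area = np.pi * a * b
    shift = geom.get("notch_shift")
    if shift is not None:
        t = abs(shift) / geom["semi"][1]  # centers t*b apart in circle coords
        lens_unit = 2 * np.arccos(t / 2) - (t / 2) * np.sqrt(4 - t * t)
        area -= a * b * lens_unit
    return float(area)


def region_scale_for_bmi(params: PhantomParams, tissue: str, bmi: float) -> float:
    """Linear-size multiplier giving expected area 1 + beta * (BMI - ref)."""
    beta = params.bmi_slopes[tissue]
    area_factor = 1.0 + beta * (bmi - params.bmi_reference)
    return float(np.sqrt(np.clip(area_factor, 0.25, None)))


def _truncated_normal(rng, mean, sd, low=None, high=None, size=None):
    x = rng.normal(mean, sd, size=size)
    while True:
        bad = np.zeros(np.shape(x), dtype=bool)
        if low is not None:
            bad |= x < low
        if high is not None:
            bad |= x > high
        n_bad = int(np.count_nonzero(bad))
        if n_bad == 0:
            return x
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)


def _ellipse_mask_bbox(size, center, semi):
    """Boolean mask of an axis-aligned ellipse, evaluated on its bounding box.

    Returns (row_slice, col_slice, mask).  Pixel centers at (i + 0.5)/size.
    """
    cy, cx = center
    ay, ax = semi
    r0 = max(int(np.floor((cy - ay) * size - 1)), 0)
    r1 = min(int(np.ceil((cy + ay) * size + 1)), size)
    c0 = max(int(np.floor((cx - ax) * size - 1)), 0)
    c1 = min(int(np.ceil((cx + ax) * size + 1)), size)
    rows = (np.arange(r0, r1) + 0.5) / size
    cols = (np.arange(c0, c1) + 0.5) / size
    dy = (rows[:, None] - cy) / ay
    dx = (cols[None, :] - cx) / ax
    return slice(r0, r1), slice(c0, c1), dy * dy + dx * dx <= 1.0


def _region_mask(size, tissue, center, semi, notch_shift=None):
    rs, cs, mask = _ellipse_mask_bbox(size, center, semi)
    if notch_shift is not None:
        # crescent: remove the medially shifted copy of the same ellipse
        cy, cx = center
        rs2, cs2, notch = _ellipse_mask_bbox(size, (cy, cx + notch_shift), semi)
        full = np.zeros((size, size), dtype=bool)
        full[rs, cs] = mask
        full[rs2, cs2] &= ~notch
        return slice(0, size), slice(0, size), full
    return rs, cs, mask


def _draw_jitter(rng, params):
    """Per-subject geometric jitter, one draw per tissue in fixed order."""
    jitter = {}
    for tissue in TISSUES:
        centers = np.clip(
            rng.normal(0.0, params.center_jitter_sd, size=2),
            -3 * params.center_jitter_sd, 3 * params.center_jitter_sd,
        )
        axes = np.clip(
            rng.normal(1.0, params.axis_jitter_sd, size=2),
            1 - 3 * params.axis_jitter_sd, 1 + 3 * params.axis_jitter_sd,
        )
        jitter[tissue] = (centers, axes)
    return jitter


def rasterize_labels(params: PhantomParams, record: SubjectRecord, rng) -> np.ndarray:
    """Label stack for one subject (no intensity synthesis).

    Raises :class:`PhantomGeometryError` if any region leaves the field of
    view or collides with another region.
    """
    size, n = params.image_size, params.n_slices
    scales = record.true_region_scales or {t: 1.0 for t in TISSUES}
    jitter = _draw_jitter(rng, params)
    labels = np.zeros((n, size, size), dtype=np.uint8)
    half = (n - 1) / 2.0
    for k in range(n):
        u = (k - half) / half if half > 0 else 0.0
        area_factor = 1.0 - params.slice_profile_curvature * u * u
        if area_factor <= 0:
            raise ValueError("slice_profile_curvature must be < 1")
        g = np.sqrt(area_factor)
        plane = labels[k]
        for tissue in TISSUES:
            geom = _GEOMETRY[tissue]
            dc, ax_jit = jitter[tissue]
            s = scales[tissue] * g
            center = (geom["center"][0] + dc[0], geom["center"][1] + dc[1])
            semi = (
                geom["semi"][0] * s * ax_jit[0],
                geom["semi"][1] * s * ax_jit[1],
            )
            if (
                center[0] - semi[0] < 0 or center[0] + semi[0] > 1
                or center[1] - semi[1] < 0 or center[1] + semi[1] > 1
            ):
                raise PhantomGeometryError(tissue, "region exceeds the field of view")
            notch = geom.get("notch_shift")
            if notch is not None:
                # scale the crescent notch with the region so that the whole
                # shape stays geometrically similar (area scales as s^2)
                notch = notch * s * ax_jit[1]
            rs, cs, mask = _region_mask(size, tissue, center, semi, notch)
            if (plane[rs, cs][mask] != 0).any():
                raise PhantomGeometryError(tissue, "region overlaps another tissue")
            sub = plane[rs, cs]
            sub[mask] = TISSUE_LABELS[tissue]
    return labels


def _bias_field(rng, n, size, amplitude):
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, size), np.linspace(-1, 1, size), indexing="ij"
    )
    cy, cx = rng.uniform(-0.5, 0.5, size=2)
    f = 1.0 + amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2))
    return np.broadcast_to(f.astype(np.float32), (n, size, size))


def render_image(params: PhantomParams, labels: np.ndarray, rng) -> np.ndarray:
    """Intensity synthesis: class means + additive Gaussian noise, clipped."""
    means = params.intensity_means
    lut = np.empty(6, dtype=np.float32)
    lut[0] = means["background"]
    for tissue, code in TISSUE_LABELS.items():
        lut[code] = means[_INTENSITY_CLASS[tissue]]
    img = lut[labels]
    if params.bias_field:
        n, size = labels.shape[0], labels.shape[1]
        img = img * _bias_field(rng, n, size, params.bias_field_amplitude)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=labels.shape).astype(
            np.float32
        )
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_subject(
    params: PhantomParams,
    record: SubjectRecord,
    seed: int,
    render: bool = True,
):
    """Deterministic image/label pair for one subject.

    Returns ``(VolumeGrid | None, LabelVolume)``; the image is omitted when
    ``render`` is false (label-only generation for fast replicate studies).
    """
    rng = np.random.default_rng(seed)
    labels = rasterize_labels(params, record, rng)
    lab = LabelVolume(labels, params.spacing, record.subject_id)
    if not render:
        return None, lab
    img = render_image(params, labels, rng)
    return VolumeGrid(img, params.spacing, record.subject_id), lab


def subject_seed(master_seed: int, index: int) -> int:
    """Stable per-subject seed derived from (master seed, subject index)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def draw_subject_record(params: PhantomParams, index: int, rng,
                        diagnosis: str) -> SubjectRecord:
    age = float(_truncated_normal(rng, params.age_mean, params.age_sd,
                                  low=params.age_min))
    sex = "male" if rng.random() < params.p_male else "female"
    bmi = float(_truncated_normal(rng, params.bmi_mean, params.bmi_sd,
                                  low=params.bmi_range[0], high=params.bmi_range[1]))
    scales = {t: region_scale_for_bmi(params, t, bmi) for t in TISSUES}
    return SubjectRecord(
        subject_id=f"sub-{index:03d}", age=age, sex=sex, bmi=bmi,
        diagnosis=diagnosis, true_region_scales=scales,
    )


def generate_cohort(
    n_subjects: int = 53,
    params: PhantomParams | None = None,
    seed: int = 0,
    out_dir=None,
    render: bool = True,
) -> CohortManifest:
    """Generate a phantom cohort; write NIfTI/CSV/JSON when ``out_dir`` given.

    Covariates are drawn from the master seed; each subject's geometry and
    noise use a per-subject seed hashed from (master seed, index), so the
    cohort is reproducible subject-by-subject.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    n_ad = int(round(params.ad_fraction * n_subjects))
    diagnoses = ["AD"] * n_ad + ["DLB"] * (n_subjects - n_ad)

    subjects, volumes = [], {}
    for i in range(n_subjects):
        rec = draw_subject_record(params, i, rng, diagnoses[i])
        vol, lab = generate_subject(params, rec, subject_seed(seed, i), render=render)
        subjects.append(rec)
        volumes[rec.subject_id] = (vol, lab)

    gen_params = {"seed": int(seed), "n_subjects": int(n_subjects),
                  "params": params.to_dict()}
    manifest = CohortManifest(
        subjects=subjects, generation_params=gen_params, volumes=volumes
    )
    if out_dir is not None:
        from . import io as hio

        hio.write_cohort(manifest, out_dir)
    return manifest
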