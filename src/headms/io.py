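"""NIfTI, CSV, JSON and YAML plumbing for cohorts and run artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import CohortManifest, LabelVolume, SubjectRecord, VolumeGrid


def _affine(spacing):
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(vol: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_labels(lab: LabelVolume, path) -> None:
    img = nib.Nifti1Image(lab.labels.astype(np.uint8), _affine(lab.spacing))
    img.header.set_zooms(lab.spacing)
    nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in {path}: {spacing}")
    return img, spacing


def read_volume(path, subject_id: str = "") -> VolumeGrid:
    img, spacing = _load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    return VolumeGrid(data, spacing, subject_id or Path(str(path)).stem)


def read_labels(path, subject_id: str = "") -> LabelVolume:
    img, spacing = _load(path)
    dtype = img.get_data_dtype()
    if not np.issubdtype(dtype, np.integer):
        raise TypeError(
            f"label file {path} has non-integer dtype {dtype}; "
            "labels must be stored as integers"
        )
    data = np.asarray(img.dataobj)
    return LabelVolume(data, spacing, subject_id or Path(str(path)).stem)


def write_cohort(manifest: CohortManifest, out_dir) -> CohortManifest:
    """Write image/label NIfTI pairs, a covariate CSV and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, (vol, lab) in manifest.volumes.items():
        lab_path = out / f"{sid}_labels.nii.gz"
        write_labels(lab, lab_path)
        img_path = out / f"{sid}_image.nii.gz"
        if vol is not None:
            write_volume(vol, img_path)
        manifest.paths[sid] = (str(img_path), str(lab_path))
    covariates_frame(manifest).to_csv(out / "covariates.csv", index=False)
    payload = {
        "subjects": [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
                "diagnosis": s.diagnosis,
                "true_region_scales": s.true_region_scales,
            }
            for s in manifest.subjects
        ],
        "paths": {k: list(v) for k, v in manifest.paths.items()},
        "generation_params": manifest.generation_params,
    }
    (out / "manifest.json").write_text(json.dumps(payload, indent=1))
    return manifest


def read_cohort(cohort_dir) -> CohortManifest:
    """Reload a written cohort manifest (volumes stay on disk, lazily loaded)."""
    path = Path(cohort_dir) / "manifest.json"
    payload = json.loads(path.read_text())
    subjects = [SubjectRecord(**s) for s in payload["subjects"]]
    return CohortManifest(
        subjects=subjects,
        paths={k: tuple(v) for k, v in payload["paths"].items()},
        generation_params=payload.get("generation_params", {}),
    )


def covariates_frame(manifest: CohortManifest) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
                "diagnosis": s.diagnosis,
            }
            for s in manifest.subjects
        ]
    )


def load_subject(manifest: CohortManifest, subject_id: str):
    """(VolumeGrid, LabelVolume) for a subject, from memory or from disk."""
    if subject_id in manifest.volumes:
        vol, lab = manifest.volumes[subject_id]
        if vol is not None:
            return vol, lab
    img_path, lab_path = manifest.paths[subject_id]
    return read_volume(img_path, subject_id), read_labels(lab_path, subject_id)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
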