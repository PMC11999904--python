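"""Overlap and surface-distance metrics for segmentation evaluation.

Conventions (documented and test-pinned):

* Dice of two empty masks is 1; of one empty and one non-empty mask, 0.
* ASSD of any empty mask is undefined and reported as NaN ("missing"),
  never as 0.
* Boundaries are 4-connected inner borders computed per 2-D slice; the
  array edge counts as outside.  Distances are exact Euclidean distances
  scaled by the (possibly anisotropic) in-plane spacing.
* DSC is reported as a percentage; all other overlap metrics as fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CLASS_MAP, N_CLASSES, TISSUES, LabelVolume


def _as_binary(mask):
    m = np.asarray(mask)
    if m.dtype != bool:
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask must be binary")
        m = m.astype(bool)
    return m


def _check_same_shape(p, g):
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")


def dice(pred, truth) -> float:
    """Dice similarity coefficient 2|P∩G| / (|P|+|G|), as a fraction in [0,1]."""
    p, g = _as_binary(pred), _as_binary(truth)
    _check_same_shape(p, g)
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / (np_ + ng)


def extract_boundary(mask) -> np.ndarray:
    """Inner 4-connected boundary of a 2-D mask (array edge counts as outside).

    Returns an (n, 2) array of (row, col) pixel coordinates.
    """
    m = _as_binary(mask)
    if m.ndim != 2:
        raise ValueError("extract_boundary expects a 2-D mask")
    if not m.any():
        return np.empty((0, 2), dtype=np.intp)
    interior = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(m & ~interior)


def _boundary_distance_map(mask, spacing):
    """Distance (mm) from every pixel to the mask's boundary set."""
    m = _as_binary(mask)
    boundary = np.ones(m.shape, dtype=bool)
    coords = extract_boundary(m)
    boundary[coords[:, 0], coords[:, 1]] = False
    return ndimage.distance_transform_edt(boundary, sampling=spacing)


def assd(pred, truth, spacing=(1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm between two 2-D masks.

    Undefined (raises) when either mask is empty; callers that tabulate
    should record such cases as missing.
    """
    p, g = _as_binary(pred), _as_binary(truth)
    _check_same_shape(p, g)
    if not p.any() or not g.any():
        raise ValueError("assd is undefined for an empty mask")
    bp = extract_boundary(p)
    bg = extract_boundary(g)
    d_to_g = _boundary_distance_map(g, spacing)
    d_to_p = _boundary_distance_map(p, spacing)
    total = d_to_g[bp[:, 0], bp[:, 1]].sum() + d_to_p[bg[:, 0], bg[:, 1]].sum()
    return float(total / (len(bp) + len(bg)))


def confusion_counts(pred, truth):
    p, g = _as_binary(pred), _as_binary(truth)
    _check_same_shape(p, g)
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    tn = int((~p & ~g).sum())
    return tp, fp, fn, tn


def extended_metrics(pred, truth) -> dict:
    """Jaccard, precision, recall, sensitivity, specificity and F1.

    Zero-denominator cases are returned as NaN (missing), never as 0.
    """
    tp, fp, fn, tn = confusion_counts(pred, truth)

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    recall = ratio(tp, tp + fn)
    return {
        "jaccard": ratio(tp, tp + fp + fn),
        "precision": ratio(tp, tp + fp),
        "recall": recall,
        "sensitivity": recall,
        "specificity": ratio(tn, tn + fp),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
    }


@dataclass
class MetricsRecord:
    """One evaluation result: model x tissue x fold x split."""

    model: str
    tissue: str
    fold: int
    split: str  # "validation" | "test"
    dsc: float  # percent, 0..100
    assd: float  # mm; NaN when undefined
    jaccard: float
    precision: float
    recall: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self):
        return dict(self.__dict__)


def evaluate_prediction(pred: LabelVolume, truth: LabelVolume,
                        spacing=None) -> list:
    """Per-tissue metric fragments for a 6-class prediction/ground-truth pair.

    Overlap metrics pool all slices; ASSD is computed per 2-D slice and
    averaged over the slices where the ground truth contains the tissue.
    Slices where the prediction is empty are undefined and excluded from the
    average; if no slice is defined the tissue's ASSD is missing (NaN).
    """
    pl = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    gl = truth.labels if isinstance(truth, LabelVolume) else np.asarray(truth)
    _check_same_shape(pl, gl)
    if pl.max() >= N_CLASSES or gl.max() >= N_CLASSES:
        raise ValueError(f"labels outside 0..{N_CLASSES - 1}")
    if spacing is None:
        spacing = truth.spacing if isinstance(truth, LabelVolume) else (1, 1, 1)
    in_plane = spacing[1:]

    out = []
    for code in range(1, N_CLASSES):
        tissue = CLASS_MAP[code]
        pm, gm = pl == code, gl == code
        slice_assds = []
        for k in range(gl.shape[0]):
            if not gm[k].any():
                continue
            if not pm[k].any():
                slice_assds.append(float("nan"))
                continue
            slice_assds.append(assd(pm[k], gm[k], spacing=in_plane))
        defined = [v for v in slice_assds if not np.isnan(v)]
        mean_assd = float(np.mean(defined)) if defined else float("nan")
        ext = extended_metrics(pm, gm)
        out.append(
            {
                "tissue": tissue,
                "dsc": 100.0 * dice(pm, gm),
                "assd": mean_assd,
                **ext,
            }
        )
    return out


def aggregate_records(records) -> "pd.DataFrame":
    """Mean/SD and median/IQR across folds, per model x tissue x split x metric."""
    import pandas as pd

    df = pd.DataFrame([r.as_dict() if isinstance(r, MetricsRecord) else r
                       for r in records])
    value_cols = [c for c in df.columns if c not in
                  ("model", "tissue", "fold", "split")]
    long = df.melt(
        id_vars=["model", "tissue", "fold", "split"],
        value_vars=value_cols, var_name="metric",
    )
    g = long.groupby(["model", "tissue", "split", "metric"])["value"]
    agg = g.agg(
        mean="mean",
        sd="std",
        median="median",
        iqr=lambda v: float(np.subtract(*np.nanpercentile(v, [75, 25]))),
        n_folds="count",
    ).reset_index()
    return agg


def tissue_order():
    return list(TISSUES)
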