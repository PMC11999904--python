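"""Slice selection, tissue area/volume quantification and BMI association.

The five analysis slices of a subject are the ones where both masseters are
at their largest (scored by the smaller of the two masseter areas); the
"single slice" area is measured on the median of the five selected slices,
and the volume sums the five slice areas times the slice increment.  The
association stage fits, per tissue and measure, an ordinary least squares
model of the measure on BMI adjusted by age and sex, evaluated at the 5%
level with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TISSUE_LABELS, TISSUES, LabelVolume


def select_slices(labels: LabelVolume, n: int = 5) -> list:
    """Indices of the n slices with the largest min(left, right) masseter area.

    Ties are broken toward the lower slice index; the result is ascending.
    """
    lab = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    if lab.shape[0] < n:
        raise ValueError(f"volume has {lab.shape[0]} slices, need at least {n}")
    lm = (lab == TISSUE_LABELS["left_masseter"]).sum(axis=(1, 2))
    rm = (lab == TISSUE_LABELS["right_masseter"]).sum(axis=(1, 2))
    score = np.minimum(lm, rm)
    if score.max() == 0:
        raise ValueError("no masseter pixels in any slice")
    # stable sort on (-score, index): equal scores resolve to the lower index
    order = np.lexsort((np.arange(len(score)), -score))
    return sorted(int(i) for i in order[:n])


def region_area(labels: LabelVolume, slice_index: int, tissue: str,
                spacing=None) -> float:
    """Cross-sectional area (cm^2) of a tissue on one slice."""
    lab = labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)
    if spacing is None:
        spacing = labels.spacing
    if not 0 <= slice_index < lab.shape[0]:
        raise IndexError(f"slice index {slice_index} out of range")
    count = int((lab[slice_index] == TISSUE_LABELS[tissue]).sum())
    return count * spacing[1] * spacing[2] / 100.0


def region_volume(labels: LabelVolume, slice_indices, tissue: str,
                  spacing=None) -> float:
    """Volume (cm^3) summed over the selected slices: sum(area) x increment."""
    if spacing is None:
        spacing = labels.spacing
    areas = [region_area(labels, k, tissue, spacing) for k in slice_indices]
    return float(sum(areas) * spacing[0] / 10.0)


@dataclass
class RegionQuantification:
    subject_id: str
    tissue: str
    area_cm2: float
    volume_cm3: float
    reference_slice: int
    source: str = "ground_truth"


def quantify_subject(labels: LabelVolume, n_slices: int = 5,
                     source: str = "ground_truth") -> list:
    """Area (reference slice) and 5-slice volume for each tissue."""
    selected = select_slices(labels, n_slices)
    reference = selected[len(selected) // 2]  # median of the selected indices
    out = []
    for tissue in TISSUES:
        out.append(
            RegionQuantification(
                subject_id=labels.subject_id,
                tissue=tissue,
                area_cm2=region_area(labels, reference, tissue),
                volume_cm3=region_volume(labels, selected, tissue),
                reference_slice=reference,
                source=source,
            )
        )
    return out


def quantification_frame(quants) -> pd.DataFrame:
    rows = []
    for q in quants:
        rows.append({"subject_id": q.subject_id, "tissue": q.tissue,
                     "measure": "area", "value": q.area_cm2, "source": q.source})
        rows.append({"subject_id": q.subject_id, "tissue": q.tissue,
                     "measure": "volume", "value": q.volume_cm3, "source": q.source})
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    tissue: str
    measure: str  # "area" | "volume"
    slope: float  # BMI coefficient
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    significant: bool  # at the 5% level, no multiplicity correction


def fit_bmi_association(quants, subjects, measures=("area", "volume"),
                        outcome="measure") -> list:
    """Per tissue x measure OLS of the measure on BMI, adjusted by age and sex.

    ``outcome="measure"`` regresses the tissue measure on BMI + age + sex
    (the default orientation); ``outcome="bmi"`` swaps the roles, regressing
    BMI on the measure + age + sex.
    """
    import statsmodels.api as sm

    qdf = quantification_frame(quants)
    cov = pd.DataFrame(
        [{"subject_id": s.subject_id, "bmi": s.bmi, "age": s.age,
          "sex_male": 1.0 if s.sex == "male" else 0.0} for s in subjects]
    )
    if len(cov) < 10:
        raise ValueError("need at least 10 subjects for the association stage")
    merged = qdf.merge(cov, on="subject_id", how="inner")
    results = []
    present = set(merged.tissue)
    for tissue in (t for t in TISSUES if t in present):
        for measure in measures:
            sub = merged[(merged.tissue == tissue) & (merged.measure == measure)]
            if sub.subject_id.duplicated().any():
                raise ValueError(
                    f"multiple quantifications per subject for {tissue}/{measure}"
                )
            if outcome == "measure":
                endog = sub["value"].to_numpy(float)
                exog = sub[["bmi", "age", "sex_male"]].to_numpy(float)
                term = 0
            elif outcome == "bmi":
                endog = sub["bmi"].to_numpy(float)
                exog = np.column_stack(
                    [sub["value"].to_numpy(float),
                     sub[["age", "sex_male"]].to_numpy(float)]
                )
                term = 0
            else:
                raise ValueError(f"unknown outcome {outcome!r}")
            if np.ptp(exog[:, term]) == 0 and outcome == "bmi":
                raise ValueError(f"constant predictor for {tissue}/{measure}")
            if np.ptp(endog) == 0:
                # degenerate outcome: no association, by convention p = 1
                slope, ci, p = 0.0, (0.0, 0.0), 1.0
            else:
                fit = sm.OLS(endog, sm.add_constant(exog)).fit()
                slope = float(fit.params[term + 1])
                ci = fit.conf_int(alpha=0.05)[term + 1]
                p = float(fit.pvalues[term + 1])
            results.append(
                RegressionResult(
                    tissue=tissue, measure=measure, slope=slope,
                    ci_low=float(ci[0]), ci_high=float(ci[1]),
                    p_value=p, n=len(sub), significant=bool(p < 0.05),
                )
            )
    return results


def regression_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
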