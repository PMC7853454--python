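"""ROI time-activity-curve extraction and SUL/TBR quantification.

SUL is the standardized uptake value normalized to lean body mass (LBM)
rather than total body weight:

    SUL = concentration [Bq/mL] * LBM [g] / injected activity [Bq]

The default LBM formula is the Janmahasatian fat-free-mass model (the
PERCIST convention); the older James formula is selectable.  ROIs smaller
than the minimum-diameter rule (15 mm diameter, 1.8 mL) are flagged — not
dropped — since partial-volume bias is a caveat, not an error.  The arterial
ROI is deliberately small (a ~10 mm cylinder in vivo) and is exempt, with
its own 0.3 mL floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    DynamicImage,
    InputError,
    LabelMap,
    ParameterError,
    SubjectMeta,
    TimeActivityCurve,
)

__all__ = [
    "LBMResult",
    "lean_body_mass",
    "to_sul",
    "extract_tac",
    "extract_all_tacs",
    "tumor_to_blood",
    "MIN_ROI_VOLUME_ML",
    "ARTERY_MIN_VOLUME_ML",
]

log = logging.getLogger(__name__)

MIN_ROI_VOLUME_ML = 1.8  # 15 mm diameter sphere equivalent
ARTERY_MIN_VOLUME_ML = 0.3  # the arterial ROI is exempt from the 1.8 mL rule


@dataclass(frozen=True)
class LBMResult:
    lbm_kg: float
    formula_id: str


def lean_body_mass(subject: SubjectMeta,
                   formula: str = "janmahasatian") -> LBMResult:
    """Lean body mass in kg.

    janmahasatian (fat-free mass):
        male:   9270·W / (6680 + 216·BMI)
        female: 9270·W / (8780 + 244·BMI),  BMI = W / (H/100)²
    james:
        male:   1.10·W − 128·(W/H)²
        female: 1.07·W − 148·(W/H)²          (H in cm)
    """
    W = subject.weight_kg
    H = subject.height_cm
    bmi = W / (H / 100.0) ** 2
    if formula == "janmahasatian":
        if subject.sex == "male":
            lbm = 9270.0 * W / (6680.0 + 216.0 * bmi)
        else:
            lbm = 9270.0 * W / (8780.0 + 244.0 * bmi)
    elif formula == "james":
        if subject.sex == "male":
            lbm = 1.10 * W - 128.0 * (W / H) ** 2
        else:
            lbm = 1.07 * W - 148.0 * (W / H) ** 2
    else:
        raise ParameterError(f"unknown LBM formula {formula!r}")
    if not (0.0 < lbm <= W):
        raise ParameterError(
            f"non-physical LBM {lbm:.1f} kg for W={W}, H={H} ({formula})"
        )
    return LBMResult(lbm_kg=float(lbm), formula_id=formula)


def to_sul(conc, subject: SubjectMeta, lbm_kg: float | None = None,
           formula: str = "janmahasatian"):
    """Convert Bq/mL concentration(s) to SUL; linear in ``conc``."""
    if subject.injected_activity_mbq <= 0:
        raise ParameterError("injected activity must be > 0")
    if lbm_kg is None:
        lbm_kg = lean_body_mass(subject, formula).lbm_kg
    if lbm_kg <= 0:
        raise ParameterError("LBM must be > 0")
    conc = np.asarray(conc, dtype=float)
    out = conc * (lbm_kg * 1000.0) / (subject.injected_activity_mbq * 1e6)
    return out if out.ndim else float(out)


def _check_alignment(img: DynamicImage, labels: LabelMap) -> None:
    if img.shape3d != labels.labels.shape:
        raise InputError(
            f"image {img.shape3d} and label map {labels.labels.shape} "
            "shapes differ; no resampling is performed"
        )
    if np.max(np.abs(np.subtract(img.voxel_size_mm, labels.voxel_size_mm))) > 1e-4:
        raise InputError("image and label map voxel geometry differ")


def extract_tac(img: DynamicImage, labels: LabelMap, region: str,
                min_volume_ml: float = MIN_ROI_VOLUME_ML,
                lbm_formula: str = "janmahasatian") -> TimeActivityCurve:
    """Mean-over-ROI TAC for one region, with SUL and size checks.

    One static 3-D mask is applied to all frames (the propagated-ROI
    convention).  Undersized ROIs are flagged and logged, not rejected; the
    artery region uses its own 0.3 mL floor.
    """
    _check_alignment(img, labels)
    mask = labels.mask(region)
    n_vox = int(np.count_nonzero(mask))
    if n_vox == 0:
        raise InputError(f"region {region!r} is empty")
    vol_ml = n_vox * img.voxel_volume_ml
    floor = ARTERY_MIN_VOLUME_ML if region == "artery" else min_volume_ml
    undersized = vol_ml < floor
    if undersized:
        log.warning("ROI %r is %.3f mL, below the %.1f mL minimum "
                    "(partial-volume bias likely)", region, vol_ml, floor)
    conc = img.values[mask].mean(axis=0)
    sul = to_sul(conc, img.subject, formula=lbm_formula)
    return TimeActivityCurve(
        region=region,
        t_mid=img.schedule.mid_minutes,
        conc=conc,
        sul=np.asarray(sul),
        n_voxels=n_vox,
        roi_volume_ml=float(vol_ml),
        undersized=bool(undersized),
    )


def extract_all_tacs(img: DynamicImage, labels: LabelMap,
                     min_volume_ml: float = MIN_ROI_VOLUME_ML,
                     lbm_formula: str = "janmahasatian",
                     ) -> dict[str, TimeActivityCurve]:
    return {
        region: extract_tac(img, labels, region, min_volume_ml, lbm_formula)
        for region in labels.names.values()
    }


def tumor_to_blood(tumor: TimeActivityCurve, blood: TimeActivityCurve,
                   at: str | float = "last",
                   ) -> tuple[np.ndarray, float]:
    """Pointwise tumor-to-blood SUL ratio plus a scalar TBR.

    Frames with non-positive blood SUL are masked (NaN) and logged.  The
    scalar defaults to the last-frame ratio; pass a time in minutes to read
    the ratio at the frame whose mid-time is closest.
    """
    if tumor.t_mid.size != blood.t_mid.size or np.any(
            np.abs(tumor.t_mid - blood.t_mid) > 1e-9):
        raise InputError("tumor and blood TACs are on different time grids")
    valid = blood.sul > 0
    ratio = np.full(tumor.sul.shape, np.nan)
    ratio[valid] = tumor.sul[valid] / blood.sul[valid]
    if not np.all(valid):
        log.warning("blood SUL <= 0 in %d frame(s); ratio masked there",
                    int(np.count_nonzero(~valid)))
    if at == "last":
        idx = len(tumor) - 1
    else:
        idx = int(np.argmin(np.abs(tumor.t_mid - float(at))))
    return ratio, float(ratio[idx])
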