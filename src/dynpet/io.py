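"""NIfTI / JSON-sidecar / CSV input-output and temporal rebinning.

Dialect: NIfTI-1 volumes; a JSON sidecar using BIDS-PET field names
(``FrameTimesStart``/``FrameDuration`` in seconds, ``InjectedRadioactivity``
in MBq, ``Weight_kg``, ``Height_cm``, ``Sex``); a long-format TAC CSV with
one row per (region, frame).  The sidecar is seconds, everything
analysis-facing is minutes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    DynamicImage,
    FormatError,
    FrameSchedule,
    InputError,
    LabelMap,
    SubjectMeta,
    TimeActivityCurve,
)

__all__ = [
    "read_dynamic",
    "write_dynamic",
    "read_labels",
    "write_labels",
    "read_tacs",
    "write_tacs",
    "rebin",
    "rebin_tac",
    "rebin_image",
]

log = logging.getLogger(__name__)

TAC_COLUMNS = ["region", "n_voxels", "roi_volume_ml", "undersized",
               "frame_index", "t_mid_min", "conc_bq_ml", "sul"]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_dynamic(img: DynamicImage, image_path, sidecar_path) -> None:
    nii = nib.Nifti1Image(np.asarray(img.values, dtype=np.float64),
                          _affine(img.voxel_size_mm))
    nii.header.set_xyzt_units("mm", "sec")
    nib.save(nii, str(image_path))
    sidecar = {
        "FrameTimesStart": img.schedule.start.tolist(),
        "FrameDuration": img.schedule.duration.tolist(),
        "InjectedRadioactivity": img.subject.injected_activity_mbq,
        "InjectedRadioactivityUnits": "MBq",
        "InjectionTime": img.subject.injection_time,
        "Weight_kg": img.subject.weight_kg,
        "Height_cm": img.subject.height_cm,
        "Sex": img.subject.sex,
        "Units": "Bq/mL",
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_dynamic(image_path, sidecar_path) -> DynamicImage:
    """Load a 4-D PET volume plus its timing/subject sidecar."""
    nii = nib.load(str(image_path))
    values = np.asarray(nii.dataobj, dtype=float)
    if values.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4-D volume, "
                          f"got shape {values.shape}")
    doc = json.loads(Path(sidecar_path).read_text())
    for key in ("FrameTimesStart", "FrameDuration", "InjectedRadioactivity",
                "Weight_kg", "Height_cm", "Sex"):
        if key not in doc:
            raise FormatError(f"sidecar missing required field {key!r}")
    schedule = FrameSchedule(
        start=np.asarray(doc["FrameTimesStart"], dtype=float),
        duration=np.asarray(doc["FrameDuration"], dtype=float),
    )
    if schedule.n_frames != values.shape[3]:
        raise FormatError(
            f"image has {values.shape[3]} frames but sidecar lists "
            f"{schedule.n_frames}")
    if doc.get("Units", None) is None:
        log.warning("sidecar has no Units field; assuming Bq/mL")
    subject = SubjectMeta(
        weight_kg=float(doc["Weight_kg"]),
        height_cm=float(doc["Height_cm"]),
        sex=str(doc["Sex"]),
        injected_activity_mbq=float(doc["InjectedRadioactivity"]),
        injection_time=str(doc.get("InjectionTime", "1970-01-01T00:00:00")),
    )
    zooms = nii.header.get_zooms()[:3]
    return DynamicImage(values=values, voxel_size_mm=tuple(float(z) for z in zooms),
                        schedule=schedule, subject=subject)


def write_labels(labels: LabelMap, image_path, names_path=None) -> None:
    nii = nib.Nifti1Image(np.asarray(labels.labels, dtype=np.int16),
                          _affine(labels.voxel_size_mm))
    nib.save(nii, str(image_path))
    if names_path is not None:
        Path(names_path).write_text(
            json.dumps({str(k): v for k, v in labels.names.items()}, indent=2))


def read_labels(image_path, names_path=None) -> LabelMap:
    nii = nib.load(str(image_path))
    arr = np.asarray(nii.dataobj)
    if not np.allclose(arr, np.round(arr)):
        raise FormatError(f"{image_path}: label volume is not integer-valued")
    arr = np.round(arr).astype(np.int16)
    if names_path is not None:
        names = {int(k): str(v)
                 for k, v in json.loads(Path(names_path).read_text()).items()}
    else:
        names = {int(i): f"region_{int(i)}" for i in np.unique(arr) if i != 0}
    zooms = nii.header.get_zooms()[:3]
    return LabelMap(labels=arr, names=names,
                    voxel_size_mm=tuple(float(z) for z in zooms))


# ---------------------------------------------------------------------------
# TAC CSV


def write_tacs(tacs: dict[str, TimeActivityCurve] | list[TimeActivityCurve],
               path) -> None:
    if isinstance(tacs, dict):
        tacs = list(tacs.values())
    rows = []
    for tac in tacs:
        for f in range(len(tac)):
            rows.append((tac.region, tac.n_voxels, tac.roi_volume_ml,
                         int(tac.undersized), f, tac.t_mid[f], tac.conc[f],
                         tac.sul[f]))
    df = pd.DataFrame(rows, columns=TAC_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_tacs(path) -> dict[str, TimeActivityCurve]:
    df = pd.read_csv(path)
    missing = set(TAC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"TAC CSV missing columns: {sorted(missing)}")
    out: dict[str, TimeActivityCurve] = {}
    for region, sub in df.groupby("region", sort=False):
        sub = sub.sort_values("frame_index")
        out[str(region)] = TimeActivityCurve(
            region=str(region),
            t_mid=sub["t_mid_min"].to_numpy(),
            conc=sub["conc_bq_ml"].to_numpy(),
            sul=sub["sul"].to_numpy(),
            n_voxels=int(sub["n_voxels"].iloc[0]),
            roi_volume_ml=float(sub["roi_volume_ml"].iloc[0]),
            undersized=bool(sub["undersized"].iloc[0]),
        )
    return out


# ---------------------------------------------------------------------------
# temporal rebinning


def _frame_mapping(src: FrameSchedule, dst: FrameSchedule,
                   tol: float = 1e-6) -> list[np.ndarray]:
    """For each target frame, the source frame indices that tile it exactly."""
    mapping = []
    for j in range(dst.n_frames):
        t0, t1 = dst.start[j], dst.end[j]
        sel = np.where((src.start >= t0 - tol) & (src.end <= t1 + tol))[0]
        if sel.size == 0:
            raise InputError(f"target frame {j} contains no source frames")
        covered = src.duration[sel].sum()
        if (abs(src.start[sel[0]] - t0) > tol
                or abs(src.end[sel[-1]] - t1) > tol
                or abs(covered - (t1 - t0)) > tol):
            raise InputError(
                f"target frame {j} [{t0}, {t1}] s is not a union of whole "
                "source frames")
        mapping.append(sel)
    return mapping


def rebin_tac(tac: TimeActivityCurve, src: FrameSchedule,
              dst: FrameSchedule) -> TimeActivityCurve:
    """Duration-weighted rebinning of a TAC from ``src`` to ``dst`` frames."""
    if src.n_frames != len(tac):
        raise InputError("TAC length does not match source schedule")
    mapping = _frame_mapping(src, dst)
    w = src.duration

    def agg(y: np.ndarray) -> np.ndarray:
        # single-source-frame targets pass through exactly (identity rebin)
        return np.array([
            y[s[0]] if s.size == 1 else np.sum(y[s] * w[s]) / np.sum(w[s])
            for s in mapping
        ])

    return TimeActivityCurve(
        region=tac.region, t_mid=dst.mid_minutes,
        conc=agg(tac.conc), sul=agg(tac.sul),
        n_voxels=tac.n_voxels, roi_volume_ml=tac.roi_volume_ml,
        undersized=tac.undersized,
    )


def rebin_image(img: DynamicImage, dst: FrameSchedule) -> DynamicImage:
    """Duration-weighted rebinning of a 4-D image along the frame axis."""
    mapping = _frame_mapping(img.schedule, dst)
    w = img.schedule.duration
    out = np.empty(img.shape3d + (dst.n_frames,), dtype=float)
    for j, sel in enumerate(mapping):
        out[..., j] = np.tensordot(img.values[..., sel], w[sel],
                                   axes=([3], [0])) / w[sel].sum()
    return DynamicImage(values=out, voxel_size_mm=img.voxel_size_mm,
                        schedule=dst, subject=img.subject)


def rebin(obj, dst: FrameSchedule, src: FrameSchedule | None = None):
    """Rebin a DynamicImage or a TimeActivityCurve onto a coarser schedule.

    Each target frame must be a union of whole source frames; target values
    are duration-weighted means, so activity·time is conserved per frame.
    """
    if isinstance(obj, DynamicImage):
        return rebin_image(obj, dst)
    if isinstance(obj, TimeActivityCurve):
        if src is None:
            raise InputError("rebinning a TAC requires its source schedule")
        return rebin_tac(obj, src, dst)
    raise InputError(f"cannot rebin object of type {type(obj).__name__}")
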