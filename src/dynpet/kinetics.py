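"""Operational TAC-shape definitions: plateau, bladder onset, peak, class.

An uptake *plateau* is the time from which the TAC slope stays close to
zero, with 0.2 SUL/min as the maximum slope magnitude.  The slope is a
least-squares fit over a short sliding window (default 3 frames) and the
plateau must be sustained: the detected window and every later window must
satisfy the threshold, so a single quiet window on the inflow shoulder or a
late re-acceleration cannot masquerade as a plateau.  With 1-min frames the
threshold equals SUL-per-frame; it is an absolute threshold, so detection is
intentionally scale-sensitive.

*Bladder-filling onset* is the first frame where bladder uptake reaches
twice the gluteal-muscle (background) uptake; reported at mid-frame
resolution without sub-frame interpolation.

Lesions are classified *stable* when a plateau is detected at or before a
cutoff (default 10 min, giving margin over the ~5 min plateaus of stable
lesions) and *rising* otherwise.  A plateau detected after the cutoff but
before scan end is classified rising with a ``late_plateau`` note: an
accumulating lesion whose late slope hovers near the threshold is still an
accumulator, and genuinely stable curves settle well before the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import InputError, TimeActivityCurve

__all__ = [
    "PlateauResult",
    "OnsetResult",
    "UptakeClass",
    "detect_plateau",
    "bladder_onset",
    "classify_uptake",
    "arterial_peak",
    "SLOPE_MAX_DEFAULT",
    "PLATEAU_CUTOFF_MIN",
]

log = logging.getLogger(__name__)

SLOPE_MAX_DEFAULT = 0.2  # SUL/min
PLATEAU_CUTOFF_MIN = 10.0


@dataclass(frozen=True)
class PlateauResult:
    plateau_time: float | None  # min; None when no sustained plateau
    plateau_level: float | None  # mean SUL over post-plateau frames
    slope_at_detection: float | None  # SUL/min of the detected window


@dataclass(frozen=True)
class OnsetResult:
    onset_time: float | None  # min; None when threshold never reached


@dataclass(frozen=True)
class UptakeClass:
    label: str  # "stable" | "rising"
    basis: float | None  # plateau time the label rests on, if any
    note: str = ""


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope of y vs t over each run of ``window`` frames."""
    n = t.size - window + 1
    slopes = np.empty(n)
    for i in range(n):
        ts = t[i:i + window]
        ys = y[i:i + window]
        tc = ts - ts.mean()
        slopes[i] = float(tc @ (ys - ys.mean()) / (tc @ tc))
    return slopes


def detect_plateau(tac: TimeActivityCurve,
                   slope_max: float = SLOPE_MAX_DEFAULT,
                   window: int = 3,
                   skip_peak: bool = True) -> PlateauResult:
    """Earliest sustained near-zero-slope window of a TAC.

    Windows are ``window`` consecutive frames; the plateau time is the mean
    mid-frame time of the earliest window (after the curve's global peak
    when ``skip_peak``) whose slope and every subsequent window's slope
    satisfy ``|slope| <= slope_max``.  Ties in the peak go to the earliest
    frame, so a constant curve plateaus at its first evaluable window.
    """
    if window < 2:
        raise InputError("window must be >= 2 frames")
    t, y = tac.t_mid, tac.sul
    if t.size < window + 1:
        raise InputError(
            f"need at least {window + 1} frames, got {t.size}")
    slopes = _window_slopes(t, y, window)
    quiet = np.abs(slopes) <= slope_max
    # sustained[i]: window i and all later windows are quiet
    sustained = np.flip(np.logical_and.accumulate(np.flip(quiet)))
    first = int(np.argmax(y)) + 1 if skip_peak else 0
    for i in range(first, slopes.size):
        if sustained[i]:
            return PlateauResult(
                plateau_time=float(t[i:i + window].mean()),
                plateau_level=float(y[i:].mean()),
                slope_at_detection=float(slopes[i]),
            )
    return PlateauResult(plateau_time=None, plateau_level=None,
                         slope_at_detection=None)


def bladder_onset(bladder: TimeActivityCurve,
                  background: TimeActivityCurve,
                  factor: float = 2.0) -> OnsetResult:
    """First mid-frame time where bladder SUL >= factor × background SUL."""
    if factor <= 0:
        raise InputError("factor must be > 0")
    if bladder.t_mid.size != background.t_mid.size or np.any(
            np.abs(bladder.t_mid - background.t_mid) > 1e-9):
        raise InputError("bladder and background TACs on different grids")
    hit = (background.sul > 0) & (bladder.sul >= factor * background.sul)
    if not np.any(hit):
        return OnsetResult(onset_time=None)
    return OnsetResult(onset_time=float(bladder.t_mid[int(np.argmax(hit))]))


def classify_uptake(tac: TimeActivityCurve,
                    plateau_cutoff: float = PLATEAU_CUTOFF_MIN,
                    slope_max: float = SLOPE_MAX_DEFAULT,
                    window: int = 3) -> UptakeClass:
    """Stable (plateau at or before the cutoff) vs rising lesion uptake."""
    if tac.t_mid[-1] < plateau_cutoff:
        raise InputError(
            f"TAC ends at {tac.t_mid[-1]:.1f} min, before the "
            f"{plateau_cutoff:.0f} min cutoff")
    res = detect_plateau(tac, slope_max=slope_max, window=window)
    if res.plateau_time is None:
        return UptakeClass(label="rising", basis=None)
    if res.plateau_time <= plateau_cutoff:
        return UptakeClass(label="stable", basis=res.plateau_time)
    log.info("region %r plateaus only at %.1f min (> %.0f min cutoff); "
             "treating as rising (late_plateau)", tac.region,
             res.plateau_time, plateau_cutoff)
    return UptakeClass(label="rising", basis=res.plateau_time,
                       note="late_plateau")


def arterial_peak(tac: TimeActivityCurve) -> tuple[float, float]:
    """(peak SUL, mid-frame time of the peak); ties go to the earliest."""
    idx = int(np.argmax(tac.sul))
    return float(tac.sul[idx]), float(tac.t_mid[idx])
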