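"""Test–retest repeatability metrics and stable-vs-rising group contrast.

Intra-patient variation is the absolute percentage change between the two
visits, |retest − test| / D × 100 with D the test value by default (the
symmetric mean-of-both denominator is selectable); the cohort is summarized
as median (range) per region.  Inter-patient variation is the coefficient
of variation, sample SD (n−1) / mean × 100, over the test-visit values.

The per-region summary value is the maximum of the frame-wise SUL_mean over
the scan (configurable to the SUL at a fixed time).  The group contrast
reports per-group mean lesion volumes (raw and whole-mL rounded, with the
ratio of rounded means), per-group mean SUL at requested times, and a Welch
two-sample t-test p-value per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import InputError, LabelMap, TimeActivityCurve

__all__ = [
    "ScanSummary",
    "RegionRepeatability",
    "RepeatabilityReport",
    "GroupContrast",
    "summary_sul",
    "intra_patient_pct",
    "inter_patient_cov",
    "cohort_repeatability",
    "group_contrast",
    "lesion_volume",
]


@dataclass(frozen=True)
class ScanSummary:
    """One region's summary for one (subject, visit)."""

    subject_id: str
    visit: str  # "test" | "retest"
    region: str
    summary_sul: float
    plateau_time: float | None = None
    uptake_class: str | None = None
    onset_time: float | None = None
    lesion_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.visit not in ("test", "retest"):
            raise InputError(f"visit must be test/retest, got {self.visit!r}")
        if self.summary_sul < 0:
            raise InputError("summary SUL must be >= 0")


@dataclass(frozen=True)
class RegionRepeatability:
    region: str
    n_subjects: int
    intra_pct: dict[str, float]  # per subject
    intra_pct_median: float
    intra_pct_range: tuple[float, float]
    inter_cov_pct: float
    summary_sul_median: float
    summary_sul_range: tuple[float, float]


@dataclass(frozen=True)
class RepeatabilityReport:
    regions: dict[str, RegionRepeatability]
    denominator: str  # "test" | "mean"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.regions.values():
            rows.append({
                "region": r.region,
                "n_subjects": r.n_subjects,
                "summary_sul_median": r.summary_sul_median,
                "summary_sul_min": r.summary_sul_range[0],
                "summary_sul_max": r.summary_sul_range[1],
                "intra_pct_median": r.intra_pct_median,
                "intra_pct_min": r.intra_pct_range[0],
                "intra_pct_max": r.intra_pct_range[1],
                "inter_cov_pct": r.inter_cov_pct,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupContrast:
    mean_volume_ml: dict[str, float]  # raw means per group
    mean_volume_ml_rounded: dict[str, float]  # whole-mL rounded means
    volume_ratio_rounded: float  # rising / stable, on rounded means
    volume_ratio_raw: float
    mean_sul_at: dict[float, dict[str, float]]  # t_eval -> group -> mean SUL
    p_value_at: dict[float, float | None]  # Welch p per t_eval (None if n=1)
    n_per_group: dict[str, int]


def summary_sul(tac: TimeActivityCurve, at: float | None = None) -> float:
    """Highest frame SUL over the scan, or the SUL at a fixed time (min)."""
    if at is None:
        return float(np.max(tac.sul))
    return float(np.interp(float(at), tac.t_mid, tac.sul))


def intra_patient_pct(x_test: float, x_retest: float,
                      denominator: str = "test") -> float:
    """Absolute test–retest percentage change."""
    if x_test <= 0 or x_retest <= 0:
        raise InputError("test/retest values must be > 0")
    if denominator == "test":
        d = x_test
    elif denominator == "mean":
        d = 0.5 * (x_test + x_retest)
    else:
        raise InputError(f"denominator must be test|mean, got {denominator!r}")
    return float(abs(x_retest - x_test) / d * 100.0)


def inter_patient_cov(values) -> float:
    """Coefficient of variation, sample SD (n−1) / mean × 100."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InputError("CoV needs at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise InputError("CoV needs a positive mean")
    return float(values.std(ddof=1) / mean * 100.0)


def _median_range(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    # midpoint-of-central-order-statistics median (numpy's default)
    return float(np.median(x)), (float(np.min(x)), float(np.max(x)))


def cohort_repeatability(summaries: list[ScanSummary],
                         denominator: str = "test") -> RepeatabilityReport:
    """Per-region intra-patient % change and inter-patient CoV for a cohort.

    Every subject must contribute exactly one test and one retest summary
    per region; the CoV is computed over the test-visit values.
    """
    regions: dict[str, RegionRepeatability] = {}
    by_region: dict[str, list[ScanSummary]] = {}
    for s in summaries:
        by_region.setdefault(s.region, []).append(s)
    for region, items in by_region.items():
        pairs: dict[str, dict[str, float]] = {}
        for s in items:
            slot = pairs.setdefault(s.subject_id, {})
            if s.visit in slot:
                raise InputError(
                    f"duplicate {s.visit} visit for {s.subject_id}/{region}")
            slot[s.visit] = s.summary_sul
        for sid, slot in pairs.items():
            if set(slot) != {"test", "retest"}:
                raise InputError(
                    f"subject {sid} lacks a paired test/retest for {region}")
        intra = {
            sid: intra_patient_pct(slot["test"], slot["retest"], denominator)
            for sid, slot in sorted(pairs.items())
        }
        tests = np.array([pairs[sid]["test"] for sid in sorted(pairs)])
        med, rng = _median_range(np.array(list(intra.values())))
        sul_med, sul_rng = _median_range(tests)
        regions[region] = RegionRepeatability(
            region=region,
            n_subjects=len(pairs),
            intra_pct=intra,
            intra_pct_median=med,
            intra_pct_range=rng,
            inter_cov_pct=inter_patient_cov(tests),
            summary_sul_median=sul_med,
            summary_sul_range=sul_rng,
        )
    return RepeatabilityReport(regions=regions, denominator=denominator)


def group_contrast(lesions: list[tuple[str, float, TimeActivityCurve]],
                   t_eval: list[float] = (5.0, 20.0)) -> GroupContrast:
    """Stable-vs-rising lesion contrast: volumes and SUL at fixed times.

    ``lesions`` holds (class label, lesion volume mL, TAC) triples; labels
    must be "stable" or "rising" and both groups must be non-empty.
    """
    groups: dict[str, list[tuple[float, TimeActivityCurve]]] = {
        "stable": [], "rising": []}
    for label, vol, tac in lesions:
        if label not in groups:
            raise InputError(f"unknown group label {label!r}")
        groups[label].append((float(vol), tac))
    for label, members in groups.items():
        if not members:
            raise InputError(f"group {label!r} is empty")

    mean_vol = {g: float(np.mean([v for v, _ in m]))
                for g, m in groups.items()}
    mean_vol_rounded = {g: float(np.round(v)) for g, v in mean_vol.items()}
    mean_sul_at: dict[float, dict[str, float]] = {}
    p_at: dict[float, float | None] = {}
    for t in t_eval:
        vals = {g: np.array([summary_sul(tac, at=t) for _, tac in m])
                for g, m in groups.items()}
        mean_sul_at[float(t)] = {g: float(v.mean()) for g, v in vals.items()}
        if min(v.size for v in vals.values()) < 2:
            p_at[float(t)] = None
        else:
            p_at[float(t)] = float(stats.ttest_ind(
                vals["rising"], vals["stable"], equal_var=False).pvalue)
    return GroupContrast(
        mean_volume_ml=mean_vol,
        mean_volume_ml_rounded=mean_vol_rounded,
        volume_ratio_rounded=mean_vol_rounded["rising"] / mean_vol_rounded["stable"],
        volume_ratio_raw=mean_vol["rising"] / mean_vol["stable"],
        mean_sul_at=mean_sul_at,
        p_value_at=p_at,
        n_per_group={g: len(m) for g, m in groups.items()},
    )


def lesion_volume(labels: LabelMap, region: str) -> float:
    """Region volume in mL: voxel count × voxel volume."""
    n = int(np.count_nonzero(labels.mask(region)))
    if n == 0:
        raise InputError(f"region {region!r} is empty")
    return n * labels.voxel_volume_ml
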