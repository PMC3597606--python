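"""Radioimmunotherapy outcome analysis.

Caliper measurements become volumes (w × h × d / 2), per-animal growth curves
are classified into four response categories, arms are summarized as mean
relative volume per day with censoring at the humane endpoint (volume above
200 mm³), a dose–response threshold is extracted across arms, and
TUNEL-positive field counts are reduced to apoptotic-cell densities.

Response taxonomy
-----------------
complete_regression
    volume at or below the disappearance threshold at some day >= 7 and
    staying there through the end of observation.
regression_with_regrowth
    volume reached the disappearance threshold but later exceeded
    ``regrowth_factor`` × threshold.
progression
    final volume above baseline with the curve never dipping below baseline.
growth_delay
    everything else: transient shrinkage (or net shrinkage) without complete
    disappearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TumorMeasurement",
    "GrowthRecord",
    "ApoptosisFieldCounts",
    "tumor_volume",
    "classify_response",
    "arm_summary",
    "dose_response_threshold",
    "apoptosis_density",
    "RESPONSE_LABELS",
    "HUMANE_ENDPOINT_MM3",
    "DISAPPEARANCE_THRESHOLD_MM3",
    "DEFAULT_REGROWTH_FACTOR",
    "DEFAULT_OBSERVATION_END_DAY",
]

RESPONSE_LABELS = ("progression", "growth_delay", "complete_regression", "regression_with_regrowth")

#: Humane endpoint: animals are censored once volume exceeds this.
HUMANE_ENDPOINT_MM3 = 200.0
#: "Completely disappeared" operationalized as volume <= 1 mm³.
DISAPPEARANCE_THRESHOLD_MM3 = 1.0
DEFAULT_REGROWTH_FACTOR = 2.0
#: Last scheduled observation day of the treatment experiment.
DEFAULT_OBSERVATION_END_DAY = 28.0


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement: three orthogonal dimensions in mm."""

    animal_id: str
    day: float
    width_mm: float
    height_mm: float
    depth_mm: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if min(self.width_mm, self.height_mm, self.depth_mm) < 0:
            raise ValueError("dimensions must be >= 0 mm")


def tumor_volume(m: TumorMeasurement) -> float:
    """Tumor volume in mm³: width × height × depth / 2."""
    return m.width_mm * m.height_mm * m.depth_mm / 2.0


@dataclass(frozen=True)
class GrowthRecord:
    """Per-animal tumor-volume (and optional body-weight) series."""

    animal_id: str
    arm: str
    days: np.ndarray
    volumes_mm3: np.ndarray
    body_weights_g: Optional[np.ndarray] = None
    censored_day: Optional[float] = None
    response: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, float))
        object.__setattr__(self, "volumes_mm3", np.asarray(self.volumes_mm3, float))
        if self.body_weights_g is not None:
            object.__setattr__(self, "body_weights_g", np.asarray(self.body_weights_g, float))
        d, v = self.days, self.volumes_mm3
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("days and volumes must be 1-D and aligned")
        if np.any(np.diff(d) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("volumes must be >= 0")
        if self.response is not None and self.response not in RESPONSE_LABELS:
            raise ValueError(f"unknown response label {self.response!r}")


def apply_censoring(record: GrowthRecord, endpoint_mm3: float = HUMANE_ENDPOINT_MM3) -> GrowthRecord:
    """Truncate a series at the first day the volume exceeds the endpoint.

    The first above-endpoint measurement is kept (it triggers euthanasia and
    sets ``censored_day``); later measurements are dropped.
    """
    over = np.flatnonzero(record.volumes_mm3 > endpoint_mm3)
    if over.size == 0:
        return record
    cut = over[0]
    return GrowthRecord(
        animal_id=record.animal_id,
        arm=record.arm,
        days=record.days[: cut + 1],
        volumes_mm3=record.volumes_mm3[: cut + 1],
        body_weights_g=None if record.body_weights_g is None else record.body_weights_g[: cut + 1],
        censored_day=float(record.days[cut]),
        response=record.response,
    )


def classify_response(
    days: Sequence[float],
    volumes_mm3: Sequence[float],
    disappearance_threshold_mm3: float = DISAPPEARANCE_THRESHOLD_MM3,
    regrowth_factor: float = DEFAULT_REGROWTH_FACTOR,
    observation_end_day: float = DEFAULT_OBSERVATION_END_DAY,
) -> str:
    """Classify one growth curve into the four-way response taxonomy."""
    d = np.asarray(days, float)
    v = np.asarray(volumes_mm3, float)
    if d.size < 3:
        raise ValueError(f"need >= 3 time points to classify, got {d.size}")
    thr = disappearance_threshold_mm3

    reached = np.flatnonzero(v <= thr)
    if reached.size:
        first = reached[0]
        if np.any(v[first:] > regrowth_factor * thr):
            return "regression_with_regrowth"
        # sustained disappearance: below threshold at some day >= 7 and at the
        # last observation within the window
        in_window = d <= observation_end_day
        if np.any((v <= thr) & (d >= 7.0)) and v[in_window][-1] <= thr:
            return "complete_regression"
        return "growth_delay"
    if v[-1] > v[0] and np.all(v >= v[0]):
        return "progression"
    return "growth_delay"


def arm_summary(records: Sequence[GrowthRecord], endpoint_mm3: float = HUMANE_ENDPOINT_MM3) -> dict:
    """Per-arm summary: mean relative volume per day, response and censor counts.

    Relative volume is volume / day-0 volume per animal. Measurements after an
    animal's censoring day are excluded; per-day n is reported alongside.
    """
    if not records:
        raise ValueError("arm has no records")
    censored = [apply_censoring(r, endpoint_mm3) for r in records]
    rows = []
    for rec in censored:
        if rec.days[0] != 0:
            raise ValueError(f"animal {rec.animal_id!r} has no day-0 volume; cannot normalize")
        v0 = rec.volumes_mm3[0]
        if v0 <= 0:
            raise ValueError(f"animal {rec.animal_id!r} has non-positive day-0 volume")
        for d, v in zip(rec.days, rec.volumes_mm3):
            rows.append({"animal_id": rec.animal_id, "day": d, "rel_volume": v / v0})
    df = pd.DataFrame(rows)
    per_day = (
        df.groupby("day", as_index=False)["rel_volume"]
        .agg(mean_rel_volume="mean",
             sd_rel_volume=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
             n="size")
    )
    responses = [r.response for r in records if r.response is not None]
    return {
        "arm": records[0].arm,
        "n_animals": len(records),
        "per_day": per_day,
        "complete_response_count": sum(r == "complete_regression" for r in responses),
        "censored_count": sum(r.censored_day is not None for r in censored),
    }


def dose_response_threshold(
    arm_doses_Gy: dict[str, float],
    arm_responses: dict[str, Sequence[str]],
    allowed_exceptions: int = 1,
) -> dict:
    """Minimal absorbed dose whose arm achieved (near-)complete regression.

    An arm qualifies when at most ``allowed_exceptions`` of its animals failed
    to reach complete regression. Returns the minimum qualifying dose plus any
    non-qualifying arms at a higher dose (empty for a monotone dose–response);
    ``threshold_Gy`` is None when no arm qualifies.
    """
    if set(arm_doses_Gy) != set(arm_responses):
        raise ValueError("arm_doses_Gy and arm_responses must cover the same arms")
    qualifying, failing = {}, {}
    for arm, labels in arm_responses.items():
        labels = list(labels)
        if not labels:
            raise ValueError(f"arm {arm!r} has no response labels")
        misses = sum(l != "complete_regression" for l in labels)
        (qualifying if misses <= allowed_exceptions else failing)[arm] = arm_doses_Gy[arm]
    if not qualifying:
        return {"threshold_Gy": None, "qualifying_arms": [], "violations_above_threshold": []}
    threshold = min(qualifying.values())
    violations = sorted(a for a, dose in failing.items() if dose > threshold)
    return {
        "threshold_Gy": threshold,
        "qualifying_arms": sorted(qualifying, key=qualifying.get),
        "violations_above_threshold": violations,
    }


@dataclass(frozen=True)
class ApoptosisFieldCounts:
    """TUNEL-positive vs total cell counts over microscope fields (>= 5)."""

    arm: str
    tunel_positive: np.ndarray
    total_cells: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "tunel_positive", np.asarray(self.tunel_positive, float))
        object.__setattr__(self, "total_cells", np.asarray(self.total_cells, float))
        p, t = self.tunel_positive, self.total_cells
        if p.shape != t.shape or p.ndim != 1:
            raise ValueError("tunel_positive and total_cells must be 1-D and aligned")
        if p.size < 5:
            raise ValueError(f"need >= 5 fields, got {p.size}")
        if np.any(t <= 0):
            raise ValueError("total_cells must be > 0 in every field")
        if np.any(p < 0) or np.any(p > t):
            raise ValueError("tunel_positive must lie in [0, total_cells]")


def apoptosis_density(afc: ApoptosisFieldCounts) -> dict:
    """Mean and SD of the per-field TUNEL-positive fraction."""
    frac = afc.tunel_positive / afc.total_cells
    return {
        "arm": afc.arm,
        "mean_fraction": float(frac.mean()),
        "sd_fraction": float(frac.std(ddof=1)) if frac.size > 1 else 0.0,
        "n_fields": int(frac.size),
    }


def compare_apoptosis(a: ApoptosisFieldCounts, b: ApoptosisFieldCounts) -> dict:
    """Descriptive two-sample comparison of per-field apoptotic fractions."""
    fa = a.tunel_positive / a.total_cells
    fb = b.tunel_positive / b.total_cells
    t, p = stats.ttest_ind(fa, fb, equal_var=False)
    return {"arms": [a.arm, b.arm], "t_statistic": float(t), "p_value": float(p)}
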