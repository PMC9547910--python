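"""Graded Chronic Pain Scale (GCPS) scoring.

The GCPS (von Korff) grades chronic pain severity from seven self-report
items covering the last six months:

* three pain-intensity ratings (0-10): pain right now, average pain,
  worst pain -> pain-intensity score = mean x 10 (0-100);
* three interference ratings (0-10): daily, social and work activities
  -> disability score = mean x 10 (0-100);
* one disability-days count (0-180).

Disability days and disability score are each binned to 0-3 points and
summed to 0-6 total disability points:

=============  ======  ================  ======
days           points  score             points
=============  ======  ================  ======
0-6            0       0-29              0
7-14           1       30-49             1
15-30          2       50-69             2
31-180         3       >= 70             3
=============  ======  ================  ======

Grades: with <= 2 disability points the intensity score decides (grade I
below 50, grade II at 50 or above); 3-4 points give grade III and 5-6
points grade IV, regardless of intensity. Grades III-IV are the "severe"
(non-functional) cases. For comparison against a three-level classifier,
grades I and II collapse to level 1, III to 2 and IV to 3.

Scores are kept unrounded (exact thirds) before thresholding; every
threshold is inclusive at the upper category (intensity exactly 50 ->
grade II). Grade 0 ("pain-free") is not modelled: an all-zero response is
still grade I, flagged with a warning, because the instrument is applied
here to a population that enrolled for back-pain care.

All seven items are required; there is no missing-item imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ValidationError

GRADES = ("I", "II", "III", "IV")

#: lower edges of the disability-score point bins (points 1, 2, 3)
SCORE_POINT_CUTS = (30.0, 50.0, 70.0)
#: lower edges of the disability-day point bins (points 1, 2, 3)
DAY_POINT_CUTS = (7, 15, 31)
#: pain-intensity score at or above which grade I becomes grade II
INTENSITY_THRESHOLD = 50.0


@dataclass(frozen=True)
class GcpsResponse:
    """The seven raw questionnaire items for one respondent."""

    pain_now: int
    pain_avg: int
    pain_worst: int
    interf_daily: int
    interf_social: int
    interf_work: int
    disability_days: int

    def __post_init__(self) -> None:
        for name in ("pain_now", "pain_avg", "pain_worst",
                     "interf_daily", "interf_social", "interf_work"):
            _check_item(name, getattr(self, name), 10)
        _check_item("disability_days", self.disability_days, 180)


@dataclass(frozen=True)
class GcpsScore:
    """Derived GCPS quantities for one respondent."""

    pain_intensity: float
    disability_score: float
    days_points: int
    score_points: int
    disability_points: int
    grade: str
    grade3: int
    severe: bool


def _check_item(name: str, value: object, hi: int) -> int:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
        raise ValidationError(f"GCPS item {name} must be an integer, got {value!r}")
    if not 0 <= int(value) <= hi:
        raise ValidationError(f"GCPS item {name}={value} outside 0..{hi}")
    return int(value)


def pain_intensity_score(pain_now: int, pain_avg: int, pain_worst: int) -> float:
    """Mean of the three 0-10 intensity items, times ten (0-100, unrounded)."""
    items = [_check_item(n, v, 10) for n, v in
             (("pain_now", pain_now), ("pain_avg", pain_avg), ("pain_worst", pain_worst))]
    return sum(items) / 3.0 * 10.0


def disability_score(interf_daily: int, interf_social: int, interf_work: int) -> float:
    """Mean of the three 0-10 interference items, times ten (0-100, unrounded)."""
    items = [_check_item(n, v, 10) for n, v in
             (("interf_daily", interf_daily), ("interf_social", interf_social),
              ("interf_work", interf_work))]
    return sum(items) / 3.0 * 10.0


def disability_days_points(disability_days: int) -> int:
    """Bin disability days: 0-6 -> 0, 7-14 -> 1, 15-30 -> 2, 31-180 -> 3."""
    days = _check_item("disability_days", disability_days, 180)
    return int(np.searchsorted(DAY_POINT_CUTS, days, side="right"))


def disability_score_points(score: float) -> int:
    """Bin the disability score: 0-29 -> 0, 30-49 -> 1, 50-69 -> 2, >= 70 -> 3."""
    if not 0.0 <= score <= 100.0:
        raise ValidationError(f"disability score {score} outside 0..100")
    return int(np.searchsorted(SCORE_POINT_CUTS, score, side="right"))


def assign_grade(pain_intensity: float, disability_points: int) -> str:
    """Combine intensity score and disability points into grade I-IV."""
    if not 0 <= disability_points <= 6:
        raise ValueError(f"disability points {disability_points} outside 0..6")
    if disability_points >= 5:
        return "IV"
    if disability_points >= 3:
        return "III"
    return "II" if pain_intensity >= INTENSITY_THRESHOLD else "I"


def collapse_to_three(grade: str) -> int:
    """Collapse the four grades to a three-level scale: I,II -> 1, III -> 2, IV -> 3."""
    try:
        return {"I": 1, "II": 1, "III": 2, "IV": 3}[grade]
    except KeyError:
        raise ValueError(f"unknown grade {grade!r}") from None


def dichotomize_gcps(grade: str) -> bool:
    """True for severe (non-functional) chronic pain, i.e. grades III and IV."""
    if grade not in GRADES:
        raise ValueError(f"unknown grade {grade!r}")
    return grade in ("III", "IV")


def score_response(response: GcpsResponse, *, warn_pain_free: bool = True) -> GcpsScore:
    """Score one complete response into a :class:`GcpsScore`."""
    intensity = pain_intensity_score(
        response.pain_now, response.pain_avg, response.pain_worst
    )
    d_score = disability_score(
        response.interf_daily, response.interf_social, response.interf_work
    )
    dp = disability_days_points(response.disability_days)
    sp = disability_score_points(d_score)
    points = dp + sp
    grade = assign_grade(intensity, points)
    if warn_pain_free and intensity == 0.0 and points == 0:
        warnings.warn(
            "all-zero GCPS response graded I (pain-free grade 0 is not modelled)",
            stacklevel=2,
        )
    return GcpsScore(
        pain_intensity=intensity,
        disability_score=d_score,
        days_points=dp,
        score_points=sp,
        disability_points=points,
        grade=grade,
        grade3=collapse_to_three(grade),
        severe=dichotomize_gcps(grade),
    )


# ---------------------------------------------------------------------------
# vectorised scoring over item arrays / frames


def grade_from_arrays(
    pain: np.ndarray, interference: np.ndarray, days: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised scorer.

    Parameters
    ----------
    pain, interference
        Integer arrays of shape (n, 3) with the 0-10 items.
    days
        Integer array of shape (n,) with disability days 0-180.
    """
    intensity = pain.sum(axis=1) / 3.0 * 10.0
    d_score = interference.sum(axis=1) / 3.0 * 10.0
    dp = np.searchsorted(DAY_POINT_CUTS, days, side="right")
    sp = np.searchsorted(SCORE_POINT_CUTS, d_score, side="right")
    points = dp + sp
    grade_num = np.where(
        points >= 5, 4, np.where(points >= 3, 3,
                                 np.where(intensity >= INTENSITY_THRESHOLD, 2, 1))
    )
    return {
        "pain_intensity": intensity,
        "disability_score": d_score,
        "days_points": dp.astype(int),
        "score_points": sp.astype(int),
        "disability_points": points.astype(int),
        "grade_num": grade_num.astype(int),
    }


def score_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Score a ``gcps_items`` table into a ``gcps_scores`` table.

    Input columns follow the interchange schema; output has one row per
    person with pain_intensity, disability_score, disability_points, grade,
    grade3 and severe.
    """
    pain = items[["pain_now", "pain_avg", "pain_worst"]].to_numpy(dtype=int)
    interf = items[["interf_daily", "interf_social", "interf_work"]].to_numpy(dtype=int)
    days = items["disability_days"].to_numpy(dtype=int)
    if len(items):
        if pain.min(initial=0) < 0 or pain.max(initial=0) > 10:
            raise ValidationError("pain items outside 0..10")
        if interf.min(initial=0) < 0 or interf.max(initial=0) > 10:
            raise ValidationError("interference items outside 0..10")
        if days.min(initial=0) < 0 or days.max(initial=0) > 180:
            raise ValidationError("disability_days outside 0..180")
    derived = grade_from_arrays(pain, interf, days)
    grade_num = derived["grade_num"]
    return pd.DataFrame(
        {
            "person_id": items["person_id"].astype(str).to_numpy(),
            "pain_intensity": derived["pain_intensity"],
            "disability_score": derived["disability_score"],
            "disability_points": derived["disability_points"],
            "grade": np.array(("", *GRADES), dtype=object)[grade_num],
            "grade3": np.where(grade_num <= 2, 1, grade_num - 1).astype(int),
            "severe": grade_num >= 3,
        }
    )
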