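"""Mandibular growth staging from serial landmark records.

Mandibular length is the Euclidean Co-Pog distance.  The growth velocity of
each interval between consecutive films is the length increase (mm) divided
by the elapsed time (months).  The pubertal peak is the interval of maximal
velocity; each film is labeled by where its *preceding* interval falls
relative to the peak window:

* before the window  -> pre-pubertal
* inside the window  -> pubertal
* after the window   -> post-pubertal

The first film of a series has no preceding interval and stays UNLABELED.
The peak window is the maximal contiguous run of intervals, containing the
argmax-velocity interval, whose velocities are at least
``relative_threshold x max velocity``; with the default threshold of 1.0
the window is the argmax interval alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import CephFilm, GrowthInterval, GrowthSeries, Point, StageLabel


class InsufficientDataError(ValueError):
    """Raised when a series has too few films/intervals for the operation."""


def mandibular_length(co: Point, pog: Point) -> float:
    """Euclidean distance between Condylion and Pogonion in mm."""
    cx, cy = (float(v) for v in co)
    px, py = (float(v) for v in pog)
    for v in (cx, cy, px, py):
        if not math.isfinite(v):
            raise ValueError("landmark coordinates must be finite")
    return math.hypot(px - cx, py - cy)


def film_lengths(series: GrowthSeries) -> List[float]:
    return [mandibular_length(f.co, f.pog) for f in series.films]


def growth_intervals(series: GrowthSeries) -> List[GrowthInterval]:
    """Per-interval mandibular growth velocities for one subject.

    Returns n-1 intervals for n films; rate = delta-length / delta-months.
    """
    if len(series.films) < 2:
        raise InsufficientDataError("need at least 2 films to form an interval")
    lengths = film_lengths(series)
    intervals: List[GrowthInterval] = []
    for i in range(len(lengths) - 1):
        dl = lengths[i + 1] - lengths[i]
        dt = series.films[i + 1].age_months - series.films[i].age_months
        if dt <= 0:
            raise ValueError("film ages must be strictly increasing")
        intervals.append(
            GrowthInterval(
                from_index=i,
                to_index=i + 1,
                delta_length_mm=dl,
                delta_months=dt,
                rate_mm_per_month=dl / dt,
            )
        )
    return intervals


def find_peak_window(
    intervals: Sequence[GrowthInterval], relative_threshold: float = 1.0
) -> Tuple[int, int]:
    """Contiguous peak window as an inclusive index range ``(lo, hi)``.

    The window is the maximal contiguous run containing the first
    argmax-rate interval whose rates are all >= threshold * max rate.
    """
    if len(intervals) == 0:
        raise InsufficientDataError("no intervals")
    if not (0 < relative_threshold <= 1):
        raise ValueError("relative_threshold must lie in (0, 1]")
    rates = [iv.rate_mm_per_month for iv in intervals]
    max_rate = max(rates)
    argmax = rates.index(max_rate)  # earliest maximum on ties
    cutoff = relative_threshold * max_rate
    # rates may be negative; a qualifying interval needs rate >= cutoff, and
    # cutoff <= max_rate always holds for threshold <= 1 when max_rate >= 0.
    # For max_rate < 0 the cutoff scales the wrong way; qualify by distance
    # from the max instead so threshold=1 still isolates the argmax.
    if max_rate >= 0:
        ok = [r >= cutoff for r in rates]
    else:
        ok = [r >= max_rate * (2 - relative_threshold) for r in rates]
    lo = argmax
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = argmax
    while hi < len(rates) - 1 and ok[hi + 1]:
        hi += 1
    return lo, hi


def assign_stage_labels(
    series: GrowthSeries, relative_threshold: float = 1.0
) -> List[StageLabel]:
    """Per-film stage labels; film 0 is UNLABELED (no preceding interval)."""
    intervals = growth_intervals(series)
    lo, hi = find_peak_window(intervals, relative_threshold)
    labels = [StageLabel.UNLABELED]
    for k in range(len(intervals)):
        if k < lo:
            labels.append(StageLabel.PRE_PUBERTAL)
        elif k <= hi:
            labels.append(StageLabel.PUBERTAL)
        else:
            labels.append(StageLabel.POST_PUBERTAL)
    return labels


@dataclass(frozen=True)
class EligibilityResult:
    passed: bool
    reasons: Tuple[str, ...]


# study window: ages 8-15 years
_AGE_LO, _AGE_HI = 8 * 12, 15 * 12
_GAP_LO, _GAP_HI = 9.0, 18.0
_MIN_FILMS = 6


def check_eligibility(series: GrowthSeries) -> EligibilityResult:
    """Inclusion/exclusion screen; returns every violated criterion.

    Inclusion: >= 6 films between ages 8 and 15, consecutive gaps within
    [9, 18] months, all films of usable quality.  Exclusion: skeletal class
    III, syndromic cases.
    """
    reasons: List[str] = []
    in_window = [f for f in series.films if _AGE_LO <= f.age_months <= _AGE_HI]
    if len(in_window) < _MIN_FILMS:
        reasons.append("too-few-films")
    ages = [f.age_months for f in series.films]
    for a, b in zip(ages, ages[1:]):
        gap = b - a
        if not (_GAP_LO <= gap <= _GAP_HI):
            reasons.append("gap-out-of-range")
            break
    if any(not f.quality_ok for f in series.films):
        reasons.append("poor-quality-film")
    if series.skeletal_class == "III":
        reasons.append("class-III-excluded")
    if series.syndromic:
        reasons.append("syndromic-excluded")
    return EligibilityResult(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# manifest I/O

MANIFEST_COLUMNS = [
    "subject_id", "sex", "skeletal_class", "film_index", "age_months",
    "co_x", "co_y", "pog_x", "pog_y", "basion_x", "basion_y",
    "c4inf_x", "c4inf_y", "image_path", "true_peak_age_months",
]


def series_from_manifest(
    df: pd.DataFrame, mm_per_pixel: float = 1.0
) -> List[GrowthSeries]:
    """Reconstruct GrowthSeries objects from a manifest table.

    Coordinates are multiplied by ``mm_per_pixel``; the synthetic generator
    declares a scale of 1.0.
    """
    s = float(mm_per_pixel)
    out: List[GrowthSeries] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("film_index")
        films = [
            CephFilm(
                subject_id=str(sid),
                age_months=float(r.age_months),
                co=(float(r.co_x) * s, float(r.co_y) * s),
                pog=(float(r.pog_x) * s, float(r.pog_y) * s),
                basion=(float(r.basion_x) * s, float(r.basion_y) * s),
                c4_inferior=(float(r.c4inf_x) * s, float(r.c4inf_y) * s),
                image_ref=(str(r.image_path) if "image_path" in df.columns and pd.notna(r.image_path) else None),
                quality_ok=bool(getattr(r, "quality_ok", True)),
            )
            for r in grp.itertuples()
        ]
        peak = None
        if "true_peak_age_months" in grp.columns and pd.notna(grp["true_peak_age_months"].iloc[0]):
            peak = float(grp["true_peak_age_months"].iloc[0])
        out.append(
            GrowthSeries(
                films=films,
                sex=str(grp["sex"].iloc[0]),
                skeletal_class=str(grp["skeletal_class"].iloc[0]),
                true_peak_age_months=peak,
            )
        )
    return out


def label_table(
    series_list: Sequence[GrowthSeries], relative_threshold: float = 1.0
) -> pd.DataFrame:
    """Labels CSV layout: one row per film with length, preceding rate, stage."""
    rows = []
    for series in series_list:
        lengths = film_lengths(series)
        intervals = growth_intervals(series)
        labels = assign_stage_labels(series, relative_threshold)
        for i, film in enumerate(series.films):
            rate = intervals[i - 1].rate_mm_per_month if i > 0 else np.nan
            rows.append(
                {
                    "subject_id": series.subject_id,
                    "film_index": i,
                    "age_months": film.age_months,
                    "length_mm": lengths[i],
                    "preceding_rate_mm_per_month": rate,
                    "stage_label": labels[i].short,
                }
            )
    return pd.DataFrame(rows)
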