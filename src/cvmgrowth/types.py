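"""Shared domain types for the growth-staging pipeline.

The pipeline works on serial lateral cephalograms: each subject has an
ordered series of films, each film carries four 2-D landmarks (Condylion,
Pogonion, Basion, inferior border of C4) plus an age in months.  Mandibular
length is the Co-Pog distance; per-interval growth velocity (mm/month)
anchors the three-stage label (pre-pubertal / pubertal / post-pubertal).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

Point = Tuple[float, float]


class StageLabel(enum.IntEnum):
    """Ordered three-stage maturation label; UNLABELED for the first film
    of a series, whose preceding growth interval is undefined."""

    PRE_PUBERTAL = 0
    PUBERTAL = 1
    POST_PUBERTAL = 2
    UNLABELED = -1

    @property
    def short(self) -> str:
        return {
            StageLabel.PRE_PUBERTAL: "pre",
            StageLabel.PUBERTAL: "pubertal",
            StageLabel.POST_PUBERTAL: "post",
            StageLabel.UNLABELED: "unlabeled",
        }[self]

    @classmethod
    def from_string(cls, s: str) -> "StageLabel":
        key = s.strip().lower().replace("-", "_").replace(" ", "_")
        table = {
            "pre": cls.PRE_PUBERTAL,
            "pre_pubertal": cls.PRE_PUBERTAL,
            "prepubertal": cls.PRE_PUBERTAL,
            "pubertal": cls.PUBERTAL,
            "post": cls.POST_PUBERTAL,
            "post_pubertal": cls.POST_PUBERTAL,
            "postpubertal": cls.POST_PUBERTAL,
            "unlabeled": cls.UNLABELED,
        }
        if key not in table:
            raise ValueError(f"unknown stage label: {s!r}")
        return table[key]


#: The three real stages in their canonical order (class axis of every
#: confusion matrix and dataset manifest).
STAGES = (StageLabel.PRE_PUBERTAL, StageLabel.PUBERTAL, StageLabel.POST_PUBERTAL)


def _check_point(name: str, p: Point) -> None:
    if len(p) != 2 or not all(math.isfinite(float(c)) for c in p):
        raise ValueError(f"{name} must be a finite 2-D point, got {p!r}")


@dataclass(frozen=True)
class CephFilm:
    """One lateral cephalogram: landmarks in mm, age in months."""

    subject_id: str
    age_months: float
    co: Point
    pog: Point
    basion: Point
    c4_inferior: Point
    image_ref: Optional[str] = None
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if not self.age_months > 0:
            raise ValueError(f"age_months must be positive, got {self.age_months}")
        for name in ("co", "pog", "basion", "c4_inferior"):
            _check_point(name, getattr(self, name))


@dataclass
class GrowthSeries:
    """Ordered film series of one subject."""

    films: Sequence[CephFilm]
    sex: str = "F"
    skeletal_class: str = "I"
    syndromic: bool = False
    true_peak_age_months: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.skeletal_class not in ("I", "II", "III"):
            raise ValueError(f"skeletal_class must be I/II/III, got {self.skeletal_class!r}")
        ages = [f.age_months for f in self.films]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("film ages must be strictly increasing")
        ids = {f.subject_id for f in self.films}
        if len(ids) > 1:
            raise ValueError(f"films span multiple subjects: {sorted(ids)}")

    @property
    def subject_id(self) -> str:
        return self.films[0].subject_id if self.films else ""

    def __len__(self) -> int:
        return len(self.films)


@dataclass(frozen=True)
class GrowthInterval:
    """Consecutive-film pair with its average growth velocity."""

    from_index: int
    to_index: int
    delta_length_mm: float
    delta_months: float
    rate_mm_per_month: float

    def __post_init__(self) -> None:
        if self.to_index != self.from_index + 1:
            raise ValueError("intervals must join consecutive films")
        if not self.delta_months > 0:
            raise ValueError("delta_months must be positive")


@dataclass
class RoiImage:
    """64x64 grayscale crop of the cervical-vertebrae region, in [0, 1]."""

    pixels: np.ndarray
    stage_label: StageLabel = StageLabel.UNLABELED
    source: Tuple[str, int] = ("", -1)
    crop_box: Optional[Tuple[int, int, int, int]] = None  # top, bottom, left, right (inclusive)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        if self.crop_box is not None:
            top, bottom, left, right = self.crop_box
            if not (top < bottom and left < right):
                raise ValueError(f"degenerate crop_box {self.crop_box}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]
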