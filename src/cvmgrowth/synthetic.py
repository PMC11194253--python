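"""Synthetic longitudinal growth series and vertebra-like ROI images.

Real input to the pipeline would be serial cephalograms with landmark
coordinates.  This module generates statistically analogous stand-ins:

* ``simulate_growth_series`` draws a film series whose mandibular length
  follows a linear background plus a logistic pubertal spurt,
  ``L(t) = baseline + linear_rate * (t - 96) + spurt_gain * sigmoid((t - peak)/scale)``,
  so the growth velocity is a logistic density with its single maximum at
  ``peak_age_months`` — a known ground truth for the staging layer.
* ``render_synthetic_roi`` draws three stacked vertebral bodies whose
  height:width ratio and lower-border concavity increase monotonically
  pre -> pubertal -> post, so the three classes are separable by
  construction and a classifier trained on them must be able to learn.

All randomness flows from explicit integer seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .staging import MANIFEST_COLUMNS
from .types import CephFilm, GrowthSeries, RoiImage, STAGES, StageLabel


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters of the linear-plus-logistic mandibular growth law.

    Defaults are desk-scale but physiologically plausible: ~100 mm
    mandibular length at age 8, slow background growth, a spurt adding
    ~12 mm centered at the sex-typical peak age, and sub-millimetre
    landmark noise.
    """

    baseline_length_mm: float = 100.0
    linear_rate_mm_per_month: float = 0.05
    spurt_gain_mm: float = 12.0
    peak_age_months: float = 144.0
    spurt_scale_months: float = 6.0
    noise_sd_mm: float = 0.0
    sex: str = "F"

    def __post_init__(self) -> None:
        if not self.baseline_length_mm > 0:
            raise ValueError("baseline_length_mm must be positive")
        if self.linear_rate_mm_per_month < 0:
            raise ValueError("linear_rate_mm_per_month must be nonnegative")
        if self.spurt_gain_mm < 0:
            raise ValueError("spurt_gain_mm must be nonnegative")
        if not (96 <= self.peak_age_months <= 180):
            raise ValueError("peak_age_months must lie in [96, 180]")
        if not self.spurt_scale_months > 0:
            raise ValueError("spurt_scale_months must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be nonnegative")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")

    def true_length(self, age_months: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(age_months, dtype=np.float64)
        out = (
            self.baseline_length_mm
            + self.linear_rate_mm_per_month * (t - 96.0)
            + self.spurt_gain_mm
            * _logistic((t - self.peak_age_months) / self.spurt_scale_months)
        )
        return float(out) if np.isscalar(age_months) else out

    def true_velocity(self, age_months: np.ndarray | float) -> np.ndarray | float:
        """Analytic dL/dt: linear rate plus a logistic-density bump peaked
        exactly at peak_age_months."""
        t = np.asarray(age_months, dtype=np.float64)
        s = _logistic((t - self.peak_age_months) / self.spurt_scale_months)
        out = self.linear_rate_mm_per_month + self.spurt_gain_mm * s * (1 - s) / self.spurt_scale_months
        return float(out) if np.isscalar(age_months) else out


#: Sex-dependent prior on the spurt peak (months): girls peak earlier.
PEAK_AGE_PRIOR = {"F": (138.0, 8.0), "M": (156.0, 8.0)}


def sample_growth_params(
    rng: np.random.Generator, sex: str, noise_sd_mm: float = 0.3
) -> GrowthModelParams:
    """Draw subject-level growth parameters from realistic priors."""
    mean, sd = PEAK_AGE_PRIOR[sex]
    # keep the peak well inside the 8-15y film window so labels span stages
    peak = float(np.clip(rng.normal(mean, sd), 115.0, 168.0))
    return GrowthModelParams(
        baseline_length_mm=float(rng.normal(100.0, 4.0)),
        linear_rate_mm_per_month=float(rng.uniform(0.02, 0.08)),
        spurt_gain_mm=float(rng.uniform(8.0, 16.0)),
        peak_age_months=peak,
        spurt_scale_months=float(rng.uniform(4.0, 8.0)),
        noise_sd_mm=noise_sd_mm,
        sex=sex,
    )


def simulate_growth_series(
    params: GrowthModelParams,
    n_films: int = 8,
    seed: int = 0,
    subject_id: str = "synthetic",
    skeletal_class: str = "I",
) -> GrowthSeries:
    """Simulate one subject's serial films.

    First film age uniform in [96, 108] months; each subsequent gap uniform
    in [9, 18] months (the study's inclusion window).  Observed Co-Pog
    distance is the true length plus Gaussian noise; Basion and the C4
    inferior border are emitted above/below a synthetic vertebral column.
    """
    if n_films < 2:
        raise ValueError("n_films must be >= 2")
    rng = np.random.default_rng(seed)
    ages = np.empty(n_films)
    ages[0] = rng.uniform(96.0, 108.0)
    for i in range(1, n_films):
        ages[i] = ages[i - 1] + rng.uniform(9.0, 18.0)
    observed = params.true_length(ages) + rng.normal(0.0, params.noise_sd_mm, n_films) \
        if params.noise_sd_mm > 0 else params.true_length(ages)
    observed = np.maximum(np.asarray(observed, dtype=np.float64), 1e-6)

    # Co fixed; Pog along a fixed anterior-inferior direction at the observed
    # distance.  Basion sits above the vertebral column, C4 below (y = row,
    # increasing downward).
    theta = rng.uniform(-0.7, -0.5)
    direction = (np.cos(theta), -np.sin(theta))  # forward and downward
    co = (20.0, 40.0)
    films = []
    for i in range(n_films):
        L = float(observed[i])
        pog = (co[0] + direction[0] * L, co[1] + direction[1] * L)
        basion = (60.0, 30.0)
        c4 = (60.0, 30.0 + 50.0 + 0.1 * (ages[i] - 96.0))
        films.append(
            CephFilm(
                subject_id=subject_id,
                age_months=float(ages[i]),
                co=co,
                pog=pog,
                basion=basion,
                c4_inferior=c4,
            )
        )
    return GrowthSeries(
        films=films,
        sex=params.sex,
        skeletal_class=skeletal_class,
        true_peak_age_months=params.peak_age_months,
    )


def simulate_labeled_series(
    index: int,
    seed: int = 0,
    noise_sd_mm: float = 0.0,
    n_films: int = 8,
) -> GrowthSeries:
    """One series from the labeled-study conditions: the spurt peak is
    guaranteed to fall inside the sampled film window (first age <= 108,
    last age >= 159 for 8 films), so every stage occurs and the peak
    interval is well defined."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))
    params = GrowthModelParams(
        baseline_length_mm=float(rng.normal(100.0, 4.0)),
        linear_rate_mm_per_month=float(rng.uniform(0.02, 0.08)),
        spurt_gain_mm=float(rng.uniform(8.0, 16.0)),
        peak_age_months=float(rng.uniform(118.0, 155.0)),
        spurt_scale_months=float(rng.uniform(4.5, 8.0)),
        noise_sd_mm=noise_sd_mm,
        sex="F" if index % 2 == 0 else "M",
    )
    film_seed = int(rng.integers(2**31))
    return simulate_growth_series(
        params, n_films=n_films, seed=film_seed, subject_id=f"L{index:04d}"
    )


def simulate_cohort(
    n_subjects: int,
    seed: int = 0,
    noise_sd_mm: float = 0.3,
    n_films_range: Tuple[int, int] = (6, 9),
) -> List[GrowthSeries]:
    """Simulate a cohort with sex-balanced, seeded subject parameters."""
    out: List[GrowthSeries] = []
    for i in range(n_subjects):
        ss = np.random.SeedSequence([int(seed), i])
        rng = np.random.default_rng(ss)
        sex = "F" if i % 2 == 0 else "M"
        params = sample_growth_params(rng, sex, noise_sd_mm=noise_sd_mm)
        n_films = int(rng.integers(n_films_range[0], n_films_range[1] + 1))
        film_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        out.append(
            simulate_growth_series(
                params, n_films=n_films, seed=film_seed, subject_id=f"S{i:04d}"
            )
        )
    return out


def cohort_manifest(series_list: Sequence[GrowthSeries]) -> pd.DataFrame:
    """Series manifest table (one row per film) in the pipeline's schema."""
    rows = []
    for series in series_list:
        for i, f in enumerate(series.films):
            rows.append(
                {
                    "subject_id": f.subject_id,
                    "sex": series.sex,
                    "skeletal_class": series.skeletal_class,
                    "film_index": i,
                    "age_months": f.age_months,
                    "co_x": f.co[0], "co_y": f.co[1],
                    "pog_x": f.pog[0], "pog_y": f.pog[1],
                    "basion_x": f.basion[0], "basion_y": f.basion[1],
                    "c4inf_x": f.c4_inferior[0], "c4inf_y": f.c4_inferior[1],
                    "image_path": f.image_ref or "",
                    "true_peak_age_months": series.true_peak_age_months,
                }
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# stage-conditioned ROI renderer


@dataclass(frozen=True)
class RenderParams:
    """Controls the synthetic vertebral-column renderer.

    ``body_aspect_by_stage`` (height:width of each vertebral body) and
    ``concavity_depth_by_stage`` (lower-border notch depth as a fraction of
    body height) must both increase strictly pre -> pubertal -> post so the
    three classes are geometrically separable.
    """

    image_size: Tuple[int, int] = (64, 64)
    stage: StageLabel = StageLabel.PRE_PUBERTAL
    body_aspect_by_stage: Dict[StageLabel, float] = field(
        default_factory=lambda: {
            StageLabel.PRE_PUBERTAL: 0.60,
            StageLabel.PUBERTAL: 0.85,
            StageLabel.POST_PUBERTAL: 1.15,
        }
    )
    concavity_depth_by_stage: Dict[StageLabel, float] = field(
        default_factory=lambda: {
            StageLabel.PRE_PUBERTAL: 0.05,
            StageLabel.PUBERTAL: 0.20,
            StageLabel.POST_PUBERTAL: 0.38,
        }
    )
    noise_sd: float = 0.05
    jitter_rotation_deg: float = 3.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.jitter_rotation_deg < 0:
            raise ValueError("jitter_rotation_deg must be nonnegative")
        for mapping, name in (
            (self.body_aspect_by_stage, "body_aspect_by_stage"),
            (self.concavity_depth_by_stage, "concavity_depth_by_stage"),
        ):
            vals = [mapping[s] for s in STAGES]
            if not (vals[0] < vals[1] < vals[2]):
                raise ValueError(f"{name} must strictly increase pre -> pubertal -> post")


_BG, _FG = 0.15, 0.85


def render_synthetic_roi(params: RenderParams, seed: int = 0) -> RoiImage:
    """Render one stage-conditioned vertebral-column phantom.

    Three stacked quadrilateral bodies, bright on dark background, with a
    parabolic notch carved into each lower border.  Deterministic given
    (params, seed).
    """
    if params.stage not in STAGES:
        raise ValueError(f"unknown stage: {params.stage}")
    rng = np.random.default_rng(seed)
    H, W = params.image_size
    aspect = params.body_aspect_by_stage[params.stage]
    concavity = params.concavity_depth_by_stage[params.stage]

    w = 0.24 * W
    h = aspect * w
    gap = 0.05 * H
    total = 3 * h + 2 * gap
    top0 = (H - total) / 2.0
    cx = W / 2.0

    rr, cc = np.mgrid[0:H, 0:W]
    img = np.full((H, W), _BG, dtype=np.float64)
    body_top, body_bottom = H, 0
    for b in range(3):
        y0 = top0 + b * (h + gap)
        y1 = y0 + h
        x0, x1 = cx - w / 2.0, cx + w / 2.0
        inside = (rr >= y0) & (rr <= y1) & (cc >= x0) & (cc <= x1)
        # parabolic notch carved upward into the lower border
        u = (cc - cx) / (w / 2.0)
        notch_depth = concavity * h * np.clip(1.0 - u**2, 0.0, None)
        notched = rr > (y1 - notch_depth)
        img[inside & ~notched] = _FG
        body_top = min(body_top, int(np.floor(y0)))
        body_bottom = max(body_bottom, int(np.ceil(y1)))
    body_bbox = (body_top, body_bottom, int(np.floor(cx - w / 2)), int(np.ceil(cx + w / 2)))

    if params.jitter_rotation_deg > 0:
        angle = float(rng.uniform(-params.jitter_rotation_deg, params.jitter_rotation_deg))
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return RoiImage(
        pixels=img,
        stage_label=params.stage,
        source=("synthetic-render", seed),
        meta={"body_bbox": body_bbox, "seed": seed},
    )


def render_synthetic_cephalogram(
    params: RenderParams,
    seed: int = 0,
    canvas: Tuple[int, int] = (128, 96),
) -> Tuple[np.ndarray, Tuple[float, float], Tuple[float, float]]:
    """Embed a rendered vertebral column in a larger dark canvas.

    Returns (image, basion_xy, c4_inferior_xy) where Basion sits just above
    the column and the C4 landmark at its lower border, so that
    ``roi.extract_roi`` recovers the column.  Used to exercise the crop
    stage end-to-end without real radiographs.
    """
    roi = render_synthetic_roi(params, seed=seed)
    H, W = canvas
    h, w = roi.pixels.shape
    if H < h + 8 or W < w + 8:
        raise ValueError("canvas too small for the rendered column")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))
    top = int(rng.integers(2, H - h - 2))
    left = int(rng.integers(2, W - w - 2))
    img = np.full((H, W), _BG, dtype=np.float64)
    if params.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, params.noise_sd, img.shape), 0.0, 1.0)
    img[top : top + h, left : left + w] = roi.pixels
    bt, bb, bl, br = roi.meta["body_bbox"]
    cx = left + (bl + br) / 2.0
    basion = (cx, float(top + max(bt - 2, 0)))
    c4 = (cx, float(top + min(bb + 1, h - 1)))
    return img, basion, c4


def build_synthetic_dataset(
    n_per_class: int,
    render: Optional[RenderParams] = None,
    seed: int = 0,
    out_dir: Optional[Path | str] = None,
) -> Tuple[List[RoiImage], pd.DataFrame]:
    """Render a balanced labeled image collection: n_per_class per stage.

    Returns the images plus a manifest (image_path, stage, seed).  If
    ``out_dir`` is given, 8-bit grayscale PNGs and ``manifest.csv`` are
    written there.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = render or RenderParams()
    images: List[RoiImage] = []
    rows = []
    for si, stage in enumerate(STAGES):
        stage_params = RenderParams(
            image_size=base.image_size,
            stage=stage,
            body_aspect_by_stage=base.body_aspect_by_stage,
            concavity_depth_by_stage=base.concavity_depth_by_stage,
            noise_sd=base.noise_sd,
            jitter_rotation_deg=base.jitter_rotation_deg,
        )
        for i in range(n_per_class):
            item_seed = int(
                np.random.SeedSequence([int(seed), si, i]).generate_state(1, dtype=np.uint32)[0]
                % (2**31)
            )
            roi = render_synthetic_roi(stage_params, seed=item_seed)
            path = ""
            if out_dir is not None:
                path = str(Path(out_dir) / f"{stage.short}_{i:04d}.png")
            rows.append({"image_path": path, "stage": stage.short, "seed": item_seed})
            images.append(roi)
    manifest = pd.DataFrame(rows, columns=["image_path", "stage", "seed"])
    if out_dir is not None:
        from .imageio_utils import write_png

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for roi, row in zip(images, rows):
            write_png(Path(row["image_path"]), roi.pixels)
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, manifest
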