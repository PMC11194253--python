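"""Balanced selection and stratified train/validation/test splitting.

The study's layout: a balanced pool (240 images per stage before quality
exclusions), an 85/15 train+validation/test division, then 80/20
train/validation within the training pool — all stratified per class.
``fixed_test_per_class`` reproduces the study's 32/32/32 test row exactly;
the fractional path is the general rule.  Rounding: per-class test count =
round(class_size x test_frac), capped so at least one training item
remains; validation = round(remaining x val_frac).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import STAGES, StageLabel

logger = logging.getLogger(__name__)


class EmptyClassError(ValueError):
    pass


class CannotStratifyError(ValueError):
    pass


@dataclass
class DatasetSplit:
    """Disjoint per-partition row indices into the labeled ROI table."""

    train: List[int]
    validation: List[int]
    test: List[int]
    seed: int
    ratios: Tuple[float, float]

    def counts(self, labels: Sequence[StageLabel]) -> pd.DataFrame:
        rows = {}
        for name, idxs in (("train", self.train), ("validation", self.validation), ("test", self.test)):
            rows[name] = {s.short: sum(1 for i in idxs if labels[i] == s) for s in STAGES}
        df = pd.DataFrame(rows).T
        df["total"] = df.sum(axis=1)
        return df


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_balanced(
    labels: Sequence[StageLabel], n_per_class: int, seed: int = 0
) -> List[int]:
    """Seeded uniform draw without replacement of n_per_class indices per
    stage; takes all (with a warning) when a class falls short."""
    if n_per_class < 0:
        raise ValueError("n_per_class must be nonnegative")
    rng = np.random.default_rng(seed)
    chosen: List[int] = []
    for stage in STAGES:
        pool = [i for i, lab in enumerate(labels) if lab == stage]
        if not pool and n_per_class > 0:
            raise EmptyClassError(f"no candidates for stage {stage.short}")
        if len(pool) < n_per_class:
            warnings.warn(
                f"stage {stage.short}: only {len(pool)} candidates for "
                f"requested {n_per_class}; taking all", stacklevel=2,
            )
            take = pool
        else:
            take = sorted(rng.choice(pool, size=n_per_class, replace=False).tolist())
        chosen.extend(take)
    return chosen


def stratified_split(
    labels: Sequence[StageLabel],
    indices: Optional[Sequence[int]] = None,
    test_frac: float = 0.15,
    val_frac: float = 0.20,
    seed: int = 0,
    fixed_test_per_class: Optional[int] = None,
    groups: Optional[Sequence[str]] = None,
) -> DatasetSplit:
    """Per-class stratified split into train/validation/test.

    ``fixed_test_per_class`` overrides the fractional test count (the
    study's 32/class).  ``groups`` (subject ids) enables subject-grouped
    splitting: all films of one subject land in one partition (off by
    default; see docs for the methodological caveat).
    """
    if indices is None:
        indices = list(range(len(labels)))
    if len(indices) == 0:
        raise ValueError("empty selection")
    if not (0 <= test_frac < 1 and 0 <= val_frac < 1):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    train: List[int] = []
    val: List[int] = []
    test: List[int] = []
    for stage in STAGES:
        pool = [i for i in indices if labels[i] == stage]
        if not pool:
            continue
        if len(pool) < 3 and (test_frac > 0 or fixed_test_per_class):
            raise CannotStratifyError(
                f"stage {stage.short} has {len(pool)} items; need >= 3 to stratify"
            )
        n = len(pool)
        if fixed_test_per_class is not None:
            n_test = min(fixed_test_per_class, max(n - 1, 0))
        else:
            n_test = min(_round_half_up(n * test_frac), max(n - 1, 0))
        rem = n - n_test
        n_val = min(_round_half_up(rem * val_frac), max(rem - 1, 0))
        if groups is not None:
            # whole subjects go to one partition; quotas are soft
            chunks = _group_chunks(pool, groups, rng)
            test_c, val_c, train_c = [], [], []
            for chunk in chunks:
                if len(test_c) < n_test:
                    test_c.extend(chunk)
                elif len(val_c) < n_val:
                    val_c.extend(chunk)
                else:
                    train_c.extend(chunk)
            test.extend(test_c)
            val.extend(val_c)
            train.extend(train_c)
        else:
            pool = [pool[j] for j in rng.permutation(len(pool))]
            test.extend(pool[:n_test])
            val.extend(pool[n_test : n_test + n_val])
            train.extend(pool[n_test + n_val :])
    return DatasetSplit(
        train=sorted(train), validation=sorted(val), test=sorted(test),
        seed=seed, ratios=(test_frac, val_frac),
    )


def _group_chunks(
    pool: List[int], groups: Sequence[str], rng: np.random.Generator
) -> List[List[int]]:
    """Group-shuffled chunks: one list of item indices per subject."""
    by_group: Dict[str, List[int]] = {}
    for i in pool:
        by_group.setdefault(str(groups[i]), []).append(i)
    keys = sorted(by_group)
    return [by_group[keys[k]] for k in rng.permutation(len(keys))]


def split_manifest(
    roi_manifest: pd.DataFrame, split: DatasetSplit
) -> pd.DataFrame:
    """Split manifest CSV layout: roi_path, stage_label, partition, seed."""
    part = {}
    for name, idxs in (("train", split.train), ("validation", split.validation), ("test", split.test)):
        for i in idxs:
            part[i] = name
    df = roi_manifest.reset_index(drop=True)
    rows = []
    for i, r in df.iterrows():
        if i not in part:
            continue
        rows.append({
            "roi_path": r.get("roi_path", r.get("image_path", "")),
            "stage_label": r.get("stage_label", r.get("stage", "")),
            "partition": part[i],
            "seed": split.seed,
        })
    return pd.DataFrame(rows, columns=["roi_path", "stage_label", "partition", "seed"])
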