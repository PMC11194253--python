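"""Diagnostic measures and chance-corrected agreement for 3-stage predictions.

Per-class measures use the one-vs-rest reduction of the 3x3 confusion
matrix (rows = true stage, columns = predicted stage, class order
pre / pubertal / post):

    sensitivity = TP/(TP+FN)      specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)              NPV = TN/(TN+FN)
    class accuracy = (TP+TN)/N    overall accuracy = trace/N

Cohen's kappa = (p_o - p_e)/(1 - p_e) with optional linear or quadratic
disagreement weights; when the true classes are balanced the unweighted
expected agreement is exactly 1/3 regardless of the predicted marginals.
Kappa values are interpreted on Altman's qualitative bands.

Zero-denominator measures are reported as ``None`` (undefined), never
silently as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import STAGES, StageLabel


class UndefinedMeasureError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 integer counts; rows true stage, columns predicted stage."""

    counts: np.ndarray
    class_order: Tuple[StageLabel, ...] = STAGES

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (3, 3):
            raise ValueError(f"confusion matrix must be 3x3, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    true_labels: Sequence[StageLabel], predicted_labels: Sequence[StageLabel]
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    idx = {s: i for i, s in enumerate(STAGES)}
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in idx or p not in idx:
            raise ValueError(f"unknown label in pair ({t}, {p})")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts=counts)


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def one_vs_rest_counts(cm: ConfusionMatrix) -> Dict[StageLabel, Dict[str, int]]:
    """Collapse the 3x3 matrix to per-class TP/FP/FN/TN."""
    c = cm.counts
    total = cm.total
    out = {}
    for i, stage in enumerate(cm.class_order):
        tp = int(c[i, i])
        fn = int(c[i, :].sum() - tp)
        fp = int(c[:, i].sum() - tp)
        tn = total - tp - fn - fp
        out[stage] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
    return out


def _ranks(values: List[Optional[float]]) -> List[Optional[int]]:
    """Rank 1 = best (largest); ties share the better rank; undefined
    measures get no rank."""
    ranks: List[Optional[int]] = []
    for v in values:
        if v is None:
            ranks.append(None)
        else:
            ranks.append(1 + sum(1 for w in values if w is not None and w > v))
    return ranks


MEASURES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


def classwise_metrics(cm: ConfusionMatrix) -> Dict[StageLabel, Dict[str, object]]:
    """Per-class one-vs-rest diagnostic measures with ranks (1 = best)."""
    if cm.total == 0:
        raise UndefinedMeasureError("empty confusion matrix")
    counts = one_vs_rest_counts(cm)
    report: Dict[StageLabel, Dict[str, object]] = {}
    for stage in cm.class_order:
        k = counts[stage]
        report[stage] = {
            **k,
            "sensitivity": _safe_div(k["TP"], k["TP"] + k["FN"]),
            "specificity": _safe_div(k["TN"], k["TN"] + k["FP"]),
            "ppv": _safe_div(k["TP"], k["TP"] + k["FP"]),
            "npv": _safe_div(k["TN"], k["TN"] + k["FN"]),
            "accuracy": _safe_div(k["TP"] + k["TN"], cm.total),
        }
    for measure in MEASURES:
        vals = [report[s][measure] for s in cm.class_order]  # type: ignore[misc]
        for s, r in zip(cm.class_order, _ranks(vals)):  # type: ignore[arg-type]
            report[s][f"{measure}_rank"] = r
    return report


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise UndefinedMeasureError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def _weight_matrix(weighting: str) -> np.ndarray:
    i = np.arange(3)
    d = np.abs(i[:, None] - i[None, :]).astype(np.float64)
    if weighting == "none":
        return (d > 0).astype(np.float64)
    if weighting == "linear":
        return d / 2.0
    if weighting == "quadratic":
        return (d / 2.0) ** 2
    raise ValueError(f"unknown weighting: {weighting!r}")


def cohens_kappa(cm: ConfusionMatrix, weighting: str = "none") -> float:
    """Chance-corrected agreement with optional ordinal disagreement
    weights; computed in the disagreement form
    kappa = 1 - sum(w*observed) / sum(w*expected)."""
    if cm.total == 0:
        raise UndefinedMeasureError("empty confusion matrix")
    w = _weight_matrix(weighting)
    p = cm.counts.astype(np.float64) / cm.total
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    exp_disagree = float((w * expected).sum())
    if exp_disagree == 0:
        raise UndefinedMeasureError("degenerate marginals: expected agreement is 1")
    obs_disagree = float((w * p).sum())
    return 1.0 - obs_disagree / exp_disagree


ALTMAN_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


def altman_band(kappa: float) -> str:
    """Altman's qualitative interpretation (upper-inclusive bins)."""
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, name in ALTMAN_BANDS:
        if kappa <= upper:
            return name
    return "very good"


def agreement_report(cm: ConfusionMatrix) -> Dict[str, object]:
    acc = overall_accuracy(cm)
    ku = cohens_kappa(cm, "none")
    return {
        "overall_accuracy": acc,
        "kappa_unweighted": ku,
        "kappa_linear": cohens_kappa(cm, "linear"),
        "kappa_quadratic": cohens_kappa(cm, "quadratic"),
        "altman_band": altman_band(ku),
    }


def full_report(cm: ConfusionMatrix) -> Dict[str, object]:
    """Report JSON: per-class measures + ranks and the agreement block."""
    per_class = classwise_metrics(cm)
    return {
        "confusion_matrix": cm.counts.tolist(),
        "class_order": [s.short for s in cm.class_order],
        "per_class": {s.short: per_class[s] for s in cm.class_order},
        "agreement": agreement_report(cm),
    }


def format_report_table(report: Dict[str, object]) -> str:
    """Markdown table mirroring the per-class measure/rank layout."""
    lines = [
        "| stage | sensitivity | specificity | PPV | NPV | accuracy |",
        "|---|---|---|---|---|---|",
    ]
    per_class = report["per_class"]  # type: ignore[assignment]
    for stage, row in per_class.items():  # type: ignore[union-attr]
        cells = []
        for m in MEASURES:
            v, r = row[m], row[f"{m}_rank"]
            cells.append("undefined" if v is None else f"{v:.6f} ({r})")
        lines.append(f"| {stage} | " + " | ".join(cells) + " |")
    ag = report["agreement"]  # type: ignore[assignment]
    lines.append("")
    lines.append(
        f"overall accuracy {ag['overall_accuracy']:.4f}; "  # type: ignore[index]
        f"kappa {ag['kappa_unweighted']:.4f} ({ag['altman_band']})"  # type: ignore[index]
    )
    return "\n".join(lines)


def matrix_from_correct_counts(
    correct: Sequence[int], per_class_total: int = 32
) -> ConfusionMatrix:
    """Build a balanced-truth confusion matrix from per-class correct counts.

    Off-diagonal errors are spread as evenly as possible across the two
    wrong columns of each row.  With balanced true classes, the overall
    accuracy, per-class sensitivities and the unweighted kappa depend only
    on the diagonal, so any such completion reproduces those measures.
    """
    if len(correct) != 3:
        raise ValueError("need one correct count per stage")
    counts = np.zeros((3, 3), dtype=np.int64)
    for i, c in enumerate(correct):
        if not (0 <= c <= per_class_total):
            raise ValueError(f"correct count {c} outside [0, {per_class_total}]")
        counts[i, i] = c
        wrong = per_class_total - c
        others = [j for j in range(3) if j != i]
        counts[i, others[0]] = wrong // 2 + wrong % 2
        counts[i, others[1]] = wrong // 2
    return ConfusionMatrix(counts=counts)
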