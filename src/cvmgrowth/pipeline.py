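"""End-to-end synthetic experiment: render -> split -> train -> evaluate.

Reproduces the study's dataset geometry on synthetic phantoms: a balanced
pool per stage, a fixed 32-per-class test partition with 85/15 then 80/20
stratified ratios, the designed CNN trained with augmentation, and the
full diagnostic report on the held-out test partition.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .classifier import (
    ModelConfig, TrainConfig, build_model, predict, train,
)
from .datasets import stratified_split
from .evaluation import confusion_matrix, full_report
from .synthetic import RenderParams, build_synthetic_dataset
from .types import STAGES


def run_synthetic_experiment(
    seed: int = 0,
    n_per_class: int = 240,
    epochs: int = 50,
    architecture: str = "designed_cnn",
    batch_size: int = 32,
    test_per_class: int = 32,
    render: Optional[RenderParams] = None,
    verbose: bool = False,
) -> Dict[str, object]:
    """Run the whole pipeline in memory and return its measurements.

    Returns a dict with the split counts, per-epoch history, the held-out
    confusion matrix and the full diagnostic report.
    """
    images, _ = build_synthetic_dataset(n_per_class, render=render, seed=seed)
    labels = [im.stage_label for im in images]
    pixels = [im.pixels for im in images]
    split = stratified_split(
        labels, test_frac=0.15, val_frac=0.20, seed=seed,
        fixed_test_per_class=test_per_class,
    )
    model = build_model(ModelConfig(architecture=architecture), seed=seed)
    cfg = TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed)
    model = train(
        model,
        [pixels[i] for i in split.train], [labels[i] for i in split.train],
        [pixels[i] for i in split.validation], [labels[i] for i in split.validation],
        cfg,
        verbose=verbose,
    )
    true_test = [labels[i] for i in split.test]
    _, pred_test = predict(model, [pixels[i] for i in split.test])
    cm = confusion_matrix(true_test, pred_test)
    report = full_report(cm)
    counts = split.counts(labels)
    return {
        "model": model,
        "split_counts": counts,
        "test_per_class": [
            sum(1 for t in true_test if t == s) for s in STAGES
        ],
        "history": model.history,
        "confusion_matrix": cm,
        "report": report,
        "test_accuracy": report["agreement"]["overall_accuracy"],
    }
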