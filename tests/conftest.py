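import numpy as np
import pytest

from cvmgrowth import classifier as clf
from cvmgrowth import synthetic
from cvmgrowth.types import CephFilm, GrowthSeries


def make_series_from_lengths(lengths, ages=None, sex="F", skeletal_class="I", **film_kw):
    """Build a series whose Co-Pog distances equal the given lengths
    (Co at origin, Pog on the x-axis)."""
    if ages is None:
        ages = [100.0 + 12.0 * i for i in range(len(lengths))]
    films = [
        CephFilm(
            subject_id="T",
            age_months=float(a),
            co=(0.0, 0.0),
            pog=(float(L), 0.0),
            basion=(50.0, 20.0),
            c4_inferior=(50.0, 80.0),
            **film_kw,
        )
        for a, L in zip(ages, lengths)
    ]
    return GrowthSeries(films=films, sex=sex, skeletal_class=skeletal_class)


def series_from_rates(rates, start_length=100.0, gap_months=12.0):
    """Series whose interval velocity sequence equals ``rates`` exactly."""
    lengths = [start_length]
    for r in rates:
        lengths.append(lengths[-1] + r * gap_months)
    return make_series_from_lengths(lengths)


@pytest.fixture(scope="session")
def phantom_bank():
    """30 noise-free-separable phantoms per stage, shared across tests."""
    images, manifest = synthetic.build_synthetic_dataset(30, seed=11)
    return images, manifest


@pytest.fixture(scope="session")
def quick_model(phantom_bank):
    """Designed CNN trained briefly on the phantom bank (20 train / 5 val /
    5 test per class, 10 epochs).  Session-scoped: training is the slow part."""
    images, _ = phantom_bank
    X = [im.pixels for im in images]
    y = [im.stage_label for im in images]
    tr, va, te = [], [], []
    for i in range(len(X)):
        k = i % 30
        (tr if k < 20 else va if k < 25 else te).append(i)
    model = clf.build_model(clf.ModelConfig(), seed=0)
    cfg = clf.TrainConfig(epochs=10, batch_size=32, seed=0)
    model = clf.train(
        model,
        [X[i] for i in tr], [y[i] for i in tr],
        [X[i] for i in va], [y[i] for i in va],
        cfg,
    )
    test_set = ([X[i] for i in te], [y[i] for i in te])
    return model, cfg, test_set
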