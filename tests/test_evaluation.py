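"""Diagnostic measures, Cohen's kappa and Altman interpretation."""

import numpy as np
import pytest

from cvmgrowth import evaluation as ev
from cvmgrowth.evaluation import (
    ConfusionMatrix, UndefinedMeasureError, altman_band, classwise_metrics,
    cohens_kappa, confusion_matrix, matrix_from_correct_counts,
    overall_accuracy,
)
from cvmgrowth.types import STAGES, StageLabel

PRE, PUB, POST = STAGES


def brute_force_measures(counts):
    """Independent scalar re-derivation with explicit loops at float64."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    out = {}
    for i in range(3):
        tp = int(counts[i, i])
        fn = sum(int(counts[i, j]) for j in range(3) if j != i)
        fp = sum(int(counts[j, i]) for j in range(3) if j != i)
        tn = total - tp - fn - fp
        out[i] = {
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "specificity": tn / (tn + fp) if tn + fp else None,
            "ppv": tp / (tp + fp) if tp + fp else None,
            "npv": tn / (tn + fn) if tn + fn else None,
            "accuracy": (tp + tn) / total,
        }
    return out


def brute_force_kappa(counts, weighting):
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    w = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            d = abs(i - j)
            w[i, j] = {"none": 1.0 if d else 0.0, "linear": d / 2, "quadratic": (d / 2) ** 2}[weighting]
    po_dis = sum(w[i, j] * counts[i, j] / total for i in range(3) for j in range(3))
    row = counts.sum(axis=1) / total
    col = counts.sum(axis=0) / total
    pe_dis = sum(w[i, j] * row[i] * col[j] for i in range(3) for j in range(3))
    return 1 - po_dis / pe_dis


class TestConfusionMatrix:
    def test_perfect_diagonal(self):
        y = [PRE] * 32 + [PUB] * 32 + [POST] * 32
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm.counts, np.diag([32, 32, 32]))

    def test_all_predicted_pre(self):
        y = [PRE] * 32 + [PUB] * 32 + [POST] * 32
        cm = confusion_matrix(y, [PRE] * 96)
        assert cm.counts[:, 0].sum() == 96
        assert cm.counts[:, 1:].sum() == 0

    def test_matches_double_loop_tally(self):
        rng = np.random.default_rng(17)
        t = [STAGES[i] for i in rng.integers(0, 3, 500)]
        p = [STAGES[i] for i in rng.integers(0, 3, 500)]
        cm = confusion_matrix(t, p)
        tally = np.zeros((3, 3), dtype=int)
        for a, b in zip(t, p):
            tally[STAGES.index(a), STAGES.index(b)] += 1
        assert np.array_equal(cm.counts, tally)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix([PRE], [PRE, PUB])

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([StageLabel.UNLABELED], [PRE])


class TestClasswiseMetrics:
    def test_printed_sensitivities_from_correct_counts(self):
        """Per-class correct counts 27/20/31 of 32: pubertal sensitivity
        0.625, post-pubertal 0.96875."""
        cm = matrix_from_correct_counts([27, 20, 31])
        m = classwise_metrics(cm)
        assert m[PUB]["sensitivity"] == 0.625
        assert m[POST]["sensitivity"] == 0.96875
        assert m[PRE]["sensitivity"] == 0.84375

    def test_reconstructed_pre_pubertal_row(self):
        """TP=27, FP=9, FN=5, TN=55 reproduces PPV 0.75, NPV ~0.916667,
        specificity ~0.859375, class accuracy ~0.854167."""
        counts = np.array([[27, 3, 2], [5, 20, 7], [4, 0, 28]])
        cm = ConfusionMatrix(counts=counts)
        k = ev.one_vs_rest_counts(cm)[PRE]
        assert (k["TP"], k["FP"], k["FN"], k["TN"]) == (27, 9, 5, 55)
        m = classwise_metrics(cm)[PRE]
        assert m["ppv"] == 0.75
        assert m["npv"] == pytest.approx(0.916667, abs=5e-7)
        assert m["specificity"] == pytest.approx(0.859375, abs=1e-12)
        assert m["accuracy"] == pytest.approx(0.854167, abs=5e-7)

    def test_identity_matrix_all_ones_tied_ranks(self):
        cm = ConfusionMatrix(counts=np.diag([5, 5, 5]))
        m = classwise_metrics(cm)
        for s in STAGES:
            for meas in ev.MEASURES:
                assert m[s][meas] == 1.0
                assert m[s][f"{meas}_rank"] == 1

    def test_rank_permutation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cm = ConfusionMatrix(counts=rng.integers(0, 30, (3, 3)))
            if cm.total == 0:
                continue
            m = classwise_metrics(cm)
            for meas in ev.MEASURES:
                vals = [m[s][meas] for s in STAGES]
                ranks = [m[s][f"{meas}_rank"] for s in STAGES]
                if None in vals:
                    continue
                # ties share the better rank; distinct values rank 1..3
                for v, r in zip(vals, ranks):
                    assert r == 1 + sum(1 for w in vals if w > v)

    def test_zero_denominator_flagged_undefined(self):
        # nothing ever predicted as POST -> PPV undefined, not 0
        counts = np.array([[10, 2, 0], [3, 9, 0], [1, 11, 0]])
        m = classwise_metrics(ConfusionMatrix(counts=counts))
        assert m[POST]["ppv"] is None
        assert m[POST]["ppv_rank"] is None

    def test_identity_sums(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            cm = ConfusionMatrix(counts=rng.integers(0, 50, (3, 3)))
            for k in ev.one_vs_rest_counts(cm).values():
                assert k["TP"] + k["FP"] + k["FN"] + k["TN"] == cm.total


class TestOverallAccuracyAndKappa:
    def test_printed_overall_accuracies(self):
        assert overall_accuracy(matrix_from_correct_counts([27, 20, 31])) == 78 / 96
        assert overall_accuracy(matrix_from_correct_counts([25, 28, 31])) == 84 / 96

    def test_zero_diagonal(self):
        counts = np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        assert overall_accuracy(ConfusionMatrix(counts=counts)) == 0.0

    def test_printed_kappas_balanced_truth(self):
        """Balanced true classes make expected agreement exactly 1/3, so
        kappa = (acc - 1/3) * 1.5: 0.71875 and 0.8125."""
        k1 = cohens_kappa(matrix_from_correct_counts([27, 20, 31]))
        k2 = cohens_kappa(matrix_from_correct_counts([25, 28, 31]))
        assert k1 == pytest.approx((78 / 96 - 1 / 3) / (2 / 3), abs=1e-12)
        assert k1 == pytest.approx(0.7188, abs=1e-4)
        assert k2 == pytest.approx(0.8125, abs=1e-12)

    def test_independence_gives_zero(self):
        # rows proportional to column marginals -> chance-level agreement
        counts = np.array([[9, 6, 15], [18, 12, 30], [3, 2, 5]])
        assert cohens_kappa(ConfusionMatrix(counts=counts)) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_one_iff_diagonal(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            counts = rng.integers(0, 20, (3, 3))
            cm = ConfusionMatrix(counts=counts)
            if cm.total == 0:
                continue
            try:
                k = cohens_kappa(cm)
            except UndefinedMeasureError:
                continue
            diagonal = counts.sum() == np.trace(counts)
            assert (abs(k - 1) < 1e-12) == diagonal

    def test_balanced_rows_linear_relation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            rows = []
            for i in range(3):
                a, b = sorted(rng.integers(0, 21, 2))
                rows.append([a, b - a, 20 - b])
            cm = ConfusionMatrix(counts=np.array(rows))
            acc = overall_accuracy(cm)
            assert cohens_kappa(cm) == pytest.approx((acc - 1 / 3) * 1.5, abs=1e-12)

    def test_all_weightings_agree_on_diagonal(self):
        cm = ConfusionMatrix(counts=np.diag([7, 11, 13]))
        for w in ("none", "linear", "quadratic"):
            assert cohens_kappa(cm, w) == 1.0

    def test_degenerate_marginals_undefined(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 10
        with pytest.raises(UndefinedMeasureError):
            cohens_kappa(ConfusionMatrix(counts=counts))

    def test_matches_brute_force_and_sklearn(self):
        """All measures and kappas agree with explicit-loop re-derivations
        to 1e-12 relative, and with scikit-learn's implementation."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(123)
        checked = 0
        while checked < 300:
            counts = rng.integers(0, 40, (3, 3))
            cm = ConfusionMatrix(counts=counts)
            if cm.total == 0:
                continue
            bf = brute_force_measures(counts)
            m = classwise_metrics(cm)
            for i, s in enumerate(STAGES):
                for meas in ev.MEASURES:
                    a, b = m[s][meas], bf[i][meas]
                    if b is None:
                        assert a is None
                    else:
                        assert a == pytest.approx(b, rel=1e-12)
            for w, sk_w in (("none", None), ("linear", "linear"), ("quadratic", "quadratic")):
                try:
                    k = cohens_kappa(cm, w)
                except UndefinedMeasureError:
                    continue
                assert k == pytest.approx(brute_force_kappa(counts, w), rel=1e-12, abs=1e-12)
                # cross-check against the independent library implementation
                t, p = [], []
                for i in range(3):
                    for j in range(3):
                        t += [i] * counts[i, j]
                        p += [j] * counts[i, j]
                sk = cohen_kappa_score(t, p, labels=[0, 1, 2], weights=sk_w)
                assert k == pytest.approx(sk, rel=1e-9, abs=1e-9)
            checked += 1


class TestAltmanBands:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.71875, "good"), (0.8125, "very good"), (1.0, "very good"),
            (0.10, "poor"), (0.20, "poor"), (0.2000001, "fair"),
            (0.40, "fair"), (0.60, "moderate"), (0.80, "good"), (-0.5, "poor"),
        ],
    )
    def test_bands(self, kappa, band):
        assert altman_band(kappa) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            altman_band(1.5)


class TestReports:
    def test_full_report_round_trip(self):
        cm = matrix_from_correct_counts([27, 20, 31])
        rep = ev.full_report(cm)
        assert rep["agreement"]["overall_accuracy"] == 0.8125
        assert rep["agreement"]["altman_band"] == "good"
        table = ev.format_report_table(rep)
        assert "pubertal" in table and "0.625000" in table
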