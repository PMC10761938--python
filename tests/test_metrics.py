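"""Classification metrics against hand evaluation, pairwise-counting
oracles and the sklearn cross-checks."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from cysreact.metrics import (
    binary_metrics,
    confusion_binary,
    confusion_tri,
    positional_enrichment,
    pr_aupr,
    roc_auc,
    tri_metrics,
)


def auc_oracle(scores, labels):
    """Exhaustive concordant-pair count, ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        m = binary_metrics(1, 1, 0, 0)
        assert m == {"Sn": 1.0, "Sp": 1.0, "ACC": 1.0, "MCC": 1.0}

    def test_hand_computed_mcc(self):
        m = binary_metrics(50, 40, 10, 5)
        expected = (50 * 40 - 10 * 5) / np.sqrt(60 * 55 * 50 * 45)
        assert m["MCC"] == pytest.approx(expected)
        assert m["MCC"] == pytest.approx(0.7156, abs=1e-4)

    def test_all_positive_on_balanced(self):
        m = binary_metrics(10, 0, 10, 0)
        assert (m["Sn"], m["Sp"], m["ACC"], m["MCC"]) == (1.0, 0.0, 0.5, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(0, 0, 0, 0)

    def test_matches_brute_force_on_random_counts(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = binary_metrics(tp, tn, fp, fn)
            assert m["ACC"] == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            if tp + fn:
                assert m["Sn"] == pytest.approx(tp / (tp + fn))
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if denom:
                assert m["MCC"] == pytest.approx((tp * tn - fp * fn) / np.sqrt(denom))


class TestRocAuc:
    def test_worked_example(self):
        _, auc = roc_auc([0.9, 0.8, 0.7, 0.3], [1, 0, 1, 0])
        assert auc == 0.75

    def test_perfect_ranking(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.uniform(size=1000)
        labels = rng.integers(0, 2, size=1000)
        _, auc = roc_auc(scores, labels)
        assert 0.45 <= auc <= 0.55

    def test_equals_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            scores = np.round(rng.uniform(size=n), 1)  # force some ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_oracle(scores, labels))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        _, a = roc_auc(scores, labels)
        _, b = roc_auc(np.exp(5 * scores), labels)
        assert a == pytest.approx(b)

    def test_matches_sklearn(self, rng):
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_area_matches_pairwise_statistic(self, rng):
        """Trapezoidal area under the emitted curve equals the rank AUC on
        tie-free scores."""
        scores = rng.permutation(np.linspace(0, 1, 60))
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        curve, auc = roc_auc(scores, labels)
        trap = np.trapezoid(curve["tpr"], curve["fpr"])
        assert abs(trap - auc) < 1e-9


class TestPrAupr:
    def test_matches_sklearn_average_precision(self, rng):
        scores = rng.uniform(size=150)
        labels = rng.integers(0, 2, size=150)
        labels[:2] = [0, 1]
        _, aupr = pr_aupr(scores, labels)
        assert aupr == pytest.approx(average_precision_score(labels, scores))

    def test_perfect_ranking(self):
        _, aupr = pr_aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert aupr == 1.0


class TestTriMetrics:
    def test_diagonal_confusion(self):
        m = tri_metrics(np.diag([5, 6, 7]))
        assert m["Accuracy"] == 1.0
        assert all(c["F1"] == 1.0 for c in m["per_class"].values())

    def test_hand_computed_matrix(self):
        cm = np.array([[8, 1, 1], [2, 6, 2], [3, 3, 4]])
        m = tri_metrics(cm)
        assert m["Accuracy"] == pytest.approx(18 / 30)
        assert m["per_class"][-1]["Precision"] == pytest.approx(8 / 13)
        assert m["per_class"][-1]["Recall"] == pytest.approx(8 / 10)
        assert m["per_class"][0]["Precision"] == pytest.approx(6 / 10)

    def test_collapse_consistency_with_binary(self, rng):
        """Merging +1/-1 into 'changed' reproduces the binary accuracy."""
        y_true = rng.choice([-1, 0, 1], size=100)
        y_pred = rng.choice([-1, 0, 1], size=100)
        tri = tri_metrics(confusion_tri(y_true, y_pred))
        b_true, b_pred = (y_true != 0).astype(int), (y_pred != 0).astype(int)
        bm = binary_metrics(*confusion_binary(b_true, b_pred))
        changed_agree = ((y_true != 0) == (y_pred != 0)).mean()
        assert bm["ACC"] == pytest.approx(changed_agree)
        assert tri["Accuracy"] <= bm["ACC"] + 1e-12  # tri is the stricter count

    def test_brute_force_per_class(self, rng):
        y_true = rng.choice([-1, 0, 1], size=60)
        y_pred = rng.choice([-1, 0, 1], size=60)
        m = tri_metrics(confusion_tri(y_true, y_pred))
        for cls in (-1, 0, 1):
            tp = np.sum((y_true == cls) & (y_pred == cls))
            fp = np.sum((y_true != cls) & (y_pred == cls))
            fn = np.sum((y_true == cls) & (y_pred != cls))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert m["per_class"][cls]["Precision"] == pytest.approx(prec)
            assert m["per_class"][cls]["Recall"] == pytest.approx(rec)


class TestPositionalEnrichment:
    def test_identical_sets_no_difference(self):
        wins = ["AAAAACAAAAA"] * 5 + ["SSSSSCSSSSS"] * 5
        df = positional_enrichment(wins, list(wins))
        assert np.allclose(df["diff"], 0)

    def test_planted_serine_enrichment(self, rng):
        pos = ["AAAASCAAAAA"[:11]] * 200  # S at offset -1
        neg = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=5))
            + "C"
            + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=5))
            for _ in range(200)
        ]
        df = positional_enrichment(pos, neg)
        row = df[(df["position"] == -1) & (df["residue"] == "S")].iloc[0]
        assert row["diff"] > 0.8
        assert row["p_value"] < 0.01

    def test_column_differences_sum_to_zero(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        mk = lambda: "".join(rng.choice(aas, size=5)) + "C" + "".join(rng.choice(aas, size=5))
        pos = [mk() for _ in range(30)]
        neg = [mk() for _ in range(40)]
        df = positional_enrichment(pos, neg)
        sums = df.groupby("position")["diff"].sum()
        assert np.allclose(sums, 0, atol=1e-12)

    def test_center_column_skipped(self):
        df = positional_enrichment(["ACA"] * 3, ["TCT"] * 3)
        assert 0 not in set(df["position"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            positional_enrichment(["ACA"], ["ACDEF"])
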