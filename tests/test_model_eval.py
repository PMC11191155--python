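import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from consensig.core_types import Dataset, NormMatrix, SampleTable
from consensig.model_eval import (
    METRIC_KEYS,
    MetricReport,
    RFHyperparams,
    _aggregate_reports,
    compute_metrics,
    protocol_cross_dataset,
    protocol_repeated_split,
    random_gene_baseline,
    train_rf,
    tune_rf,
)


def brute_force_confusion_metrics(tp, fn, fp, tn):
    """Exact rational metrics from a 2x2 confusion table (class 0 positive)."""
    def frac(a, b):
        return Fraction(a, b) if b else Fraction(0)

    pc0, rc0 = frac(tp, tp + fp), frac(tp, tp + fn)
    pc1, rc1 = frac(tn, tn + fn), frac(tn, tn + fp)
    f10 = frac(2 * pc0.numerator * rc0.denominator * rc0.numerator * pc0.denominator,
               (pc0 + rc0).numerator * pc0.denominator * rc0.denominator * (pc0 + rc0).denominator) \
        if (pc0 + rc0) else Fraction(0)
    # simpler: harmonic mean via Fractions directly
    f10 = 2 * pc0 * rc0 / (pc0 + rc0) if (pc0 + rc0) else Fraction(0)
    f11 = 2 * pc1 * rc1 / (pc1 + rc1) if (pc1 + rc1) else Fraction(0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = float((tp * tn - fp * fn) / np.sqrt(float(denom))) if denom else 0.0
    return {
        "PC0": float(pc0), "RC0": float(rc0), "F10": float(f10),
        "PC1": float(pc1), "RC1": float(rc1), "F11": float(f11),
        "MPC": float((pc0 + pc1) / 2), "MRC": float((rc0 + rc1) / 2),
        "MF1": float((f10 + f11) / 2), "MCC": mcc,
    }


def confusion_to_vectors(tp, fn, fp, tn):
    y_true = [0] * (tp + fn) + [1] * (fp + tn)
    y_pred = [0] * tp + [1] * fn + [0] * fp + [1] * tn
    score0 = [1 - p for p in y_pred]
    return np.array(y_true), np.array(y_pred), np.array(score0)


class TestComputeMetrics:
    def test_perfect_prediction_all_ones(self):
        y = np.array([0, 0, 1, 1, 1])
        score = np.array([0.9, 0.8, 0.1, 0.2, 0.3])
        rep = compute_metrics(y, y, score)
        for k in METRIC_KEYS:
            assert rep[k] == pytest.approx(1.0), k

    def test_majority_guess_has_zero_mcc_and_zero_minority_recall(self):
        y = np.array([0, 0, 0, 0, 1, 1])
        pred = np.zeros(6, dtype=int)
        rep = compute_metrics(y, pred, np.ones(6) * 0.9)
        assert rep["MCC"] == 0.0
        assert rep["RC1"] == 0.0
        assert rep.flags  # undefined class-1 precision flagged

    def test_worked_confusion_example(self):
        y_true = np.array([0, 0, 0, 1, 1])
        y_pred = np.array([0, 0, 1, 1, 0])
        rep = compute_metrics(y_true, y_pred, 1.0 - y_pred)
        assert rep["PC0"] == pytest.approx(2 / 3)
        assert rep["RC0"] == pytest.approx(2 / 3)
        assert rep["PC1"] == pytest.approx(1 / 2)
        assert rep["RC1"] == pytest.approx(1 / 2)
        assert rep["MCC"] == pytest.approx(1 / 6)

    def test_exhaustive_small_confusion_tables(self):
        """Agreement with the exact rational oracle over all tables with cells <= 6."""
        for tp, fn, fp, tn in itertools.product(range(7), repeat=4):
            if tp + fn == 0 or fp + tn == 0:
                continue  # y_true single-class: contract error, skip
            y_true, y_pred, score0 = confusion_to_vectors(tp, fn, fp, tn)
            rep = compute_metrics(y_true, y_pred, score0)
            oracle = brute_force_confusion_metrics(tp, fn, fp, tn)
            for k, v in oracle.items():
                assert rep[k] == pytest.approx(v, abs=1e-12), (k, tp, fn, fp, tn)

    def test_roc_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.integers(0, 2, 50)
            if len(set(y.tolist())) < 2:
                continue
            s = rng.normal(size=50)
            rep = compute_metrics(y, 1 - y, s)
            u = stats.mannwhitneyu(s[y == 0], s[y == 1], alternative="two-sided").statistic
            auc = u / (np.sum(y == 0) * np.sum(y == 1))
            assert rep["ROC_AUC"] == pytest.approx(auc, abs=1e-12)

    def test_macro_f1_between_class_f1s_and_mcc_sign_flip(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        pred = rng.integers(0, 2, 40)
        rep = compute_metrics(y, pred, 1.0 - pred)
        assert min(rep["F10"], rep["F11"]) - 1e-12 <= rep["MF1"] <= max(rep["F10"], rep["F11"]) + 1e-12
        flipped = compute_metrics(y, 1 - pred, pred.astype(float))
        assert flipped["MCC"] == pytest.approx(-rep["MCC"], abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics([0, 0], [0, 1], [0.5, 0.5])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            compute_metrics([0, 1], [0], [0.5])


def _toy_dataset(n=60, p=8, seed=0, informative=True, role="train", prefix="s"):
    rng = np.random.default_rng(seed)
    y = np.array([0] * int(0.65 * n) + [1] * (n - int(0.65 * n)))
    vals = rng.normal(size=(p, n))
    if informative:
        vals[0] += (y == 0) * 2.0
        vals[1] -= (y == 0) * 1.5
    ids = [f"{prefix}{j}" for j in range(n)]
    nm = NormMatrix([f"g{i}" for i in range(p)], ids, vals)
    st = SampleTable(
        pd.DataFrame(
            {"sample_id": ids, "class_label": y, "batch_id": ["b"] * n, "role": [role] * n}
        )
    )
    return Dataset(nm, st)


class TestTrainAndTune:
    def test_training_separable_resubstitution_perfect(self):
        ds = _toy_dataset(seed=1)
        X = ds.matrix.values.T
        y = ds.samples.class_labels
        clf = train_rf(X, y, RFHyperparams(n_trees=100, mtry=3), seed=0)
        assert np.mean(clf.predict(X) == y) == 1.0
        p0 = clf.predict_proba_class0(X)
        assert np.all((p0 >= 0) & (p0 <= 1))

    def test_seed_determinism(self):
        ds = _toy_dataset(seed=2)
        X = ds.matrix.values.T
        y = ds.samples.class_labels
        a = train_rf(X, y, seed=7).predict_proba_class0(X)
        b = train_rf(X, y, seed=7).predict_proba_class0(X)
        assert np.array_equal(a, b)

    def test_mtry_exceeding_features_errors(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="mtry"):
            train_rf(X, y, RFHyperparams(mtry=5))

    def test_tune_grid_of_one_returns_it(self):
        ds = _toy_dataset(seed=3)
        X = ds.matrix.values.T
        y = ds.samples.class_labels
        hp = tune_rf(X, y, grid_size=1, n_cv=3, n_trees=50, seed=0)
        assert hp.mtry == 1 and hp.split_rule == "gini" and hp.min_node_size == 1

    def test_tune_tiebreak_on_separable_toy(self):
        """Every grid point is perfect on a separable toy; smallest mtry wins."""
        rng = np.random.default_rng(4)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        X = np.column_stack([(y == 0) * 4.0 + rng.normal(0, 0.1, n), rng.normal(size=n)])
        hp = tune_rf(X, y, grid_size=8, n_cv=2, n_trees=50, seed=1)
        assert hp.mtry == 1
        assert hp.split_rule == "gini"
        assert hp.min_node_size == 1

    def test_default_profile_matches_documented_optimum(self):
        hp = RFHyperparams()
        assert (hp.n_trees, hp.mtry, hp.split_rule, hp.min_node_size) == (500, 3, "extratrees", 1)


class TestProtocols:
    def test_repeated_split_ci_arithmetic(self):
        """Mean/CI of hand-fed metric vectors match direct arithmetic."""
        vals = [0.9, 0.8, 1.0, 0.7, 0.85]
        reports = []
        for v in vals:
            d = {k: v for k in METRIC_KEYS}
            reports.append(MetricReport(d))
        agg = _aggregate_reports(reports)
        mean = np.mean(vals)
        sd = np.std(vals, ddof=1)
        assert agg.mean["MCC"] == pytest.approx(mean)
        assert agg.ci_low["MCC"] == pytest.approx(mean - 1.96 * sd)
        assert agg.ci_high["MCC"] == pytest.approx(mean + 1.96 * sd)

    def test_single_repetition_degenerate_ci(self):
        ds = _toy_dataset(seed=5)
        rep = protocol_repeated_split(ds, ["g0", "g1"], RFHyperparams(n_trees=50, mtry=2),
                                      n_rep=1, seed=0)
        assert rep.ci_low["MCC"] == pytest.approx(rep.mean["MCC"])
        assert rep.ci_high["MCC"] == pytest.approx(rep.mean["MCC"])

    def test_cross_dataset_identity_equals_resubstitution(self):
        ds = _toy_dataset(seed=6)
        hp = RFHyperparams(n_trees=100, mtry=2)
        rep = protocol_cross_dataset(ds, ds, ["g0", "g1", "g2"], hp, seed=0)
        X = np.asarray(ds.matrix.values, dtype=float)[[0, 1, 2]].T
        y = ds.samples.class_labels
        from consensig.balance import adasyn

        rng = np.random.default_rng(0)
        bal = adasyn(X, y, seed=int(rng.integers(2**31)))
        clf = train_rf(bal.X, bal.y, hp, seed=int(rng.integers(2**31)))
        direct = compute_metrics(y, clf.predict(X), clf.predict_proba_class0(X))
        for k in METRIC_KEYS:
            assert rep[k] == pytest.approx(direct[k]), k

    def test_cross_dataset_separated_signal(self):
        ds_tr = _toy_dataset(seed=7, prefix="t")
        ds_va = _toy_dataset(seed=8, n=40, role="validation", prefix="v")
        rep = protocol_cross_dataset(ds_tr, ds_va, ["g0", "g1"], RFHyperparams(n_trees=100, mtry=2), seed=0)
        assert rep["MCC"] > 0.5

    def test_cross_dataset_missing_gene_errors(self):
        ds = _toy_dataset(seed=9)
        with pytest.raises(ValueError, match="absent"):
            protocol_cross_dataset(ds, ds, ["nope"], seed=0)

    def test_empty_gene_set_errors(self):
        ds = _toy_dataset(seed=9)
        with pytest.raises(ValueError, match="empty gene set"):
            protocol_cross_dataset(ds, ds, [], seed=0)

    def test_random_baseline_near_zero_on_noise(self):
        ds_tr = _toy_dataset(seed=10, n=80, p=30, informative=False, prefix="t")
        ds_va = _toy_dataset(seed=11, n=60, p=30, informative=False, role="validation", prefix="v")
        rep = random_gene_baseline(ds_tr, ds_va, n_genes=5, n_rep=20,
                                   hp=RFHyperparams(n_trees=50, mtry=3), seed=0)
        assert abs(rep.mean["MCC"]) < 0.15

    def test_random_baseline_seed_reproducible(self):
        ds_tr = _toy_dataset(seed=12, prefix="t")
        ds_va = _toy_dataset(seed=13, n=40, role="validation", prefix="v")
        hp = RFHyperparams(n_trees=30, mtry=2)
        a = random_gene_baseline(ds_tr, ds_va, n_genes=3, n_rep=5, hp=hp, seed=4)
        b = random_gene_baseline(ds_tr, ds_va, n_genes=3, n_rep=5, hp=hp, seed=4)
        assert a.mean == b.mean

    def test_random_baseline_too_many_genes_errors(self):
        ds = _toy_dataset(seed=14)
        with pytest.raises(ValueError, match="n_genes"):
            random_gene_baseline(ds, ds, n_genes=99, n_rep=2, seed=0)
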