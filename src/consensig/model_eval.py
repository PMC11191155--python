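"""Random-forest modelling and the twelve-metric evaluation suite.

Metrics are chosen for imbalanced binary problems: per-class precision,
recall and F1 (class 0 = metastasis, the majority class in the motivating
study; class 1 = non-metastasis), their macro averages (unweighted mean
over the two classes), ROC-AUC, PR-AUC (average precision with class 0 as
the positive class) and the Matthews correlation coefficient.

Conventions for degenerate inputs: a precision with no predicted positives
is reported as 0 (and flagged); an MCC whose denominator has a zero factor
is 0.  Macro-F1 is the mean of the two class F1s, not the F1 of the macro
precision/recall.

Three validation protocols are provided: repeated stratified 90/10 splits
within one cohort (mean and 95% CI over repetitions), single cross-dataset
train -> validation evaluation, and a random-gene baseline repeating the
cross-dataset protocol on randomly drawn gene sets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from consensig.balance import adasyn
from consensig.core_types import Dataset

METRIC_KEYS = (
    "PC0", "RC0", "F10", "PC1", "RC1", "F11",
    "MPC", "MRC", "MF1", "ROC_AUC", "PR_AUC", "MCC",
)


@dataclass
class RFHyperparams:
    """Random-forest settings (ranger-style naming).

    The documented default profile mirrors the motivating study's reported
    optimum: 500 trees, mtry 3, extratrees splitting, min node size 1.
    """

    n_trees: int = 500
    mtry: int = 3
    split_rule: str = "extratrees"  # or "gini"
    min_node_size: int = 1

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.mtry <= 0 or self.min_node_size <= 0:
            raise ValueError("RF hyperparameters must be positive")
        if self.split_rule not in ("gini", "extratrees"):
            raise ValueError("split_rule must be 'gini' or 'extratrees'")


@dataclass
class MetricReport:
    values: dict[str, float]
    flags: list[str] = field(default_factory=list)
    mean: Optional[dict[str, float]] = None
    ci_low: Optional[dict[str, float]] = None
    ci_high: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        missing = [k for k in METRIC_KEYS if k not in self.values]
        if missing:
            raise ValueError(f"metric report missing keys: {missing}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload: dict = {k: self.values[k] for k in METRIC_KEYS}
        if self.flags:
            payload["flags"] = self.flags
        for name in ("mean", "ci_low", "ci_high"):
            block = getattr(self, name)
            if block is not None:
                payload[name] = block
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], score0: Sequence[float]
) -> MetricReport:
    """Twelve evaluation metrics from labels, predictions and class-0 scores.

    ``score0`` is the predicted probability (or any monotone score) of
    class 0, which is treated as the positive class for ROC and PR curves.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    score0 = np.asarray(score0, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) != len(score0):
        raise ValueError("y_true, y_pred and score0 must have equal length")
    if len(set(y_true.tolist())) != 2:
        raise ValueError("y_true must contain both classes")

    flags: list[str] = []

    def prf(cls: int) -> tuple[float, float, float]:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        if tp + fp == 0:
            flags.append(f"PC{cls}_undefined_no_predicted_positives")
            pc = 0.0
        else:
            pc = tp / (tp + fp)
        rc = tp / (tp + fn)  # class present in y_true by precondition
        f1 = 0.0 if pc + rc == 0 else 2 * pc * rc / (pc + rc)
        return pc, rc, f1

    pc0, rc0, f10 = prf(0)
    pc1, rc1, f11 = prf(1)

    tp = int(np.sum((y_true == 0) & (y_pred == 0)))
    tn = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 1) & (y_pred == 0)))
    fn = int(np.sum((y_true == 0) & (y_pred == 1)))
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in denom_factors):
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(np.prod([float(f) for f in denom_factors])))

    # ROC-AUC: Mann-Whitney statistic of score0, class 0 positive, ties 1/2
    roc = float(roc_auc_score((y_true == 0).astype(int), score0))
    # PR-AUC: average precision, class 0 positive
    pr = float(average_precision_score((y_true == 0).astype(int), score0))

    values = {
        "PC0": pc0, "RC0": rc0, "F10": f10,
        "PC1": pc1, "RC1": rc1, "F11": f11,
        "MPC": (pc0 + pc1) / 2, "MRC": (rc0 + rc1) / 2, "MF1": (f10 + f11) / 2,
        "ROC_AUC": roc, "PR_AUC": pr, "MCC": float(mcc),
    }
    return MetricReport(values, flags=flags)


class RFClassifier:
    """Thin wrapper fixing class order and the class-0 probability contract.

    ``split_rule='extratrees'`` maps to random-split trees (ExtraTrees with
    bootstrap), ``'gini'`` to standard CART forests; ``mtry`` is the number
    of features tried per split and ``min_node_size`` the minimum leaf
    size.  The predicted class-0 probability is the mean vote over trees
    (trees grown to purity, so tree probabilities are votes).
    """

    def __init__(self, hp: RFHyperparams, n_features: int, seed: Optional[int] = None):
        if hp.mtry > n_features:
            raise ValueError(f"mtry={hp.mtry} exceeds the {n_features} available features")
        cls = ExtraTreesClassifier if hp.split_rule == "extratrees" else RandomForestClassifier
        self._model = cls(
            n_estimators=hp.n_trees,
            max_features=hp.mtry,
            min_samples_leaf=hp.min_node_size,
            bootstrap=True,
            random_state=None if seed is None else int(seed) % (2**31),
            n_jobs=1,
        )
        self.hp = hp

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RFClassifier":
        self._model.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict(X)

    def predict_proba_class0(self, X: np.ndarray) -> np.ndarray:
        proba = self._model.predict_proba(X)
        j = int(np.flatnonzero(self._model.classes_ == 0)[0])
        return proba[:, j]


def train_rf(
    X: np.ndarray, y: np.ndarray, hp: Optional[RFHyperparams] = None, seed: Optional[int] = None
) -> RFClassifier:
    """Fit a random forest; deterministic under ``seed``.

    The caller is responsible for balancing X upstream (the protocols below
    apply ADASYN to training partitions only).
    """
    hp = hp or RFHyperparams()
    X = np.asarray(X, dtype=float)
    return RFClassifier(hp, n_features=X.shape[1], seed=seed).fit(X, np.asarray(y))


def tune_rf(
    X: np.ndarray,
    y: np.ndarray,
    grid_size: int = 10,
    n_cv: int = 5,
    n_trees: int = 500,
    seed: Optional[int] = None,
) -> RFHyperparams:
    """Grid search over (mtry, split_rule, min_node_size) at fixed n_trees.

    ``grid_size`` combinations are scored by stratified ``n_cv``-fold CV
    accuracy with ADASYN applied to each training fold; ties break to the
    smallest mtry, then gini, then the smallest min_node_size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("tuning requires both classes")
    if counts.min() < n_cv:
        raise ValueError(f"need at least n_cv={n_cv} samples per class")
    p = X.shape[1]

    mtry_grid = sorted(set(int(m) for m in np.linspace(1, p, num=max(1, (grid_size + 1) // 2))))
    grid: list[tuple[int, str, int]] = []
    for rule in ("gini", "extratrees"):
        for node in (1, 5):
            for m in mtry_grid:
                grid.append((m, rule, node))
    # deterministic, sorted by the tie-break order so argmax-first wins ties
    grid = sorted(set(grid), key=lambda t: (t[0], t[1] != "gini", t[2]))[:grid_size]

    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_cv, shuffle=True, random_state=int(rng.integers(2**31)))
    splits = list(skf.split(X, y))

    best: tuple[float, int] = (-1.0, -1)
    for gi, (m, rule, node) in enumerate(grid):
        hp = RFHyperparams(n_trees=n_trees, mtry=m, split_rule=rule, min_node_size=node)
        accs = []
        for tr, te in splits:
            bal = adasyn(X[tr], y[tr], seed=int(rng.integers(2**31)))
            clf = train_rf(bal.X, bal.y, hp, seed=int(rng.integers(2**31)))
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        acc = float(np.mean(accs))
        if acc > best[0] + 1e-12:
            best = (acc, gi)
    m, rule, node = grid[best[1]]
    return RFHyperparams(n_trees=n_trees, mtry=m, split_rule=rule, min_node_size=node)


def _aggregate_reports(reports: list[MetricReport]) -> MetricReport:
    """Mean and 95% CI (mean +/- 1.96 * sd across repetitions) per metric."""
    arr = {k: np.array([r.values[k] for r in reports]) for k in METRIC_KEYS}
    mean = {k: float(v.mean()) for k, v in arr.items()}
    sd = {k: (float(v.std(ddof=1)) if len(v) > 1 else 0.0) for k, v in arr.items()}
    ci_low = {k: mean[k] - 1.96 * sd[k] for k in METRIC_KEYS}
    ci_high = {k: mean[k] + 1.96 * sd[k] for k in METRIC_KEYS}
    flags = sorted({f for r in reports for f in r.flags})
    return MetricReport(dict(mean), flags=flags, mean=mean, ci_low=ci_low, ci_high=ci_high)


def _dataset_xy(ds: Dataset, genes: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids)}
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        raise ValueError(f"gene {missing[0]!r} absent from dataset matrix")
    if not genes:
        raise ValueError("empty gene set")
    idx = np.array([gene_pos[g] for g in genes])
    X = np.asarray(ds.matrix.values, dtype=float)[idx].T
    return X, ds.samples.class_labels


def protocol_repeated_split(
    ds: Dataset,
    genes: Sequence[str],
    hp: Optional[RFHyperparams] = None,
    n_rep: int = 100,
    test_frac: float = 0.10,
    seed: Optional[int] = None,
) -> MetricReport:
    """Repeated stratified train/test splits within one cohort.

    Per repetition: a stratified ``1 - test_frac`` / ``test_frac`` split,
    ADASYN on the training part, a fresh forest, evaluation on the untouched
    test part.  Reports per-metric mean and 95% CI over repetitions.
    """
    hp = hp or RFHyperparams()
    X, y = _dataset_xy(ds, genes)
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(n_rep):
        for attempt in range(10):
            idx = np.arange(len(y))
            test_parts = []
            for cls in np.unique(y):
                cls_idx = idx[y == cls]
                n_test = max(1, int(round(test_frac * len(cls_idx))))
                test_parts.append(rng.choice(cls_idx, size=n_test, replace=False))
            test_idx = np.sort(np.concatenate(test_parts))
            train_mask = np.ones(len(y), bool)
            train_mask[test_idx] = False
            if len(set(y[test_idx].tolist())) == 2 and len(set(y[train_mask].tolist())) == 2:
                break
        else:
            raise RuntimeError("could not draw a test split containing both classes")
        bal = adasyn(X[train_mask], y[train_mask], seed=int(rng.integers(2**31)))
        hp_eff = hp if hp.mtry <= X.shape[1] else RFHyperparams(
            hp.n_trees, X.shape[1], hp.split_rule, hp.min_node_size
        )
        clf = train_rf(bal.X, bal.y, hp_eff, seed=int(rng.integers(2**31)))
        reports.append(
            compute_metrics(y[test_idx], clf.predict(X[test_idx]), clf.predict_proba_class0(X[test_idx]))
        )
    return _aggregate_reports(reports)


def protocol_cross_dataset(
    ds_train: Dataset,
    ds_valid: Dataset,
    genes: Sequence[str],
    hp: Optional[RFHyperparams] = None,
    seed: Optional[int] = None,
) -> MetricReport:
    """Train once on the ADASYN-balanced train cohort, evaluate once on the
    untouched validation cohort."""
    hp = hp or RFHyperparams()
    X_tr, y_tr = _dataset_xy(ds_train, genes)
    X_va, y_va = _dataset_xy(ds_valid, genes)
    rng = np.random.default_rng(seed)
    bal = adasyn(X_tr, y_tr, seed=int(rng.integers(2**31)))
    hp_eff = hp if hp.mtry <= X_tr.shape[1] else RFHyperparams(
        hp.n_trees, X_tr.shape[1], hp.split_rule, hp.min_node_size
    )
    clf = train_rf(bal.X, bal.y, hp_eff, seed=int(rng.integers(2**31)))
    return compute_metrics(y_va, clf.predict(X_va), clf.predict_proba_class0(X_va))


def random_gene_baseline(
    ds_train: Dataset,
    ds_valid: Dataset,
    n_genes: int = 15,
    n_rep: int = 100,
    hp: Optional[RFHyperparams] = None,
    seed: Optional[int] = None,
) -> MetricReport:
    """Cross-dataset protocol repeated on randomly drawn gene sets.

    Per repetition, ``n_genes`` genes are drawn uniformly without
    replacement from the train matrix; mean and 95% CI over repetitions.
    """
    pool = list(ds_train.gene_ids)
    if n_genes > len(pool):
        raise ValueError(f"n_genes={n_genes} exceeds the {len(pool)} available genes")
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(n_rep):
        genes = [pool[i] for i in rng.choice(len(pool), size=n_genes, replace=False)]
        reports.append(
            protocol_cross_dataset(ds_train, ds_valid, genes, hp, seed=int(rng.integers(2**31)))
        )
    return _aggregate_reports(reports)
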