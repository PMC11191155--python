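"""Single-run variable-selection algorithms: LASSO, Boruta, varSelRF-style.

Each selector takes a samples x features matrix with binary labels and
returns the selected feature names plus diagnostics.  They are the three
engines the consensus module resamples:

* L1-penalised logistic regression with a cross-validated lambda path
  (fast pre-selection, captures linear signal, minimal-optimal);
* Boruta: all-relevant search comparing real features against shuffled
  "shadow" copies under a random forest, with binomial hit tests;
* backward elimination tracking random-forest out-of-bag error, keeping
  the smallest set within c standard errors of the minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = ["SelectorResult", "lasso_select", "boruta_select", "varselrf_select"]


@dataclass
class SelectorResult:
    selector: str  # lasso | boruta | varselrf
    selected: list[str]
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"selector": self.selector, "selected": self.selected, "diagnostics": self.diagnostics}


def _l1_logistic(C: float, random_state: int = 0) -> LogisticRegression:
    """Pure-L1 logistic regression across sklearn's penalty-API change.

    random_state must be fixed: liblinear otherwise draws from the global
    NumPy RNG, breaking run-to-run determinism.
    """
    import sklearn

    major, minor = (int(v) for v in sklearn.__version__.split(".")[:2])
    if (major, minor) >= (1, 8):
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=200, random_state=random_state
        )
    return LogisticRegression(
        penalty="l1", C=C, solver="liblinear", max_iter=200, random_state=random_state
    )


def _as_named(X: np.ndarray, feature_names: Optional[Sequence[str]]) -> tuple[np.ndarray, list[str]]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")
    return X, names


def _check_two_classes(y: np.ndarray, min_per_class: int = 2) -> np.ndarray:
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("selection requires exactly two classes in y")
    if counts.min() < min_per_class:
        raise ValueError(f"each class needs at least {min_per_class} samples")
    return y


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    n_cv: int = 5,
    rule: str = "min",
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
    seed: Optional[int] = None,
) -> SelectorResult:
    """L1 logistic regression; features with nonzero coefficients selected.

    Features are standardised internally, a descending lambda path is built
    from the data (lambda_max zeroes every coefficient), and lambda is
    chosen by ``n_cv``-fold CV binomial deviance, either at the minimum
    (``rule="min"``, permissive) or by the one-standard-error rule
    (``rule="1se"``, parsimonious).
    """
    X, names = _as_named(X, feature_names)
    y = _check_two_classes(y)
    y01 = (y == np.unique(y)[1]).astype(int)

    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant feature(s) before LASSO")
    keep_idx = np.flatnonzero(~const)
    if keep_idx.size == 0:
        return SelectorResult("lasso", [], {"lambda": None, "note": "all features constant"})
    Xs = (X[:, keep_idx] - X[:, keep_idx].mean(axis=0)) / sd[keep_idx]
    n = Xs.shape[0]

    fit_seed = int(np.random.default_rng(seed).integers(2**31))
    # lambda_max: smallest penalty with all-zero coefficients
    p_bar = y01.mean()
    lambda_max = np.max(np.abs(Xs.T @ (y01 - p_bar))) / n
    lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambdas)

    def path_deviance(X_tr, y_tr, X_te, y_te) -> np.ndarray:
        dev = np.empty(n_lambdas)
        for i, lam in enumerate(lambdas):
            clf = _l1_logistic(1.0 / (lam * len(y_tr)), fit_seed)
            clf.fit(X_tr, y_tr)
            prob = clf.predict_proba(X_te)[:, 1]
            dev[i] = 2.0 * log_loss(y_te, prob, labels=[0, 1], normalize=False) / len(y_te)
        return dev

    skf = StratifiedKFold(n_splits=n_cv, shuffle=True, random_state=seed)
    devs = np.vstack(
        [path_deviance(Xs[tr], y01[tr], Xs[te], y01[te]) for tr, te in skf.split(Xs, y01)]
    )
    mean_dev = devs.mean(axis=0)
    se_dev = devs.std(axis=0, ddof=1) / np.sqrt(n_cv)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        i_sel = i_min
    elif rule == "1se":
        # largest lambda (smallest index) within one SE of the minimum
        ok = mean_dev <= mean_dev[i_min] + se_dev[i_min]
        i_sel = int(np.flatnonzero(ok)[0])
    else:
        raise ValueError(f"unknown lambda rule {rule!r}")

    lam = lambdas[i_sel]
    clf = _l1_logistic(1.0 / (lam * n), fit_seed)
    clf.fit(Xs, y01)
    nz = np.flatnonzero(np.abs(clf.coef_[0]) > 0)
    selected = [names[keep_idx[i]] for i in nz]
    return SelectorResult(
        "lasso",
        selected,
        {"lambda": float(lam), "rule": rule, "cv_deviance": float(mean_dev[i_sel])},
    )


def _importances(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    importance: str,
    rng: np.random.Generator,
    n_repeats: int = 3,
) -> np.ndarray:
    if importance == "gini":
        return forest.feature_importances_
    if importance == "permutation":
        from sklearn.inspection import permutation_importance

        res = permutation_importance(
            forest, X, y, n_repeats=n_repeats, random_state=int(rng.integers(2**31))
        )
        return res.importances_mean
    raise ValueError(f"unknown importance measure {importance!r}")


def boruta_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    max_runs: int = 100,
    alpha: float = 0.01,
    n_estimators: int = 100,
    importance: str = "permutation",
    tentative: str = "reject",
    seed: Optional[int] = None,
) -> SelectorResult:
    """All-relevant feature selection by shadow-feature comparison.

    Each iteration appends a shuffled (shadow) copy of every feature, fits
    a random forest, and scores a "hit" for an undecided feature whose
    importance exceeds the maximum shadow importance.  Accumulated hits are
    tested against Binomial(n_iter, 0.5), two-sided at level ``alpha``
    with a Bonferroni correction over the undecided features (mirroring
    the reference implementation's multiplicity adjustment): the upper
    tail confirms, the lower tail rejects.  Features still undecided at
    ``max_runs`` are rejected by
    default (``tentative="reject"``) or resolved by comparing their median
    importance to the median of the shadow maxima (``tentative="median"``).
    """
    if max_runs < 10:
        raise ValueError("max_runs < 10 leaves the binomial test underpowered")
    X, names = _as_named(X, feature_names)
    y = _check_two_classes(y, min_per_class=5)
    rng = np.random.default_rng(seed)
    p = X.shape[1]

    status = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    hits = np.zeros(p, dtype=int)
    imp_history: list[np.ndarray] = []
    shadow_max_history: list[float] = []
    n_iter = 0
    for _ in range(max_runs):
        undecided = np.flatnonzero(status == 0)
        if undecided.size == 0:
            break
        n_iter += 1
        # every original feature and one shadow per feature stay in the
        # model for the whole run: a shadow pool that shrank with the
        # undecided set would lower the importance bar in late iterations,
        # letting surviving (winner's-curse) noise features accumulate hits
        shadows = X.copy()
        for col in range(p):
            rng.shuffle(shadows[:, col])
        X_aug = np.hstack([X, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        forest.fit(X_aug, y)
        imp = _importances(forest, X_aug, y, importance, rng)
        real_imp = imp[:p]
        shadow_max = float(imp[p:].max())
        shadow_max_history.append(shadow_max)
        imp_history.append(real_imp.copy())

        for f in undecided:
            if real_imp[f] > shadow_max:
                hits[f] += 1
        # binomial decisions on undecided features; Bonferroni over all p
        # features (constant across iterations — a level based on the
        # shrinking undecided set would grow more liberal exactly when the
        # surviving features are the winner's-curse ones)
        level = alpha / 2.0 / p
        for f in undecided:
            p_greater = stats.binom.sf(hits[f] - 1, n_iter, 0.5)
            p_less = stats.binom.cdf(hits[f], n_iter, 0.5)
            if p_greater < level:
                status[f] = 1
            elif p_less < level:
                status[f] = -1

    if tentative == "median" and np.any(status == 0):
        med_shadow = float(np.median(shadow_max_history))
        imps = np.vstack(imp_history)
        for f in np.flatnonzero(status == 0):
            vals = imps[:, f]
            vals = vals[~np.isnan(vals)]
            status[f] = 1 if vals.size and np.median(vals) > med_shadow else -1

    selected = [names[i] for i in np.flatnonzero(status == 1)]
    return SelectorResult(
        "boruta",
        selected,
        {
            "n_iterations": n_iter,
            "hits": {names[i]: int(hits[i]) for i in range(p)},
            "n_tentative": int(np.sum(status == 0)),
        },
    )


def varselrf_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    drop_frac: float = 0.2,
    c_sd: float = 1.0,
    n_trees_first: int = 2000,
    n_trees_iter: int = 500,
    importance: str = "permutation",
    seed: Optional[int] = None,
) -> SelectorResult:
    """Backward elimination on random-forest OOB error.

    Features are ranked by importance once, from the initial forest (the
    ranking is *not* recomputed during elimination, which avoids overfitting
    the elimination path); at each step the least-important ``drop_frac``
    fraction (at least one feature) is removed and the out-of-bag error of a
    fresh forest recorded.  The result is the smallest set whose OOB error
    is within ``c_sd`` standard errors (SE = sqrt(err(1-err)/n)) of the
    minimum observed error.
    """
    if not 0.0 < drop_frac < 1.0:
        raise ValueError("drop_frac must be in (0, 1)")
    X, names = _as_named(X, feature_names)
    y = _check_two_classes(y, min_per_class=5)
    rng = np.random.default_rng(seed)
    n = X.shape[0]

    def oob_error(cols: np.ndarray, n_trees: int) -> float:
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            oob_score=True,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(X[:, cols], y)
        oob = forest.oob_decision_function_
        # samples never out-of-bag (rare with many trees) count as errors
        pred_ok = np.full(n, False)
        have = ~np.isnan(oob[:, 0])
        pred_ok[have] = forest.classes_[np.argmax(oob[have], axis=1)] == y[have]
        return float(1.0 - pred_ok.mean())

    first = RandomForestClassifier(
        n_estimators=n_trees_first, oob_score=True, random_state=int(rng.integers(2**31)), n_jobs=1
    )
    first.fit(X, y)
    imp = _importances(first, X, y, importance, rng)
    order = np.argsort(-imp, kind="stable")  # most important first

    cols = order.copy()
    path_sizes = [len(cols)]
    oob0 = first.oob_decision_function_
    have = ~np.isnan(oob0[:, 0])
    ok = np.full(n, False)
    ok[have] = first.classes_[np.argmax(oob0[have], axis=1)] == y[have]
    path_errors = [float(1.0 - ok.mean())]
    path_cols = [cols.copy()]
    while len(cols) > 1:
        n_drop = max(1, int(np.floor(drop_frac * len(cols))))
        cols = cols[: len(cols) - n_drop]
        path_sizes.append(len(cols))
        path_errors.append(oob_error(cols, n_trees_iter))
        path_cols.append(cols.copy())

    errors = np.array(path_errors)
    i_min = int(np.argmin(errors))
    min_err = errors[i_min]
    se = np.sqrt(min_err * (1.0 - min_err) / n)
    within = errors <= min_err + c_sd * se + 1e-12
    # smallest set (sizes are decreasing along the path)
    i_sel = int(np.flatnonzero(within)[-1])
    selected = [names[i] for i in path_cols[i_sel]]
    return SelectorResult(
        "varselrf",
        selected,
        {
            "path_sizes": path_sizes,
            "path_oob_errors": [float(e) for e in errors],
            "chosen_size": len(selected),
            "min_oob_error": float(min_err),
        },
    )
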