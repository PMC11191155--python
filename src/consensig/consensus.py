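"""Fold x model consensus variable selection.

The robustness engine: a stratified K-fold partition of the training
cohort; within each fold's training portion, many resampled models are
fitted per selector.  LASSO runs first on all genes; genes appearing in at
least ``model_freq`` of a fold's LASSO models form that fold's pool.
Boruta and varSelRF-style backward elimination then run on the pool, on
the *same* resamples per model index so that selector agreement is not
confounded by resampling noise.  A gene is fold-selected by a selector
when it appears in at least ``model_freq`` of that selector's models in
the fold; the robust set contains the genes fold-selected in at least
``min_folds`` folds by *both* tree-based selectors.

Every resample is ADASYN-balanced before fitting; no sample outside a
fold's training portion ever influences a selection record.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from consensig.balance import adasyn
from consensig.core_types import Dataset
from consensig.select import boruta_select, lasso_select, varselrf_select

logger = logging.getLogger(__name__)

SELECTORS = ("lasso", "boruta", "varselrf")


@dataclass
class ConsensusParams:
    n_folds: int = 10
    n_models: int = 100
    model_freq: float = 0.80
    min_folds: int = 5
    # subsample90: stratified 90% draw without replacement per model.  The
    # bootstrap alternative duplicates rows, which lets noise features
    # memorise labels and beat their shuffled shadows in Boruta — so the
    # duplicate-free scheme is the default.
    resample: str = "subsample90"
    seed: int = 0
    # selector settings used inside the loop (kept modest for tractability)
    lasso_rule: str = "min"
    lasso_n_cv: int = 5
    lasso_n_lambdas: int = 20
    boruta_max_runs: int = 25
    boruta_alpha: float = 0.01
    rf_n_estimators: int = 70
    varselrf_n_trees_first: int = 300
    varselrf_n_trees_iter: int = 150
    # c=0 returns the OOB-error-minimising set: per-model parsimony (the
    # standalone 1-SE rule) discards redundant relevant genes, which fights
    # the all-relevant consensus objective; FP control here comes from the
    # cross-selector and cross-fold thresholds instead.
    varselrf_c_sd: float = 0.0
    importance: str = "gini"
    adasyn_k: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.model_freq <= 1.0:
            raise ValueError("model_freq must be in (0, 1]")
        if not 1 <= self.min_folds <= self.n_folds:
            raise ValueError("min_folds must be between 1 and n_folds")
        if self.resample not in ("bootstrap", "subsample90"):
            raise ValueError("resample must be 'bootstrap' or 'subsample90'")


@dataclass
class SelectionLedger:
    """Long-format record of every (fold, model, selector, gene) selection."""

    records: pd.DataFrame  # columns: fold, model, selector, gene
    n_folds: int
    n_models: int
    fold_pools: dict[int, list[str]] = field(default_factory=dict)
    fold_train_sample_ids: dict[int, list[str]] = field(default_factory=dict)

    def write(self, path: Union[str, Path]) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def read(cls, path: Union[str, Path], n_folds: int, n_models: int) -> "SelectionLedger":
        df = pd.read_csv(path, dtype={"fold": int, "model": int, "selector": str, "gene": str})
        return cls(df, n_folds=n_folds, n_models=n_models)


def derive_seed(base_seed: int, fold: int, model: int, selector: str) -> int:
    """Stable, platform-independent per-(fold, model, selector) seed < 2^31."""
    key = f"{base_seed}|{fold}|{model}|{selector}".encode()
    return int.from_bytes(hashlib.blake2s(key, digest_size=4).digest(), "big") % (2**31)


def _resample_indices(
    y: np.ndarray, scheme: str, rng: np.random.Generator
) -> np.ndarray:
    """Stratified bootstrap (counts preserved) or stratified 90% subsample."""
    idx_parts = []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        if scheme == "bootstrap":
            idx_parts.append(rng.choice(cls_idx, size=len(cls_idx), replace=True))
        else:
            take = max(2, int(round(0.9 * len(cls_idx))))
            idx_parts.append(rng.choice(cls_idx, size=take, replace=False))
    return np.sort(np.concatenate(idx_parts))


def _fold_threshold(cp: ConsensusParams) -> int:
    # "at least model_freq of models" — inclusive at the boundary
    return int(np.ceil(cp.model_freq * cp.n_models - 1e-9))


def run_selection_cv(
    ds_train: Dataset, cp: ConsensusParams
) -> tuple[SelectionLedger, list[str]]:
    """Run the full fold x model selection and return (ledger, robust set).

    ``ds_train`` must hold preprocessed (normalised, filtered, corrected)
    log expression for train-role samples only.
    """
    values = np.asarray(ds_train.matrix.values, dtype=float)
    genes = list(ds_train.gene_ids)
    X_all = values.T  # samples x genes
    y_all = ds_train.samples.class_labels
    sample_ids = np.array(ds_train.sample_ids)

    classes, counts = np.unique(y_all, return_counts=True)
    if len(classes) != 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < cp.n_folds:
        raise ValueError(
            f"a class has only {counts.min()} samples, fewer than n_folds={cp.n_folds}; "
            "reduce n_folds"
        )

    skf = StratifiedKFold(n_splits=cp.n_folds, shuffle=True, random_state=cp.seed % (2**31))
    recs: list[tuple[int, int, str, str]] = []
    fold_pools: dict[int, list[str]] = {}
    fold_train_ids: dict[int, list[str]] = {}
    gene_arr = np.array(genes)

    for fold, (train_idx, _held_idx) in enumerate(skf.split(X_all, y_all), start=1):
        Xf = X_all[train_idx]
        yf = y_all[train_idx]
        fold_train_ids[fold] = sample_ids[train_idx].tolist()

        # stage 1: resampled LASSO models on all genes
        lasso_counts = np.zeros(len(genes), dtype=int)
        per_model_lasso: list[set[str]] = []
        for m in range(1, cp.n_models + 1):
            rs_rng = np.random.default_rng(derive_seed(cp.seed, fold, m, "resample"))
            idx = _resample_indices(yf, cp.resample, rs_rng)
            bal = adasyn(
                Xf[idx], yf[idx], k=cp.adasyn_k, seed=derive_seed(cp.seed, fold, m, "adasyn1")
            )
            res = lasso_select(
                bal.X,
                bal.y,
                feature_names=genes,
                n_cv=cp.lasso_n_cv,
                rule=cp.lasso_rule,
                n_lambdas=cp.lasso_n_lambdas,
                seed=derive_seed(cp.seed, fold, m, "lasso"),
            )
            sel = set(res.selected)
            per_model_lasso.append(sel)
            for g in res.selected:
                recs.append((fold, m, "lasso", g))
        for i, g in enumerate(genes):
            lasso_counts[i] = sum(g in s for s in per_model_lasso)
        pool = gene_arr[lasso_counts >= _fold_threshold(cp)].tolist()
        fold_pools[fold] = pool
        if not pool:
            warnings.warn(f"fold {fold}: empty LASSO pool, fold contributes no selections")
            continue
        gene_pos = {g: i for i, g in enumerate(genes)}
        pool_idx = np.array([gene_pos[g] for g in pool])

        # stage 2: Boruta and varSelRF on the pool, paired on the same resamples
        for m in range(1, cp.n_models + 1):
            rs_rng = np.random.default_rng(derive_seed(cp.seed, fold, m, "resample"))
            idx = _resample_indices(yf, cp.resample, rs_rng)
            bal = adasyn(
                Xf[np.ix_(idx, pool_idx)],
                yf[idx],
                k=cp.adasyn_k,
                seed=derive_seed(cp.seed, fold, m, "adasyn2"),
            )
            b_res = boruta_select(
                bal.X,
                bal.y,
                feature_names=pool,
                max_runs=cp.boruta_max_runs,
                alpha=cp.boruta_alpha,
                n_estimators=cp.rf_n_estimators,
                importance=cp.importance,
                seed=derive_seed(cp.seed, fold, m, "boruta"),
            )
            for g in b_res.selected:
                recs.append((fold, m, "boruta", g))
            v_res = varselrf_select(
                bal.X,
                bal.y,
                feature_names=pool,
                c_sd=cp.varselrf_c_sd,
                n_trees_first=cp.varselrf_n_trees_first,
                n_trees_iter=cp.varselrf_n_trees_iter,
                importance=cp.importance,
                seed=derive_seed(cp.seed, fold, m, "varselrf"),
            )
            for g in v_res.selected:
                recs.append((fold, m, "varselrf", g))

    records = pd.DataFrame(recs, columns=["fold", "model", "selector", "gene"])
    ledger = SelectionLedger(
        records, n_folds=cp.n_folds, n_models=cp.n_models,
        fold_pools=fold_pools, fold_train_sample_ids=fold_train_ids,
    )
    robust, _ = aggregate_ledger(ledger, cp)
    return ledger, robust


def aggregate_ledger(
    ledger: SelectionLedger, cp: ConsensusParams
) -> tuple[list[str], pd.DataFrame]:
    """Recompute per-fold selection flags and the robust set from raw records.

    Returns the robust gene list plus a summary table (gene x selector ->
    number of folds, out of ``n_folds``, in which the gene was selected in
    at least ``model_freq`` of that selector's models).
    """
    thr = _fold_threshold(cp)
    df = ledger.records
    if df.empty:
        return [], pd.DataFrame(columns=["gene", "lasso", "boruta", "varselrf"])
    per_fold = (
        df.groupby(["selector", "fold", "gene"])["model"].nunique().reset_index(name="n_models")
    )
    fold_selected = per_fold[per_fold["n_models"] >= thr]
    fold_counts = (
        fold_selected.groupby(["selector", "gene"])["fold"].nunique().reset_index(name="n_folds")
    )
    if fold_counts.empty:
        return [], pd.DataFrame(columns=["gene", *SELECTORS])
    table = fold_counts.pivot(index="gene", columns="selector", values="n_folds")
    for s in SELECTORS:
        if s not in table.columns:
            table[s] = np.nan
    table = table[list(SELECTORS)].fillna(0).astype(int).reset_index()
    robust = sorted(
        table.loc[(table["boruta"] >= cp.min_folds) & (table["varselrf"] >= cp.min_folds), "gene"]
    )
    return robust, table.sort_values("gene").reset_index(drop=True)
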