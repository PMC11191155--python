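"""ASCA-style removal of systematic batch variance from log expression.

The correction follows the ANOVA-simultaneous-component-analysis idea of
"removal of systematic noise", batch factor only: decompose the batch
submodel (each sample replaced by its batch mean, genes centred) by SVD,
call a component *systematic* when its variance share exceeds ``beta``
times the average share (average over one component per batch), and
subtract the reconstruction of the systematic part from every sample of
the corresponding batch.  Class-associated variance is untouched except
insofar as it is confounded with batch means.

By default the model is fitted on the combined train + validation matrix —
pragmatic for cohorts occupying different technical spaces, but a known
source of (mild) train/validation leakage, so a strict mode is provided
that fits on train samples only and merely aligns each validation batch's
gene means to the train grand means.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from consensig.core_types import NormMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    n_components: int
    batch_ids: list[str]
    batch_sizes: list[int]
    effects: np.ndarray  # (n_batches, n_genes) reconstructed systematic effects
    variance_shares: np.ndarray
    beta: float
    mode: str = "joint"

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "n_components": self.n_components,
            "batch_ids": self.batch_ids,
            "batch_sizes": self.batch_sizes,
            "effects": self.effects.tolist(),
            "variance_shares": self.variance_shares.tolist(),
            "beta": self.beta,
            "mode": self.mode,
        }
        Path(path).write_text(json.dumps(payload))


def _asca_effects(
    values: np.ndarray, batch_codes: np.ndarray, batch_list: list[str], beta: float
) -> tuple[np.ndarray, int, np.ndarray]:
    """Systematic per-batch effect vectors from the batch submodel SVD.

    `values` is genes x samples, already gene-centred across these samples.
    Returns (effects (batches x genes), n_retained, variance shares).
    """
    n_batches = len(batch_list)
    # batch submodel: every sample's profile replaced by its batch mean
    means = np.vstack(
        [values[:, batch_codes == b].mean(axis=1) for b in range(n_batches)]
    )  # (batches, genes)
    sizes = np.array([(batch_codes == b).sum() for b in range(n_batches)])
    sub = np.repeat(means, sizes, axis=0)  # (samples, genes), grouped by batch

    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.sum(s**2)
    if total <= 0:
        return np.zeros_like(means), 0, np.zeros(n_batches)
    shares = s**2 / total
    # retain components whose variance share exceeds beta x the average share
    # over all PCA components of the submodel matrix; with few batches every
    # non-trace component passes, i.e. the full batch-mean structure is removed
    threshold = beta / min(sub.shape)
    retained = shares >= threshold - 1e-12
    k = int(np.sum(retained[: min(len(shares), n_batches)]))
    if k == 0:
        return np.zeros_like(means), 0, shares[:n_batches]
    recon = (u[:, :k] * s[:k]) @ vt[:k]  # (samples, genes)
    # rows within a batch are identical; take the first row of each block
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    effects = recon[starts]
    return effects, k, shares[:n_batches]


def arsyn_correct(
    nm: NormMatrix,
    st: SampleTable,
    beta: float = 2.0,
    mode: str = "joint",
) -> tuple[NormMatrix, BatchModel]:
    """Remove systematic batch effects from a log-expression matrix.

    mode="joint" fits the batch submodel on all samples together (the
    default, mirroring integrated multi-cohort preprocessing); mode="strict"
    fits on train-role samples only and aligns validation batch means to the
    train gene means, avoiding any validation influence on the fit.
    """
    if nm.sample_ids != st.sample_ids:
        raise ValueError("matrix and sample table are not aligned")
    batches = st.batch_ids
    batch_list = sorted(set(batches))
    if len(batch_list) < 2:
        warnings.warn("single batch: batch correction is the identity")
        model = BatchModel(0, batch_list, [len(batches)], np.zeros((1, nm.n_genes)), np.zeros(1), beta, mode)
        return NormMatrix(list(nm.gene_ids), list(nm.sample_ids), nm.values.copy()), model
    st.check_batches_have_both_classes()

    values = nm.values.copy()
    code_of = {b: i for i, b in enumerate(batch_list)}
    codes = np.array([code_of[b] for b in batches])

    if mode == "joint":
        centers = values.mean(axis=1, keepdims=True)
        centred = values - centers
        effects, k, shares = _asca_effects(centred, codes, batch_list, beta)
        corrected = centred - effects.T[:, codes] + centers
        sizes = [int((codes == i).sum()) for i in range(len(batch_list))]
        model = BatchModel(k, batch_list, sizes, effects, shares, beta, mode)
        return NormMatrix(list(nm.gene_ids), list(nm.sample_ids), corrected), model

    if mode == "strict":
        train = st.roles == "train"
        train_batches = sorted(set(batches[train]))
        if len(train_batches) < 2:
            warnings.warn("single train batch: strict correction only re-centres validation batches")
        centers = values[:, train].mean(axis=1, keepdims=True)
        corrected = values - centers
        # fit on train only
        t_list = train_batches
        t_code_of = {b: i for i, b in enumerate(t_list)}
        t_codes = np.array([t_code_of[b] for b in batches[train]])
        if len(t_list) >= 2:
            effects, k, shares = _asca_effects(corrected[:, train], t_codes, t_list, beta)
        else:
            effects, k, shares = np.zeros((1, nm.n_genes)), 0, np.zeros(1)
        for b in t_list:
            corrected[:, train & (batches == b)] -= effects[t_code_of[b]][:, None]
        # validation batches: align their gene means to the train grand mean (0 here)
        for b in sorted(set(batches[~train])):
            sel = (~train) & (batches == b)
            corrected[:, sel] -= corrected[:, sel].mean(axis=1, keepdims=True)
        corrected += centers
        sizes = [int((batches == b).sum()) for b in t_list]
        model = BatchModel(k, t_list, sizes, effects, shares, beta, mode)
        return NormMatrix(list(nm.gene_ids), list(nm.sample_ids), corrected), model

    raise ValueError(f"unknown batch-correction mode {mode!r}")


def batch_variance_diag(nm: NormMatrix, st: SampleTable) -> tuple[np.ndarray, float]:
    """Per-gene one-way R² of the batch factor, plus the across-gene mean.

    R²_g = between-batch sum of squares / total sum of squares; a gene with
    zero total variance gets R² = 0.
    """
    batches = st.batch_ids
    batch_list = sorted(set(batches))
    if len(batch_list) < 2:
        raise ValueError("batch diagnostic needs at least 2 batches")
    values = nm.values
    grand = values.mean(axis=1, keepdims=True)
    ss_tot = np.sum((values - grand) ** 2, axis=1)
    ss_between = np.zeros(nm.n_genes)
    for b in batch_list:
        sel = batches == b
        ss_between += sel.sum() * (values[:, sel].mean(axis=1) - grand[:, 0]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_between / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)
    return r2, float(np.mean(r2))
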