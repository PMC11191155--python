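"""TMM normalisation, log-CPM transformation and train-derived gene filters.

TMM (trimmed mean of M-values) estimates per-sample scale factors from a
doubly trimmed, precision-weighted mean of per-gene log ratios against a
reference sample, accounting for sequencing depth and RNA composition.
The transform is log2 counts-per-million with a pseudo-count.

Three filters operate on the log2-CPM matrix, all computed from
*train-role samples only* and then applied to every sample:

* low expression: gene mean below the chosen quantile of all gene means;
* low effect: absolute between-class mean difference below a log2 cutoff
  (0.1 by default — small effect sizes are expected for subtle phenotypes,
  so only near-zero effects are discarded);
* batch inconsistency: the sign of the class difference disagrees between
  train batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from consensig.core_types import CountMatrix, NormMatrix, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class NormFactors:
    """Per-sample positive TMM scale factors, geometric mean 1."""

    sample_ids: list[str]
    factors: np.ndarray
    reference_sample: str = ""

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if len(self.factors) != len(self.sample_ids):
            raise ValueError("factor vector length mismatch")
        if np.any(self.factors <= 0):
            raise ValueError("scale factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"geometric mean of factors is {gm}, expected 1")


@dataclass
class FilterParams:
    expr_quantile: float = 0.05
    min_abs_lfc: float = 0.1
    consistency_rule: str = "same_sign"  # only strategy currently implemented

    def __post_init__(self) -> None:
        if not 0.0 <= self.expr_quantile < 1.0:
            raise ValueError("expr_quantile must be in [0, 1)")
        if self.min_abs_lfc < 0:
            raise ValueError("min_abs_lfc must be >= 0")


@dataclass
class GeneMask:
    """Kept/removed flags per gene, with a removal reason."""

    gene_ids: list[str]
    kept: np.ndarray  # bool
    reason: list[str]  # "" for kept genes

    def kept_genes(self) -> list[str]:
        return [g for g, k in zip(self.gene_ids, self.kept) if k]

    def intersect(self, other: "GeneMask") -> "GeneMask":
        if self.gene_ids != other.gene_ids:
            raise ValueError("gene id mismatch between masks")
        kept = self.kept & other.kept
        reason = [
            a if a else b for a, b in zip(self.reason, other.reason)
        ]
        return GeneMask(self.gene_ids, kept, ["" if k else r for k, r in zip(kept, reason)])

    def write(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"gene_id": self.gene_ids, "kept": self.kept.astype(int), "reason": self.reason}
        ).to_csv(path, sep="\t", index=False)


def _tmm_factor_one(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float
) -> float:
    """TMM factor of one sample against the reference column."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    if o.size == 0:
        return 1.0
    with np.errstate(divide="ignore"):
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))

    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 10:
        warnings.warn("fewer than 10 usable genes after TMM trimming; factor falls back to 1")
        return 1.0
    f = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return float(f) if np.isfinite(f) else 1.0


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """TMM scale factors (doubly trimmed, precision-weighted mean of M-values).

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the across-sample mean of that statistic (ties: lowest index).
    """
    values = cm.values.astype(float)
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        j = int(np.argmin(totals))
        raise ValueError(f"sample {cm.sample_ids[j]!r} has no counts")
    q75 = np.array([np.quantile(values[:, j] / totals[j], 0.75) for j in range(cm.n_samples)])
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            1.0
            if j == ref_j
            else _tmm_factor_one(cm.values[:, j], cm.values[:, ref_j], trim_m, trim_a)
            for j in range(cm.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(list(cm.sample_ids), factors, reference_sample=cm.sample_ids[ref_j])


def log_cpm(cm: CountMatrix, nf: NormFactors, prior_count: float = 0.5) -> NormMatrix:
    """log2 counts-per-million on TMM-adjusted library sizes.

    value_gj = log2( (y_gj + prior) / (N_j * f_j + 2*prior) * 1e6 ).
    """
    if nf.sample_ids != cm.sample_ids:
        raise ValueError("normalisation factors are not aligned to the count matrix samples")
    lib = cm.values.sum(axis=0).astype(float) * nf.factors
    vals = np.log2((cm.values + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    return NormMatrix(list(cm.gene_ids), list(cm.sample_ids), vals)


def _train_class_means(
    nm: NormMatrix, st: SampleTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    train = st.roles == "train"
    y = st.class_labels
    in0 = train & (y == 0)
    in1 = train & (y == 1)
    if not in0.any() or not in1.any():
        raise ValueError("both classes must be present among train-role samples")
    return nm.values[:, train].mean(axis=1), nm.values[:, in0].mean(axis=1), nm.values[:, in1].mean(axis=1)


def filter_genes(nm: NormMatrix, st: SampleTable, fp: FilterParams | None = None) -> GeneMask:
    """Low-expression and low-effect filters, thresholds from train samples.

    A gene is removed if its train-sample mean log-CPM falls strictly below
    the ``expr_quantile`` quantile of all gene means, or if the absolute
    class-mean difference is strictly below ``min_abs_lfc``.
    """
    fp = fp or FilterParams()
    mean_all, mean0, mean1 = _train_class_means(nm, st)
    cutoff = np.quantile(mean_all, fp.expr_quantile)
    low_expr = mean_all < cutoff
    # strict "<" with a representation guard: a difference within 1e-9 of the
    # cutoff counts as at the boundary and is kept
    low_fc = np.abs(mean0 - mean1) < fp.min_abs_lfc - 1e-9
    kept = ~(low_expr | low_fc)
    reason = [
        "" if k else ("low_expr" if le else "low_fc")
        for k, le, lf in zip(kept, low_expr, low_fc)
    ]
    return GeneMask(list(nm.gene_ids), kept, reason)


def filter_batch_inconsistent(nm: NormMatrix, st: SampleTable) -> GeneMask:
    """Keep genes whose class-difference sign agrees across all train batches.

    With a single train batch the mask is the identity (vacuous consistency).
    """
    train = st.roles == "train"
    y = st.class_labels
    batches = st.batch_ids
    train_batches = sorted(set(batches[train]))
    if len(train_batches) < 2:
        return GeneMask(list(nm.gene_ids), np.ones(nm.n_genes, bool), [""] * nm.n_genes)
    signs = []
    for b in train_batches:
        in0 = train & (batches == b) & (y == 0)
        in1 = train & (batches == b) & (y == 1)
        if not in0.any() or not in1.any():
            raise ValueError(f"train batch {b!r} is missing a class")
        signs.append(np.sign(nm.values[:, in0].mean(axis=1) - nm.values[:, in1].mean(axis=1)))
    signs = np.vstack(signs)
    kept = np.all(signs == signs[0], axis=0)
    reason = ["" if k else "batch_inconsistent" for k in kept]
    return GeneMask(list(nm.gene_ids), kept, reason)


def apply_mask(nm: NormMatrix, mask: GeneMask) -> NormMatrix:
    if mask.gene_ids != nm.gene_ids:
        raise ValueError("mask gene ids do not match matrix")
    keep = np.asarray(mask.kept, bool)
    return NormMatrix(
        [g for g, k in zip(nm.gene_ids, keep) if k], list(nm.sample_ids), nm.values[keep]
    )
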