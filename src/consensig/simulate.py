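"""Multi-batch negative-binomial RNA-seq count simulator with planted signal.

Emulates the structure of pooled multi-cohort bulk RNA-seq studies of a
binary phenotype: several technical batches with gene-specific systematic
shifts, variable sequencing depth, a ~65/35 class imbalance, and a small
set of signature genes up-regulated in class 0 (the metastasis / majority
class) by a modest log2 fold change.  Counts are negative binomial with
variance mu + dispersion * mu^2, the canonical bulk RNA-seq count model;
dispersion is constant across genes.

Not modelled: paired samples, continuous covariates, or tumour-cellularity
heterogeneity — a green recovery test establishes behaviour under clean
batch + imbalance structure only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from consensig.core_types import CountMatrix, Dataset, SampleTable


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror the motivating study's structure: three train batches
    of moderate size, 65% class-0 prevalence, modest planted fold changes.
    """

    n_genes: int = 500
    n_batches: int = 3
    samples_per_batch: int = 100
    prop_class0: float = 0.65
    baseline_logmean_mu: float = 5.0  # log2 scale mean abundance
    baseline_logmean_sd: float = 2.0
    nb_dispersion: float = 0.16  # BCV 0.4, canonical for human bulk cohorts
    batch_logfc_sd: float = 0.5
    libsize_range: tuple[float, float] = (0.5, 2.0)
    n_signal: int = 15
    signal_lfc: float = 1.0
    n_validation_batches: int = 0  # trailing batches get role "validation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_batches < 1 or self.samples_per_batch < 2:
            raise ValueError("n_genes, n_batches, samples_per_batch must be positive (>=2 genes/samples)")
        if not 0.0 < self.prop_class0 < 1.0:
            raise ValueError("prop_class0 must be in (0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.libsize_range[0] > self.libsize_range[1] or self.libsize_range[0] <= 0:
            raise ValueError("libsize_range must satisfy 0 < min <= max")
        if self.n_signal > self.n_genes:
            raise ValueError("n_signal cannot exceed n_genes")
        if self.n_validation_batches >= self.n_batches and self.n_validation_batches > 0:
            raise ValueError("need at least one train batch")


@dataclass
class SyntheticTruth:
    """Planted signature genes and their log2 fold changes (class 0 vs 1)."""

    signal_genes: list[str]
    lfc_per_gene: list[float]

    def __post_init__(self) -> None:
        if len(self.signal_genes) != len(self.lfc_per_gene):
            raise ValueError("signal_genes and lfc_per_gene length mismatch")

    def write(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"gene_id": self.signal_genes, "lfc": self.lfc_per_gene}).to_csv(
            path, sep="\t", index=False
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson if 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # NB number-of-successes parameter
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_dataset(
    cfg: SimConfig, truth: Optional[SyntheticTruth] = None
) -> tuple[Dataset, SyntheticTruth]:
    """Generate a count Dataset plus the planted-signal ground truth.

    The mean of gene g in sample j is
    ``baseline_g * 2^batchshift_{g,b(j)} * 2^(lfc_g if class(j)==0) * libsize_j``.
    Passing an existing ``truth`` re-plants the same genes/effects in a new
    cohort (e.g. to simulate an independent validation dataset); gene ids
    must then use the same naming convention (same n_genes).

    Deterministic: the same config (and truth) yields bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]

    baseline = 2.0 ** rng.normal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sd, cfg.n_genes)

    if truth is None:
        signal_idx = rng.choice(cfg.n_genes, size=cfg.n_signal, replace=False)
        signal_idx.sort()
        truth = SyntheticTruth(
            [gene_ids[i] for i in signal_idx], [float(cfg.signal_lfc)] * cfg.n_signal
        )
    else:
        missing = [g for g in truth.signal_genes if g not in set(gene_ids)]
        if missing:
            raise ValueError(f"truth gene {missing[0]!r} not producible with n_genes={cfg.n_genes}")
    lfc = np.zeros(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for g, fc in zip(truth.signal_genes, truth.lfc_per_gene):
        lfc[gene_pos[g]] = fc

    # gene x batch systematic shifts, drawn once
    batch_shift = rng.normal(0.0, cfg.batch_logfc_sd, size=(cfg.n_genes, cfg.n_batches))

    n_per_batch = cfg.samples_per_batch
    n0 = int(round(cfg.prop_class0 * n_per_batch))
    n0 = min(max(n0, 1), n_per_batch - 1)

    sample_ids: list[str] = []
    classes: list[int] = []
    batches: list[str] = []
    roles: list[str] = []
    cols: list[np.ndarray] = []
    first_valid = cfg.n_batches - cfg.n_validation_batches
    for b in range(cfg.n_batches):
        role = "validation" if b >= first_valid else "train"
        libsize = np.exp(
            rng.uniform(np.log(cfg.libsize_range[0]), np.log(cfg.libsize_range[1]), n_per_batch)
        )
        for j in range(n_per_batch):
            cls = 0 if j < n0 else 1
            mu = baseline * 2.0 ** batch_shift[:, b]
            if cls == 0:
                mu = mu * 2.0**lfc
            mu = mu * libsize[j]
            cols.append(_nb_draw(rng, mu, cfg.nb_dispersion))
            sample_ids.append(f"b{b}_s{j:03d}")
            classes.append(cls)
            batches.append(f"batch{b}")
            roles.append(role)

    values = np.column_stack(cols).astype(np.int64)
    cm = CountMatrix(gene_ids, sample_ids, values)
    st = SampleTable(
        pd.DataFrame(
            {"sample_id": sample_ids, "class_label": classes, "batch_id": batches, "role": roles}
        )
    )
    return Dataset(cm, st), truth


@dataclass
class RecoveryReport:
    sensitivity: float
    false_positives: int
    true_positives: int
    n_signal: int


def score_recovery(selected: Sequence[str], truth: SyntheticTruth) -> RecoveryReport:
    """Score a selected gene set against the planted signal.

    Sensitivity is |selected ∩ signal| / |signal|, defined as 1.0 when no
    signal genes were planted; false positives count selected non-signal genes.
    """
    sel = set(selected)
    sig = set(truth.signal_genes)
    tp = len(sel & sig)
    fp = len(sel - sig)
    sens = 1.0 if not sig else tp / len(sig)
    return RecoveryReport(sensitivity=sens, false_positives=fp, true_positives=tp, n_signal=len(sig))
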