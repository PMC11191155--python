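"""Data model for expression matrices and sample annotations.

Counts live in a genes x samples matrix with ordered, unique string
identifiers on both axes.  Sample annotations carry the binary class
(0 = metastasis, 1 = non-metastasis -- note class 0 is the *majority*
class in the motivating study), a batch/cohort identifier and a cohort
role (train or validation).  Gene identifiers are opaque strings; no
symbol mapping is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = ("train", "validation")
VALID_CLASSES = (0, 1)

CLASS_METASTASIS = 0
CLASS_NON_METASTASIS = 1


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), integer, non-negative

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise ValueError("empty count matrix")
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("count matrix needs at least 2 genes and 2 samples")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.all(np.isfinite(self.values)) or np.any(rounded != self.values):
                raise ValueError("counts must be integers")
            self.values = rounded.astype(np.int64)
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class NormMatrix:
    """Normalised log2 counts-per-million, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalised matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleTable:
    """Per-sample class label, batch id and cohort role."""

    frame: pd.DataFrame  # columns: sample_id, class_label, batch_id, role

    REQUIRED = ("sample_id", "class_label", "batch_id", "role")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required column(s): {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        labels = pd.to_numeric(df["class_label"], errors="coerce")
        bad = labels.isna() | ~labels.isin(VALID_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown class label {df.loc[bad, 'class_label'].iloc[0]!r}; "
                f"allowed: {list(VALID_CLASSES)} (0 = metastasis, 1 = non-metastasis)"
            )
        df["class_label"] = labels.astype(int)
        df["batch_id"] = df["batch_id"].astype(str)
        df["role"] = df["role"].astype(str)
        bad_role = ~df["role"].isin(VALID_ROLES)
        if bad_role.any():
            raise ValueError(
                f"unknown role {df.loc[bad_role, 'role'].iloc[0]!r}; allowed roles: {list(VALID_ROLES)}"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def class_labels(self) -> np.ndarray:
        return self.frame["class_label"].to_numpy()

    @property
    def batch_ids(self) -> np.ndarray:
        return self.frame["batch_id"].to_numpy()

    @property
    def roles(self) -> np.ndarray:
        return self.frame["role"].to_numpy()

    def subset(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(self.frame.loc[np.asarray(mask)].reset_index(drop=True))

    def check_batches_have_both_classes(self) -> None:
        """Every batch used for batch correction must contain both classes."""
        for batch, grp in self.frame.groupby("batch_id"):
            present = set(grp["class_label"])
            if present != set(VALID_CLASSES):
                raise ValueError(
                    f"batch {batch!r} does not contain both classes (found {sorted(present)})"
                )


@dataclass
class Dataset:
    """A matrix (counts or normalised) order-aligned with its sample table."""

    matrix: Union[CountMatrix, NormMatrix]
    samples: SampleTable

    def __post_init__(self) -> None:
        if self.matrix.sample_ids != self.samples.sample_ids:
            raise ValueError("matrix sample ids and sample table are not order-aligned")

    @property
    def gene_ids(self) -> list[str]:
        return self.matrix.gene_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    def subset_samples(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask)
        mat = self.matrix
        cls = type(mat)
        new_mat = cls(
            gene_ids=list(mat.gene_ids),
            sample_ids=[s for s, m in zip(mat.sample_ids, mask) if m],
            values=mat.values[:, mask],
        )
        return Dataset(new_mat, self.samples.subset(mask))

    def restrict_role(self, role: Literal["train", "validation"]) -> "Dataset":
        return self.subset_samples(self.samples.roles == role)


def read_counts(path: Union[str, Path], fmt: str | None = None) -> CountMatrix:
    """Read a gene x sample count matrix from TSV/CSV or MatrixMarket triplet.

    TSV/CSV: first column gene ids, header row sample ids.  The ``mtx``
    format expects sidecar id files ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` (one id per line) next to the ``.mtx`` file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"tsv": "tsv", "txt": "tsv", "csv": "csv", "mtx": "mtx"}.get(suffix, "tsv")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy()
        if values.dtype == object or not np.issubdtype(values.dtype, np.number):
            for j, col in enumerate(df.columns):
                coerced = pd.to_numeric(df[col], errors="coerce")
                if coerced.isna().any():
                    row = df.index[coerced.isna().to_numpy().argmax()]
                    raise ValueError(f"non-numeric count at gene {row!r}, sample {col!r}")
            values = df.apply(pd.to_numeric).to_numpy()
        return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)
    if fmt in ("mtx", "mtx-triplet"):
        from scipy.io import mmread

        raw = mmread(path)
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        genes = Path(str(path).removesuffix(".mtx") + ".genes.txt").read_text().split()
        samples = Path(str(path).removesuffix(".mtx") + ".samples.txt").read_text().split()
        return CountMatrix(genes, samples, mat)
    raise ValueError(f"unknown counts format {fmt!r}")


def write_counts(cm: CountMatrix, path: Union[str, Path], fmt: str = "tsv") -> None:
    sep = "\t" if fmt == "tsv" else ","
    cm.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_metadata(path: Union[str, Path]) -> SampleTable:
    """Read per-sample metadata (CSV or TSV by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return SampleTable(pd.read_csv(path, sep=sep))


def write_metadata(st: SampleTable, path: Union[str, Path]) -> None:
    st.frame.to_csv(path, index=False)


def align_dataset(cm: Union[CountMatrix, NormMatrix], st: SampleTable) -> Dataset:
    """Subset/reorder matrix columns to the sample-table order.

    Matrix columns absent from the table are dropped with a warning; a table
    id absent from the matrix is a hard error.
    """
    col_index = {s: j for j, s in enumerate(cm.sample_ids)}
    missing = [s for s in st.sample_ids if s not in col_index]
    if missing:
        raise ValueError(f"sample id {missing[0]!r} in metadata but absent from matrix")
    extra = [s for s in cm.sample_ids if s not in set(st.sample_ids)]
    if extra:
        warnings.warn(f"dropping {len(extra)} matrix column(s) absent from metadata: {extra[:5]}")
        logger.warning("dropping matrix columns absent from metadata: %s", extra)
    order = [col_index[s] for s in st.sample_ids]
    cls = type(cm)
    mat = cls(list(cm.gene_ids), list(st.sample_ids), cm.values[:, order])
    return Dataset(mat, st)
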