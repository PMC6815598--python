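"""Expression-matrix container plus delimited-text I/O.

Datasets are samples-by-genes tables with one class label per sample.
Gene column order in the input file defines gene index order; indices are
0-based internally and 1-based in user-facing reports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, ParseError, ValidationError

_MIN_SAMPLES = 4
_MIN_GENES = 2
_MIN_CLASS_SIZE = 2

_DELIMITERS = {"csv": ",", "tsv": "\t"}


@dataclass
class ExpressionDataset:
    """An M x N expression matrix with per-sample class labels.

    Parameters
    ----------
    matrix : ndarray of shape (M, N)
        Expression level of gene ``j`` in sample ``i`` (arbitrary units).
    gene_ids : list of str
        Unique identifiers, one per column of ``matrix``.
    labels : ndarray of shape (M,)
        Class label per sample; treated as opaque strings.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    labels: np.ndarray
    classes: list[str] = field(init=False)
    class_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise ValidationError("expression matrix must be 2-dimensional")
        m, n = self.matrix.shape
        if m < _MIN_SAMPLES:
            raise ValidationError(f"need at least {_MIN_SAMPLES} samples, got {m}")
        if n < _MIN_GENES:
            raise ValidationError(f"need at least {_MIN_GENES} genes, got {n}")
        if len(self.gene_ids) != n:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n} matrix columns"
            )
        if len(set(self.gene_ids)) != n:
            dupes = [g for g, k in Counter(self.gene_ids).items() if k > 1]
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.labels.shape != (m,):
            raise ValidationError("labels must be one per sample")
        if not np.all(np.isfinite(self.matrix)):
            bad = np.argwhere(~np.isfinite(self.matrix))[0]
            raise ValidationError(
                f"non-finite expression value at sample {bad[0] + 1}, "
                f"gene {self.gene_ids[bad[1]]}"
            )
        counts = Counter(str(y) for y in self.labels)
        self.classes = sorted(counts)
        self.class_counts = {k: counts[k] for k in self.classes}
        if len(self.classes) < 2:
            raise ValidationError("dataset must contain at least 2 classes")
        small = [k for k, v in self.class_counts.items() if v < _MIN_CLASS_SIZE]
        if small:
            raise ValidationError(
                f"every class needs >= {_MIN_CLASS_SIZE} samples; too small: {small}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def label_codes(self) -> np.ndarray:
        """Labels encoded as integers in ``classes`` order."""
        lookup = {k: i for i, k in enumerate(self.classes)}
        return np.array([lookup[str(y)] for y in self.labels], dtype=np.intp)

    def subset(self, gene_indices: Sequence[int]) -> "ExpressionDataset":
        """Restrict to the given gene columns, preserving their relative order."""
        idx = np.asarray(gene_indices, dtype=np.intp)
        if idx.size < _MIN_GENES:
            raise ContractError("subset must keep at least 2 genes")
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_genes):
            raise ContractError("gene index out of range")
        return ExpressionDataset(
            matrix=self.matrix[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            labels=self.labels.copy(),
        )


def load_dataset(
    path: str | Path,
    label_column: str,
    dialect: str = "csv",
    impute_missing: bool = False,
    transpose: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression table into a validated dataset.

    The file must have a header row; every column except ``label_column``
    is taken as a gene, in file order. With ``impute_missing`` each blank
    expression cell is replaced by its gene's mean; the default is to
    reject files with missing values.
    """
    path = Path(path)
    if dialect not in _DELIMITERS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=_DELIMITERS[dialect], float_precision="round_trip")
    if transpose:
        frame = frame.set_index(frame.columns[0]).T.reset_index(drop=True)
    if label_column not in frame.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found in {path.name}"
        )
    labels = frame[label_column].astype(str).to_numpy(dtype=object)
    expr = frame.drop(columns=[label_column])
    gene_ids = [str(c) for c in expr.columns]
    numeric = expr.apply(pd.to_numeric, errors="coerce")

    parseable = numeric.isna() & expr.notna()
    if parseable.to_numpy().any():
        i, j = np.argwhere(parseable.to_numpy())[0]
        raise ParseError(
            f"non-numeric expression value {expr.iat[i, j]!r} at "
            f"sample {i + 1}, gene {gene_ids[j]}"
        )
    if numeric.isna().to_numpy().any():
        if impute_missing:
            numeric = numeric.fillna(numeric.mean())
        else:
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise ParseError(
                f"missing expression value at sample {i + 1}, gene {gene_ids[j]}"
            )
    return ExpressionDataset(
        matrix=numeric.to_numpy(dtype=float), gene_ids=gene_ids, labels=labels
    )


def save_dataset(
    ds: ExpressionDataset,
    path: str | Path,
    label_column: str = "label",
    dialect: str = "csv",
) -> None:
    """Write a dataset back to delimited text (inverse of :func:`load_dataset`)."""
    if dialect not in _DELIMITERS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    if label_column in ds.gene_ids:
        raise ConfigurationError(
            f"label column name {label_column!r} collides with a gene id"
        )
    frame = pd.DataFrame(ds.matrix, columns=ds.gene_ids)
    frame[label_column] = ds.labels
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(path, sep=_DELIMITERS[dialect], index=False, float_format="%.17g")


def write_selection(
    gene_ids: Sequence[str], scores: Sequence[float], path: str | Path
) -> None:
    """Write selected genes as ``gene_id<TAB>fisher_score`` lines with a header."""
    if len(gene_ids) != len(scores):
        raise ContractError(
            f"{len(gene_ids)} gene ids but {len(scores)} scores"
        )
    with open(path, "w") as fh:
        fh.write("gene_id\tfisher_score\n")
        for gid, sc in zip(gene_ids, scores):
            fh.write(f"{gid}\t{sc!r}\n")


def read_selection(path: str | Path) -> tuple[list[str], list[float]]:
    """Read a file written by :func:`write_selection`."""
    gene_ids: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ParseError(f"{path}: missing selection header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated fields")
            gene_ids.append(parts[0])
            try:
                scores.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {parts[1]!r}") from exc
    return gene_ids, scores
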