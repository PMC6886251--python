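"""Reading, writing and preprocessing of staged expression matrices.

The on-disk format is a genes-by-samples table (TSV or CSV) with two header
rows: the first gives sample identifiers, the second — whose first cell is
``#Q`` — gives the integer disease-stage label (CAG-repeat count ``Q``) of
each sample.  Gene labels (disease-related vs non-disease-related) live in a
two-column table ``gene_id,label`` with labels ``1``/``0`` or ``pos``/``neg``.

Preprocessing mirrors the standard pipeline for staged RNA-seq tables:
drop unexpressed genes, keep the high-variance genes, and z-score each
sample column.  Population (1/m) standard deviations are used throughout so
results are deterministic and library-independent.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneLabelSet",
    "read_expression_table",
    "write_expression_table",
    "filter_unexpressed",
    "filter_low_variance",
    "normalize_samples",
    "read_gene_labels",
    "write_gene_labels",
]

#: stages of the Huntington's-disease mouse design this package emulates
DEFAULT_Q_ORDER: tuple[int, ...] = (20, 80, 92, 111, 140, 175)


@dataclass
class ExpressionMatrix:
    """A genes × samples expression grid with per-sample stage labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``.
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Sample identifiers, one per column.
    sample_qs
        Integer stage label (``Q``) per sample.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    sample_qs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.sample_qs = np.asarray(self.sample_qs, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes × samples matrix")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != m or self.sample_qs.shape != (m,):
            raise ValueError("sample ids/stages inconsistent with columns")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id {g!r}")
            seen.add(g)
        if len(np.unique(self.sample_qs)) < 2:
            raise ValueError("need at least two distinct stages Q")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def q_order(self) -> tuple[int, ...]:
        """Distinct stages in ascending numeric order."""
        return tuple(int(q) for q in np.unique(self.sample_qs))

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            self.values[keep],
            [self.gene_ids[i] for i in keep],
            self.sample_ids,
            self.sample_qs,
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            self.values[:, keep],
            self.gene_ids,
            [self.sample_ids[i] for i in keep],
            self.sample_qs[keep],
        )


@dataclass
class GeneLabelSet:
    """Known disease-related (positive) and non-disease-related gene ids."""

    positives: set[str] = field(default_factory=set)
    negatives: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(
                f"genes labeled both positive and negative: {sorted(overlap)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)

    def missing_from(self, x: ExpressionMatrix) -> set[str]:
        """Labeled genes absent from the expression matrix."""
        present = set(x.gene_ids)
        return (self.positives | self.negatives) - present


def _dialect_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in {"tsv", "csv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_expression_table(
    path: str | Path,
    dialect: str | None = None,
    allowed_qs: tuple[int, ...] | None = None,
) -> ExpressionMatrix:
    """Read a genes × samples expression table.

    The first header row carries sample ids (first cell is a corner label
    such as ``gene_id``); the second header row starts with ``#Q`` and
    carries the integer stage of each sample.

    Raises
    ------
    ValueError
        On duplicate gene ids (naming the id), non-numeric cells (with
        row/column coordinates) or, when ``allowed_qs`` is given, stage
        labels outside that set.
    """
    sep = _dialect_sep(path, dialect)
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
        qrow = fh.readline().rstrip("\n").split(sep)
    if not qrow or qrow[0] != "#Q":
        raise ValueError(f"{path}: second header row must start with '#Q'")
    sample_ids = header[1:]
    if len(qrow) - 1 != len(sample_ids):
        raise ValueError(f"{path}: #Q row has {len(qrow) - 1} entries for "
                         f"{len(sample_ids)} samples")
    try:
        sample_qs = np.array([int(q) for q in qrow[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer stage in #Q row: {exc}") from exc
    if allowed_qs is not None:
        bad = sorted(set(sample_qs) - set(allowed_qs))
        if bad:
            raise ValueError(
                f"{path}: unknown stage labels {bad}; allowed: {sorted(allowed_qs)}"
            )

    df = pd.read_csv(path, sep=sep, skiprows=2, header=None, index_col=0,
                     dtype={0: str})
    if df.shape[1] != len(sample_ids):
        raise ValueError(f"{path}: data rows have {df.shape[1]} columns, "
                         f"header has {len(sample_ids)}")
    gene_ids = [str(g) for g in df.index]
    dup = pd.Index(gene_ids).duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene id {gene_ids[int(np.flatnonzero(dup)[0])]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna().to_numpy() & ~df.isna().to_numpy()
    if bad_mask.any():
        r, c = map(int, np.argwhere(bad_mask)[0])
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at gene {gene_ids[r]!r}"
            f" (row {r + 3}), sample {sample_ids[c]!r} (column {c + 2})"
        )
    if numeric.isna().to_numpy().any():
        r, c = map(int, np.argwhere(numeric.isna().to_numpy())[0])
        raise ValueError(f"{path}: missing value at gene {gene_ids[r]!r}, "
                         f"sample {sample_ids[c]!r}")
    return ExpressionMatrix(numeric.to_numpy(float), gene_ids, sample_ids, sample_qs)


def write_expression_table(
    x: ExpressionMatrix, path: str | Path, dialect: str | None = None
) -> None:
    """Write ``x`` in the two-header-row format read back by
    :func:`read_expression_table`."""
    sep = _dialect_sep(path, dialect)
    with Path(path).open("w") as fh:
        fh.write(sep.join(["gene_id", *x.sample_ids]) + "\n")
        fh.write(sep.join(["#Q", *[str(int(q)) for q in x.sample_qs]]) + "\n")
        for gid, row in zip(x.gene_ids, x.values):
            fh.write(sep.join([gid, *(repr(float(v)) for v in row)]) + "\n")


def filter_unexpressed(x: ExpressionMatrix, zero_filter: str = "all") -> ExpressionMatrix:
    """Remove unexpressed genes.

    ``zero_filter="all"`` (default) drops genes that are zero in *every*
    sample; ``"any"`` drops genes with a zero in any sample (destructive for
    sparse RNA-seq, provided for completeness).
    """
    if zero_filter == "all":
        keep = ~np.all(x.values == 0, axis=1)
    elif zero_filter == "any":
        keep = ~np.any(x.values == 0, axis=1)
    else:
        raise ValueError(f"zero_filter must be 'all' or 'any', got {zero_filter!r}")
    if not keep.any():
        raise ValueError("all genes unexpressed")
    if keep.all():
        return x
    return x.subset_genes(keep)


def filter_low_variance(x: ExpressionMatrix, keep: int) -> ExpressionMatrix:
    """Keep the ``keep`` genes with largest across-sample (population)
    variance; ties broken by input order; output preserves input order."""
    if keep <= 0:
        raise ValueError(f"keep must be positive, got {keep}")
    if keep > x.n_genes:
        raise ValueError(f"keep={keep} exceeds {x.n_genes} genes")
    if keep == x.n_genes:
        return x
    var = x.values.var(axis=1)
    top = np.sort(np.argsort(-var, kind="stable")[:keep])
    return x.subset_genes(top)


def normalize_samples(x: ExpressionMatrix, method: str = "zscore") -> ExpressionMatrix:
    """Normalize each sample column.

    ``zscore`` (default) centres each column and divides by its population
    standard deviation; ``quantile`` replaces each column by the mean sorted
    profile (classical quantile normalization); ``none`` is the identity.
    """
    if method == "none":
        return x
    if method == "zscore":
        mu = x.values.mean(axis=0)
        sd = x.values.std(axis=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(
                f"sample {x.sample_ids[int(flat[0])]!r} has zero variance"
            )
        vals = (x.values - mu) / sd
    elif method == "quantile":
        order = np.argsort(x.values, axis=0, kind="stable")
        ranks = np.empty_like(order)
        m = x.n_samples
        np.put_along_axis(ranks, order, np.arange(x.n_genes)[:, None].repeat(m, 1), axis=0)
        mean_sorted = np.sort(x.values, axis=0).mean(axis=1)
        vals = mean_sorted[ranks]
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return ExpressionMatrix(vals, x.gene_ids, x.sample_ids, x.sample_qs)


_POS_LABELS = {"1", "pos", "positive", "disease", "disease-related"}
_NEG_LABELS = {"0", "neg", "negative", "non-disease", "non-disease-related"}


def read_gene_labels(path: str | Path, allow_empty: bool = False) -> GeneLabelSet:
    """Read a two-column ``gene_id,label`` table (``1/0`` or ``pos/neg``).

    A gene listed twice with conflicting labels is an error; listed twice
    consistently is tolerated.  An empty positive (or negative) class raises
    unless ``allow_empty`` is set, in which case it warns.
    """
    pos: set[str] = set()
    neg: set[str] = set()
    path = Path(path)
    with path.open() as fh:
        sep = "," if path.suffix == ".csv" or "," in path.read_text()[:200] else "\t"
        reader = csv.reader(fh, delimiter=sep)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene_id{sep}label")
            gid, label = row[0].strip(), row[1].strip().lower()
            if lineno == 1 and label in {"label", "class"}:
                continue  # header row
            if label in _POS_LABELS:
                target, other = pos, neg
            elif label in _NEG_LABELS:
                target, other = neg, pos
            else:
                raise ValueError(f"{path}:{lineno}: unknown label {row[1]!r}")
            if gid in other:
                raise ValueError(f"gene {gid!r} listed with conflicting labels")
            target.add(gid)
    if not pos or not neg:
        msg = "gene label file has an empty class"
        if not allow_empty:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return GeneLabelSet(pos, neg)


def write_gene_labels(labels: GeneLabelSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id,label\n")
        for gid in sorted(labels.positives):
            fh.write(f"{gid},1\n")
        for gid in sorted(labels.negatives):
            fh.write(f"{gid},0\n")
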