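"""Reading, validation and CSV export of count matrices and sample metadata.

The two inputs of the pipeline are plain delimited text files:

* a count matrix with genes/miRNAs as rows and samples as columns; the
  first column holds gene identifiers and the header row holds sample
  identifiers;
* a metadata table with samples as rows and experimental variables as
  columns, containing a two-level group factor (e.g. disease vs control).

All validation failures raise :class:`~ecnorm.errors.ValidationError` with a
message that names the offending cell/row/column; nothing is silently
coerced (except the documented ``strict=False`` float-rounding mode for
upstream estimators that emit fractional expected counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CountMatrix",
    "SampleMetadata",
    "read_count_matrix",
    "read_metadata",
    "write_count_matrix",
    "write_results_csv",
]


@dataclass(frozen=True)
class CountMatrix:
    """Integer expression matrix (genes x samples) with identifiers.

    Invariants (enforced at construction): counts are non-negative
    integers, identifiers are unique, and the matrix has at least
    2 genes and 2 samples.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_genes, n_samples), integer dtype
    gene_label: str = "gene_id"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("count matrix must be two-dimensional")
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must have an integer dtype")
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "counts", counts)
        g, s = counts.shape
        if len(self.gene_ids) != g or len(self.sample_ids) != s:
            raise ValidationError("identifier lengths do not match matrix shape")
        if g < 2 or s < 2:
            raise ValidationError(
                f"count matrix must have at least 2 genes and 2 samples, got {g}x{s}"
            )
        if len(set(self.gene_ids)) != g:
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene identifier: {dup!r}")
        if len(set(self.sample_ids)) != s:
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.gene_ids),
                          columns=list(self.sample_ids))
        df.index.name = self.gene_label
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strict: bool = True) -> "CountMatrix":
        """Build from a genes-x-samples DataFrame, validating every cell."""
        values = _validate_cells(df, strict=strict)
        return cls(
            gene_ids=tuple(str(g) for g in df.index),
            sample_ids=tuple(str(c) for c in df.columns),
            counts=values,
            gene_label=str(df.index.name or "gene_id"),
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample experimental variables with a two-level group factor.

    ``reference`` is the group level coded 0 in the design; log2 fold
    changes are reported for the other level relative to it.  Extra
    metadata columns are carried along untouched in ``table``.
    """

    sample_ids: tuple[str, ...]
    group: tuple[str, ...]
    reference: str
    table: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "group", tuple(str(g) for g in self.group))
        if len(self.sample_ids) != len(self.group):
            raise ValidationError("group labels do not match sample identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(
                f"duplicate sample identifier: {_first_duplicate(self.sample_ids)!r}"
            )
        levels = sorted(set(self.group))
        if len(levels) != 2:
            raise ValidationError(
                f"group must have exactly 2 levels, got {len(levels)}: {levels}"
            )
        if self.reference not in levels:
            raise ValidationError(
                f"reference level {self.reference!r} not among group levels {levels}"
            )
        for lev in levels:
            n = sum(g == lev for g in self.group)
            if n < 2:
                raise ValidationError(
                    f"group level {lev!r} has {n} sample(s); at least 2 required"
                )

    @property
    def levels(self) -> tuple[str, str]:
        """(reference, non-reference) group levels."""
        other = next(l for l in sorted(set(self.group)) if l != self.reference)
        return (self.reference, other)

    @property
    def indicator(self) -> np.ndarray:
        """0/1 design column: 1 for the non-reference group."""
        return np.asarray([0 if g == self.reference else 1 for g in self.group],
                          dtype=float)

    def aligned_to(self, sample_ids) -> "SampleMetadata":
        """Reorder to ``sample_ids``; error on any set mismatch."""
        wanted = [str(s) for s in sample_ids]
        have = set(self.sample_ids)
        missing = sorted(set(wanted) - have)
        extra = sorted(have - set(wanted))
        if missing or extra:
            raise ValidationError(
                "metadata samples do not match count-matrix samples; "
                f"missing from metadata: {missing}; only in metadata: {extra}"
            )
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [order[s] for s in wanted]
        table = self.table.iloc[idx] if self.table is not None else None
        return SampleMetadata(
            sample_ids=tuple(wanted),
            group=tuple(self.group[i] for i in idx),
            reference=self.reference,
            table=table,
        )

    def with_reference(self, reference: str) -> "SampleMetadata":
        return replace(self, reference=str(reference))


def _first_duplicate(items) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""  # pragma: no cover


def _sniff_delimiter(path: Path, delimiter: str) -> str:
    if delimiter == "comma":
        return ","
    if delimiter == "tab":
        return "\t"
    if delimiter != "auto":
        raise ValidationError(f"unknown delimiter option {delimiter!r}")
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".tab"}:
        return "\t"
    if suffix == ".csv":
        return ","
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    return ","


def _validate_cells(df: pd.DataFrame, strict: bool) -> np.ndarray:
    """Check every cell is a non-negative integer; return int64 array."""
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError("empty count matrix")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = series.index[int(np.flatnonzero(bad.to_numpy())[0])]
            raise ValidationError(
                f"non-numeric cell {series[row]!r} at gene {row!r}, sample {col!r}"
            )
        arr = numeric.to_numpy(dtype=float)
        frac = arr != np.floor(arr)
        if frac.any():
            i = int(np.flatnonzero(frac)[0])
            if strict:
                raise ValidationError(
                    f"non-integer count {arr[i]!r} at gene {series.index[i]!r}, "
                    f"sample {col!r} (use strict=False to round)"
                )
            warnings.warn(
                f"rounding non-integer counts in sample {col!r} "
                "(strict=False)", UserWarning, stacklevel=3,
            )
            arr = np.rint(arr)
        values[:, j] = arr.astype(np.int64)
    return values


def read_count_matrix(path, delimiter: str = "auto",
                      strict: bool = True) -> CountMatrix:
    """Read and validate a genes-x-samples count matrix from CSV/TSV.

    Parameters
    ----------
    path
        Delimited text file; first column = gene identifiers, header row =
        sample identifiers.
    delimiter
        ``"auto"`` (sniff from extension then content), ``"comma"`` or
        ``"tab"``.
    strict
        When False, fractional counts (e.g. RSEM expected counts) are
        rounded to the nearest integer with a warning instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"count matrix file not found: {path}")
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    return CountMatrix.from_frame(df, strict=strict)


def write_count_matrix(cm: CountMatrix, path, delimiter: str = "comma") -> None:
    """Write a count matrix back to CSV/TSV (inverse of read_count_matrix)."""
    sep = "\t" if delimiter == "tab" else ","
    cm.to_frame().to_csv(path, sep=sep)


def read_metadata(path, group_col: str = "group", delimiter: str = "auto",
                  reference: str | None = None) -> SampleMetadata:
    """Read and validate the sample metadata table.

    The first column holds sample identifiers; ``group_col`` names the
    two-level factor (defaults to ``"group"``).  ``reference`` picks the
    level coded 0 in the design; by default the lexicographically first
    level is used.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"metadata file not found: {path}")
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    if group_col not in df.columns:
        raise ValidationError(
            f"metadata is missing the group column {group_col!r}; "
            f"available columns: {list(df.columns)}"
        )
    group = [str(g) for g in df[group_col]]
    ref = str(reference) if reference is not None else min(set(group))
    return SampleMetadata(
        sample_ids=tuple(str(s) for s in df.index),
        group=tuple(group),
        reference=ref,
        table=df,
    )


def write_results_csv(table: pd.DataFrame, path) -> None:
    """Export a result table as RFC-4180-style CSV with a header row.

    Zero data rows are allowed; zero columns are not.  Floats are written
    at full precision (>= 6 significant digits).
    """
    if table.shape[1] == 0:
        raise ValidationError("result table has no columns")
    table.to_csv(path, index=False)
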