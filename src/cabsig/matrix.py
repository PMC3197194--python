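"""Core data containers and plain-text I/O.

The toolkit operates on a single in-memory representation: an
:class:`ExpressionMatrix` holding already log2-normalized expression values
with genes on rows and samples on columns, plus optional per-sample
metadata (group label, pairing ID, timepoint).  Values are never
re-normalized here; upstream summarization (e.g. RMA) is assumed done.

Files are ordinary TSV/CSV: header row of sample IDs, first column of gene
IDs.  Gene signatures are one-ID-per-line text files; ``#`` starts a
comment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    MatrixFormatError,
    SignatureTooSmallError,
    UnknownIDError,
)

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "SampleGroup",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_signature",
    "read_sample_metadata",
]

_METADATA_COLUMNS = ("group", "pair_id", "timepoint")


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise MatrixFormatError(f"duplicate {axis} ID: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    Parameters
    ----------
    data
        DataFrame with gene IDs as index and sample IDs as columns; all
        values finite floats.
    metadata
        Optional per-sample table indexed by sample ID with any of the
        columns ``group``, ``pair_id``, ``timepoint``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        _check_unique(list(self.data.index), "gene")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise MatrixFormatError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixFormatError(
                "non-finite value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        self.data = self.data.astype(float, copy=False)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if self.metadata is not None:
            missing = [s for s in self.sample_ids if s not in self.metadata.index]
            if missing:
                raise MatrixFormatError(
                    f"metadata missing for samples: {missing[:5]}"
                )

    # -- basic views ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"

    # -- subsetting ----------------------------------------------------
    def subset(
        self,
        genes: "GeneSignature | Iterable[str] | None" = None,
        samples: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted (and reordered) to the request.

        Ordering follows the *request*, not this matrix.  Unknown IDs raise
        :class:`UnknownIDError` naming the offender.
        """
        gene_list = (
            list(genes.gene_ids)
            if isinstance(genes, GeneSignature)
            else (None if genes is None else list(genes))
        )
        sample_list = None if samples is None else list(samples)
        if gene_list is not None:
            known = set(self.data.index)
            for g in gene_list:
                if g not in known:
                    raise UnknownIDError(f"unknown gene ID: {g!r}")
        if sample_list is not None:
            known = set(self.data.columns)
            for s in sample_list:
                if s not in known:
                    raise UnknownIDError(f"unknown sample ID: {s!r}")
        out = self.data
        if gene_list is not None:
            out = out.loc[gene_list]
        if sample_list is not None:
            out = out[sample_list]
        meta = self.metadata
        if meta is not None and sample_list is not None:
            meta = meta.loc[sample_list]
        return ExpressionMatrix(out.copy(), None if meta is None else meta.copy())


@dataclass(frozen=True)
class GeneSignature:
    """Ordered list of signature gene IDs (the 'M' genes scored jointly)."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SignatureTooSmallError(f"signature {self.name!r} has duplicate IDs")
        if len(self.gene_ids) < 2:
            raise SignatureTooSmallError(
                f"signature {self.name!r} needs >= 2 genes, got {len(self.gene_ids)}"
            )

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_ids(cls, ids: Iterable[str], name: str = "signature") -> "GeneSignature":
        """Build a signature, de-duplicating with a warning (first occurrence wins)."""
        out: list[str] = []
        seen: set[str] = set()
        dups: list[str] = []
        for i in ids:
            if i in seen:
                dups.append(i)
            else:
                seen.add(i)
                out.append(i)
        if dups:
            warnings.warn(f"duplicated signature IDs dropped: {dups}", stacklevel=2)
        return cls(name, tuple(out))


@dataclass(frozen=True)
class SampleGroup:
    """A labeled subset of a matrix's samples (e.g. the 'high' cluster)."""

    label: str
    sample_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise DegenerateInputError(f"group {self.label!r} is empty")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MatrixFormatError(f"group {self.label!r} repeats a sample ID")

    def __len__(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_expression_matrix(
    path: str | Path,
    dialect: str | None = None,
    missing: str = "error",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Parameters
    ----------
    path
        TSV/CSV file: header row of sample IDs, first column gene IDs.
    dialect
        ``"tsv"`` or ``"csv"``; inferred from the extension when ``None``.
    missing
        ``"error"`` (default) rejects any missing cell; ``"drop_genes"``
        silently removes genes containing missing values.
    transpose
        Set when the file has samples on rows.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "sample" if not transpose else "gene")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.hasnans or any(pd.isna(c) for c in df.columns):
        raise MatrixFormatError(f"{path}: empty gene or sample ID")
    _check_unique(list(df.index.astype(str)), "gene")
    _check_unique(list(df.columns.astype(str)), "sample")
    try:
        numeric = df.astype(float)  # exact parse; to_numeric's fast path is lossy
    except (ValueError, TypeError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"{path}: non-numeric value {df.iat[gi, si]!r} at gene "
            f"{df.index[gi]!r}, sample {df.columns[si]!r}"
        ) from None
    if transpose:
        numeric = numeric.T
    if numeric.isna().to_numpy().any():
        if missing == "drop_genes":
            numeric = numeric.dropna(axis=0)
        else:
            gi, si = np.argwhere(numeric.isna().to_numpy())[0]
            raise MatrixFormatError(
                f"{path}: missing value at gene {numeric.index[gi]!r}, "
                f"sample {numeric.columns[si]!r} (use missing='drop_genes' to drop)"
            )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: str | None = None
) -> None:
    """Write the matrix back to TSV/CSV at full float precision (round-trip safe)."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    matrix.data.to_csv(path, sep=sep, index_label="gene_id", float_format=lambda v: repr(float(v)))


def read_gene_signature(
    path: str | Path,
    expression: ExpressionMatrix | None = None,
    name: str | None = None,
) -> tuple[GeneSignature, list[str]]:
    """Read a one-ID-per-line signature file.

    When ``expression`` is given the signature is restricted to IDs present
    in the matrix; the second return value lists the absent IDs (never
    silently dropped).  Fewer than two usable IDs raises
    :class:`SignatureTooSmallError`.
    """
    path = Path(path)
    ids: list[str] = []
    for line in path.read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            ids.append(token)
    if not ids:
        raise SignatureTooSmallError(f"{path}: no gene IDs found")
    sig = GeneSignature.from_ids(ids, name=name or path.stem)
    absent: list[str] = []
    if expression is not None:
        known = set(expression.gene_ids)
        present = [g for g in sig.gene_ids if g in known]
        absent = [g for g in sig.gene_ids if g not in known]
        if len(present) < 2:
            raise SignatureTooSmallError(
                f"{path}: only {len(present)} signature IDs present in the matrix"
            )
        sig = GeneSignature(sig.name, tuple(present))
    return sig, absent


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV (columns: sample_id, group, pair_id, timepoint)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise MatrixFormatError(f"{path}: metadata needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MatrixFormatError(f"{path}: duplicate sample_id {dup!r}")
    df = df.set_index("sample_id")
    keep = [c for c in df.columns if c in _METADATA_COLUMNS]
    return df[keep]
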