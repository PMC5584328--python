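"""Expression-matrix containers and I/O.

Every stage of the pipeline operates on a single canonical representation:
a genes-in-rows, samples-in-columns :class:`pandas.DataFrame` of non-negative
abundances, wrapped in :class:`ExpressionMatrix` together with the declared
value kind (raw ``counts`` or length/depth-scaled ``rpkm``/``fpkm``) and an
optional sample -> condition map.

Matrices are exchanged as plain UTF-8 TSV files: header row of sample IDs,
first column of gene IDs, one gene per row, no missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

VALID_KINDS = ("counts", "rpkm", "fpkm")

__all__ = [
    "ExpressionMatrix",
    "LogMatrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_lengths",
    "read_condition_map",
    "read_reference_list",
    "compute_rpkm",
    "log_transform",
]


class ExpressionDataError(ValueError):
    """Raised when an input matrix or table violates its contract."""


def _find_duplicates(labels) -> list:
    seen: set = set()
    dups = []
    for x in labels:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """A gene x sample abundance matrix with declared value kind.

    Parameters
    ----------
    data:
        DataFrame with gene IDs as the index and sample IDs as columns.
        All entries must be finite and >= 0.
    kind:
        One of ``"counts"``, ``"rpkm"``, ``"fpkm"``. ``fpkm`` is treated
        identically to ``rpkm`` downstream; the kind is kept for provenance.
    conditions:
        Optional map ``sample_id -> condition label`` covering a subset or
        all of the samples.
    """

    data: pd.DataFrame
    kind: str
    conditions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ExpressionDataError(
                f"kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )
        dup_g = _find_duplicates(self.data.index)
        if dup_g:
            raise ExpressionDataError(f"duplicate gene ID(s): {dup_g}")
        dup_s = _find_duplicates(self.data.columns)
        if dup_s:
            raise ExpressionDataError(f"duplicate sample ID(s): {dup_s}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ExpressionDataError("expression values must be numeric")
        if values.size:
            bad = ~np.isfinite(values) | (values < 0)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise ExpressionDataError(
                    "expression values must be finite and non-negative; "
                    f"offending cell at gene {self.data.index[g]!r}, "
                    f"sample {self.data.columns[s]!r}"
                )
        if self.conditions is not None:
            unknown = set(self.conditions) - set(self.data.columns)
            if unknown:
                raise ExpressionDataError(
                    f"condition map names unknown sample(s): {sorted(unknown)}"
                )

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def with_kind(self, kind: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data, kind, self.conditions)


@dataclass
class LogMatrix:
    """Entry-wise ``log2(value + pseudocount)`` view of an expression matrix."""

    data: pd.DataFrame
    pseudocount: float = 1.0
    source_kind: str = "counts"


def read_expression_tsv(
    path: str | Path,
    kind: str,
    conditions: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes in rows, samples in columns).

    The first row holds sample IDs, the first column gene IDs. Duplicated
    IDs, negative values and non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup_g = _find_duplicates(df.index)
    if dup_g:
        raise ExpressionDataError(f"{path}: duplicate gene ID(s): {dup_g}")
    dup_s = _find_duplicates(df.columns)
    if dup_s:
        raise ExpressionDataError(f"{path}: duplicate sample ID(s): {dup_s}")
    try:
        numeric = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ExpressionDataError(
                        f"{path}: non-numeric cell {cell!r} at gene "
                        f"{gene!r}, sample {sample!r}"
                    ) from None
        raise
    return ExpressionMatrix(
        numeric, kind, dict(conditions) if conditions is not None else None
    )


def write_expression_tsv(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    """Write a matrix back to TSV in the same layout ``read_expression_tsv`` expects."""
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column ``gene_id <TAB> length_nt`` table.

    A header line is auto-detected by a non-numeric second field. Lengths
    must be positive integers.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[1] != 2:
        raise ExpressionDataError(
            f"{path}: expected two columns (gene_id, length_nt), got {raw.shape[1]}"
        )
    first = raw.iloc[0, 1]
    try:
        float(first)
    except (TypeError, ValueError):
        raw = raw.iloc[1:]
    lengths = pd.Series(
        raw.iloc[:, 1].astype(float).to_numpy(), index=raw.iloc[:, 0].to_numpy()
    )
    dup = _find_duplicates(lengths.index)
    if dup:
        raise ExpressionDataError(f"{path}: duplicate gene ID(s) in length table: {dup}")
    bad = lengths[(lengths <= 0) | (lengths != lengths.round())]
    if len(bad):
        raise ExpressionDataError(
            f"{path}: lengths must be positive integers; offending gene "
            f"{bad.index[0]!r} has length {bad.iloc[0]}"
        )
    return lengths.astype(int)


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Read a ``sample_id <TAB> condition`` map (header auto-detected)."""
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[1] != 2:
        raise ExpressionDataError(
            f"{path}: expected two columns (sample_id, condition), got {raw.shape[1]}"
        )
    if list(raw.iloc[0]) == ["sample_id", "condition"]:
        raw = raw.iloc[1:]
    return dict(zip(raw.iloc[:, 0], raw.iloc[:, 1]))


def read_reference_list(path: str | Path) -> list[str]:
    """Read a plain-text reference-gene list: one ID per line, ``#`` comments."""
    ids = []
    for line in Path(path).read_text().splitlines():
        stripped = line.split("#", 1)[0].strip()
        if stripped:
            ids.append(stripped)
    return ids


def compute_rpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm[g, s] = counts[g, s] * 1e9 / (library_size[s] * length[g])``
    with ``library_size[s]`` the column sum of the count matrix.
    """
    if counts.kind != "counts":
        raise ExpressionDataError(
            f"compute_rpkm expects a counts matrix, got kind={counts.kind!r}"
        )
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ExpressionDataError(f"missing transcript length for gene(s): {missing[:5]}")
    lib = counts.data.sum(axis=0)
    zero_lib = lib[lib <= 0]
    if len(zero_lib):
        raise ExpressionDataError(
            f"zero library size for sample(s): {list(zero_lib.index)}"
        )
    glen = lengths.reindex(counts.gene_ids).to_numpy(dtype=float)
    values = counts.data.to_numpy(dtype=float) * 1e9
    values /= lib.to_numpy(dtype=float)[None, :]
    values /= glen[:, None]
    rpkm = pd.DataFrame(values, index=counts.data.index, columns=counts.data.columns)
    return ExpressionMatrix(rpkm, "rpkm", counts.conditions)


def log_transform(
    matrix: ExpressionMatrix | pd.DataFrame, pseudocount: float = 1.0
) -> LogMatrix:
    """Entry-wise ``log2(value + pseudocount)``; pseudocount must be > 0."""
    if not (pseudocount > 0 and math.isfinite(pseudocount)):
        raise ExpressionDataError(f"pseudocount must be positive, got {pseudocount}")
    if isinstance(matrix, ExpressionMatrix):
        df, kind = matrix.data, matrix.kind
    else:
        df, kind = matrix, "counts"
    return LogMatrix(np.log2(df + pseudocount), pseudocount, kind)
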