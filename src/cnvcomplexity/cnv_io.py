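"""Readers and writers for InferCNV-style CNV matrices and gene position tables.

Matrix files are plain text: first row holds cell names (quoted or
unquoted), the first column of every following row holds the gene name and
the remaining fields hold one value per cell.  Discrete matrices carry the
six HMM copy-number states ``{1..6}`` with 3 = copy-neutral; continuous
matrices carry denoised expression-ratio values with neutral around 1.0.

Gene position files are headerless 4-column TSV: gene, chromosome, start,
end, with 1-based inclusive coordinates (the InferCNV gene ordering file
convention).  Chromosomes are kept in file order; genes are sorted by start
within each chromosome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CnvParseError",
    "CnvValidationError",
    "GenePosition",
    "DiscreteCnvMatrix",
    "ContinuousCnvMatrix",
    "read_cnv_matrix",
    "write_cnv_matrix",
    "read_gene_positions",
]

#: InferCNV "multiplier" dialect for the 6 HMM states (state 3 = neutral).
MULTIPLIER_BY_STATE = {1: 0.0, 2: 0.5, 3: 1.0, 4: 1.5, 5: 2.0, 6: 3.0}
STATE_BY_MULTIPLIER = {v: k for k, v in MULTIPLIER_BY_STATE.items()}

NEUTRAL_STATE = 3
VALID_STATES = frozenset(range(1, 7))


class CnvParseError(ValueError):
    """Raised when a matrix or position file cannot be parsed."""


class CnvValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclass(frozen=True)
class GenePosition:
    """One row of a gene ordering table (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CnvValidationError(
                f"gene {self.gene_id!r}: start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise CnvValidationError(
                f"gene {self.gene_id!r}: end ({self.end}) < start ({self.start})"
            )


def _check_ids(gene_ids: Sequence[str], cell_ids: Sequence[str], data: np.ndarray) -> None:
    if data.ndim != 2:
        raise CnvValidationError(f"matrix must be 2-D, got ndim={data.ndim}")
    if data.shape != (len(gene_ids), len(cell_ids)):
        raise CnvValidationError(
            f"shape {data.shape} does not match {len(gene_ids)} genes x "
            f"{len(cell_ids)} cells"
        )
    if len(gene_ids) == 0 or len(cell_ids) == 0:
        raise CnvValidationError("matrix must have at least one gene and one cell")
    if len(set(gene_ids)) != len(gene_ids):
        raise CnvValidationError("duplicate gene ids")
    if len(set(cell_ids)) != len(cell_ids):
        raise CnvValidationError("duplicate cell ids")


@dataclass
class DiscreteCnvMatrix:
    """Genes x cells integer copy-number states in ``{1..6}``, neutral = 3."""

    gene_ids: list[str]
    cell_ids: list[str]
    states: np.ndarray
    neutral_state: int = NEUTRAL_STATE

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if not np.issubdtype(self.states.dtype, np.integer):
            as_int = self.states.astype(np.int64, copy=True)
            if not np.array_equal(as_int, self.states):
                raise CnvValidationError("discrete states must be integers")
            self.states = as_int
        _check_ids(self.gene_ids, self.cell_ids, self.states)
        bad = (self.states < 1) | (self.states > 6)
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise CnvValidationError(
                f"state {self.states[g, c]} out of range {{1..6}} at gene "
                f"{self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ContinuousCnvMatrix:
    """Genes x cells real denoised CNV values, copy-neutral around 1.0."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_ids(self.gene_ids, self.cell_ids, self.values)
        if not np.isfinite(self.values).all():
            raise CnvValidationError("continuous matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


CnvMatrix = Union[DiscreteCnvMatrix, ContinuousCnvMatrix]


def _tokenize(line: str) -> list[str]:
    """Split a whitespace/tab-delimited line honouring double quotes."""
    # csv cannot split on "any run of whitespace": normalise tabs to spaces,
    # let skipinitialspace collapse runs, drop empty fields.
    parts = next(csv.reader([line.replace("\t", " ")], delimiter=" ", skipinitialspace=True))
    return [p for p in parts if p != ""]


def read_cnv_matrix(
    path: Union[str, Path],
    kind: Literal["discrete", "continuous"],
    *,
    dialect: Literal["state", "multiplier"] = "state",
) -> CnvMatrix:
    """Read a genes x cells CNV matrix from InferCNV-style text.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited file; first row = cell names (quoted or
        unquoted), first column = gene names.
    kind
        ``"discrete"`` validates six integer HMM states; ``"continuous"``
        accepts any finite real values.
    dialect
        For discrete matrices only: ``"state"`` expects values in ``{1..6}``;
        ``"multiplier"`` maps the alternative InferCNV encoding
        ``{0, 0.5, 1, 1.5, 2, 3}`` onto states ``{1..6}``.
    """
    if kind not in ("discrete", "continuous"):
        raise ValueError(f"kind must be 'discrete' or 'continuous', got {kind!r}")
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise CnvParseError(f"{path}: empty file")

    cell_ids = _tokenize(lines[0])
    if not cell_ids:
        raise CnvParseError(f"{path}: line 1: malformed header (no cell names)")
    n_cells = len(cell_ids)

    gene_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = _tokenize(ln)
        if len(fields) != n_cells + 1:
            raise CnvParseError(
                f"{path}: line {lineno}: expected {n_cells + 1} fields "
                f"(gene + {n_cells} cells), got {len(fields)}"
            )
        gene_ids.append(fields[0])
        rows.append(fields[1:])
    if not gene_ids:
        raise CnvParseError(f"{path}: no data rows")

    try:
        values = np.array(rows, dtype=float)
    except ValueError as exc:
        raise CnvParseError(f"{path}: non-numeric matrix entry: {exc}") from exc

    if kind == "continuous":
        return ContinuousCnvMatrix(gene_ids, cell_ids, values)

    if dialect == "multiplier":
        states = np.full(values.shape, -1, dtype=np.int64)
        for mult, state in STATE_BY_MULTIPLIER.items():
            states[values == mult] = state
        bad = states < 0
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise CnvValidationError(
                f"{path}: value {values[g, c]} is not a valid CNV multiplier "
                f"at gene {gene_ids[g]!r}, cell {cell_ids[c]!r}"
            )
        return DiscreteCnvMatrix(gene_ids, cell_ids, states)

    rounded = np.rint(values)
    nonint = values != rounded
    if nonint.any():
        g, c = np.argwhere(nonint)[0]
        raise CnvValidationError(
            f"{path}: non-integer discrete state {values[g, c]} at gene "
            f"{gene_ids[g]!r}, cell {cell_ids[c]!r}"
        )
    bad = (rounded < 1) | (rounded > 6)
    if bad.any():
        g, c = np.argwhere(bad)[0]
        raise CnvValidationError(
            f"{path}: discrete state {int(rounded[g, c])} out of range {{1..6}} "
            f"at gene {gene_ids[g]!r}, cell {cell_ids[c]!r}"
        )
    return DiscreteCnvMatrix(gene_ids, cell_ids, rounded.astype(np.int64))


def write_cnv_matrix(matrix: CnvMatrix, path: Union[str, Path]) -> Path:
    """Write a CNV matrix as tab-delimited text with unquoted names.

    Round-trips discrete matrices bit-exactly and continuous matrices to
    full ``repr`` precision (well within 1e-9).
    """
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise CnvValidationError("refusing to write a degenerate (empty) matrix")
    path = Path(path)
    data = matrix.states if isinstance(matrix, DiscreteCnvMatrix) else matrix.values
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.cell_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, data):
            fh.write(gene + "\t" + "\t".join(repr(v) if isinstance(v, float) else str(v) for v in row.tolist()) + "\n")
    return path


def read_gene_positions(path: Union[str, Path]) -> list[GenePosition]:
    """Read a headerless gene/chrom/start/end table in genomic order.

    Chromosomes keep their order of first appearance in the file; within a
    chromosome genes are sorted by ascending start coordinate.
    """
    path = Path(path)
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["gene_id", "chrom", "start", "end"],
            dtype={"gene_id": str, "chrom": str},
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CnvParseError(f"{path}: {exc}") from exc
    if table.shape[1] != 4:
        raise CnvParseError(f"{path}: expected 4 tab-delimited columns")
    for col in ("start", "end"):
        if not np.issubdtype(table[col].dtype, np.integer):
            raise CnvParseError(f"{path}: non-integer coordinates in column {col!r}")
    dups = table["gene_id"][table["gene_id"].duplicated()]
    if len(dups):
        raise CnvValidationError(f"{path}: duplicate gene id {dups.iloc[0]!r}")

    chrom_rank = {c: i for i, c in enumerate(table["chrom"].drop_duplicates())}
    table = table.assign(_rank=table["chrom"].map(chrom_rank))
    table = table.sort_values(["_rank", "start"], kind="stable")
    return [
        GenePosition(row.gene_id, row.chrom, int(row.start), int(row.end))
        for row in table.itertuples(index=False)
    ]
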