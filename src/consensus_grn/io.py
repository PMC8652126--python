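"""Expression-matrix and edge-table I/O.

The pipeline's sole input is a gene-expression matrix stored as CSV/TSV with
genes in rows and conditions (samples, experiments) in columns; the first
column holds gene identifiers and the header row holds condition identifiers.
Outputs are per-edge tables (one row per unordered gene pair) written as CSV,
loadable in Cytoscape as edge-attribute tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateGeneError,
    DimensionError,
    ValidationError,
)

MIN_CONDITIONS = 4  # t with n-2 df needs n > 2; the bootstrap needs variation

EDGE_TABLE_COLUMNS = ["gene_a", "gene_b", "score", "t", "p", "fdr"]

VALID_METHODS = ("correlation", "pcr", "pls", "ridge")


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x conditions expression matrix.

    Attributes
    ----------
    gene_ids
        Ordered, unique gene identifiers (length p).
    condition_ids
        Ordered, unique condition identifiers (length n).
    values
        ``(p, n)`` float array of finite expression values.
    standardized
        True once every gene row has mean 0 and sample sd 1 (n-1 denominator).
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    @property
    def p(self) -> int:
        """Number of genes."""
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        """Number of conditions."""
        return len(self.condition_ids)

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise DimensionError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if p != len(self.gene_ids) or n != len(self.condition_ids):
            raise DimensionError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.condition_ids)} condition ids"
            )
        dup_genes = _duplicates(self.gene_ids)
        if dup_genes:
            raise ValidationError(f"duplicate gene id(s): {', '.join(dup_genes)}")
        dup_conds = _duplicates(self.condition_ids)
        if dup_conds:
            raise ValidationError(f"duplicate condition id(s): {', '.join(dup_conds)}")
        if n < MIN_CONDITIONS:
            raise DimensionError(
                f"need at least {MIN_CONDITIONS} conditions, got {n}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value for gene '{self.gene_ids[bad[0]]}' "
                f"at condition '{self.condition_ids[bad[1]]}'"
            )
        if self.standardized:
            means = self.values.mean(axis=1)
            sds = self.values.std(axis=1, ddof=1)
            if np.any(np.abs(means) > 1e-10) or np.any(np.abs(sds - 1) > 1e-8):
                raise ValidationError(
                    "matrix flagged standardized but rows are not mean-0/sd-1"
                )

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


def _infer_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_expression_matrix(
    path: str | Path, delimiter: str | None = None
) -> ExpressionMatrix:
    """Read a genes-by-conditions CSV/TSV into an :class:`ExpressionMatrix`.

    The first row must be a header of condition ids, the first column gene
    ids, every remaining cell numeric. Row and column order are preserved.

    Raises
    ------
    ValidationError
        On duplicate identifiers or any empty/non-numeric cell (the message
        names the gene and condition of the first offending cell).
    DimensionError
        If fewer than 4 condition columns are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g) for g in raw.index]
    condition_ids = [str(c) for c in raw.columns]

    dup = _duplicates(gene_ids)
    if dup:
        raise ValidationError(f"duplicate gene id(s) in {path.name}: {', '.join(dup)}")
    dup = _duplicates(condition_ids)
    if dup:
        raise ValidationError(
            f"duplicate condition id(s) in {path.name}: {', '.join(dup)}"
        )
    if len(condition_ids) < MIN_CONDITIONS:
        raise DimensionError(
            f"{path.name}: need at least {MIN_CONDITIONS} conditions, "
            f"got {len(condition_ids)}"
        )

    try:
        # numpy's string-to-float conversion is correctly rounded, so a
        # write -> read round trip is bit-exact
        values = raw.to_numpy(dtype=str).astype(np.float64)
    except ValueError:
        numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
        bad = np.argwhere(numeric.isna().to_numpy())
        if not bad.size:
            raise ValidationError(
                f"{path.name}: non-numeric cell encountered"
            ) from None
        r, c = bad[0]
        cell = raw.iat[r, c]
        desc = "empty cell" if cell.strip() == "" else f"non-numeric cell '{cell}'"
        raise ValidationError(
            f"{path.name}: {desc} for gene '{gene_ids[r]}' "
            f"at condition '{condition_ids[c]}'"
        ) from None
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"{path.name}: non-finite value for gene '{gene_ids[r]}' "
            f"at condition '{condition_ids[c]}'"
        )
    return ExpressionMatrix(gene_ids, condition_ids, values, standardized=False)


def constant_genes(x: ExpressionMatrix, tol: float = 0.0) -> list[str]:
    """Names of genes whose row is constant (sample sd <= tol)."""
    sds = x.values.std(axis=1, ddof=1)
    return [g for g, s in zip(x.gene_ids, sds) if s <= tol]


def drop_constant_genes(x: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Remove constant gene rows; returns the filtered matrix and dropped names."""
    dropped = set(constant_genes(x))
    if not dropped:
        return x, []
    keep = [i for i, g in enumerate(x.gene_ids) if g not in dropped]
    return (
        ExpressionMatrix(
            [x.gene_ids[i] for i in keep],
            list(x.condition_ids),
            x.values[keep],
            standardized=x.standardized,
        ),
        sorted(dropped),
    )


def standardize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize every gene row to mean 0 and sample sd 1 (n-1 denominator).

    Idempotent: standardizing an already-standardized matrix is a no-op up to
    floating error. Constant genes cannot be standardized; drop them first
    (see :func:`drop_constant_genes`) or fix the input.
    """
    const = constant_genes(x)
    if const:
        raise DegenerateGeneError(
            f"constant gene row(s), sd = 0: {', '.join(const)}"
        )
    values = standardize_values(x.values)
    return ExpressionMatrix(
        list(x.gene_ids), list(x.condition_ids), values, standardized=True
    )


def standardize_values(values: np.ndarray) -> np.ndarray:
    """Row-wise (x - mean) / sd with sample sd; no validation, used internally."""
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    return (values - means) / sds


@dataclasses.dataclass
class EdgeTable:
    """Per-edge statistics for one scoring method (or the consensus).

    ``df`` has columns gene_a, gene_b, score, t, p, fdr with gene_a preceding
    gene_b in the input gene order and each unordered pair at most once.
    """

    df: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS + ("consensus",):
            raise ValidationError(f"unknown method label '{self.method}'")
        missing = [c for c in EDGE_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"edge table missing column(s): {missing}")
        pairs = list(zip(self.df["gene_a"], self.df["gene_b"]))
        if any(a == b for a, b in pairs):
            raise ValidationError("edge table contains a self-pair")
        if len(set(map(frozenset, pairs))) != len(pairs):
            raise ValidationError("edge table contains a duplicated gene pair")
        for col in ("p", "fdr"):
            v = self.df[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValidationError(f"column '{col}' outside [0, 1]")


def write_edge_table(table: EdgeTable, path: str | Path) -> None:
    """Write an edge table as CSV, rows sorted by descending ``|score|``.

    Ties are broken by (gene_a, gene_b) lexical order so output is
    deterministic; reading the file back reproduces the table exactly.
    """
    df = table.df.copy()
    df["_abs"] = df["score"].abs()
    df = df.sort_values(
        by=["_abs", "gene_a", "gene_b"], ascending=[False, True, True], kind="stable"
    ).drop(columns="_abs")
    df.to_csv(path, index=False, columns=EDGE_TABLE_COLUMNS)


def read_edge_table(path: str | Path, method: str) -> EdgeTable:
    """Read back a CSV written by :func:`write_edge_table`."""
    df = pd.read_csv(path, dtype={"gene_a": str, "gene_b": str})
    return EdgeTable(df=df, method=method)
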