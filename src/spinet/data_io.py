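"""Reading, validation, alignment, and standardization of expression / condition tables.

The pipeline consumes a genes x samples matrix of log expression ratios and a
samples x condition-variables table mixing continuous measurements (rates,
durations) with binary presence/absence indicators. Both are plain delimited
text with a header row; the first column carries row identifiers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "ExpressionMatrix",
    "ConditionTable",
    "read_expression",
    "read_conditions",
    "align_samples",
    "standardize",
    "standardize_expression",
    "standardize_conditions",
    "write_expression",
    "write_conditions",
]


class DataValidationError(ValueError):
    """Raised when an input table violates the data contract."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    dup = seen[seen.duplicated()].unique().tolist()
    if dup:
        raise DataValidationError(f"duplicate {what} identifier(s): {dup}")


def _check_finite(values: np.ndarray, row_ids, col_ids, what: str) -> None:
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise DataValidationError(
            f"{what} contains a missing or non-finite value at "
            f"row {row_ids[r]!r}, column {col_ids[c]!r}"
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log expression ratios."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise DataValidationError("need at least 2 genes and 2 samples")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        _check_finite(self.values, self.gene_ids, self.sample_ids, "expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ConditionTable:
    """Samples x condition-variables table; each variable tagged continuous or binary."""

    sample_ids: list[str]
    variable_ids: list[str]
    values: np.ndarray
    variable_kind: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variable_ids)):
            raise DataValidationError(
                f"condition shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variable_ids)} variables"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.variable_ids, "variable")
        _check_finite(self.values, self.sample_ids, self.variable_ids, "condition table")
        if not self.variable_kind:
            self.variable_kind = [
                _infer_kind(self.values[:, j]) for j in range(len(self.variable_ids))
            ]
        if len(self.variable_kind) != len(self.variable_ids):
            raise DataValidationError("variable_kind length mismatch")
        for vid, kind in zip(self.variable_ids, self.variable_kind):
            if kind not in ("continuous", "binary"):
                raise DataValidationError(f"unknown kind {kind!r} for variable {vid!r}")
            if kind == "binary":
                vals = set(np.unique(self.values[:, self.variable_ids.index(vid)]))
                if not vals <= {0.0, 1.0}:
                    raise DataValidationError(
                        f"binary variable {vid!r} takes values outside {{0,1}}: {sorted(vals)}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_ids)


def _infer_kind(column: np.ndarray) -> str:
    distinct = set(np.unique(column))
    return "binary" if distinct == {0.0, 1.0} else "continuous"


def _read_table(path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate row identifier(s) in {path}: {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate column identifier(s) in {path}: {dup}")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"non-numeric cell in {path} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return coerced


def read_expression(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples log-ratio matrix from delimited text.

    First column: gene identifiers; header row: sample identifiers.
    Duplicated identifiers, missing values, and non-numeric cells are
    rejected with an error naming the offending row/column.
    """
    df = _read_table(path, delimiter)
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def read_conditions(path, delimiter: str = "\t", kinds: dict | None = None) -> ConditionTable:
    """Read a samples x condition-variables table.

    A variable whose observed values are exactly {0, 1} is tagged ``binary``,
    anything else ``continuous``; ``kinds`` overrides inference per variable id.
    """
    df = _read_table(path, delimiter)
    inferred = [_infer_kind(df[c].to_numpy(dtype=float)) for c in df.columns]
    if kinds:
        unknown = set(kinds) - set(df.columns)
        if unknown:
            raise DataValidationError(f"kind override for unknown variable(s): {sorted(unknown)}")
        inferred = [kinds.get(c, k) for c, k in zip(df.columns, inferred)]
    return ConditionTable(
        list(df.index), list(df.columns), df.to_numpy(dtype=float), inferred
    )


def align_samples(expression: ExpressionMatrix, conditions: ConditionTable) -> ConditionTable:
    """Reorder condition rows to the expression matrix's sample order.

    Alignment is a pure permutation: a mismatch in either direction is an
    error reporting both set differences, so no sample is dropped silently.
    """
    expr_set, cond_set = set(expression.sample_ids), set(conditions.sample_ids)
    if expr_set != cond_set:
        raise DataValidationError(
            "sample identifiers differ between expression and conditions; "
            f"expression-only: {sorted(expr_set - cond_set)}, "
            f"conditions-only: {sorted(cond_set - expr_set)}"
        )
    order = [conditions.sample_ids.index(s) for s in expression.sample_ids]
    return replace(
        conditions,
        sample_ids=[conditions.sample_ids[i] for i in order],
        values=conditions.values[order, :],
        variable_kind=list(conditions.variable_kind),
    )


def standardize(
    values: np.ndarray,
    axis: str = "rows",
    ddof: int = 1,
    labels: tuple | None = None,
) -> np.ndarray:
    """Center to mean 0 and scale to variance 1 along ``rows``, ``columns``, or ``both``.

    ``both`` standardizes columns (arrays) first, then rows (transcripts), so the
    per-transcript slices clustering consumes end exactly at mean 0 / variance 1.
    A zero-variance slice is an error naming the offending row or column.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise DataValidationError("standardize expects a 2-D matrix")
    row_labels, col_labels = labels if labels else (None, None)
    if axis == "both":
        out = standardize(values, "columns", ddof, labels)
        return standardize(out, "rows", ddof, labels)
    if axis == "rows":
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=ddof, keepdims=True)
        flat_sd = sd.ravel()
        names = row_labels if row_labels is not None else range(values.shape[0])
    elif axis == "columns":
        mean = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, ddof=ddof, keepdims=True)
        flat_sd = sd.ravel()
        names = col_labels if col_labels is not None else range(values.shape[1])
    else:
        raise ValueError(f"axis must be 'rows', 'columns' or 'both', got {axis!r}")
    zero = np.flatnonzero(flat_sd == 0)
    if zero.size:
        offender = list(names)[zero[0]]
        raise DataValidationError(
            f"zero-variance {axis[:-1]} {offender!r}: cannot standardize a constant slice"
        )
    return (values - mean) / sd


def standardize_expression(
    expression: ExpressionMatrix, axis: str = "both", ddof: int = 1
) -> ExpressionMatrix:
    vals = standardize(
        expression.values, axis, ddof, labels=(expression.gene_ids, expression.sample_ids)
    )
    return ExpressionMatrix(expression.gene_ids, expression.sample_ids, vals)


def standardize_conditions(conditions: ConditionTable, ddof: int = 1) -> np.ndarray:
    """Return condition values standardized per variable (binary ones included).

    Z-statistics downstream are scale-invariant, so binary indicators are put on
    the same footing as continuous rates; the original {0,1} coding stays in the
    ``ConditionTable``.
    """
    return standardize(
        conditions.values, "columns", ddof, labels=(conditions.sample_ids, conditions.variable_ids)
    )


def write_expression(expression: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    # %.17g guarantees bit-exact float64 round trips through text
    expression.to_frame().to_csv(path, sep=delimiter, float_format="%.17g")


def write_conditions(conditions: ConditionTable, path, delimiter: str = "\t") -> None:
    conditions.to_frame().to_csv(path, sep=delimiter, float_format="%.17g")
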