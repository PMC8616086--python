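"""Count-matrix handling for the stable-cell evidence stream.

A count matrix is a :class:`pandas.DataFrame` whose index holds unique gene
identifiers and whose columns hold unique sample identifiers; raw matrices
contain non-negative integers.  This module provides TSV I/O, the low-count
gene filter, quantile normalization, and the fold-change downregulation
screen used to nominate candidate miRNA targets from a miRNA-overexpressing
versus control stable-cell comparison.
"""

from __future__ import annotations

from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd


class CountTableError(ValueError):
    """Raised when a count table file or matrix violates its contract."""


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample TSV of raw read counts.

    The file must have a header row (first field names the gene column,
    remaining fields are sample identifiers) and one row per gene with
    non-negative integer counts.

    Raises
    ------
    CountTableError
        On malformed rows, duplicate gene or sample identifiers, or
        negative / non-integer counts.  The message names the offending
        line (1-based, counting the header as line 1).
    """
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dupes = {s for s in samples if samples.count(s) > 1}
    if dupes:
        raise CountTableError(
            f"{path}: duplicate sample id {sorted(dupes)[0]!r} in header"
        )
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CountTableError(f"{path}: cannot parse count table: {exc}") from exc

    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        line = int(np.flatnonzero(raw.index == dup)[-1]) + 2
        raise CountTableError(f"{path}: duplicate gene id {dup!r} (line {line})")
    out = {}
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0) | (vals < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CountTableError(
                f"{path}: invalid count {raw[col].iloc[i]!r} for gene "
                f"{raw.index[i]!r}, sample {col!r} (line {i + 2}): "
                "counts must be non-negative integers"
            )
        out[col] = vals.astype(np.int64)
    frame = pd.DataFrame(out, index=raw.index)
    frame.index.name = raw.index.name or "gene"
    return frame


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a count matrix as TSV (gene ids in the first column)."""
    out = matrix.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")


def filter_low_counts(
    matrix: pd.DataFrame, min_count: int = 2, mode: str = "each"
) -> pd.DataFrame:
    """Drop genes that fail the minimum raw read-count requirement.

    With ``mode="each"`` (default) a gene is retained only if its count is at
    least ``min_count`` in *every* library; with ``mode="total"`` the counts
    are summed across libraries before comparison.  Gene order is preserved
    and an empty result is allowed.
    """
    if mode not in ("each", "total"):
        raise ValueError(f"mode must be 'each' or 'total', got {mode!r}")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        return matrix.copy()
    if mode == "each":
        keep = (matrix >= min_count).all(axis=1)
    else:
        keep = matrix.sum(axis=1) >= min_count
    return matrix.loc[keep].copy()


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a count matrix across samples.

    Every column is mapped onto the reference distribution formed by the
    across-sample mean of order statistics, so all columns share the same
    sorted value vector while within-column rank order is preserved.  Tied
    values within a column receive the mean of the reference values spanned
    by their ranks (the averaged-ties convention).
    """
    if matrix.shape[1] < 1:
        raise ValueError("quantile normalization requires at least one sample")
    if matrix.shape[0] == 0:
        return matrix.astype(float)

    X = matrix.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average the reference values over each tie group's rank span
        out[:, j] = (
            pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
        )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def select_downregulated(
    matrix: pd.DataFrame,
    control_samples: Sequence[str],
    mir_samples: Sequence[str],
    fc_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Screen for genes downregulated in the miRNA condition.

    For each gene the fold change is computed on pseudocounted condition
    means, ``FC = (mean_mir + pseudocount) / (mean_control + pseudocount)``,
    and a gene is selected iff ``FC < fc_threshold`` (strict, so a gene
    exactly at a 2-fold drop with the default threshold is *not* selected).

    Returns a frame indexed by gene with columns ``mean_control``,
    ``mean_mir``, ``fold_change``, ``log2fc`` and boolean ``selected``.
    """
    control = list(control_samples)
    mir = list(mir_samples)
    if not control or not mir:
        raise ValueError("both condition groups must contain at least one sample")
    unknown = (set(control) | set(mir)) - set(matrix.columns)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)}")
    overlap = set(control) & set(mir)
    if overlap:
        raise ValueError(f"samples assigned to both conditions: {sorted(overlap)}")
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")

    mean_control = matrix[control].mean(axis=1)
    mean_mir = matrix[mir].mean(axis=1)
    fc = (mean_mir + pseudocount) / (mean_control + pseudocount)
    result = pd.DataFrame(
        {
            "mean_control": mean_control,
            "mean_mir": mean_mir,
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "selected": fc < fc_threshold,
        }
    )
    result.index.name = matrix.index.name or "gene"
    return result


def downregulated_genes(screen: pd.DataFrame) -> set[str]:
    """Gene set selected by :func:`select_downregulated`."""
    return set(screen.index[screen["selected"]])
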