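"""The RISC-pulldown enrichment statistic R_RC and its calibrated cutoff.

A RISC-trap experiment sequences the mRNA pool captured by a miRNA of
interest and, separately, the pool captured by a control miRNA.  The two
captured libraries cannot be assumed to share complexity or total mRNA
amount, so ordinary between-sample normalization is inappropriate.  The
ratio-of-read-counts statistic instead combines a per-gene ratio with a
complementary totals term that corrects for unequal captured-library sizes:

    R_RC = log2((n2 + f) / (n1 + f)) + log2((t1 - n1 + f) / (t2 - n2 + f))

where n1, n2 are a gene's read counts in the control-miRNA and
miRNA-of-interest pulldowns, t1, t2 the library totals over all genes, and
f > 0 a pseudocount keeping the logs finite at zero counts.  Positive R_RC
means the gene is preferentially captured by the miRNA of interest.

The selection cutoff is not a constant: it is recalibrated on every run as
an upper quantile (default 0.95) of the R_RC distribution observed in a
control cell context where no true enrichment is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def compute_rrc(n1, n2, t1, t2, f: float):
    """Evaluate the R_RC statistic for scalar or array counts.

    Computed as ``(log2(n2+f) - log2(n1+f)) + (log2(t1-n1+f) - log2(t2-n2+f))``,
    an algebraically identical grouping under which swapping
    ``(n1, t1) <-> (n2, t2)`` negates the result exactly in floating point.

    Raises
    ------
    ValueError
        If ``f <= 0``, any count is negative, or any ``n_i`` exceeds its
        total ``t_i``.
    """
    if f <= 0:
        raise ValueError(f"pseudocount f must be positive, got {f}")
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if (n1 < 0).any() or (n2 < 0).any():
        raise ValueError("read counts must be non-negative")
    if (n1 > t1).any() or (n2 > t2).any():
        raise ValueError("per-gene counts cannot exceed library totals")
    value = (np.log2(n2 + f) - np.log2(n1 + f)) + (
        np.log2(t1 - n1 + f) - np.log2(t2 - n2 + f)
    )
    return value if value.ndim else float(value)


@dataclass(frozen=True)
class PulldownPair:
    """One control-vs-miRNA pulldown comparison.

    ``n1``/``n2`` are per-gene counts for the control-miRNA and
    miRNA-of-interest pulldowns; ``t1``/``t2`` are the corresponding library
    totals over all retained genes (column sums of the matrix the counts
    came from, taken after any low-count filtering).
    """

    n1: pd.Series
    n2: pd.Series
    t1: int
    t2: int
    f: float = 0.5
    source: str = ""

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError(f"pseudocount f must be positive, got {self.f}")
        if not self.n1.index.equals(self.n2.index):
            raise ValueError("pulldown columns must share one gene index")
        if (self.n1 < 0).any() or (self.n2 < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.n1 > self.t1).any() or (self.n2 > self.t2).any():
            raise ValueError("per-gene counts cannot exceed library totals")

    @classmethod
    def from_matrix(
        cls,
        matrix: pd.DataFrame,
        control_col: str | None = None,
        mir_col: str | None = None,
        f: float = 0.5,
        source: str = "",
    ) -> "PulldownPair":
        """Build a pair from a two-column (control, miR) count matrix.

        Totals are the column sums of ``matrix``, so the matrix should
        already be low-count filtered if filtering is wanted.
        """
        if control_col is None:
            control_col = matrix.columns[0]
        if mir_col is None:
            mir_col = matrix.columns[1]
        return cls(
            n1=matrix[control_col],
            n2=matrix[mir_col],
            t1=int(matrix[control_col].sum()),
            t2=int(matrix[mir_col].sum()),
            f=f,
            source=source,
        )


def compute_rrc_table(pair: PulldownPair) -> pd.DataFrame:
    """Per-gene R_RC values for one pulldown pair.

    Returns a frame indexed by gene with columns ``n1``, ``n2``, ``rrc``.
    """
    values = compute_rrc(
        pair.n1.to_numpy(), pair.n2.to_numpy(), pair.t1, pair.t2, pair.f
    )
    table = pd.DataFrame(
        {"n1": pair.n1.to_numpy(), "n2": pair.n2.to_numpy(), "rrc": values},
        index=pair.n1.index,
    )
    table.index.name = pair.n1.index.name or "gene"
    return table


@dataclass(frozen=True)
class RrcThreshold:
    """An enrichment cutoff calibrated from a control-context R_RC table."""

    value: float
    q: float = 0.95
    source: str = ""
    n_calibration_genes: int = 0
    params: dict = field(default_factory=dict, compare=False)


def calibrate_threshold(
    control: pd.DataFrame, q: float = 0.95, source: str = ""
) -> RrcThreshold:
    """Empirical q-quantile of a control-context R_RC table.

    Uses the linear-interpolation quantile definition (the order-statistic
    position ``1 + q * (n - 1)``), so e.g. 100 values 0.01..1.00 give a
    0.95-quantile of 0.9505.
    """
    if len(control) == 0:
        raise ValueError("cannot calibrate a threshold from an empty table")
    if not 0 < q < 1:
        raise ValueError(f"calibration quantile must lie in (0, 1), got {q}")
    value = float(np.quantile(control["rrc"].to_numpy(), q, method="linear"))
    return RrcThreshold(value=value, q=q, source=source, n_calibration_genes=len(control))


def select_enriched(cancer: pd.DataFrame, threshold: RrcThreshold | float) -> set[str]:
    """Genes whose R_RC strictly exceeds the calibrated threshold."""
    cut = threshold.value if isinstance(threshold, RrcThreshold) else float(threshold)
    return set(cancer.index[cancer["rrc"] > cut])


def write_rrc_table(table: pd.DataFrame, path) -> None:
    """Write an R_RC table as TSV (gene, n1, n2, rrc)."""
    out = table.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")
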