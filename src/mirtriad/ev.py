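"""Extracellular-vesicle quantification arithmetic.

Three small, exact procedures used around EV particle counting and miRNA
quantification:

- ``aggregate_trps``: tunable-resistive-pulse-sensing (TRPS) technical
  replicates can undercount when the nanopore partially clogs without
  tripping quality-control flags, so replicate noise is biased downward.
  The aggregation rule therefore keeps the mean of the *k* highest
  technical replicates (default 3) per biological replicate.
- ``copies_per_vesicle``: absolute miRNA copies (e.g. from ddPCR) divided
  by particle count, plus a paired-difference helper for comparing large
  versus small EV classes.
- ``fit_standard_curve`` / ``quantify``: the standard qPCR calibration
  model — quantification cycle linear in log10(concentration) — fitted by
  least squares and inverted for absolute quantification, with an explicit
  flag when a query falls outside the calibrated range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def aggregate_trps(
    replicates: Sequence[float], k: int = 3, allow_fewer: bool = False
) -> float:
    """Mean of the ``k`` highest technical replicate concentrations.

    Parameters
    ----------
    replicates
        Particle concentrations (particles/mL), all positive.
    k
        Number of top replicates to average.
    allow_fewer
        If True and fewer than ``k`` replicates are supplied, fall back to
        the mean of all replicates with a logged warning instead of raising.
    """
    values = np.asarray(list(replicates), dtype=float)
    if values.size == 0:
        raise ValueError("at least one replicate is required")
    if (values <= 0).any():
        raise ValueError("particle concentrations must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if values.size < k:
        if not allow_fewer:
            raise ValueError(
                f"need at least k={k} technical replicates, got {values.size}"
            )
        logger.warning(
            "only %d replicates for top-%d aggregation; using all of them",
            values.size,
            k,
        )
        return float(values.mean())
    top = np.sort(values)[-k:]
    return float(top.mean())


def copies_per_vesicle(total_copies: float, total_particles: float) -> float:
    """Absolute cargo copies per particle (e.g. ddPCR copies / TRPS count)."""
    if total_particles <= 0:
        raise ValueError("total_particles must be positive")
    if total_copies < 0:
        raise ValueError("total_copies must be non-negative")
    return total_copies / total_particles


def copies_per_vesicle_difference(
    copies_a: float, particles_a: float, copies_b: float, particles_b: float
) -> float:
    """Paired difference in copies/vesicle between two EV classes (a - b)."""
    return copies_per_vesicle(copies_a, particles_a) - copies_per_vesicle(
        copies_b, particles_b
    )


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of quantification cycle on log10(concentration).

    ``efficiency`` is the amplification efficiency implied by the slope
    (``10**(-1/slope) - 1``; 1.0 = perfect doubling per cycle).  It is
    reported as a diagnostic, not used for correction.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    log10_conc_range: tuple[float, float]
    n_points: int
    unit: str = "M"


@dataclass(frozen=True)
class Quantification:
    """An inverted standard-curve query."""

    concentration: float
    log10_concentration: float
    extrapolated: bool
    unit: str = "M"


def fit_standard_curve(
    concentrations: Sequence[float], cycles: Sequence[float], unit: str = "M"
) -> StandardCurve:
    """Fit the calibration line ``cycle = intercept + slope*log10(conc)``.

    Requires at least two distinct positive concentrations; with exactly two
    points the line interpolates them.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    cq = np.asarray(list(cycles), dtype=float)
    if conc.shape != cq.shape:
        raise ValueError("concentrations and cycles must have equal length")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.unique(conc).size < 2:
        raise ValueError("at least two distinct concentrations are required")
    x = np.log10(conc)
    fit = stats.linregress(x, cq)
    if not np.isfinite(fit.slope) or fit.slope == 0:
        raise ValueError("degenerate calibration: slope is zero or non-finite")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(10.0 ** (-1.0 / fit.slope) - 1.0),
        log10_conc_range=(float(x.min()), float(x.max())),
        n_points=int(conc.size),
        unit=unit,
    )


def quantify(curve: StandardCurve, cycle_value: float) -> Quantification:
    """Invert the standard curve at one measured quantification cycle.

    A query whose implied concentration lies outside the calibrated range is
    still returned, but with ``extrapolated=True``.
    """
    log10_conc = (cycle_value - curve.intercept) / curve.slope
    lo, hi = curve.log10_conc_range
    eps = 1e-9 * max(1.0, abs(hi - lo))
    extrapolated = not (lo - eps <= log10_conc <= hi + eps)
    return Quantification(
        concentration=float(10.0**log10_conc),
        log10_concentration=float(log10_conc),
        extrapolated=extrapolated,
        unit=curve.unit,
    )
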