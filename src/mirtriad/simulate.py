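"""Synthetic study generator with planted miRNA targets.

Emulates the three data types the triangulation pipeline consumes — a
stable-cell RNA-seq comparison (miRNA-overexpressing vs control vector),
RISC-trap pulldown pairs in a "normal" and a "cancer" cell context, and a
gene-by-predictor boolean call table — with a known planted target set, so
every downstream stage can be validated end-to-end without any sequencing
data.

Counts are negative-binomial in the mean-dispersion parameterization
(variance ``mu + dispersion * mu**2``; dispersion 0 degenerates to Poisson).
Per-gene baseline means are drawn log-normally on the log2 scale and scaled
to the configured library size.  The control pulldown library is generated
at a smaller depth than the miRNA pulldown (factor ``control_pulldown_scale``)
so the totals-correction term of the R_RC statistic is actually exercised.

All randomness flows from one master seed: each output table consumes its
own sub-stream derived by stably hashing a table label, so regenerating any
single table is deterministic and independent of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Names used for the call table when exactly five predictors are simulated,
#: mirroring the five commonly combined target-prediction algorithms.
PREDICTOR_NAMES = ("miRanda", "miRDB", "miRWalk", "PicTar", "TargetScan")

PULLDOWN_CONTEXTS = ("normal", "cancer")


class SimConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic study.

    Parameters
    ----------
    n_genes, n_targets
        Size of the gene universe and of the planted target set.
    library_size
        Expected total read count per library.
    nb_dispersion
        Negative-binomial dispersion (variance ``mu + d*mu**2``); 0 = Poisson.
    de_log2fc
        Planted log2 fold change of targets in the miRNA stable cell
        (typically negative: targets are degraded).
    pulldown_log2_enrich
        Planted log2 enrichment of targets in the cancer-context miRNA
        pulldown (typically positive: targets are captured).
    predictor_sensitivity, predictor_specificity
        Per-predictor probability of calling a true target, and of *not*
        calling a non-target.
    n_replicates
        Libraries per condition in the stable-cell design (default 1,
        mirroring a single-library-per-arm study design).
    control_pulldown_scale
        Depth of the control pulldown relative to the miRNA pulldown.
    baseline_log2_mean, baseline_log2_sd
        Log2-scale location and spread of per-gene baseline means.
    """

    n_genes: int = 2000
    n_targets: int = 50
    library_size: int = 5_000_000
    nb_dispersion: float = 0.1
    de_log2fc: float = -2.0
    pulldown_log2_enrich: float = 3.0
    predictor_sensitivity: float = 0.9
    predictor_specificity: float = 0.98
    n_predictors: int = 5
    n_replicates: int = 1
    control_pulldown_scale: float = 0.7
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be positive")
        if not 0 <= self.n_targets <= self.n_genes:
            raise SimConfigError(
                f"n_targets must lie in [0, n_genes]; got {self.n_targets} "
                f"targets for {self.n_genes} genes"
            )
        if self.library_size <= 0:
            raise SimConfigError("library_size must be positive")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        for name in ("predictor_sensitivity", "predictor_specificity"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise SimConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.n_predictors < 1:
            raise SimConfigError("n_predictors must be positive")
        if self.n_replicates < 1:
            raise SimConfigError("n_replicates must be positive")
        if self.control_pulldown_scale <= 0:
            raise SimConfigError("control_pulldown_scale must be positive")
        if self.baseline_log2_sd < 0:
            raise SimConfigError("baseline_log2_sd must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Planted-target labels and effect sizes for one synthetic study."""

    target_genes: tuple[str, ...]
    de_log2fc: float
    pulldown_log2_enrich: float

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "de_log2fc": self.de_log2fc,
                "pulldown_log2_enrich": self.pulldown_log2_enrich,
            },
            index=pd.Index(self.target_genes, name="gene"),
        )
        return frame


def _rng(seed: int, label: str) -> np.random.Generator:
    """Sub-stream generator: master seed + stable hash of the table label."""
    key = zlib.crc32(label.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _universe(config: SimConfig) -> tuple[pd.Index, np.ndarray, SimTruth]:
    """Shared gene universe: ids, baseline means, and the planted truth.

    Drawn from its own sub-stream so every table of a study sees the same
    genes, means, and target set.
    """
    rng = _rng(config.seed, "universe")
    genes = pd.Index(
        [f"G{i + 1:06d}" for i in range(config.n_genes)], name="gene"
    )
    log2_means = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    means = np.exp2(log2_means)
    means *= config.library_size / means.sum()
    target_idx = rng.choice(config.n_genes, size=config.n_targets, replace=False)
    truth = SimTruth(
        target_genes=tuple(sorted(genes[target_idx])),
        de_log2fc=config.de_log2fc,
        pulldown_log2_enrich=config.pulldown_log2_enrich,
    )
    return genes, means, truth


def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(means)
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p)


def simulate_stable_counts(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Stable-cell count matrix: control-vector vs miRNA-overexpressing.

    Target genes have their baseline mean multiplied by
    ``2**config.de_log2fc`` in the miRNA condition; all counts are
    negative-binomial with the configured dispersion.  Columns are
    ``control_1..r`` then ``mir_1..r``.
    """
    genes, means, truth = _universe(config)
    rng = _rng(config.seed, "stable")
    is_target = genes.isin(truth.target_genes)
    mir_means = np.where(is_target, means * 2.0**config.de_log2fc, means)
    cols = {}
    for i in range(config.n_replicates):
        cols[f"control_{i + 1}"] = _draw_counts(rng, means, config.nb_dispersion)
    for i in range(config.n_replicates):
        cols[f"mir_{i + 1}"] = _draw_counts(rng, mir_means, config.nb_dispersion)
    return pd.DataFrame(cols, index=genes), truth


def simulate_pulldown_counts(
    config: SimConfig, context: str
) -> tuple[pd.DataFrame, SimTruth]:
    """Pulldown pair (control-miRNA vs miRNA-of-interest) for one context.

    In the ``"cancer"`` context target genes are enriched by
    ``2**config.pulldown_log2_enrich`` in the miRNA pulldown; in the
    ``"normal"`` context no gene is enriched.  The control pulldown is
    generated at ``control_pulldown_scale`` times the miRNA pulldown depth,
    so the two library totals deliberately differ.
    """
    if context not in PULLDOWN_CONTEXTS:
        raise SimConfigError(
            f"context must be one of {PULLDOWN_CONTEXTS}, got {context!r}"
        )
    genes, means, truth = _universe(config)
    rng = _rng(config.seed, f"pulldown_{context}")
    control_means = means * config.control_pulldown_scale
    if context == "cancer":
        is_target = genes.isin(truth.target_genes)
        mir_means = np.where(
            is_target, means * 2.0**config.pulldown_log2_enrich, means
        )
    else:
        mir_means = means
    frame = pd.DataFrame(
        {
            "pulldown_control": _draw_counts(rng, control_means, config.nb_dispersion),
            "pulldown_mir": _draw_counts(rng, mir_means, config.nb_dispersion),
        },
        index=genes,
    )
    return frame, truth


def simulate_predictions(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Boolean gene-by-predictor call table with imperfect predictors.

    Each predictor independently calls a true target positive with
    probability ``predictor_sensitivity`` and a non-target positive with
    probability ``1 - predictor_specificity``.
    """
    genes, _, _ = _universe(config)
    missing = set(truth.target_genes) - set(genes)
    if missing:
        raise SimConfigError(
            f"truth contains genes outside the simulated universe: {sorted(missing)[:5]}"
        )
    rng = _rng(config.seed, "predictions")
    is_target = genes.isin(truth.target_genes)
    p_call = np.where(
        is_target, config.predictor_sensitivity, 1.0 - config.predictor_specificity
    )
    calls = rng.random((config.n_genes, config.n_predictors)) < p_call[:, None]
    if config.n_predictors == len(PREDICTOR_NAMES):
        names = list(PREDICTOR_NAMES)
    else:
        names = [f"predictor_{i + 1}" for i in range(config.n_predictors)]
    return pd.DataFrame(calls, index=genes, columns=names)


@dataclass(frozen=True)
class SimStudy:
    """All tables of one synthetic study, sharing a single planted truth."""

    config: SimConfig
    stable: pd.DataFrame
    pulldown_normal: pd.DataFrame
    pulldown_cancer: pd.DataFrame
    predictions: pd.DataFrame
    truth: SimTruth


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate the full input set for one triangulation run."""
    stable, truth = simulate_stable_counts(config)
    normal, _ = simulate_pulldown_counts(config, "normal")
    cancer, _ = simulate_pulldown_counts(config, "cancer")
    predictions = simulate_predictions(config, truth)
    return SimStudy(
        config=config,
        stable=stable,
        pulldown_normal=normal,
        pulldown_cancer=cancer,
        predictions=predictions,
        truth=truth,
    )


def write_study(study: SimStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study tables as TSV into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stable": outdir / "stable_counts.tsv",
        "pulldown_normal": outdir / "pulldown_normal.tsv",
        "pulldown_cancer": outdir / "pulldown_cancer.tsv",
        "predictions": outdir / "predictions.tsv",
        "truth": outdir / "truth.tsv",
    }
    study.stable.to_csv(paths["stable"], sep="\t")
    study.pulldown_normal.to_csv(paths["pulldown_normal"], sep="\t")
    study.pulldown_cancer.to_csv(paths["pulldown_cancer"], sep="\t")
    study.predictions.astype(int).to_csv(paths["predictions"], sep="\t")
    study.truth.to_frame().to_csv(paths["truth"], sep="\t")
    return paths
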