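"""Predictor consensus and three-way evidence triangulation.

The final target call requires a gene to clear three independent screens:

1. downregulated more than 2-fold in the miRNA-overexpressing stable cell
   (expression evidence),
2. R_RC above the control-calibrated enrichment cutoff in the cancer-context
   RISC pulldown (direct-binding evidence),
3. called a target by at least ``min_votes`` of the prediction algorithms
   (sequence evidence).

The intersection of the three gene sets is the reported target set.  Genes
absent from the prediction table are explicit negatives (zero votes): the
pipeline does not guess at database coverage gaps.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import counts as _counts
from . import rrc as _rrc
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-predictor boolean call table from TSV (0/1 cells)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r} in prediction table")
    return frame.astype(bool)


def vote_counts(calls: pd.DataFrame) -> pd.Series:
    """Positive calls per gene (row sums of the boolean matrix)."""
    return calls.sum(axis=1).astype(int)


def consensus_predictions(calls: pd.DataFrame, min_votes: int = 4) -> set[str]:
    """Genes called by at least ``min_votes`` predictors."""
    n_predictors = calls.shape[1]
    if min_votes > n_predictors:
        raise ValueError(
            f"min_votes={min_votes} exceeds the number of predictors ({n_predictors})"
        )
    votes = vote_counts(calls)
    return set(votes.index[votes >= min_votes])


@dataclass(frozen=True)
class TargetReport:
    """The three evidence sets, their overlaps, and the final target set.

    ``support`` holds one row per gene in the union of the evidence sets,
    with the per-gene supporting values (log2 fold change, R_RC, vote
    count), membership flags, and the final call.  ``final_targets`` is
    ordered by descending R_RC, ties broken by ascending log2 fold change,
    then lexicographically.
    """

    de_genes: frozenset[str]
    rrc_genes: frozenset[str]
    predicted_genes: frozenset[str]
    final_targets: tuple[str, ...]
    overlaps: dict[str, int]
    support: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        final = set(self.final_targets)
        for name, evidence in (
            ("de", self.de_genes),
            ("rrc", self.rrc_genes),
            ("predicted", self.predicted_genes),
        ):
            if not final <= evidence:
                raise PipelineError(
                    f"final targets are not a subset of the {name} evidence set"
                )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the report tables and a provenance record into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": outdir / "report.tsv",
            "final_targets": outdir / "final_targets.txt",
            "provenance": outdir / "provenance.txt",
        }
        if self.support is not None:
            self.support.to_csv(paths["report"], sep="\t")
        paths["final_targets"].write_text(
            "".join(f"{g}\n" for g in self.final_targets)
        )
        lines = ["# triangulation provenance"]
        for key in sorted(self.params):
            lines.append(f"{key}\t{self.params[key]}")
        for key in sorted(self.overlaps):
            lines.append(f"overlap.{key}\t{self.overlaps[key]}")
        lines.append(f"n_final_targets\t{len(self.final_targets)}")
        paths["provenance"].write_text("".join(f"{l}\n" for l in lines))
        return paths


def intersect_evidence(
    de: set[str], rrc: set[str], pred: set[str], params: dict | None = None
) -> TargetReport:
    """Intersect the three evidence sets into a :class:`TargetReport`.

    The report carries all pairwise overlap counts alongside the triple
    intersection; final targets are ordered lexicographically (callers with
    per-gene values may reorder via :func:`build_report`).
    """
    de, rrc, pred = set(de), set(rrc), set(pred)
    final = de & rrc & pred
    overlaps = {
        "de": len(de),
        "rrc": len(rrc),
        "predicted": len(pred),
        "de_rrc": len(de & rrc),
        "de_predicted": len(de & pred),
        "rrc_predicted": len(rrc & pred),
        "de_rrc_predicted": len(final),
    }
    return TargetReport(
        de_genes=frozenset(de),
        rrc_genes=frozenset(rrc),
        predicted_genes=frozenset(pred),
        final_targets=tuple(sorted(final)),
        overlaps=overlaps,
        params=dict(params or {}),
    )


def build_report(
    screen: pd.DataFrame,
    cancer_table: pd.DataFrame,
    votes: pd.Series,
    de: set[str],
    enriched: set[str],
    predicted: set[str],
    params: dict | None = None,
    annotations: set[str] | None = None,
) -> TargetReport:
    """Assemble the full report with per-gene supporting values.

    ``annotations`` (optional) flags — never filters — genes of prior
    interest, e.g. a user-supplied vesicle-trafficking list.
    """
    base = intersect_evidence(de, enriched, predicted, params=params)
    union = sorted(de | enriched | predicted)
    support = pd.DataFrame(index=pd.Index(union, name="gene"))
    support["log2fc"] = screen["log2fc"].reindex(union)
    support["rrc"] = cancer_table["rrc"].reindex(union)
    support["votes"] = votes.reindex(union).fillna(0).astype(int)
    support["in_de"] = support.index.isin(de)
    support["in_rrc"] = support.index.isin(enriched)
    support["in_predicted"] = support.index.isin(predicted)
    final = set(base.final_targets)
    support["final_target"] = support.index.isin(final)
    if annotations is not None:
        support["annotated"] = support.index.isin(annotations)
    # descending R_RC, ties by ascending log2FC, then gene id
    order = support.assign(
        _rrc=-support["rrc"].fillna(-np.inf), _fc=support["log2fc"].fillna(np.inf)
    ).sort_values(["_rrc", "_fc"], kind="stable")
    support = support.loc[order.index]
    final_ordered = tuple(g for g in support.index if g in final)
    return TargetReport(
        de_genes=base.de_genes,
        rrc_genes=base.rrc_genes,
        predicted_genes=base.predicted_genes,
        final_targets=final_ordered,
        overlaps=base.overlaps,
        support=support,
        params=base.params,
    )


def _split_conditions(
    matrix: pd.DataFrame, config: PipelineConfig
) -> tuple[list[str], list[str]]:
    if config.control_samples is not None and config.mir_samples is not None:
        return list(config.control_samples), list(config.mir_samples)
    control = [c for c in matrix.columns if str(c).startswith("control")]
    mir = [c for c in matrix.columns if str(c).startswith("mir")]
    if not control or not mir:
        raise PipelineError(
            "cannot infer condition groups from column names; set "
            "control_samples / mir_samples in the configuration"
        )
    return control, mir


def triangulate_tables(
    stable: pd.DataFrame,
    pulldown_normal: pd.DataFrame,
    pulldown_cancer: pd.DataFrame,
    predictions: pd.DataFrame,
    config: PipelineConfig | None = None,
    annotations: set[str] | None = None,
) -> TargetReport:
    """Run the full triangulation on in-memory tables.

    Stages: low-count filter -> quantile normalization -> fold-change screen
    on the stable-cell matrix; low-count filter -> R_RC -> quantile
    calibration (normal context) -> enrichment selection (cancer context);
    predictor consensus; three-way intersection.
    """
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    filt = stage(
        "filter_stable",
        _counts.filter_low_counts,
        stable,
        config.min_count,
        config.low_count_mode,
    )
    logger.info("filter_stable: %d -> %d genes", len(stable), len(filt))
    normalized = stage("quantile_normalize", _counts.quantile_normalize, filt)
    control, mir = _split_conditions(stable, config)
    screen = stage(
        "de_screen",
        _counts.select_downregulated,
        normalized,
        control,
        mir,
        config.fc_threshold,
        config.pseudocount,
    )
    de = _counts.downregulated_genes(screen)
    logger.info("de_screen: %d of %d genes selected", len(de), len(screen))

    normal_filt = stage(
        "filter_pulldown_normal",
        _counts.filter_low_counts,
        pulldown_normal,
        config.min_count,
        config.low_count_mode,
    )
    normal_table = stage(
        "rrc_normal",
        _rrc.compute_rrc_table,
        _rrc.PulldownPair.from_matrix(normal_filt, f=config.f, source="normal"),
    )
    threshold = stage("calibrate_threshold", _rrc.calibrate_threshold, normal_table, config.q, "normal")
    logger.info(
        "calibrate_threshold: q=%.3f over %d genes -> %.4f",
        config.q,
        len(normal_table),
        threshold.value,
    )
    cancer_filt = stage(
        "filter_pulldown_cancer",
        _counts.filter_low_counts,
        pulldown_cancer,
        config.min_count,
        config.low_count_mode,
    )
    cancer_table = stage(
        "rrc_cancer",
        _rrc.compute_rrc_table,
        _rrc.PulldownPair.from_matrix(cancer_filt, f=config.f, source="cancer"),
    )
    enriched = _rrc.select_enriched(cancer_table, threshold)
    logger.info("rrc_screen: %d of %d genes enriched", len(enriched), len(cancer_table))

    predicted = stage(
        "consensus", consensus_predictions, predictions, config.min_votes
    )
    votes = vote_counts(predictions)
    logger.info("consensus: %d of %d genes called", len(predicted), len(votes))

    params = config.params()
    params["rrc_threshold"] = threshold.value
    params["rrc_threshold_source"] = threshold.source
    report = build_report(
        screen,
        cancer_table,
        votes,
        de,
        enriched,
        predicted,
        params=params,
        annotations=annotations,
    )
    logger.info("final targets: %d", len(report.final_targets))
    return report


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> TargetReport:
    """File-based entry point: read all inputs, triangulate, write outputs.

    Requires the four input paths on ``config``; writes the report into
    ``config.out_dir`` if set.  Provenance includes all parameters and a
    SHA-256 digest of every input file.
    """
    for name in ("stable", "pulldown_normal", "pulldown_cancer", "predictions"):
        if getattr(config, name) is None:
            raise PipelineError(f"configuration is missing the {name!r} input path")
    stable = _counts.read_counts(config.stable)
    normal = _counts.read_counts(config.pulldown_normal)
    cancer = _counts.read_counts(config.pulldown_cancer)
    predictions = read_predictions(config.predictions)
    annotations = None
    if config.annotations is not None:
        annotations = {
            line.strip()
            for line in Path(config.annotations).read_text().splitlines()
            if line.strip()
        }
    report = triangulate_tables(
        stable, normal, cancer, predictions, config=config, annotations=annotations
    )
    digests = {
        f"sha256.{name}": _sha256(getattr(config, name))
        for name in ("stable", "pulldown_normal", "pulldown_cancer", "predictions")
    }
    report.params.update(digests)
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report
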