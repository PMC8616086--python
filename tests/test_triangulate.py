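"""Consensus voting, evidence intersection, and the end-to-end pipeline."""

import dataclasses

import pandas as pd
import pytest

from mirtriad import (
    PipelineConfig,
    PipelineError,
    TargetReport,
    consensus_predictions,
    intersect_evidence,
    run_pipeline,
    simulate_study,
    triangulate_tables,
    vote_counts,
    write_study,
)


def _calls(rows: dict[str, list[bool]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"p{i}" for i in range(1, 6)]
    )


class TestConsensus:
    def test_four_of_five_rule(self):
        calls = _calls(
            {
                "g4of5": [True, True, True, True, False],
                "g3of5": [True, True, True, False, False],
                "g5of5": [True] * 5,
                "g0of5": [False] * 5,
            }
        )
        assert consensus_predictions(calls, min_votes=4) == {"g4of5", "g5of5"}

    def test_vote_counts_match_direct_enumeration(self):
        calls = _calls({"a": [True, False, True, False, True], "b": [False] * 5})
        votes = vote_counts(calls)
        for gene in calls.index:
            assert votes[gene] == sum(1 for v in calls.loc[gene] if v)

    def test_min_votes_beyond_predictor_count(self):
        with pytest.raises(ValueError, match="exceeds"):
            consensus_predictions(_calls({"a": [True] * 5}), min_votes=6)


class TestIntersectEvidence:
    def test_three_way_set_arithmetic(self):
        report = intersect_evidence({"A", "B", "C"}, {"B", "C", "D"}, {"C", "D", "E"})
        assert report.final_targets == ("C",)
        assert report.overlaps["de_rrc"] == 2
        assert report.overlaps["de_predicted"] == 1
        assert report.overlaps["rrc_predicted"] == 2
        assert report.overlaps["de_rrc_predicted"] == 1

    def test_identical_sets(self):
        s = {"x", "y"}
        report = intersect_evidence(s, s, s)
        assert set(report.final_targets) == s

    def test_any_empty_set_empties_the_result(self):
        report = intersect_evidence(set(), {"a"}, {"a"})
        assert report.final_targets == ()

    def test_final_must_be_subset_of_every_evidence_set(self):
        with pytest.raises(PipelineError, match="subset"):
            TargetReport(
                de_genes=frozenset({"a"}),
                rrc_genes=frozenset({"a"}),
                predicted_genes=frozenset(),
                final_targets=("a",),
                overlaps={},
            )


class TestPipeline:
    def test_planted_targets_recovered(self, small_sim_config):
        study = simulate_study(small_sim_config)
        report = triangulate_tables(
            study.stable,
            study.pulldown_normal,
            study.pulldown_cancer,
            study.predictions,
        )
        truth = set(study.truth.target_genes)
        final = set(report.final_targets)
        assert final, "expected at least one recovered target"
        assert len(final & truth) / len(final) >= 0.9
        assert len(final & truth) / len(truth) >= 0.5

    def test_final_subset_of_each_evidence_stream(self, small_sim_config):
        study = simulate_study(small_sim_config)
        report = triangulate_tables(
            study.stable,
            study.pulldown_normal,
            study.pulldown_cancer,
            study.predictions,
        )
        final = set(report.final_targets)
        assert final <= report.de_genes
        assert final <= report.rrc_genes
        assert final <= report.predicted_genes

    def test_null_study_yields_almost_nothing(self, small_sim_config):
        null_cfg = dataclasses.replace(
            small_sim_config, de_log2fc=0.0, pulldown_log2_enrich=0.0
        )
        study = simulate_study(null_cfg)
        report = triangulate_tables(
            study.stable,
            study.pulldown_normal,
            study.pulldown_cancer,
            study.predictions,
        )
        assert len(report.final_targets) <= 2

    def test_relaxing_thresholds_never_shrinks_the_target_set(self, small_sim_config):
        study = simulate_study(small_sim_config)
        tables = (
            study.stable,
            study.pulldown_normal,
            study.pulldown_cancer,
            study.predictions,
        )
        strict = triangulate_tables(*tables, config=PipelineConfig())
        relaxed = triangulate_tables(
            *tables,
            config=PipelineConfig(fc_threshold=0.7, q=0.8, min_votes=3),
        )
        assert set(strict.final_targets) <= set(relaxed.final_targets)

    def test_report_ordering_descending_rrc(self, small_sim_config):
        study = simulate_study(small_sim_config)
        report = triangulate_tables(
            study.stable,
            study.pulldown_normal,
            study.pulldown_cancer,
            study.predictions,
        )
        rrc = report.support.loc[list(report.final_targets), "rrc"].to_numpy()
        assert (rrc[:-1] >= rrc[1:]).all()

    def test_genes_missing_from_predictions_are_negatives(self, small_sim_config):
        study = simulate_study(small_sim_config)
        # drop every prediction row: consensus evidence collapses to nothing
        empty_calls = study.predictions.iloc[:0]
        report = triangulate_tables(
            study.stable,
            study.pulldown_normal,
            study.pulldown_cancer,
            empty_calls,
        )
        assert report.final_targets == ()

    def test_stage_errors_carry_the_stage_name(self, small_sim_config):
        study = simulate_study(small_sim_config)
        with pytest.raises(PipelineError, match="consensus"):
            triangulate_tables(
                study.stable,
                study.pulldown_normal,
                study.pulldown_cancer,
                study.predictions,
                config=PipelineConfig(min_votes=6 + 1),
            )


class TestFilePipeline:
    def _config(self, tmp_path, study, out_name):
        paths = write_study(study, tmp_path / "inputs")
        return PipelineConfig(
            stable=str(paths["stable"]),
            pulldown_normal=str(paths["pulldown_normal"]),
            pulldown_cancer=str(paths["pulldown_cancer"]),
            predictions=str(paths["predictions"]),
            out_dir=str(tmp_path / out_name),
        )

    def test_byte_identical_reruns(self, tmp_path, small_sim_config):
        study = simulate_study(small_sim_config)
        cfg1 = self._config(tmp_path, study, "run1")
        cfg2 = dataclasses.replace(cfg1, out_dir=str(tmp_path / "run2"))
        run_pipeline(cfg1)
        run_pipeline(cfg2)
        for name in ("report.tsv", "final_targets.txt", "provenance.txt"):
            a = (tmp_path / "run1" / name).read_bytes()
            b = (tmp_path / "run2" / name).read_bytes()
            assert a == b, f"{name} differs between identical runs"

    def test_provenance_records_thresholds_and_digests(self, tmp_path, small_sim_config):
        study = simulate_study(small_sim_config)
        report = run_pipeline(self._config(tmp_path, study, "run"))
        text = (tmp_path / "run" / "provenance.txt").read_text()
        assert "rrc_threshold" in text
        assert "fc_threshold\t0.5" in text
        assert "sha256.stable" in report.params

    def test_annotation_list_flags_but_does_not_filter(self, tmp_path, small_sim_config):
        study = simulate_study(small_sim_config)
        cfg = self._config(tmp_path, study, "run")
        flagged_gene = study.truth.target_genes[0]
        ann = tmp_path / "annotations.txt"
        ann.write_text(f"{flagged_gene}\n")
        plain = run_pipeline(cfg)
        annotated = run_pipeline(dataclasses.replace(cfg, annotations=str(ann)))
        assert plain.final_targets == annotated.final_targets
        assert bool(annotated.support.loc[flagged_gene, "annotated"]) is True

    def test_missing_input_path_is_an_error(self):
        with pytest.raises(PipelineError, match="stable"):
            run_pipeline(PipelineConfig())
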