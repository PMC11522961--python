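"""Open-world rule evaluation, partial diagnoses, traces, batch monotonicity."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from mciscreen import (
    INACTIVE,
    SubjectRecord,
    TreeVote,
    classify_batch,
    compile_tree,
    diagnose,
    ensemble_votes,
    evaluate_record,
    explain,
    infer_votes,
    rule_fires,
)
from mciscreen.engine import BatteryMismatchError, results_to_dataframe
from tests.conftest import toy_record


@pytest.fixture(scope="module")
def worked_rules(worked_tree, spanish_style_schema):
    rules = compile_tree(worked_tree, spanish_style_schema)
    mci = [r for r in rules if r.consequent.args[1] == 1
           and len(r.antecedent) == 9][0]
    return mci, spanish_style_schema.property_map


class TestRuleFires:
    def test_worked_rule_fires_on_satisfying_record(self, worked_rules):
        """9<=9.5, 20<=24.5, 40>32.5, 20>14.75: all four comparisons hold."""
        rule, pm = worked_rules
        record = SubjectRecord(
            "s", scores={"praxias": 9.0, "cal_rey": 20.0, "TrailATi": 40.0}
        )
        fired, bindings = rule_fires(rule, record, property_map=pm)
        assert fired
        assert bindings["?CR"] == bindings["?CR2"] == 20.0

    def test_missing_score_is_silent_not_false(self, worked_rules):
        rule, pm = worked_rules
        record = SubjectRecord("s", scores={"praxias": 9.0, "TrailATi": 40.0})
        fired, bindings = rule_fires(rule, record, property_map=pm)
        assert not fired and bindings == {}

    def test_boundary_value_satisfies_less_than_or_equal(self, worked_rules):
        rule, pm = worked_rules
        record = SubjectRecord(
            "s", scores={"praxias": 9.5, "cal_rey": 20.0, "TrailATi": 40.0}
        )
        assert rule_fires(rule, record, property_map=pm)[0]


class TestInferVotes:
    def test_complete_record_matches_traversal_oracle(self, trained_setup):
        schema, records, model, program = trained_setup
        for record in records[:100]:
            engine = [v.vote for v in infer_votes(program, record)]
            assert engine == ensemble_votes(model, record)

    def test_blocking_specific_trees(self, toy_program):
        """Scores removed for the features of trees 0, 1 and 7 only: those
        three trees are inactive, the other eight still vote."""
        values = {i: 9 for i in range(11)}
        for blocked in (0, 1, 7):
            del values[blocked]
        votes = infer_votes(toy_program, toy_record(values))
        inactive = [v.tree_index for v in votes if v.vote is INACTIVE]
        assert inactive == [0, 1, 7]
        assert sum(v.vote for v in votes if v.vote is not INACTIVE) == 8

    def test_empty_score_map_deactivates_all_trees(self, toy_program):
        votes = infer_votes(toy_program, toy_record({}))
        assert all(v.vote is INACTIVE for v in votes)
        assert all(v.fired_rule_id is None for v in votes)

    def test_battery_mismatch_rejected(self, toy_program):
        stranger = SubjectRecord("s", scores={}, battery_id="other_battery")
        with pytest.raises(BatteryMismatchError):
            infer_votes(toy_program, stranger)


def votes_from(pattern: list) -> list[TreeVote]:
    return [
        TreeVote(i, v, None if v is INACTIVE else f"T{i}_L0")
        for i, v in enumerate(pattern)
    ]


class TestDiagnose:
    def test_all_zero_votes_is_automatic_healthy(self):
        result = diagnose(votes_from([0] * 11), th=2, n_trees=11)
        assert (result.status, result.label) == ("automatic", "Healthy")
        assert result.vote_sum == 0 and result.conclusive

    def test_partial_sum_reaching_threshold_is_conclusive_mci(self):
        pattern = [1, 1, 0, 0, 0, 0, 0, 0] + [INACTIVE] * 3
        result = diagnose(votes_from(pattern), th=2, n_trees=11)
        assert (result.status, result.label) == ("partial", "MCI")
        assert result.conclusive and result.n_active == 8

    def test_no_active_trees_is_undetermined(self):
        result = diagnose(votes_from([INACTIVE] * 11), th=2, n_trees=11)
        assert (result.status, result.label) == ("no_data", "Undetermined")
        assert not result.conclusive

    def test_partial_sum_below_threshold_is_preliminary_healthy(self):
        pattern = [1, 0, 0, 0, 0] + [INACTIVE] * 6
        result = diagnose(votes_from(pattern), th=2, n_trees=11)
        assert (result.status, result.label) == ("partial", "Healthy")
        assert not result.conclusive

    def test_wrong_vote_count_rejected(self):
        with pytest.raises(ValueError, match="votes"):
            diagnose(votes_from([0, 1]), th=2, n_trees=11)


class TestOpenWorldSoundness:
    @given(drop=st.sets(st.integers(min_value=0, max_value=7), max_size=8))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_removing_scores_never_flips_votes(self, trained_setup, drop):
        """Deleting scores can only deactivate trees, never change a vote."""
        schema, records, model, program = trained_setup
        record = records[13]
        before = {v.tree_index: v.vote for v in infer_votes(program, record)}
        test_ids = list(schema.test_ids)
        reduced = SubjectRecord(
            record.subject_id,
            scores={k: v for k, v in record.scores.items()
                    if k not in {test_ids[i] for i in drop}},
            battery_id=record.battery_id,
        )
        after = {v.tree_index: v.vote for v in infer_votes(program, reduced)}
        for i, vote in after.items():
            if vote is not INACTIVE:
                assert vote == before[i]

    def test_activating_trees_never_decreases_sum(self, toy_program):
        """Completing missing scores adds 0 or 1 per newly active tree."""
        partial = toy_record({0: 9, 1: 9})
        res_partial = evaluate_record(toy_program, partial)
        complete_mci = toy_record({i: 9 for i in range(11)})
        complete_hlt = toy_record({0: 9, 1: 9} | {i: 1 for i in range(2, 11)})
        assert evaluate_record(toy_program, complete_mci).vote_sum >= res_partial.vote_sum
        assert evaluate_record(toy_program, complete_hlt).vote_sum == res_partial.vote_sum


class TestClassifyBatch:
    def test_result_independent_of_batch_composition(self, trained_setup):
        schema, records, model, program = trained_setup
        record = records[42]
        alone = evaluate_record(program, record)
        in_batch, _ = classify_batch(program, records[:200])
        assert in_batch[42] == alone

    def test_adding_records_never_changes_earlier_results(self, trained_setup):
        _, records, _, program = trained_setup
        first, _ = classify_batch(program, records[:50])
        extended, _ = classify_batch(program, records[:120])
        assert extended[:50] == first

    def test_screening_batch_summary_counts(self, toy_program):
        """354-case screening batch: 9 fully score-less records, 5 records
        blocking three trees, the rest complete -> 340 automatic diagnoses,
        5 partial, 9 without data."""
        records = []
        for i in range(340):
            records.append(toy_record({j: (9 if j < i % 4 else 1) for j in range(11)},
                                      subject_id=f"c{i}"))
        for i in range(5):
            values = {j: 9 for j in range(11)}
            for blocked in (0, 1, 7):
                del values[blocked]
            records.append(toy_record(values, subject_id=f"p{i}"))
        for i in range(9):
            records.append(toy_record({}, subject_id=f"e{i}"))
        results, summary = classify_batch(toy_program, records)
        assert summary.n_cases == 354
        assert summary.n_automatic == 340
        assert summary.n_partial == 5
        assert summary.n_no_data == 9
        assert summary.n_automatic_mci + summary.n_automatic_healthy == 340
        assert summary.n_partial_conclusive_mci == 5  # eight active votes of 1

    def test_empty_batch(self, toy_program):
        results, summary = classify_batch(toy_program, [])
        assert results == [] and summary.n_cases == 0

    def test_confusion_classes_balance(self, trained_setup):
        """TP+FP+TN+FN equals the number of automatic diagnoses."""
        schema, records, model, _ = trained_setup
        from mciscreen import compile_program

        program = compile_program(model, schema, include_confusion=True)
        results, summary = classify_batch(program, records[:150])
        n_conf = sum(r.confusion_class is not None for r in results)
        assert n_conf == summary.n_automatic


class TestExplain:
    def test_automatic_trace_shape_and_content(self, trained_setup):
        _, records, _, program = trained_setup
        result = evaluate_record(program, records[0])
        assert result.status == "automatic"
        n_leaf = sum(1 for r in result.trace if r.startswith("T"))
        assert len(result.trace) == n_leaf + 2  # + aggregation + diagnosis
        assert result.trace[-2] == "AGG"
        assert result.trace[-1] in ("DIAG_MCI", "DIAG_HEALTHY")
        text = explain(result, program)
        assert f"Case {records[0].subject_id}" in text
        assert "vote sum" in text

    def test_healthy_trace_ends_with_healthy_rule(self, toy_program):
        result = evaluate_record(toy_program, toy_record({i: 1 for i in range(11)}))
        assert result.vote_sum == 0
        assert result.trace[-1] == "DIAG_HEALTHY"
        assert "sum" in explain(result, toy_program)

    def test_no_data_trace_reports_zero_firings(self, toy_program):
        result = evaluate_record(toy_program, toy_record({}))
        assert result.trace == []
        assert "zero rules fired" in explain(result, toy_program)

    def test_partial_trace_contains_only_leaf_rules(self, toy_program):
        values = {i: 9 for i in range(11)}
        for blocked in (0, 1, 7):
            del values[blocked]
        result = evaluate_record(toy_program, toy_record(values))
        assert result.status == "partial"
        assert len(result.trace) == 8
        assert all(r.startswith("T") for r in result.trace)

    def test_annotations_independent_of_diagnosis(self, toy_battery_schema,
                                                  toy_model):
        """The impaired-state assertion fires for Healthy and MCI cases alike."""
        from mciscreen import AnnotationMapping, compile_program

        program = compile_program(
            toy_model, toy_battery_schema,
            annotations=[AnnotationMapping(
                "t3", 2.0, "le", "has_semantic_memory_state", "impaired"
            )],
        )
        healthy = toy_record({i: 1 for i in range(11)})
        mci = toy_record({3: 1} | {i: 9 for i in range(11) if i != 3})
        res_h = evaluate_record(program, healthy)
        res_m = evaluate_record(program, mci)
        assert res_h.label == "Healthy" and res_m.label == "MCI"
        assert res_h.annotations == [("has_semantic_memory_state", "impaired")]
        assert res_m.annotations == [("has_semantic_memory_state", "impaired")]


class TestResultsIO:
    def test_dataframe_and_writers(self, toy_program, tmp_path):
        from mciscreen import write_results

        records = [toy_record({i: 9 for i in range(11)}, subject_id="a"),
                   toy_record({}, subject_id="b")]
        results, _ = classify_batch(toy_program, records)
        df = results_to_dataframe(results)
        assert list(df["label"]) == ["MCI", "Undetermined"]
        assert df.loc[1, "votes"] == ";".join(["-"] * 11)
        write_results(results, tmp_path / "r.csv", fmt="csv")
        write_results(results, tmp_path / "r.jsonl", fmt="jsonl")
        assert (tmp_path / "r.csv").exists()
        assert len((tmp_path / "r.jsonl").read_text().splitlines()) == 2
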