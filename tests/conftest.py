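"""Shared fixtures: the worked-example battery fragment, a hand-built
11-tree rule program for missing-data scenarios, and small cohorts."""

from __future__ import annotations

import pytest

from mciscreen import (
    BatterySchema,
    CohortConfig,
    DecisionTreeModel,
    EnsembleConfig,
    EnsembleModel,
    SubjectRecord,
    TestDefinition,
    TreeNode,
    compile_program,
    generate_cohort,
    train_ensemble,
)

# Rendered translation of the example leaf
# "if (Praxias_cons <= 9.5) and (cal_rey <= 24.5) and (TrailATi > 32.5)
#  and (cal_rey > 14.75) then class: MCI" — the reference string the
# compiler must reproduce (tree index generalised to n).
WORKED_RULE_TEXT = (
    "Subject(?p) ^ has_praxias_score (?p, ?PC) ^ swrlb:lessThanOrEqual (?PC, 9.5)"
    " ^ has_Rey_complex_figure_score (?p, ?CR) ^ swrlb:lessThanOrEqual (?CR, 24.5)"
    " ^ has_Trail_Making_test_A_score (?p, ?TMA) ^ swrlb:greaterThan (?TMA, 32.5)"
    " ^ has_Rey_complex_figure_score (?p, ?CR2) ^ swrlb:greaterThan (?CR2, 14.75)"
    " - > pred_n(?p, 1)"
)


def leaf(label: int, probability: float = 0.5, support: int = 10) -> TreeNode:
    return TreeNode(class_label=label, probability=probability, support=support)


@pytest.fixture(scope="session")
def spanish_style_schema() -> BatterySchema:
    """Three-test fragment mirroring the worked example's battery."""
    return BatterySchema(
        battery_id="spanish_battery",
        tests=(
            TestDefinition("praxias", "Praxias_cons", "has_praxias_score",
                           0, 11, var_name="PC"),
            TestDefinition("cal_rey", "cal_rey", "has_Rey_complex_figure_score",
                           0, 36, var_name="CR"),
            TestDefinition("TrailATi", "TrailATi", "has_Trail_Making_test_A_score",
                           0, 300, higher_is_better=False, var_name="TMA"),
        ),
    )


@pytest.fixture(scope="session")
def worked_tree() -> DecisionTreeModel:
    """Tree #10 whose deepest left path is the worked-example leaf."""
    mci_leaf = leaf(1, probability=0.8116, support=69)
    inner = TreeNode(
        test_id="TrailATi", threshold=32.5,
        left=leaf(0),
        right=TreeNode(
            test_id="cal_rey", threshold=14.75,
            left=leaf(0), right=mci_leaf,
        ),
    )
    root = TreeNode(
        test_id="praxias", threshold=9.5,
        left=TreeNode(test_id="cal_rey", threshold=24.5, left=inner, right=leaf(0)),
        right=leaf(0),
    )
    return DecisionTreeModel(tree_index=10, root=root)


@pytest.fixture(scope="session")
def toy_battery_schema() -> BatterySchema:
    """Eleven single-purpose binary-ish tests, one per toy tree."""
    return BatterySchema(
        battery_id="toy_battery",
        tests=tuple(
            TestDefinition(f"t{i}", f"t{i}", f"has_t{i}_score", 0, 10)
            for i in range(11)
        ),
    )


@pytest.fixture(scope="session")
def toy_model(toy_battery_schema) -> EnsembleModel:
    """Eleven depth-1 trees; tree i votes MCI iff score t_i > 5."""
    trees = [
        DecisionTreeModel(
            tree_index=i,
            root=TreeNode(
                test_id=f"t{i}", threshold=5.0, left=leaf(0), right=leaf(1)
            ),
        )
        for i in range(11)
    ]
    return EnsembleModel(
        battery_id="toy_battery",
        trees=trees,
        threshold=2,
        config=EnsembleConfig(n_trees=11, seed=0),
    )


@pytest.fixture(scope="session")
def toy_program(toy_model, toy_battery_schema):
    return compile_program(toy_model, toy_battery_schema, include_confusion=True)


def toy_record(values: dict[int, float], subject_id: str = "X",
               gold: int | None = None) -> SubjectRecord:
    """Record for the toy battery; keys are tree/test indices."""
    return SubjectRecord(
        subject_id=subject_id,
        scores={f"t{i}": float(v) for i, v in values.items()},
        gold_label=gold,
        battery_id="toy_battery",
    )


@pytest.fixture(scope="session")
def labeled_cohort():
    """Small complete synthetic cohort shared by training tests."""
    config = CohortConfig(n_subjects=300, seed=7)
    schema, records, gold = generate_cohort(config)
    return schema, records, gold


@pytest.fixture(scope="session")
def trained_setup(labeled_cohort):
    """Ensemble + compiled program on the shared cohort."""
    schema, records, _ = labeled_cohort
    model = train_ensemble(records, schema, EnsembleConfig(seed=7))
    program = compile_program(model, schema)
    return schema, records, model, program
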