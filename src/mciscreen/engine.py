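"""Monotonic forward-chaining evaluation of rule programs over case records.

The engine works under the open-world assumption: a rule whose antecedent
needs a score the record does not have is silently inactive — absence of a
fact is never treated as its negation, and nothing asserted is ever
retracted.  Evaluation is two-phase by construction: all per-tree leaf
rules first, then the aggregation and diagnosis rules (the sum rule can
only fire after every tree has issued a prediction).

Missing scores therefore degrade the result gracefully rather than
blocking it:

* every tree active  -> ``automatic`` diagnosis (the rule system decides);
* some trees blocked -> ``partial``: the engine sums the active votes
  itself; the result is conclusive only when the sum already reaches the
  threshold (a below-threshold "Healthy" from partial information is
  flagged as non-conclusive);
* no tree active     -> ``no_data``, label ``Undetermined``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ensemble import INACTIVE
from .rules import (
    GOLD_PROPERTY,
    RuleAtom,
    RuleProgram,
    SWRLRule,
    render_swrl,
)
from .schema import SubjectRecord

__all__ = [
    "BatteryMismatchError",
    "TreeVote",
    "DiagnosisResult",
    "BatchSummary",
    "rule_fires",
    "infer_votes",
    "diagnose",
    "evaluate_record",
    "classify_batch",
    "explain",
    "results_to_dataframe",
    "write_results",
]


class BatteryMismatchError(ValueError):
    """A program was asked to consume records from a different battery."""


@dataclass(frozen=True)
class TreeVote:
    """One tree's contribution: its vote and the leaf rule that produced it."""

    tree_index: int
    vote: int | None  # 0, 1, or INACTIVE (None)
    fired_rule_id: str | None = None

    def __post_init__(self) -> None:
        if (self.vote is INACTIVE) != (self.fired_rule_id is None):
            raise ValueError("a vote is present exactly when a leaf rule fired")


@dataclass
class DiagnosisResult:
    """Per-case outcome with full provenance for explanation."""

    subject_id: str
    evaluation_index: int
    votes: list[TreeVote]
    n_active: int
    vote_sum: int
    status: str  # automatic | partial | no_data
    label: str  # Healthy | MCI | Undetermined
    conclusive: bool
    trace: list[str] = field(default_factory=list)
    annotations: list[tuple[str, str]] = field(default_factory=list)
    confusion_class: str | None = None
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class BatchSummary:
    """Label-by-status counts over a classified batch.

    Conclusive partial MCI cases are counted apart from automatic MCI so
    the caution attached to partial information survives aggregation.
    """

    n_cases: int = 0
    n_automatic: int = 0
    n_partial: int = 0
    n_no_data: int = 0
    n_automatic_healthy: int = 0
    n_automatic_mci: int = 0
    n_partial_conclusive_mci: int = 0
    n_partial_inconclusive_healthy: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


_UNBOUND = object()


def _resolve(term, bindings: dict):
    if isinstance(term, str) and term.startswith("?"):
        return bindings.get(term, _UNBOUND)
    return term


def _compare(op: str, x: float, y: float) -> bool:
    if op == "lessThanOrEqual":
        return x <= y
    if op == "greaterThan":
        return x > y
    if op == "greaterThanOrEqual":
        return x >= y
    if op == "lessThan":
        return x < y
    if op == "equal":
        return x == y
    raise ValueError(f"unsupported builtin swrlb:{op}")


def rule_fires(
    rule: SWRLRule,
    record: SubjectRecord,
    assertions: Mapping | None = None,
    property_map: Mapping[str, str] | None = None,
) -> tuple[bool, dict]:
    """Evaluate one rule's antecedent against a record plus prior assertions.

    Returns ``(fired, bindings)``.  Open-world contract: an unbound property
    (a missing score, an absent prediction) makes the rule silently not
    fire; no negative fact is ever produced.

    ``assertions`` may carry ``"props"`` (property name -> value, e.g. the
    asserted sum or gold label), ``"preds"`` (tree index -> vote) and
    ``"labels"`` (set of asserted class names).
    """
    a = assertions or {}
    props: Mapping = a.get("props", {})
    preds: Mapping = a.get("preds", {})
    labels = a.get("labels", set())
    pm = property_map or {}
    bindings: dict = {}

    def bind_or_check(var_or_const, value) -> bool:
        if isinstance(var_or_const, str) and var_or_const.startswith("?"):
            current = bindings.get(var_or_const, _UNBOUND)
            if current is _UNBOUND:
                bindings[var_or_const] = value
                return True
            return current == value
        return var_or_const == value

    for atom in rule.antecedent:
        if atom.kind == "class":
            if not bind_or_check(atom.args[0], record.subject_id):
                return False, {}
        elif atom.kind == "label":
            if atom.name not in labels:
                return False, {}
        elif atom.kind in ("property", "sum", "state"):
            name = atom.name
            if name in props:
                value = props[name]
            elif name in pm and pm[name] in record.scores:
                value = record.scores[pm[name]]
            else:
                return False, {}  # unbound property: silent, not false
            subj, obj = atom.args
            if not bind_or_check(obj, value):
                return False, {}
        elif atom.kind == "prediction":
            idx = atom.pred_index
            if idx not in preds:
                return False, {}
            if not bind_or_check(atom.args[1], preds[idx]):
                return False, {}
        elif atom.kind == "builtin":
            values = [_resolve(arg, bindings) for arg in atom.args]
            if atom.name == "add":
                if any(v is _UNBOUND for v in values[1:]):
                    return False, {}
                if not bind_or_check(atom.args[0], sum(values[1:])):
                    return False, {}
            else:
                if any(v is _UNBOUND for v in values):
                    return False, {}
                if not _compare(atom.name, *values):
                    return False, {}
        else:  # pragma: no cover
            raise ValueError(f"unknown atom kind {atom.kind!r}")
    return True, bindings


def infer_votes(program: RuleProgram, record: SubjectRecord) -> list[TreeVote]:
    """Run every tree's leaf rules on a record; blocked trees stay inactive."""
    if record.battery_id is not None and record.battery_id != program.battery_id:
        raise BatteryMismatchError(
            f"record belongs to battery {record.battery_id!r}, program to "
            f"{program.battery_id!r}"
        )
    votes: list[TreeVote] = []
    for i in sorted(program.leaf_rules):
        vote = TreeVote(i, INACTIVE, None)
        for rule in program.leaf_rules[i]:
            fired, _ = rule_fires(rule, record, property_map=program.property_map)
            if fired:
                vote = TreeVote(i, int(rule.consequent.args[1]), rule.rule_id)
                break
        votes.append(vote)
    return votes


def diagnose(
    votes: Sequence[TreeVote],
    th: int,
    n_trees: int,
    subject_id: str = "",
    evaluation_index: int = 1,
) -> DiagnosisResult:
    """Turn per-tree votes into a diagnosis under the conclusiveness contract.

    * all trees active: automatic; MCI iff the sum reaches ``th``;
    * some active: partial; conclusive MCI if the partial sum already
      reaches ``th``, otherwise a non-conclusive (preliminary) Healthy;
    * none active: no_data, Undetermined.
    """
    votes = list(votes)
    if len(votes) != n_trees:
        raise ValueError(f"expected {n_trees} votes, got {len(votes)}")
    active = [v for v in votes if v.vote is not INACTIVE]
    n_active = len(active)
    vote_sum = sum(v.vote for v in active)
    trace = [v.fired_rule_id for v in votes if v.fired_rule_id is not None]
    if n_active == 0:
        status, label, conclusive = "no_data", "Undetermined", False
    elif n_active == n_trees:
        status = "automatic"
        label = "MCI" if vote_sum >= th else "Healthy"
        conclusive = True
    else:
        status = "partial"
        if vote_sum >= th:
            label, conclusive = "MCI", True
        else:
            label, conclusive = "Healthy", False
    return DiagnosisResult(
        subject_id=subject_id,
        evaluation_index=evaluation_index,
        votes=votes,
        n_active=n_active,
        vote_sum=vote_sum,
        status=status,
        label=label,
        conclusive=conclusive,
        trace=trace,
    )


def evaluate_record(program: RuleProgram, record: SubjectRecord) -> DiagnosisResult:
    """Full per-case evaluation: leaf rules, aggregation/diagnosis, optional
    confusion bookkeeping and state annotations."""
    votes = infer_votes(program, record)
    result = diagnose(
        votes,
        program.threshold,
        program.n_trees,
        subject_id=record.subject_id,
        evaluation_index=record.evaluation_index,
    )
    result.scores = dict(record.scores)

    if result.status == "automatic":
        # replay the aggregation and diagnosis rules through the engine so the
        # trace reflects actual rule firings, and check them against the
        # arithmetic the votes imply
        assertions = {"props": {}, "preds": {v.tree_index: v.vote for v in votes}}
        fired, bindings = rule_fires(
            program.aggregation_rule, record, assertions, program.property_map
        )
        if not fired or bindings.get("?s") != result.vote_sum:  # pragma: no cover
            raise RuntimeError("aggregation rule disagrees with summed votes")
        assertions["props"]["sum"] = result.vote_sum
        result.trace.append(program.aggregation_rule.rule_id)
        fired_labels = []
        for rule in program.diagnosis_rules:
            fired, _ = rule_fires(rule, record, assertions, program.property_map)
            if fired:
                fired_labels.append(rule)
        if len(fired_labels) != 1:  # pragma: no cover
            raise RuntimeError("diagnosis rules must fire exactly once")
        diag_rule = fired_labels[0]
        if diag_rule.consequent.name != result.label:  # pragma: no cover
            raise RuntimeError("diagnosis rule disagrees with vote arithmetic")
        result.trace.append(diag_rule.rule_id)

    if (
        program.confusion_rules
        and record.gold_label is not None
        and result.label in ("Healthy", "MCI")
    ):
        assertions = {
            "props": {GOLD_PROPERTY: record.gold_label},
            "labels": {result.label},
        }
        for rule in program.confusion_rules:
            fired, _ = rule_fires(rule, record, assertions, program.property_map)
            if fired:
                result.confusion_class = rule.consequent.name
                break

    for rule in program.annotation_rules:
        fired, _ = rule_fires(rule, record, property_map=program.property_map)
        if fired:
            result.annotations.append(
                (rule.consequent.name, str(rule.consequent.args[1]))
            )
    return result


def classify_batch(
    program: RuleProgram, records: Iterable[SubjectRecord]
) -> tuple[list[DiagnosisResult], BatchSummary]:
    """Classify records independently; batch composition cannot change any
    individual result (monotonicity)."""
    results = [evaluate_record(program, r) for r in records]
    summary = BatchSummary(n_cases=len(results))
    for r in results:
        if r.status == "automatic":
            summary.n_automatic += 1
            if r.label == "MCI":
                summary.n_automatic_mci += 1
            else:
                summary.n_automatic_healthy += 1
        elif r.status == "partial":
            summary.n_partial += 1
            if r.conclusive:
                summary.n_partial_conclusive_mci += 1
            else:
                summary.n_partial_inconclusive_healthy += 1
        else:
            summary.n_no_data += 1
    return results, summary


# ---------------------------------------------------------------------------
# explanation
# ---------------------------------------------------------------------------

def _rule_by_id(program: RuleProgram, rule_id: str) -> SWRLRule:
    for rule in program.all_rules():
        if rule.rule_id == rule_id:
            return rule
    raise KeyError(rule_id)


def explain(result: DiagnosisResult, program: RuleProgram) -> str:
    """Human-readable justification: every fired rule with the case's values."""
    inv = {v: k for k, v in program.property_map.items()}
    lines = [
        f"Case {result.subject_id} (evaluation {result.evaluation_index}): "
        f"{result.label} [{result.status}"
        f"{'' if result.conclusive else ', not conclusive'}]"
    ]
    if result.status == "no_data":
        lines.append("  no scores present: zero rules fired, no classification possible")
        return "\n".join(lines)
    for rule_id in result.trace:
        rule = _rule_by_id(program, rule_id)
        lines.append(f"  {rule_id}: {render_swrl(rule)}")
        if rule_id.startswith("T"):
            for atom in rule.antecedent:
                if atom.kind == "property":
                    test_id = program.property_map.get(atom.name)
                    if test_id in result.scores:
                        lines.append(
                            f"    {atom.name} = {result.scores[test_id]:g}"
                        )
    inactive = [v.tree_index for v in result.votes if v.fired_rule_id is None]
    if inactive:
        lines.append(
            "  trees not activated (missing scores): "
            + ", ".join(f"#{i}" for i in inactive)
        )
    lines.append(f"  vote sum over {result.n_active} active trees = {result.vote_sum}")
    if result.status == "partial":
        if result.conclusive:
            lines.append(
                f"  partial sum already reaches threshold {program.threshold}: "
                "conclusive MCI"
            )
        else:
            lines.append(
                f"  partial sum below threshold {program.threshold}: preliminary, "
                "non-conclusive Healthy"
            )
    for prop, state in result.annotations:
        lines.append(f"  annotation: {prop} = \"{state}\"")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------

def results_to_dataframe(results: Sequence[DiagnosisResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject_id,
                "evaluation_index": r.evaluation_index,
                "votes": ";".join(
                    "-" if v.vote is INACTIVE else str(v.vote) for v in r.votes
                ),
                "n_active": r.n_active,
                "vote_sum": r.vote_sum,
                "status": r.status,
                "label": r.label,
                "conclusive": r.conclusive,
                "confusion_class": r.confusion_class or "",
                "annotations": ";".join(f"{p}={s}" for p, s in r.annotations),
                "trace": ";".join(r.trace),
            }
        )
    return pd.DataFrame(rows)


def write_results(
    results: Sequence[DiagnosisResult], path: str | Path, fmt: str = "csv"
) -> None:
    """Write per-case results as CSV or JSON lines."""
    path = Path(path)
    df = results_to_dataframe(results)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for row in df.to_dict(orient="records"):
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown results format {fmt!r}")
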