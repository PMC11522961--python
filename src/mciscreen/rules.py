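"""Compile trained trees and the surrounding decision logic into SWRL-style rules.

Each leaf of each tree becomes one Horn rule: the root-to-leaf comparisons
form the antecedent and the leaf class becomes a per-tree prediction
assertion (``pred_i(?p, 0|1)``).  Because the rule language is monotonic —
facts are asserted, never retracted — the ensemble cannot be aggregated by
counting; instead a single rule with the n-ary ``swrlb:add`` builtin sums
the per-tree predictions once every tree has spoken, and two diagnosis
rules partition the possible sums at the decision threshold.  Optional rule
families cover confusion-matrix bookkeeping (TP/FP/TN/FN classes, for
evaluating the rule system in place) and domain annotations that flag
impaired cognitive states from single test cutoffs, independent of the
diagnosis.

The renderer emits the human-readable SWRLTab dialect (atoms joined by
`` ^ ``, implication `` - > ``, builtins namespaced ``swrlb:``) and the
parser accepts it back, so a rule program round-trips through text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ensemble import DecisionTreeModel, EnsembleModel
from .schema import BatterySchema

__all__ = [
    "LABEL_CLASSES",
    "GOLD_PROPERTY",
    "SUBJECT_VAR",
    "RuleAtom",
    "SWRLRule",
    "RuleProgram",
    "AnnotationMapping",
    "compile_tree",
    "compile_aggregation",
    "compile_diagnosis",
    "compile_confusion",
    "compile_annotation_rules",
    "compile_program",
    "render_swrl",
    "render_program",
    "parse_rule",
    "parse_swrl",
    "program_to_json",
    "program_from_json",
]

#: Class names a rule may assert about a subject.
LABEL_CLASSES = ("MCI", "Healthy", "TP_Scores", "FP_Scores", "TN_Scores", "FN_Scores")

#: Data property holding the clinical gold label for confusion rules.
GOLD_PROPERTY = "has_gold_label"

SUBJECT_VAR = "?p"
SUM_PROPERTY = "sum"

_COMPARISONS = {"lessThanOrEqual", "greaterThan", "greaterThanOrEqual", "lessThan", "equal"}
_BUILTINS = _COMPARISONS | {"add"}


@dataclass(frozen=True)
class RuleAtom:
    """One atom of a rule.

    ``kind`` is one of ``class`` (OWL class membership test/assertion of the
    Subject class), ``property`` (data property), ``builtin`` (``swrlb:``
    comparison or ``add``), ``prediction`` (per-tree vote property
    ``pred_i``), ``sum`` (the vote-sum property), ``label`` (diagnosis or
    confusion class) or ``state`` (annotation data property).  ``args``
    holds variables (strings starting with ``?``), numbers, or plain strings
    (rendered as quoted literals).
    """

    kind: str
    name: str
    args: tuple = ()

    def __post_init__(self) -> None:
        if self.kind == "label" and self.name not in LABEL_CLASSES:
            raise ValueError(f"unknown label class {self.name!r}")
        if self.kind == "builtin" and self.name not in _BUILTINS:
            raise ValueError(f"unsupported builtin swrlb:{self.name}")

    @property
    def pred_index(self) -> int:
        if self.kind != "prediction":
            raise ValueError("not a prediction atom")
        return int(self.name.split("_", 1)[1])


@dataclass(frozen=True)
class SWRLRule:
    """A Horn rule: ordered antecedent atoms and a single consequent."""

    rule_id: str
    antecedent: tuple[RuleAtom, ...]
    consequent: RuleAtom

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", tuple(self.antecedent))
        bound = _bound_vars(self.antecedent)
        for a in _vars_of(self.consequent):
            if a not in bound:
                raise ValueError(
                    f"rule {self.rule_id}: consequent variable {a} never bound"
                )


def _vars_of(atom: RuleAtom) -> list[str]:
    return [a for a in atom.args if isinstance(a, str) and a.startswith("?")]


def _bound_vars(atoms: Iterable[RuleAtom]) -> set[str]:
    bound: set[str] = set()
    for atom in atoms:
        bound.update(_vars_of(atom))
    return bound


@dataclass(frozen=True)
class AnnotationMapping:
    """One literature-derived cutoff linking a test to a cognitive state."""

    test_id: str
    cutoff: float
    direction: str  # "le": impaired when score <= cutoff; "ge": when >= cutoff
    state_property: str  # e.g. "has_semantic_memory_state"
    state_text: str  # e.g. "impaired"

    def __post_init__(self) -> None:
        if self.direction not in ("le", "ge"):
            raise ValueError(f"direction must be 'le' or 'ge', got {self.direction!r}")


@dataclass
class RuleProgram:
    """All rule families for one battery, plus what the engine needs to run them."""

    battery_id: str
    n_trees: int
    threshold: int
    leaf_rules: dict[int, list[SWRLRule]]
    aggregation_rule: SWRLRule
    diagnosis_rules: tuple[SWRLRule, SWRLRule]
    confusion_rules: tuple[SWRLRule, ...] = ()
    annotation_rules: tuple[SWRLRule, ...] = ()
    property_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.leaf_rules) != list(range(self.n_trees)):
            raise ValueError("leaf_rules must cover tree indices 0..n_trees-1")
        if not 1 <= self.threshold <= self.n_trees:
            raise ValueError(
                f"threshold must be in [1, {self.n_trees}], got {self.threshold}"
            )
        agg_preds = {
            a.pred_index for a in self.aggregation_rule.antecedent
            if a.kind == "prediction"
        }
        if agg_preds != set(range(self.n_trees)):
            raise ValueError("aggregation rule must reference every tree exactly once")

    def all_rules(self) -> list[SWRLRule]:
        out: list[SWRLRule] = []
        for i in sorted(self.leaf_rules):
            out.extend(self.leaf_rules[i])
        out.append(self.aggregation_rule)
        out.extend(self.diagnosis_rules)
        out.extend(self.confusion_rules)
        out.extend(self.annotation_rules)
        return out


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _subject_atom() -> RuleAtom:
    return RuleAtom("class", "Subject", (SUBJECT_VAR,))


class _VarAllocator:
    """Fresh variables per rule: first use ``?CR``, reuse ``?CR2``, ``?CR3``..."""

    def __init__(self) -> None:
        self._counts: dict[str, int] = {}

    def fresh(self, stem: str) -> str:
        n = self._counts.get(stem, 0) + 1
        self._counts[stem] = n
        return f"?{stem}" if n == 1 else f"?{stem}{n}"


def compile_tree(tree: DecisionTreeModel, schema: BatterySchema) -> list[SWRLRule]:
    """One rule per leaf, path conditions in root-to-leaf order.

    Every comparison binds a fresh variable through its own property atom;
    a feature tested twice on a path gets a suffixed variable (?CR, ?CR2)
    rather than a merged interval, mirroring how each tree condition maps
    to exactly one builtin.
    """
    rules: list[SWRLRule] = []
    for ordinal, (conds, leaf) in enumerate(tree.leaves()):
        alloc = _VarAllocator()
        atoms: list[RuleAtom] = [_subject_atom()]
        for test_id, op, threshold in conds:
            t = schema.by_id(test_id)
            var = alloc.fresh(t.var_stem)
            atoms.append(RuleAtom("property", t.property_name, (SUBJECT_VAR, var)))
            atoms.append(RuleAtom("builtin", op, (var, float(threshold))))
        consequent = RuleAtom(
            "prediction",
            f"pred_{tree.tree_index}",
            (SUBJECT_VAR, int(leaf.class_label)),
        )
        rules.append(
            SWRLRule(f"T{tree.tree_index}_L{ordinal}", tuple(atoms), consequent)
        )
    return rules


def compile_aggregation(n_trees: int) -> SWRLRule:
    """The single sum rule: fires only once every tree has predicted.

    Monotonicity rules out a counter, so the n-ary ``swrlb:add`` builtin
    sums all per-tree prediction values in one step.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    atoms: list[RuleAtom] = [_subject_atom()]
    vote_vars = [f"?d{i}" for i in range(n_trees)]
    for i, var in enumerate(vote_vars):
        atoms.append(RuleAtom("prediction", f"pred_{i}", (SUBJECT_VAR, var)))
    atoms.append(RuleAtom("builtin", "add", tuple(["?s"] + vote_vars)))
    consequent = RuleAtom("sum", SUM_PROPERTY, (SUBJECT_VAR, "?s"))
    return SWRLRule("AGG", tuple(atoms), consequent)


def compile_diagnosis(th: int, n_trees: int) -> tuple[SWRLRule, SWRLRule]:
    """The two final-diagnosis rules: MCI when sum >= th, Healthy when sum < th.

    ``th`` is the minimum number of trees that must vote MCI; for any
    asserted sum exactly one of the pair fires.
    """
    if not 1 <= th <= n_trees:
        raise ValueError(f"threshold must be in [1, {n_trees}], got {th}")
    sum_atom = RuleAtom("sum", SUM_PROPERTY, (SUBJECT_VAR, "?s"))
    rule_mci = SWRLRule(
        "DIAG_MCI",
        (
            _subject_atom(),
            sum_atom,
            RuleAtom("builtin", "greaterThanOrEqual", ("?s", int(th))),
        ),
        RuleAtom("label", "MCI", (SUBJECT_VAR,)),
    )
    rule_healthy = SWRLRule(
        "DIAG_HEALTHY",
        (
            _subject_atom(),
            sum_atom,
            RuleAtom("builtin", "lessThan", ("?s", int(th))),
        ),
        RuleAtom("label", "Healthy", (SUBJECT_VAR,)),
    )
    return rule_mci, rule_healthy


def compile_confusion() -> tuple[SWRLRule, SWRLRule, SWRLRule, SWRLRule]:
    """Confusion-matrix rules pairing the inferred label with the gold label."""

    def rule(rule_id: str, label: str, gold: int, target: str) -> SWRLRule:
        return SWRLRule(
            rule_id,
            (
                _subject_atom(),
                RuleAtom("label", label, (SUBJECT_VAR,)),
                RuleAtom("property", GOLD_PROPERTY, (SUBJECT_VAR, gold)),
            ),
            RuleAtom("label", target, (SUBJECT_VAR,)),
        )

    return (
        rule("CONF_TP", "MCI", 1, "TP_Scores"),
        rule("CONF_FN", "Healthy", 1, "FN_Scores"),
        rule("CONF_FP", "MCI", 0, "FP_Scores"),
        rule("CONF_TN", "Healthy", 0, "TN_Scores"),
    )


def compile_annotation_rules(
    mappings: Sequence[AnnotationMapping], schema: BatterySchema
) -> tuple[SWRLRule, ...]:
    """Score-cutoff rules asserting cognitive/brain states, diagnosis-independent."""
    rules: list[SWRLRule] = []
    for k, m in enumerate(mappings):
        t = schema.by_id(m.test_id)  # KeyError for unknown test
        var = f"?{t.var_stem}"
        op = "lessThanOrEqual" if m.direction == "le" else "greaterThanOrEqual"
        rules.append(
            SWRLRule(
                f"ANN{k}_{m.test_id}",
                (
                    _subject_atom(),
                    RuleAtom("property", t.property_name, (SUBJECT_VAR, var)),
                    RuleAtom("builtin", op, (var, float(m.cutoff))),
                ),
                RuleAtom("state", m.state_property, (SUBJECT_VAR, m.state_text)),
            )
        )
    return tuple(rules)


def compile_program(
    model: EnsembleModel,
    schema: BatterySchema,
    include_confusion: bool = False,
    annotations: Sequence[AnnotationMapping] = (),
) -> RuleProgram:
    """Compile a trained ensemble into a complete rule program for its battery."""
    if model.battery_id != schema.battery_id:
        raise ValueError(
            f"model battery {model.battery_id!r} does not match schema "
            f"battery {schema.battery_id!r}"
        )
    leaf_rules = {t.tree_index: compile_tree(t, schema) for t in model.trees}
    return RuleProgram(
        battery_id=model.battery_id,
        n_trees=model.n_trees,
        threshold=model.threshold,
        leaf_rules=leaf_rules,
        aggregation_rule=compile_aggregation(model.n_trees),
        diagnosis_rules=compile_diagnosis(model.threshold, model.n_trees),
        confusion_rules=compile_confusion() if include_confusion else (),
        annotation_rules=compile_annotation_rules(annotations, schema),
        property_map=schema.property_map,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt_number(v: float) -> str:
    return f"{float(v):g}"


def _fmt_arg(arg: object) -> str:
    if isinstance(arg, str):
        return arg if arg.startswith("?") else f'"{arg}"'
    if isinstance(arg, bool):
        return str(int(arg))
    if isinstance(arg, int):
        return str(arg)
    return _fmt_number(arg)


def _render_atom(atom: RuleAtom) -> str:
    args = ", ".join(_fmt_arg(a) for a in atom.args)
    if atom.kind == "builtin":
        return f"swrlb:{atom.name} ({args})"
    if atom.kind in ("property", "sum", "state"):
        # data-property atoms carry a space before the argument list,
        # class/prediction atoms do not (SWRLTab typography)
        return f"{atom.name} ({args})"
    return f"{atom.name}({args})"


def render_swrl(rule: SWRLRule) -> str:
    """Render one rule in the human-readable SWRLTab dialect."""
    body = " ^ ".join(_render_atom(a) for a in rule.antecedent)
    return f"{body} - > {_render_atom(rule.consequent)}"


def render_program(program: RuleProgram) -> str:
    """Render all rule families, one rule per line, ids as comments."""
    lines = [
        f"# battery: {program.battery_id}",
        f"# n_trees: {program.n_trees}",
        f"# threshold: {program.threshold}",
    ]
    for rule in program.all_rules():
        lines.append(f"# {rule.rule_id}")
        lines.append(render_swrl(rule))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parsing (round-trip of the rendered dialect)
# ---------------------------------------------------------------------------

_ATOM_RE = re.compile(r"^(swrlb:)?([A-Za-z_][A-Za-z0-9_]*)\s*\(([^)]*)\)$")


def _parse_arg(token: str):
    token = token.strip()
    if token.startswith("?"):
        return token
    if token.startswith('"') and token.endswith('"'):
        return token[1:-1]
    value = float(token)
    return int(value) if value == int(value) else value


def _parse_atom(text: str) -> RuleAtom:
    m = _ATOM_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse atom {text!r}")
    is_builtin, name, argtext = m.group(1), m.group(2), m.group(3)
    args = tuple(_parse_arg(t) for t in argtext.split(",") if t.strip())
    if is_builtin:
        return RuleAtom("builtin", name, args)
    if name == "Subject":
        return RuleAtom("class", name, args)
    if re.fullmatch(r"pred_\d+", name):
        return RuleAtom("prediction", name, args)
    if name == SUM_PROPERTY:
        return RuleAtom("sum", name, args)
    if name in LABEL_CLASSES:
        return RuleAtom("label", name, args)
    if name.endswith("_state"):
        return RuleAtom("state", name, args)
    return RuleAtom("property", name, args)


def parse_rule(text: str, rule_id: str = "R") -> SWRLRule:
    """Parse one rendered rule; accepts both ``- >`` and ``->`` implications."""
    text = text.strip().rstrip(".").strip()
    normalized = text.replace(" - > ", " -> ")
    if " -> " not in normalized:
        raise ValueError(f"rule has no implication: {text!r}")
    body, head = normalized.split(" -> ", 1)
    antecedent = tuple(_parse_atom(part) for part in body.split("^"))
    return SWRLRule(rule_id, antecedent, _parse_atom(head))


def parse_swrl(text: str) -> list[SWRLRule]:
    """Parse a rule file: one rule per line, ``# <id>`` comments name rules."""
    rules: list[SWRLRule] = []
    pending_id: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            comment = line.lstrip("#").strip()
            if comment and ":" not in comment and " " not in comment:
                pending_id = comment
            continue
        rules.append(parse_rule(line, rule_id=pending_id or f"R{len(rules)}"))
        pending_id = None
    return rules


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _atom_to_dict(atom: RuleAtom) -> dict:
    return {"kind": atom.kind, "name": atom.name, "args": list(atom.args)}


def _atom_from_dict(d: Mapping) -> RuleAtom:
    return RuleAtom(d["kind"], d["name"], tuple(d["args"]))


def _rule_to_dict(rule: SWRLRule) -> dict:
    return {
        "rule_id": rule.rule_id,
        "antecedent": [_atom_to_dict(a) for a in rule.antecedent],
        "consequent": _atom_to_dict(rule.consequent),
    }


def _rule_from_dict(d: Mapping) -> SWRLRule:
    return SWRLRule(
        d["rule_id"],
        tuple(_atom_from_dict(a) for a in d["antecedent"]),
        _atom_from_dict(d["consequent"]),
    )


def program_to_json(program: RuleProgram) -> str:
    doc = {
        "battery_id": program.battery_id,
        "n_trees": program.n_trees,
        "threshold": program.threshold,
        "leaf_rules": {
            str(i): [_rule_to_dict(r) for r in program.leaf_rules[i]]
            for i in sorted(program.leaf_rules)
        },
        "aggregation_rule": _rule_to_dict(program.aggregation_rule),
        "diagnosis_rules": [_rule_to_dict(r) for r in program.diagnosis_rules],
        "confusion_rules": [_rule_to_dict(r) for r in program.confusion_rules],
        "annotation_rules": [_rule_to_dict(r) for r in program.annotation_rules],
        "property_map": program.property_map,
    }
    return json.dumps(doc, indent=2) + "\n"


def program_from_json(text: str) -> RuleProgram:
    doc = json.loads(text)
    diag = [_rule_from_dict(r) for r in doc["diagnosis_rules"]]
    return RuleProgram(
        battery_id=doc["battery_id"],
        n_trees=int(doc["n_trees"]),
        threshold=int(doc["threshold"]),
        leaf_rules={
            int(i): [_rule_from_dict(r) for r in rules]
            for i, rules in doc["leaf_rules"].items()
        },
        aggregation_rule=_rule_from_dict(doc["aggregation_rule"]),
        diagnosis_rules=(diag[0], diag[1]),
        confusion_rules=tuple(_rule_from_dict(r) for r in doc["confusion_rules"]),
        annotation_rules=tuple(_rule_from_dict(r) for r in doc["annotation_rules"]),
        property_map=dict(doc["property_map"]),
    )
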