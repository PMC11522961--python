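# mciscreen

Explainable decision support for population screening of **Mild Cognitive
Impairment (MCI)** from neuropsychological test batteries.

Population screenings produce large volumes of test protocols that must be
reviewed case by case, and real screening data are messy: subjects refuse
individual tests, some assessments are administered late, and some records
carry nothing but an identifier. `mciscreen` is built for exactly that
setting. It trains a small, fully inspectable classifier, compiles it into
declarative rules, and classifies new cases with an inference engine that
degrades gracefully under missing data instead of deleting or imputing
records — every diagnosis comes with the complete chain of rules that
produced it, so a neuropsychologist can audit any decision.

## The model

1. **Bagged tree ensemble.** An odd number of shallow CART decision trees
   (default 11, depth ≤ 4) is trained on bootstrap resamples (default 25%
   of the training split, drawn with replacement). Each tree votes 0
   (Healthy) or 1 (MCI); the ensemble score is the vote sum
   *s* ∈ {0, …, *n*}.

2. **Rule compilation.** Every leaf of every tree becomes one Horn rule in
   the human-readable SWRL dialect, e.g.

   ```
   Subject(?p) ^ has_praxias_score (?p, ?PC) ^ swrlb:lessThanOrEqual (?PC, 9.5)
     ^ has_Rey_complex_figure_score (?p, ?CR) ^ swrlb:lessThanOrEqual (?CR, 24.5)
     ^ has_Trail_Making_test_A_score (?p, ?TMA) ^ swrlb:greaterThan (?TMA, 32.5)
     ^ has_Rey_complex_figure_score (?p, ?CR2) ^ swrlb:greaterThan (?CR2, 14.75)
     - > pred_10(?p, 1)
   ```

   The rule language is monotonic (facts are asserted, never retracted), so
   the ensemble is aggregated not by counting but by a single rule with the
   n-ary `swrlb:add` builtin, which fires once every tree has predicted;
   two diagnosis rules then partition the possible sums at the decision
   threshold *th*: **MCI ⟺ s ≥ th**.

3. **Threshold selection.** Each *th* ∈ {1, …, *n*} is an operating point.
   For screening, *th* is chosen to maximise the **F2 score**
   Fβ = (1+β²)·P·R / (β²·P + R) with β = 2, weighting recall (missed MCI
   cases) four times precision while still penalising the trivial
   everyone-is-MCI classifier.

4. **Open-world inference over missing data.** A rule whose antecedent needs
   an absent score is silently inactive — absence is never evidence. Per
   case this yields an **automatic** diagnosis (all trees active), a
   **partial** one (the engine sums the active votes; conclusive only if the
   partial sum already reaches *th* — a below-threshold "Healthy" from
   partial information is explicitly flagged as preliminary), or
   **no data** (score-less record, label Undetermined).

A battery schema (per-test valid ranges and ontology-style property names)
stands in for the ontology layer: it standardises column names, rejects
out-of-range values, and never imputes. Several batteries can coexist; a
rule program only ever consumes records of its own battery.

## Worked example

```python
import mciscreen as m

config = m.CohortConfig(seed=1)                      # n=600, 40% MCI, 8 tests
schema, records, gold = m.generate_cohort(config)
train, test = m.split_train_test(records, 0.8, seed=1)
model = m.train_ensemble(train, schema, m.EnsembleConfig(seed=1))

sums = [sum(v for v in m.ensemble_votes(model, r) if v is not None) for r in train]
curves = m.threshold_curves(sums, [r.gold_label for r in train], model.n_trees)
model.threshold = m.select_threshold(curves, beta=2.0)
print("F2-selected threshold:", model.threshold)

program = m.compile_program(model, schema)
results, summary = m.classify_batch(program, test)
report = m.compute_report(results, [r.gold_label for r in test],
                          threshold=model.threshold)
print(report.to_text())
```

prints

```
F2-selected threshold: 3
cases evaluated : 120 (automatic_only)
threshold (th)  : 3
TP/FP/TN/FN     : 46/17/55/2
accuracy        : 0.842
precision       : 0.730
recall          : 0.958
F1              : 0.829
F2              : 0.902
ROC-AUC         : 0.954
```

Of the 11-tree votes, 3 MCI votes suffice here to flag a case: the
F2-driven threshold trades precision (0.730) for recall (0.958) — on this
held-out set only 2 of 48 MCI cases are missed, at the cost of 17 healthy
subjects flagged for expert review, which is the right trade for a first
screening filter. `m.explain(results[0], program)` prints the full
rule-firing trace behind any single diagnosis.

The same pipeline is available from the shell:

```
mciscreen simulate --out work --n 600 --seed 1
mciscreen train    --schema work/schema.csv --cases work/cases.csv --out work/model.json --seed 1
mciscreen compile  --model work/model.json --schema work/schema.csv --out work/program.json
mciscreen classify --program work/program.json --schema work/schema.csv \
                   --cases work/cases.csv --out work/results.csv
mciscreen export-swrl --program work/program.json --out work/rules.swrl
```

plus `evaluate`, `curves` and `explain` subcommands.

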