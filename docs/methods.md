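# Methods

## Model and procedure

`mciscreen` implements a three-stage screening pipeline: (1) battery-schema
validation of case records, (2) training of a bagged decision-tree ensemble
and its compilation into monotonic SWRL-style rules, (3) forward-chaining
inference over new cases under the open-world assumption.

**Classifier.** The classifier is bootstrap aggregation over an odd number
of shallow CART trees. From the labeled records, a stratified 80/20
train/test partition is drawn; each tree is trained on a with-replacement
resample of 25% of the training split (all resamples the same size). Votes
are the numeric class codes (Healthy = 0, MCI = 1) so they can be summed;
the case-level score is the vote sum s, and the final label is MCI exactly
when s ≥ th. The odd tree count makes majority voting tie-free; th itself
is a tunable screening knob, not fixed at majority.

**Tree induction.** CART with Gini impurity, axis-aligned `<=` splits at
midpoints between consecutive observed values, default depth ≤ 4 and ≥ 5
cases per leaf. Shallow depth is a design constraint, not an optimisation:
every leaf must remain a readable conjunction of at most four comparisons.
Missing values are handled without imputation at every stage:

* during induction, each candidate split is scored on the cases where its
  feature is present, and the Gini gain is scaled by the complete-case
  fraction at the node so sparsely observed features must earn their keep;
  cases missing the chosen split feature are set aside at that node (no
  surrogate splits);
* at prediction time a tree abstains (`INACTIVE`) as soon as its traversed
  path needs an absent score; a missing feature on the untaken branch is
  irrelevant.

Deterministic tie-breaks: equal-gain splits resolve to the lower feature
index then the lower threshold; a tied leaf (equal class counts) predicts
Healthy, on the principle that a single ambiguous leaf should not flag MCI —
that is the ensemble's job. Ties at a split threshold go left
(`lessThanOrEqual`), matching the rendered builtin.

**Rule compilation.** Each leaf compiles to one Horn rule: a `Subject(?p)`
class atom, then one data-property atom plus one comparison builtin per
path condition in root-to-leaf order; a feature tested twice on a path gets
a fresh suffixed variable (`?CR`, `?CR2`) rather than a merged interval, so
the rendered rule is a literal transcript of the tree path. The rule
language is monotonic — deductive, no retraction, no revision — which
forbids counter-style aggregation; the ensemble is instead aggregated by a
single rule whose antecedent contains every tree's prediction atom and one
n-ary `swrlb:add`, and which therefore cannot fire until all trees have
predicted. Two diagnosis rules partition the asserted sums at th. Optional
families: four confusion-matrix rules (pairing the inferred label with a
`has_gold_label` assertion — the gold-label property name is this package's
choice) and annotation rules that assert impaired cognitive states from
single-test cutoffs, independent of the diagnosis. Cutoff mappings are
user-supplied configuration, since such norms are battery- and
population-specific.

**Variable naming.** SWRL variable stems are conventional test
abbreviations, which are not mechanically derivable from any single
identifier; the schema therefore carries an optional per-test `var_name`,
with a fallback that takes the initials of the column-name tokens.

**Inference engine.** Fixed two-phase evaluation (all leaf rules, then
aggregation/diagnosis) rather than a general RETE network: the rule
families are stratified by construction, so the fixed order is complete.
For automatic cases the aggregation and diagnosis rules are genuinely
replayed through the generic rule evaluator (and cross-checked against the
vote arithmetic) so the recorded trace reflects actual rule firings. For
partial cases the engine computes the active-vote sum itself — outside the
rule semantics, which cannot sum an incomplete prediction set — and keeps
the caution visible: conclusive only when the partial sum already reaches
th, since activating further trees can only add 0 or 1 votes. Batch
summaries count conclusive-partial MCI separately from automatic MCI for
the same reason.

**Threshold selection and metrics.** Every th in 0..n_trees defines one
operating point of the vote-sum classifier; th = 0 (everyone MCI, recall
exactly 1) is kept on the curves but never selectable. Selection maximises
F-beta over th ≥ 1 with ties to the lowest threshold; the default beta = 2
weights recall four times precision, appropriate when a missed MCI case
costs more than a reviewable false positive. An alternative criterion
returns the minimum threshold maximising recall. ROC-AUC uses the integer
vote sum as score (rank-based, midrank ties); partial-status cases are
excluded from curves and AUC because sums over differing numbers of active
trees are not comparable. Metrics default to automatic diagnoses only;
`all_conclusive` additionally includes conclusive-partial MCI cases, and
the report states which policy was used.

## Synthetic cohorts

No public screening cohort ships with the package, so all tests and the
acceptance script run on generated data emulating the structure such
cohorts have. Per class (prevalence exact by construction:
`round(prevalence * n)` MCI labels), scores follow a one-factor Gaussian
model: a latent cognitive factor loads on every test (default loading 0.3,
sign-flipped for tests where higher is worse, e.g. timed trail-making),
plus independent noise; values are truncated to each test's valid range and
rounded to integers by default (continuous mode exists for
induction-oracle tests). Demographics are drawn uniformly from a screening
population: age 58–93 years, education 0–22 years, coded sex.
The default battery is eight illustrative tests (MMSE-like global score,
semantic fluency, figure copy, trail-making A, digit span, word-list
recall, clock drawing, naming) with plausible ranges and a standardized
healthy-vs-MCI shift of 1.2 SD per test — a separation at which screening
is achievable but imperfect, i.e. the reference conditions for the
package's end-to-end checks (n = 600, prevalence 0.4).

Missingness is MCAR: each score is removed independently with a fixed
rate, and a configurable fraction of records is emptied entirely
(identifier, evaluation number and sex retained) to emulate enrolled
subjects who never reached testing.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: informative missingness (refusal correlating
with impairment), test-specific non-Gaussian score shapes (ceiling effects
beyond simple truncation), repeated evaluations of the same subject
(every generated record is independent), age/education effects on scores,
and realistic inter-test correlation structure beyond a single factor.
Held-out recall on the default cohort is a property of these synthetic
conditions, not a clinical performance claim.

## Numerical choices and degenerate inputs

* Split search requires a strictly positive Gini gain (> 1e-12); otherwise
  the node becomes a leaf. Pure nodes, nodes below 2·min_leaf cases, and
  max-depth nodes are leaves.
* F-beta is defined as 0 when precision = recall = 0; curve points with no
  predicted positives (precision) or single-class gold (recall) are NaN and
  reported as undefined thresholds; threshold selection treats NaN as
  -infinity.
* Record validation accepts "", "NA", "N/A", "NaN", "none", "null"
  (case-insensitive) as missing; strict mode rejects a record with any
  violation, lenient mode drops only the offending scores. Validation is
  idempotent and never imputes.
* Stratified splitting falls back to unstratified when the minority class
  has fewer than 2 members (only reachable on toy inputs).
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical inputs give byte-identical serialized models and
  rendered rule programs.

## Problem sizes

Default suites run on cohorts of 200–1,000 records. The engine-vs-traversal
equivalence check uses 1,000 complete records × 11 trees; end-to-end recall
is averaged over 10 seeds at n = 600. These sizes give stable statistics
(binomial SE on recall at n≈48 positives ≈ 0.03, averaged over seeds) while
keeping the full pipeline fast on one CPU.

## Known limitations

* The rule engine covers exactly the generated rule families (leaf,
  aggregation, diagnosis, confusion, annotation); it is not a general OWL-DL
  reasoner, does not emit OWL/XML or RDF, and has no negation.
* Induction is plain CART: no pruning, surrogate splits, oblique splits, or
  probability calibration; leaf `probability` is the raw class-1 training
  fraction.
* MCAR missingness in the generator understates the difficulty of real
  screening gaps, which are plausibly informative.
* ROC-AUC from an 11-tree vote sum has only 13 operating points; it is
  coarser than a continuous-score AUC.
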