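# Methods

This note documents the modelling and engineering decisions behind
`firearm_intent`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical
conventions used throughout.

## Problem setting

One *case* is one firearm-injury encounter, represented by one or more
free-text notes (ED note, progress note, discharge summary). The target is
a five-way intent label — accident, assault, legal intervention, self-harm,
unknown — where *unknown* covers both undetermined and credibly conflicting
circumstances. The pipeline's central design constraint is that the unknown
class is defined by the *absence* of information, so the feature set must
measure how much intent-relevant content a chart holds, not only what it
says.

## Text processing

**Tokenization.** One tokenizer is shared by every stage (lexicon matching,
candidate-term scoring, context triggers, the pattern parser): case-folded,
whitespace-split, punctuation emitted as single-character tokens. Matching
semantics are therefore identical wherever a surface form is compared.

**Sections and sentences.** Notes are tiled into sections at configured
`HEADER:` markers; text before the first header is the `preamble` section.
Sentences end at `.`, `!`, `?` followed by whitespace and a capital, with a
small abbreviation guard list, and always at newlines (clinical notes are
heavily line-structured). Segmentation is exhaustive and non-overlapping by
construction, so every term mention has exactly one section.

**Lexicon matching.** Greedy longest-match, left to right, over 1–5-token
surfaces; at equal length the category registry order breaks ties.
Confusion terms are matched in a first pass; any informative match whose
span is fully contained in a confusion span is suppressed. Confusion
matches themselves are kept for audit output but never become mentions, so
they carry no signal downstream. Suppression is deliberately
containment-based (not overlap-based): a term extending beyond the
confusion span still counts.

**Context modifiers.** Negation and non-patient-subject triggers scope
forward over a window of 6 tokens (configurable) within the sentence;
history triggers scope in both directions because clinical style places
"years ago" after the condition. A scope terminator (`but`, `;`,
`however`) between trigger and term cancels the modifier. Scopes never
cross sentence boundaries; this sacrifices some recall for testability and
matches common clinical-negation practice.

**Candidate-term scoring.** New lexicon candidates are ranked by an
intent-specificity ratio: the fraction of an intent's cases containing the
n-gram divided by the fraction of all cases containing it. A term unique to
a class that is 10% of the corpus scores 10; a uniformly spread term scores
1. Terms in fewer than 3 cases are dropped by default — the ranked list is
meant for human curation, and singletons are noise at the corpus sizes this
tool targets.

## Dependency roles

Role extraction consumes labelled arcs (`nsubj`, `nsubjpass`/`nsubj:pass`,
`obj`/`dobj`, `agent`/`obl:agent`, `advmod`, `obl`/`prep`, `pobj`) from any
parser provider (a callable `tokens → ParsedSentence`). Active voice: the
subject of a shooting verb is the shooter, the object the person shot.
Passive voice, which dominates clinical narratives ("pt was shot by …"),
flips the roles: the passive subject is the person shot and the by-agent
the shooter. A reflexive person shot with a shooter present flags the event
self-directed. Circumstance phrases are adverbial modifiers and
prepositional subtrees, capped at 8 tokens.

Two providers ship: a deterministic pattern parser covering the clause
shapes the templates and typical trauma narratives use, and a JSON
gold-parse replayer for tests. Role logic reads only arcs and token
strings, so providers are interchangeable; tests assert that identical arcs
yield identical events. Coreference across sentences is out of scope.

## Rule system

Rules are data, declared in `data/ruleset.json` with a small predicate
language (`require_category`, `require_tag`, `event_role`, `event_flag`,
`pair_count`, `count_explicit`, `distinct_explicit_intents`), so a revised
rule inventory needs no code change. The default set has 14 rules: five
explicit-intent rules (one per class, counting the no-information
attestation as the unknown class's explicit cue), three role rules, two
location rules, two information-density rules and two meta rules.

Decisions worth recording:

* Explicit-intent rules require an affirmed, non-historical,
  patient-subject mention — otherwise "denies suicidal ideation" would
  assert self-harm, which is precisely what modifier extraction exists to
  prevent.
* The assault-shooter rule excludes self-directed events, police actors,
  and non-person shooter phrases ("the gun discharged"): a firearm as
  grammatical subject is an accident pattern, not an assailant.
* Information density is the number of unique (term surface+category,
  section, negated, historical, other_subject) pairs. The context signature
  was chosen so that verbatim duplication of a note — the documentation
  drift that grows as EHR systems accumulate copy-forward text — changes no
  count and hence no feature. *High-info note* compares the best single
  note against threshold T (boundary inclusive, ≥); *low-info case*
  compares the whole case against a lower threshold (strict <). Both
  scopes are provided because density can be judged per document or per
  case; the high-info rule uses per-note max, the low-info rule per-case.
* Conflicting intent counts distinct asserted *intents*, not rule firings:
  two assault cues corroborate, they do not conflict.
* Meta rules may reference only explicit-intent outcomes, which rules out
  cycles structurally.

**Threshold tuning** maximizes the unknown-class F-score of the end-to-end
pipeline over an integer grid (default 1–15), fitting the classifier on the
training partition and scoring on the tuning partition; ties resolve to the
smallest threshold. Fitting and scoring on the same cases is supported (and
is the fallback when no training partition is supplied) but overfits: every
threshold then reaches the same ceiling and the tie-break, not the data,
picks the value.

## Classifier

The production model is scikit-learn gradient boosting with depth-1 stumps,
learning rate 0.1 and 300 trees — deliberately shallow, since the features
are 14 binary indicators and the model's job is calibrated weighting, not
representation learning. Random forest, logistic regression (maximum
entropy), SVM, AdaBoost and k-nearest-neighbour are available behind the
same interface for comparison runs, using their library defaults (recorded
in the comparison output). Probabilities follow each library estimator's
multiclass contract; the predicted label is the probability argmax with
exact ties broken by descending training prevalence, then class order —
a deterministic rule that favours the empirically dominant class (assault).

Persistence writes a JSON manifest (algorithm, hyperparameters, feature
names, class order, ruleset hash, seed) beside the fitted state; loading
refuses a file whose format version, ruleset hash or feature names
disagree, which is what makes the train-here/apply-there workflow safe.
*Recalibration* retrains the identical specification on another site's
labels with no state carried over.

Tree ensembles report impurity importances (non-negative, summing to 1);
other algorithms fall back to seeded permutation importance.

## Evaluation

Confusion matrices are 5×5 with predicted intent in rows and adjudicated
intent in columns. Per-class specificity, precision, recall and F are
computed from the matrix in exact rational arithmetic (`fractions`), with
0/0 defined as 0 for precision/recall/F and 1 for specificity — the
convention matters for the legal-intervention class, whose counts are tiny.
Rounding (half-up, two decimals) happens only in reports. The macro
("unweighted average") F is the plain mean of the five per-class F values.
AUROC/AUPRC are one-vs-rest per class via trapezoidal ROC integration and
step-wise PR summation; a class absent from the truth labels is reported as
undefined (NaN), never 0. Splits permute case ids under a seed and allocate
contiguously with largest-remainder sizing (each partition within one case
of its target); stratification is available but off by default, since
labels may not exist at split time. The ICD comparison restricts both arms
to cases that actually carry an ICD intent code, so the two arms are always
scored on identical cases.

## Synthetic data

The generator exists because gunshot-injury EHR extracts cannot be shared.
It emulates, per site profile: the adjudicated intent mix; ICD miscoding as
a row-stochastic matrix from true to coded intent; documentation density
(mean informative sentences per case, by intent); cue strength (the
probability a case's intent is explicitly documented — below 1 for every
class, since real charts often omit the circumstance, and lowest for legal
intervention); notes per case; filler volume; and a redundancy factor that
writes each informative sentence multiple times to model copy-forward
drift. Every emitted construct is recorded in a per-case generation log,
which tests use as the oracle instead of re-parsing the prose.

The default development-site profile uses intent shares
(0.075, 0.708, 0.018, 0.054, 0.145) with sparse unknowns (mean 1
informative sentence vs 7 elsewhere) and weak unknown attestation (0.30);
the external-site profile uses (0.148, 0.664, 0.036, 0.114, 0.036) with
uniform density and strong attestation, mirroring a newer EHR where unknown
intent is written down rather than inferred from sparsity. Miscoding
matrices are built from the two sites' published marginal distributions by
a donor/recipient transfer: classes whose true share exceeds their coded
share donate the surplus proportionally to the deficit classes. This
reproduces the coded marginals exactly given the true marginals and puts
the dominant error where surveillance audits find it — assault-truth coded
as accident. The joint (true × coded) distribution is otherwise
unconstrained by published numbers; the matrix ships in the profile and is
easy to override.

What the generator does **not** emulate: realistic clinical prose (the
grammar is template-based by design — determinism and log-checkability
outrank fluency), misspellings, cross-sentence anaphora, contradictory
documentation between notes, or coder-specific ICD idiosyncrasies beyond
the marginal transfer. Consequently, passing end-to-end tests demonstrates
that the pipeline's machinery is correct and that its qualitative
advantages over ICD coding hold under the stated generative assumptions —
not that real-data accuracy would match the synthetic benchmark, which is
substantially easier than real charts.

One known artefact of the small template pool: documentation density
correlates with the presence of *every* term category, so on some draws the
booster can separate unknown-intent cases through correlated surrogate
features (e.g. location rules) instead of the designed density rules, and
the impurity importance of the density rules collapses toward zero even
though classification quality is unchanged. The site-transfer comparison in
the acceptance script is therefore read at fixed seeds and as a
separated-vs-uniform contrast, not as an absolute importance level.

## Benchmark sizes and defaults

The standard benchmark generates 1000 cases (60/20/20 split), tunes the
threshold on the tuning partition, trains the gbm on the training
partition, and evaluates on the held-out test partition; the site-transfer
comparison uses 600 cases per site. These sizes echo the scale of a
single-institution chart-review study while keeping the full suite fast on
a laptop. All randomness flows from explicit seeds (numpy `default_rng`
plus scikit-learn `random_state`), so every reported number is exactly
reproducible.
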