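# firearm-intent

Coding the **intent** of a firearm injury — accident, assault, legal
intervention, self-harm, or unknown — from free-text hospital notes.

Hospital discharge data capture nearly every gunshot injury seen in US
emergency departments, but the intent implied by the external-cause ICD code
is notoriously unreliable: medical-records coders systematically over-assign
*accident* and under-assign *assault*. Injury-surveillance researchers who
need intent-specific counts therefore either hand-review charts or accept
biased ICD coding. This package implements a hybrid NLP + machine-learning
pipeline that assigns intent directly from the clinical narrative, plus the
evaluation harness to compare it against ICD coding, and a synthetic note
generator so the entire pipeline can be developed and tested without
protected health data.

## The method

A case (one injury encounter, possibly several notes) is classified in three
steps:

1. **Lexicon term extraction.** A specialized lexicon of 1–5 token terms
   (shooting verbs, explicit intent cues, police actors, incident locations
   with `inside`/`outside` tags, no-information attestations) is matched
   greedily, longest-first, over each sentence. *Confusion terms* such as
   "police report" suppress the shorter informative terms they contain.
   Every match carries clinical context: section, negation ("denies SI"),
   historical status ("GSW 10 years ago"), and non-patient subject
   ("brother was shot"). Sentences containing shooting verbs get a
   dependency parse from which the **shooter** (verb subject, or by-agent in
   passive voice), **person shot** (object / passive subject) and
   circumstance phrases are read off; a reflexive object ("shot himself")
   marks the event self-directed.
2. **Expert rules → binary features.** A declarative rule set maps the
   extraction to a 0/1 feature vector: explicit-intent rules (an affirmed,
   non-historical cue of each class), role rules (assault shooter = a
   non-self, non-police, person shooter; legal shooter = a police actor),
   location rules, information-density rules (*high-info note*: some note
   has ≥ T unique (term, context) pairs; *low-info case*: the whole case has
   < t pairs — T tuned for unknown-intent F-score), and meta rules
   (no explicit intent; conflicting intents).
3. **Shallow boosting.** A gradient-boosting classifier over the binary
   features — depth-1 stumps, learning rate 0.1, 300 trees — yields a
   probability per intent; the argmax is the assigned label (exact ties go
   to the most prevalent training class). The fitted model is saved with a
   manifest (feature names, class order, ruleset hash) and can be applied at
   a new site unchanged, or *recalibrated* — retrained with the identical
   specification on local labels.

Evaluation follows the standard per-class definitions — specificity
TN/(TN+FP), precision TP/(TP+FP), recall TP/(TP+FN),
F = 2PR/(P+R), macro (unweighted) average F over the five classes, and
one-vs-rest AUROC/AUPRC — computed in exact rational arithmetic from the
confusion matrix (predicted intent in rows, adjudicated intent in columns)
and rounded half-up to two decimals only for reporting.

## Worked example

```bash
firearm-intent simulate --n 600 --seed 7 -o run/sim
firearm-intent extract  --notes run/sim/notes.jsonl -o run/ext
firearm-intent train    --features run/ext/features.csv --labels run/sim/labels.csv --seed 7 -o run/model
firearm-intent predict  --features run/ext/features.csv --model run/model/model.joblib -o run/pred
firearm-intent evaluate --predictions run/pred/predictions.csv --labels run/sim/labels.csv -o run/eval
```

The final command prints (training and evaluating on the same 600 simulated
cases, so these numbers describe fit, not generalization):

```
                    specificity  precision  recall  f_score  auroc  auprc
accident                   1.00       1.00    0.73     0.85   0.99   0.87
assault                    0.93       0.98    1.00     0.99   1.00   1.00
legal_intervention         1.00       1.00    1.00     1.00   1.00   1.00
self_harm                  1.00       1.00    0.94     0.97   1.00   0.98
unknown                    1.00       1.00    0.99     0.99   1.00   1.00
average                     NaN        NaN     NaN     0.96    NaN    NaN
```

Each row is one intent class: e.g. every case the model labelled *accident*
truly was one (precision 1.00) but it found only 73% of true accidents
(recall 0.73) — the rest had no documented cue and mostly fell to *assault*
or *unknown*. The `average` row is the macro F over the five classes.
Held-out performance is lower; the synthetic benchmark in
`scripts/acceptance.py` reports it properly. The same commands run on real
note exports in the documented JSON-lines/CSV formats.

As a library, the rule featurizer and classifier are scikit-learn
estimators and compose with sklearn tooling:

```python
from sklearn.pipeline import Pipeline
from firearm_intent import RuleFeaturizer, IntentClassifier

model = Pipeline([
    ("features", RuleFeaturizer()),
    ("intent", IntentClassifier(algorithm="gbm", random_state=0)),
])
```

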