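# asdphen

Transparent sentence-level DSM-5 criterion labeling and record-level ASD
case labeling for clinical notes.

## The problem

Most machine-learning phenotyping systems read a child's clinical record and
emit a single opaque label: ASD or not. Clinicians cannot see *why*, and a
black-box model may latch onto spurious correlates (a clinic name, a referral
template) rather than documented behavior. `asdphen` takes the opposite
route: it labels **individual sentences** with the DSM-5 behavior criteria
they describe, then derives the case label with the deterministic clinical
rule — so every decision comes with the exact sentences that support it.

The seven criterion codes are:

| Code | Behavior class |
|------|----------------|
| A1 | deficits in social-emotional reciprocity |
| A2 | deficits in nonverbal communicative behavior |
| A3 | deficits in developing and maintaining relationships |
| B1 | stereotyped or repetitive movements / speech |
| B2 | insistence on sameness |
| B3 | highly restricted, fixated interests |
| B4 | hyper- or hyporeactivity to sensory input |

A record is labeled ASD when its sentences document **all three A criteria
and at least two B criteria**:

```
ASD(S)  =  {A1, A2, A3} ⊆ S  ∧  |S ∩ {B1, B2, B3, B4}| ≥ 2
```

where `S` is the set of criteria with at least one labeled sentence. The
number of examples per criterion is irrelevant — one correctly labeled A1
sentence contributes as much as ten. This redundancy is what makes the
approach robust: with a per-example miss rate `q` and `k` examples of a
criterion in a record, the criterion is lost only with probability `q^k`.

## What is in the package

* **Rule-based parser** (`asdphen.rules`) — pattern rules over lexicon term
  lists (literal tokens, lexicon slots, bounded gaps, per-rule negation
  guards), with a small plain-text DSL (grammar in `docs/rule_dsl.md`) and a
  demo ruleset.
* **Three trainable sentence labelers** (`asdphen.classifiers`) — a
  per-criterion bidirectional GRU, a per-criterion bidirectional LSTM with
  attention whose input is augmented with the parser's matched lexicon terms
  (the hybrid model), and a multilabel bidirectional LSTM with a fixed 0.5
  decision threshold. Built on a compact numpy autodiff core
  (`asdphen.nn`); embeddings are pluggable (deterministic seeded-hash
  vectors by default, GloVe-format text files optionally).
* **Ensembles and case labeling** (`asdphen.ensemble`) — strict majority
  vote and inclusive-or combiners per sentence, the DSM-5 case rule per
  record, and evidence lists for every criterion.
* **Instrument score mapping** (`asdphen.instruments`) — ASDS / CARS / GADS
  / GARS / GARS2 / MCHAT / ADOS cutoffs to ASD / Probable ASD / Not ASD and
  any-test-positive aggregation.
* **Evaluation** (`asdphen.evaluation`) — precision, recall, F1, accuracy,
  specificity (`accuracy=(TP+TN)/(P+N)`, `F1=2·TP/(2·TP+FP+FN)`,
  `specificity=TN/N`), per-criterion tables with unweighted means, exact
  two-sided Fisher tests and Pearson chi-square with standardized residuals
  for 2×2 case comparisons.
* **Synthetic corpus generator** (`asdphen.synthetic`) — seeded corpora with
  the statistical shape of annotated surveillance data (per-criterion label
  prevalences of 0.4–2.5%, ~half of records meeting the case rule), since
  real sentence-annotated records are not redistributable.
* **CLI** (`asdphen`) — `simulate`, `parse`, `train`, `predict`, `ensemble`,
  `case`, `evaluate`, `compare-instruments`, each seeded and writing a
  provenance manifest.

## Worked example

```python
import asdphen as ap

rs = ap.demo_ruleset()
records = ap.generate_corpus(ap.small_config(seed=0))
print(ap.corpus_summary(records).to_string(index=False))

parser_pred = ap.parse_corpus(records, rs)
decisions = ap.run_pipeline(records, [parser_pred],
                            ap.EnsembleSpec(("parser",), "inclusive_or"))
gold = {r.record_id: bool(r.gold_case) for r in records}
m = ap.metrics(ap.confusion(ap.decisions_as_cases(decisions), gold))
print("parser-only case accuracy:", round(m.accuracy, 3))
d = decisions[0]
print(d.record_id, "->", "ASD" if d.label else "No ASD",
      sorted(c.value for c in d.criteria_present))
```

prints

```
 records  sentences  A1  A2  A3  B1  B2  B3  B4
      64       3880 191 168 164 144 114 107 136
parser-only case accuracy: 0.984
r0000 -> No ASD ['A1', 'A3', 'B2']
```

The corpus summary counts labeled sentences per criterion (a 64-record
desk-scale corpus with ~3.9k sentences). The parser alone recovers the case
labels almost perfectly on this synthetic corpus because every cue phrasing
is covered by the demo rules; record `r0000` documents A1, A3 and B2 only,
so the DSM-5 rule correctly returns "No ASD" (A2 is missing). Trained
classifiers, ensembles, and the full command-line chain are exercised the
same way — see `tests/test_acceptance.py` for an end-to-end run.

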