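# Methods

## The decision model

`asdphen` separates phenotyping into two stages so that the final decision
is auditable:

1. **Criterion labeling.** Every sentence of a record is assigned a
   (possibly empty) subset of the seven DSM-5 criterion codes A1–A3 (social
   communication deficits) and B1–B4 (restricted/repetitive behaviors).
   Sentences may carry several labels; a single behavior description can
   legitimately evidence more than one criterion.
2. **Case labeling.** The record-level decision applies the clinical rule to
   the set `S` of criteria with at least one labeled sentence:
   `ASD ⇔ {A1,A2,A3} ⊆ S ∧ |S ∩ {B1..B4}| ≥ 2`. Counts of examples per
   criterion are deliberately ignored, matching clinical practice.

The separation buys robustness through redundancy: if a criterion has `k`
example sentences in a record and each is independently missed with
probability `q`, the criterion disappears from `S` only with probability
`q^k`. The `simulate_redundancy` helper quantifies this: at `q = 0.3` and
`k = 5`, case accuracy over simulated cohorts exceeds 0.95 even though
sentence-level recall is only 0.7. Case accuracy is monotonically
non-decreasing in `k`, which the test suite verifies by simulation.

## Predictors

Four sentence labelers feed the ensembles.

**Rule-based parser.** Pattern rules over lexicon term lists; see
`docs/rule_dsl.md` for the grammar and matching semantics. Design choices
that were genuinely open: token matching is lowercase with edge punctuation
stripped (the smallest workable semantics); gap slots default to small
bounds (≤4 in the demo rules); negation is handled by per-rule guard
lexicons with whole-sentence scope rather than a global negation detector,
because negated and affirmative phrasings are *both* criterion evidence and
polarity is therefore rule-local. Rules never span sentences. The shipped
demo ruleset is small by design — the engine is the deliverable.

**Per-criterion bidirectional GRU** (`binary_gru`). One binary classifier
per criterion, trained on all sentences (no down-sampling of negatives and
no oversampling). Decision: sigmoid score strictly greater than the
threshold (default 0.5).

**Hybrid bidirectional LSTM** (`hybrid_lstm`). Also per-criterion. The
attention-pooled text encoding is concatenated with a side channel that
encodes which parser lexicon terms occur in the sentence (a multi-hot
vector passed through a small dense layer). This is the mechanism for
injecting the rule base's curated knowledge into a neural model; with an
empty ruleset the side channel vanishes and the model reduces to a
text-only BiLSTM. The test suite includes a controlled corpus whose labels
depend only on lexicon-term presence, where the side channel is decisive.

**Multilabel bidirectional LSTM** (`multilabel_lstm`). A single model with
seven sigmoid outputs; every label whose score strictly exceeds the 0.5
threshold is assigned. A score exactly at the threshold does not assign the
label (strict reading of "above").

### Network core

The recurrent models are implemented on a compact reverse-mode autodiff
core (`asdphen.nn`): 2-D float32 tensors, standard GRU/LSTM cells run in
both directions over padded token batches with mask-carried hidden states,
additive attention pooling, stable binary cross-entropy on logits, and
Adam. Gradients are verified against central finite differences in the
test suite. Everything is driven by seeded numpy Generators and the code
never iterates hash-ordered containers while consuming randomness, so
identical seeds give identical parameters and predictions across processes
and platforms.

### Embeddings

Embeddings are pluggable, fixed (not fine-tuned), and OOV-total: the
default provider derives each token's vector from a salted blake2b hash of
the token string, giving deterministic pseudo-random vectors with no
external file; a loader for 300-d GloVe-format text files is provided for
pretrained vectors. Out-of-vocabulary tokens map to a hash vector (default
provider) or the zero vector (GloVe), never an error.

### Presets

Two preset families are first-class (`asdphen.classifiers.PRESETS`):

* Reference presets carry the full-scale hyperparameters: the GRU family
  trains 2 epochs with 128 units, depth 9, batch 1000; the LSTM models
  train 10 epochs with batch 16, 150 recurrent units, 10 parser-input
  units, 20 attention units, 150 final-layer units; multilabel threshold
  0.5. "Depth 9" is interpreted as total block depth — embedding, two
  stacked bidirectional recurrent blocks (4 directional cells), pooling,
  two dense blocks, output — since the block order is otherwise
  under-determined; configs with `layers ≥ 8` stack a second recurrent
  layer.
* Small presets (`*_small`: 16 units, depth 5, 6–8 epochs, learning rate
  0.01) are sized for desk-scale corpora of a few thousand sentences and
  are what the tests and the acceptance run use. The small multilabel
  preset keeps batch size 16: with ~95% negative label marginals, large
  batches let the shared multilabel head settle into the all-negative
  solution, while small noisy batches escape it reliably across seeds.

## Ensembles and case decisions

Two combiners operate per sentence and label:

* **majority vote** — keep a label iff strictly more than half of the
  members assign it. Strictness is the only reading under which "majority"
  is well defined for even member counts; for the two-member ensemble it
  means unanimity, making that ensemble the most precision-oriented
  configuration.
* **inclusive or** — the union of member labels.

Majority labels are a subset of OR labels by construction, so at the case
level the OR ensemble can never have lower sensitivity and the majority
ensemble can never have lower specificity, on any inputs; the suite asserts
this as set logic over randomized prediction sets. The standard comparison
grid is {all four predictors, the three neural models, the two best
models} × {majority, or}. Votes are unweighted: the parser counts the same
as a neural model.

Every case decision retains, per criterion, the list of supporting
sentence ids, and the report writer quotes the sentences themselves —
transparency is the point of the method, so evidence is never discarded.

## Synthetic corpora

Sentence-annotated surveillance records cannot be redistributed, so the
generator produces corpora with the same statistical shape:

* **Scale.** Default: 150 records, ~229 sentences per record
  (negative-binomial, shape 20), ~34k sentences total. The small preset
  uses 64 records × ~60 sentences (~3.8k sentences).
* **Marginal prevalences.** Defaults are per-criterion labeled-sentence
  proportions between 0.43% (B3) and 2.49% (A1) of sentences, the regime
  of real annotated data. The small preset boosts them to 3–5% so each
  criterion keeps ~100 positive training sentences at desk scale.
* **Per-record structure.** Real criteria cluster by child, so each record
  first *activates* each criterion independently (defaults: 0.91 for A
  criteria, 0.57 for B criteria), and only active criteria emit labeled
  sentences, at a within-record rate that preserves the configured
  marginal prevalence. The activation defaults were chosen so that roughly
  half of generated records meet the case rule once within-record sampling
  losses are accounted for, mirroring a surveillance population in which
  every child exhibits some ASD-like behaviors. Case labels are always
  derived from the realized sentence labels — never forced — so the
  corpus validator holds by construction.
* **Text.** Labeled sentences embed criterion cue phrases (canonical EHR
  phrasings, all covered by the demo ruleset) in templated clinical
  filler; background sentences come from a neutral phrase pool. Two noise
  knobs make the task imperfect: `cue_noise` (a cue sentence loses its
  gold label — annotation noise, default 2%) and `cross_talk` (a foreign
  criterion's cue appears in a labeled sentence, default 2%).
* **Instruments.** An optional helper attaches 1–3 diagnostic-instrument
  administrations per record that agree with the gold case label with
  probability 0.75 — instruments are imperfect, which is what the
  comparison is about.

What the generator does **not** emulate: real clinical language (vocabulary
breadth, negation subtleties, co-reference across sentences), label
correlations beyond per-record activation, inter-annotator variability.
Passing tests on synthetic corpora therefore demonstrate that the pipeline
machinery is correct and that the redundancy argument holds — not that any
particular accuracy transfers to real records.

## Instrument mapping

Score cutoffs: ASDS >110 ASD, 90–110 Probable, else Not; GARS >110 ASD,
80–110 Probable, else Not; GARS2 ≥85 ASD; MCHAT ≥2 ASD; CARS categories
Severe / Mild to Moderate / NOS are ASD; GADS High/Probable are ASD,
Borderline is Probable; ADOS results pass through. Scores are compared as
exact decimals with no rounding, and every cutoff has a two-sided boundary
test. Aggregation over a child's tests is any-test-positive with all
duplicates retained; whether Probable ASD counts as positive is an explicit
`probable_policy` parameter (default `as_asd`) because conventions for
borderline results differ, and both behaviors are first-class.

## Evaluation conventions

* The five metrics follow the printed formulas; a 0/0 metric is an
  *undefined marker* (`None`, NaN in DataFrames), never silently 0. A
  `zero_fill` option restores the print-a-zero convention used for
  predictors that assign no labels.
* Per-criterion tables score each criterion as an independent binary task
  over all sentences; the summary row is the unweighted arithmetic mean of
  the seven values (undefined entries enter as 0 under the table
  convention).
* For 2×2 case comparisons the module reports **both** the two-sided Fisher
  exact test and the Pearson chi-square with standardized residuals
  `(O−E)/√E`. Fisher is computed by exact integer hypergeometric
  enumeration (`math.comb`), so tie handling is exact; the suite checks it
  against an independent float oracle on every table with total ≤ 60 and
  against scipy. Pearson uses no continuity correction. Zero-margin tables
  return p = 1 with a warning rather than an exception. For the reference
  table (10,0 / 1,3) the computed standardized residual of the
  (No ASD, No ASD) cell is 2.31 (adjusted residuals, not reported, would
  be larger).

## Numerical and reproducibility choices

* float32 weights and activations; Adam with bias correction; Glorot
  uniform initialization; LSTM forget-gate bias 1.
* Sentence encoding truncates at 24 tokens (synthetic sentences are
  shorter; raise `max_tokens` for real notes).
* One run seed fans out to per-stage seeds by stable hashing of the stage
  name, so stages can be rerun independently yet reproducibly; all derived
  seeds stay below 2³¹.
* Prediction files, decision JSON, and corpus serialization are sorted and
  canonical, so identical runs are byte-identical.

## Problem sizes used by the tests and the acceptance run

The suite trains on a 48-record (~2.9k sentence) split of the small-preset
corpus and evaluates on the 16 held-out records; the acceptance script uses
the same sizes with seeds derived from its `--seed`. These sizes keep a
full train-and-evaluate cycle of all three architectures in the low
minutes on one CPU while leaving each criterion enough positive sentences
(~60–200) to be learnable.

## Known limitations

* The demo ruleset covers the synthetic cue inventory, not real clinical
  language; parser scores on real notes depend entirely on the supplied
  rule base.
* The hash-embedding default provides no semantic generalization between
  tokens; pretrained embeddings are expected to matter on real text.
* The multilabel model is the least stable of the three at desk scale
  (shared head, rare positives) — consistent with per-criterion training
  being the default design.
* No transformer models, no sentence segmentation (corpora arrive
  pre-segmented), no structured-data features, and no DSM-5 C/D/E criteria
  (only A1–A3, B1–B4 are mapped).
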