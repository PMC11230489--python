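# Methods

## The labeling model

`weakseal` treats a generative language model as a knowledge-free
annotator.  Labeling happens at the sentence level: transformer context
windows are too small for whole clinical notes, so each note is
sentence-segmented and every sentence is placed into the input slot of
a fixed 4-section prompt (system role, task instruction, `k = 8`
uniformly sampled few-shot sentence/label pairs, input placeholder).
Decoding is greedy (`top_k = 1`) with a 128-token output cap, so a
given backend is fully deterministic.  The expected output is a JSON
array of `{"text": ..., "type": ...}` objects; the same canon is used
for the few-shot examples, for SFT completions (appended after the
closing `[/INST]` token), and by the parser, so generation, training
and post-processing share one format by construction.

The package deliberately does not execute GPU fine-tuning or real LLM
decoding.  The generation surface is a single-method contract
(`prompt → text`), with replay, oracle, echo and corruptor backends for
deterministic desk-scale runs; SFT is supported by exporting a
prompt+completion JSONL and a hyperparameter manifest (cosine schedule,
initial learning rate 2·10⁻⁵, weight decay 0.1, sequence length 4096,
2 epochs, batch size 1) that any external trainer can consume.

## Post-processing and its failure semantics

Raw generations become weak labels in four steps: (1) text extraction
after the last closing dialect token, truncating at any newly generated
opening token; (2) JSON formatting via the non-greedy pattern `{.*?}`,
each match parsed independently; (3) span recovery by exact,
case-sensitive string matching; (4) entity-type filtering against the
task schema.  Choices that the steps leave open were resolved as
follows:

- **Repeated mentions.** Records are processed in generation order and
  each takes the *leftmost occurrence not already covered* by a prior
  recovery, so duplicate texts consume occurrences left to right.  One
  record yields at most one entity.
- **Duplicates vs. not-found.** When a record has no free occurrence
  left, it is logged `duplicate` if a prior recovery already holds the
  same (text, type) — the span it would have received — otherwise
  `text_not_found`.  (A covered span can never be re-assigned, so an
  explicit identical-span check would be unreachable.)
- **Failure definition.** A sentence is `failed` only when *zero*
  objects parse and no `[]` token appears; an explicit empty list is a
  successful empty labeling, and a sentence with some malformed objects
  but at least one parsed record is not failed.  This keeps the failure
  statistic a pure formatting signal.
- **Strict keys, no trimming.** Only the keys `text`/`type` are
  accepted and parsed texts are matched verbatim — no lowercasing,
  whitespace trimming or alias keys — mirroring the exact-matching
  philosophy of the recovery step (and the fact that SFT teaches the
  canon).

Accounting is conservative by invariant: per sentence, parsed records =
recovered entities + drops (`text_not_found` | `duplicate` |
`off_schema_type`), and pre-parse failures are logged as `bad_object` /
`no_json`.  The corpus report aggregates totals, failure percentages,
and per-sentence/per-note entity-count quartiles.

## Gold-note selection and two-stage training

With `N` training notes and a gold budget `n_s`, the gold subset
minimizes distance to the median entity count: median for even `N` is
the arithmetic mean of the middle two counts, and ties are broken by
ascending note id, making selection deterministic.  A small exhaustive
search over all size-`n_s` subsets is used as the test oracle; the
greedy top-`n_s` rule provably attains the same minimal total distance.

Training stage 1 fits the tagger on BIO-encoded sentences of the
`N − n_s` weak notes, stage 2 continues *from the stage-1 weights* on
the `n_s` gold notes.  Each stage splits its sentences 80/20
(train/validation) with a fixed seed — sentence-level splitting
maximizes validation coverage when `n_s` is tiny.  Every epoch is
scored on validation strict micro-F1; the best checkpoint is restored,
and training halts after 8 consecutive non-improving epochs (so a
constant validation score yields exactly 9 epochs).

Two reference taggers implement the pluggable interface:

- a **dictionary memorizer** (majority tag per token surface) — the
  exact oracle on corpora where the token→tag mapping is unambiguous;
- a **greedy perceptron tagger** over sparse lexical features (token,
  3-character suffix, shape, neighboring tokens, previous predicted
  tag), used for the noise experiments.  It is a deliberately small
  model: the point of the experiments is the *relative* value of weak
  pre-training, not absolute tagging accuracy.

BIO conversion resolves overlapping gold entities by keeping the longer
span (single-layer BIO cannot express overlap), snaps entity boundaries
that fall inside a token outward to token boundaries, and repairs an
orphan `I-X` to `B-X` on decoding.  An entity crossing a sentence
boundary triggers a merge of the two sentences rather than truncation,
preserving gold recall; this repair rule is this package's choice.

## Evaluation

Strict = identical (start, end, label); lenient (= relaxed) = identical
label with ≥ 1 character of overlap.  Matching is greedy one-to-one on
(overlap desc, gold start, predicted start), then TP/FP/FN are pooled
over all notes and types before micro precision/recall/F1 (0/0 → 0).
Strict matches are a subset of lenient matches, so strict micro-F1 ≤
lenient micro-F1 always — a property test, and a useful sanity check on
any report.

## Compute budgeting

Per-sentence inference cost uses the standard decoder forward-pass
approximation `n_tokens_out × (2N + 2·n_layer·n_ctx·d_attn)` in exact
integer arithmetic; the printed scientific form truncates (not rounds)
the mantissa at 4 significant digits.  `n_ctx` is estimated from the
rendered prompt's token count — the few-shot block dominates prompt
length, so a single configured value represents all prompts of a task
to within ~20%.  Corpus-level GPU time is projected with an OLS line
through (notes, seconds) timing samples.

## Synthetic data: what it does and does not emulate

The generator builds notes of 3–8 sentences from a filler vocabulary
with typed entity phrases (drug-like, dose-like, symptom-like) planted
at token boundaries.  Entities per sentence follow a zero-inflated
Poisson (defaults `p_zero = 0.25`, mean 2.5, capped at 6), giving the
low per-sentence medians (0–3) typical of clinical concept benchmarks.
All vocabularies are mutually word-disjoint, so exact-match span
recovery is unambiguous and every injected mutation is attributable:
hallucinated texts come from a vocabulary disjoint from all sentences
(guaranteeing `text_not_found`), swapped types are off-schema names
(guaranteeing `off_schema_type`), and format corruption emits braceless
free text (guaranteeing `no_json`).  A noise ledger records each
mutation and an audit test matches ledger entries 1:1 to drop reasons
or surviving wrong labels.

This controls what passing tests mean: they demonstrate the *pipeline
mechanics* — lossless round-trips, exact accounting, calibrated failure
rates, the benefit of weak pre-training when gold data is scarce — not
performance on real clinical language.  Real notes have ambiguous
surface forms, entities crossing tokenizer quirks, nested mentions and
non-verbatim LLM paraphrases, none of which the generator produces.

## Problem sizes and defaults

Experiments in the test suite and the acceptance script use corpora of
20–300 notes: 200 notes for the oracle round-trip, 2,000 sentences for
the failure-rate calibration (3σ binomial band), 200 random corpora of
N ≤ 12 for the selection oracle, 1,000 random sentences for the BIO
round-trip, and 300 training + 100 held-out notes × 5 seeds for the
two-stage comparison (weak labels carrying 30% type noise, `n_s = 3`).
These sizes give stable statistics while keeping any single run in the
seconds-to-a-minute range on one CPU.

## Known limitations

- The local causal-LM adapter is not included; backends are replay,
  oracle, echo and corruptor.  Real-model runs can be replayed from a
  JSONL store.
- The run manifest and configuration surfaces are JSON; YAML is not
  parsed.
- Single-layer BIO drops one entity of every overlapping gold pair.
- The perceptron tagger is unregularized and feature-poor by design;
  it is a scaffold for the weak-supervision experiments, not a
  production clinical tagger.
- The i2b2 XML adapter covers the common `<TEXT>`/`<TAGS>` attribute
  dialect only.
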