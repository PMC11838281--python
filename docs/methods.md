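# Methods

This note records the models, conventions and numerical choices behind the
toolkit, and what the synthetic experiments do and do not demonstrate.

## Data model and coordinate conventions

All annotation is flat, contiguous character spans: a mention is
`(start, end, type, text)` with 0-based, end-exclusive offsets into the
*document* (a 3-character mention starting at character 48 is `[48, 51)`).
Sentence segmentation produces intervals in the same document coordinates,
and sentence-local spans produced during extraction are shifted back by the
sentence start, so segmentation differences can never corrupt stored
offsets. Duplicated `(start, end, type)` triples are treated as data errors
and surfaced by validation rather than silently deduplicated.

The shipped schema has 15 entity types drawn from the attributes PDCM
curation platforms use (diagnosis, age_category, genetic_effect, model_type,
molecular_char, biomarker, treatment, response_to_treatment, sample_type,
tumour_type, cancer_grade, cancer_stage, clinical_trial, host_strain,
model_id). Type names double as XML tag names and BIO label suffixes, so
they must be whitespace- and angle-bracket-free; schema order is contractual
(it fixes the BIO label order and the prompt-initialization cycle).

## Sentence segmentation

A deliberately transparent rule set replaces heavyweight clinical NLP
segmenters: a boundary follows `.`, `!` or `?` when the next non-space
character is an uppercase letter or digit, with guards for a list of
scholarly abbreviations ("et al.", "Fig.", "vs.", "e.g.", ...), single
capital initials ("J."), and digit-period-digit (decimals, versions).
Intervals are whitespace-trimmed and cover every non-whitespace character
exactly once. Because all spans are stored document-level, an imperfect
boundary only changes the text window handed to a model.

## Direct prompting and tag recovery

The prompt is assembled deterministically from an instruction, one
definition line per schema type, `n` worked input/output example pairs
(default 5, validated to parse cleanly), and the query sentence. Extraction
is sentence-at-a-time.

Tag recovery scans the completion left-to-right with a *closed* tag
vocabulary — only `<name>` / `</name>` for schema names count as tags, so
genuine `<` characters in scientific text stay literal. Offsets are
accumulated in tag-stripped coordinates. Pathologies never raise: nested
tags are ignored with a warning (the annotation scheme is flat, so nesting
is a model error), unbalanced tags are stripped and warned, and
attribute-bearing or self-closing tags are stripped as malformed. If the
tag-stripped residual differs from the source sentence, strict mode rejects
the sentence outright; lenient mode computes a character-level longest
common subsequence (dynamic programming, O(nm); sentences are short) and
maps span endpoints through it. Lenient alignment requires ≥ 90% of source
characters to align and every character of a surviving span to be aligned,
else the span (or sentence) is dropped — a drift budget chosen once so that
single-word drops survive but rewritten sentences do not.

## Soft prompting

The task is cast as 31-way token classification over IOB2 labels. The
tokenizer splits on whitespace and detaches leading/trailing punctuation,
keeping exact offsets; gold spans whose boundaries fall mid-token are
snapped outward to token boundaries (with a warning counter), since BIO
cannot represent sub-token boundaries.

The trainable state is a prompt of `L = 30` vectors in the backbone's
embedding space plus a linear head from hidden states to labels. Casting
extraction as 31-way classification requires a trainable readout; a linear
head trained jointly with the prompt is the smallest such readout, and the
backbone itself stays frozen — its SHA-256 parameter fingerprint is asserted
identical before and after every training run. Prompt vector *i* is
initialized from the embedding of type name *i mod 15* (multi-piece names
like `response_to_treatment` are averaged over their underscore-separated
pieces), so a length-30 prompt uses each type embedding exactly twice.
Training minimizes token-level cross-entropy over real-token positions only
(prompt positions are excluded from loss and decoding) with Adam at
learning rate 0.001 for 50 epochs, seeded shuffling, no scheduler. History
records per-epoch mean loss and dev micro-F1 (span-level, exact match); the
best-dev state is returned. Per-epoch loss monotonicity is not asserted
anywhere — only start-to-end improvement.

Decoding repairs invalid label sequences with the IOB2 convention: `I-x`
without a preceding `B-x`/`I-x` (including after a different type) opens a
new span. Decoded spans are always valid intervals regardless of the label
sequence.

### The toy backbone

`ToyBackbone` is a deterministic miniature language model used by the tests
and examples: hashed token embeddings (blake2b into a 4096-row seeded
table, d = 32) and one mixing layer
`h_i = tanh(W1 e_i + W2 · mean(e_0..e_i) + b)` with hidden size 128. The
causal-mean context term is what makes prompt vectors matter — they shift
every downstream position — and its weight is kept small (scale 0.1) so
token identity dominates each position, which is what a linear head over a
frozen representation needs to classify tokens. The analytic
vector-Jacobian product of the layer is exposed for training and verified
against numerical gradients. Real LLM backbones satisfy the same contract;
nothing in the trainer is toy-specific.

## Evaluation

True positives are counted by a one-to-one maximum-cardinality matching
between gold and predicted spans of the same type within one document,
found by deterministic augmenting-path search (candidates in start order)
and cross-checked in the tests against brute-force enumeration and an
independent Hopcroft–Karp implementation. Overlap credit is binary — any
≥ 1-character same-type overlap — not fractional. Maximum matching makes the
mode ordering a theorem: exact-mode TP ≤ overlap-mode TP for any input,
hence exact P/R/F1 ≤ overlap P/R/F1. Pooled rows are micro-averages of
summed counts; types with neither gold nor predicted spans are omitted
rather than reported as 0 or 100. Scores are on the 0–100 scale.

Pairwise IAA scores one annotator as gold against another (per-type F1 is
symmetric under the swap, which the tests assert) and averages per-type F1
over all unordered pairs, exact match by default. The learning-curve runner
subsamples `ceil(f·N)` training sentences per fraction with a fixed seed,
retrains from scratch, and scores micro P/R/F1 on a held-out set.

Corpus splitting shuffles lexicographically sorted document ids with a
seeded Fisher–Yates, then cuts at `round(n·r_train)` / `round(n·r_dev)`;
100 documents at 60:20:20 give exactly 60/20/20. A seeded random split is
the default because no stratification scheme is clearly preferable for
abstracts.

## Synthetic data

`generate_corpus` assembles 3–8 template sentences per document from
per-type surface lexicons (seeded from the schema's curation examples:
"PDX", "BRCA1", "NOD-SCID", "PHLC402", "grade 1", "phase II", ...), with
mentions embedded at recorded offsets. Per-type mention counts are Poisson
around a frequency profile; the default profile mirrors a curated abstract
collection (~33 mentions per abstract, diagnosis/biomarker/treatment
frequent, cancer_grade/cancer_stage rare). Two stress features are built
in: comma-separated biomarker list sentences (dense same-type adjacency for
the BIO codec and parser) and boundary variants appending " models" to
model_type mentions (exact-vs-overlap disagreement by construction). The
lexicons intentionally contain the biomarker/treatment ambiguity ("MEK" vs
"MEK inhibitor therapy").

`perturb_annotations` derives simulated annotators by independent per-span
deletions, word-boundary shifts, type confusions (default pair
biomarker↔treatment) and spurious single-word insertions, so expected
TP/FP/FN are available in closed form — e.g. a 0.3 deletion rate must
appear as recall 70% within a binomial interval, and boundary-shift-only
noise must give overlap-F1 = 100 with exact-F1 < 100. The mock tagger
applies the same error model (plus tag malformation and text drift) when
answering prompts from the gold corpus, keyed per sentence from
(seed, sentence digest) so output is independent of call order.

`cue_word_dataset` is the corpus for parameter-recovery experiments:
entities are dedicated cue tokens that never occur as filler or under
another type, so the token→label mapping is noise-free and a working
trainer must approach perfect held-out F1. The recovery experiment uses 240
training and 60 dev sentences — roughly the scale of a small curated
training split — at the method defaults, and lifts dev micro-F1 from ≤ 20
to ≥ 90 (in practice to 100).

### What the synthetic experiments do not show

Template sentences are not real scientific prose: no anaphora, no
discontinuous or nested mentions, no genuinely ambiguous context that only
world knowledge resolves. Passing the synthetic suites demonstrates that
the machinery is correct — offsets exact, codecs invertible, scores equal
to their closed-form expectations, training able to recover a recoverable
signal — not that any particular LLM reaches any particular F1 on real
abstracts. Real-model performance requires plugging a real generator or
backbone into the adapter contracts.

## Known limitations

* Discontinuous and nested gold spans are out of scope (the annotation
  model is flat).
* The direct-prompting route ships no clients for proprietary APIs; the
  file-replay adapter reproduces recorded runs offline instead.
* P-tuning-style prompt encoders (LSTM/MLP) are deliberately absent; the
  plain prompt-tuning parameterization is the supported method.
* Sub-word pooling strategy is delegated to the backbone adapter; the
  trainer classifies exactly the tokens the offset tokenizer produces.
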