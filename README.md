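# pdcm-ner

A schema-driven toolkit for extracting patient-derived cancer model (PDCM)
metadata — diagnoses, model types, biomarkers, treatments, host strains and
the like — from scientific abstracts, built for curators and text-mining
researchers who need *character-exact* entity mentions rather than bags of
strings.

Curation platforms that aggregate PDX, organoid and cell-line models depend
on attributes scattered through free text. The toolkit implements the two
LLM-era extraction routes for this task, plus everything needed to evaluate
them:

* **Direct prompting with inline tag recovery.** A generative model is asked
  to re-emit each sentence with every entity wrapped in
  `<entity_type>...</entity_type>` tags (the tag vocabulary is exactly the
  schema's 15 type names). Character offsets are recovered by scanning the
  tagged output in tag-stripped coordinates — models are unreliable at
  counting characters, but stripping tags is exact. When the generated text
  drifts from the source, a longest-common-subsequence alignment maps
  surviving spans back (lenient mode) or the sentence is rejected (strict
  mode).
* **Soft prompting as BIO token classification.** A sequence of 30
  continuous "virtual token" vectors, initialized from the embeddings of the
  entity-type names, is prepended to the (frozen) backbone's input and
  trained jointly with a linear head over the `2k + 1 = 31` BIO labels
  (`B-`/`I-` per type plus `O`), with token-level cross-entropy for 50
  epochs at learning rate 0.001. Only the prompt and the head are updated;
  the backbone's parameter fingerprint is asserted unchanged.
* **Evaluation.** Span-level precision `P = TP/(TP+FP)`, recall
  `R = TP/(TP+FN)` and `F1 = 2PR/(P+R)` (0–100 scale) in two settings:
  *exact* (identical start, end, type) and *overlapping* (same type, ≥ 1
  shared character), with true positives counted by a one-to-one
  maximum-cardinality matching so one long prediction can never claim two
  gold mentions. Pairwise-F1 inter-annotator agreement and learning curves
  (F1 vs training fraction) build on the same scorer.
* **Synthetic corpora.** A generator emits documents with exactly-known gold
  spans under configurable per-type frequency profiles, plus simulated
  annotators and mock generative taggers with controlled error rates
  (deletions, boundary shifts, type confusions, spurious and malformed
  tags), so the whole pipeline is testable end to end offline — injected
  error rates must be recovered by the scorer within binomial confidence
  intervals.

## Worked example

Offset recovery on the shipped reference abstract, in which the string
"ALK" occurs four times (`examples/01_offset_recovery.py`):

```text
first mention : 'ALK' at characters 48..51
second mention: 'ALK' at characters 323..326 (sentence-local 141..144 + sentence start 182)
substring check: ALK
```

The parser pinned each tagged mention to its exact position: the first
parenthesised "ALK" spans characters 48–51 of the document, and the second
one — parsed inside its own sentence, which starts at character 182 — maps
back to document characters 323–326. `substring check` confirms the offsets
index the original text.

Soft-prompt training on a learnable synthetic task
(`examples/03_soft_prompt_training.py`):

```text
backbone frozen: True
loss 1.892 -> 0.000; best dev micro-F1 100.0

learning curve (span F1 on held-out sentences vs training fraction):
  fraction 0.05  ( 12 sentences)  F1 70.0
  fraction 0.25  ( 60 sentences)  F1 99.5
  fraction 1.0   (240 sentences)  F1 100.0
```

Training lifted held-out span F1 from near zero to 100 while the backbone
stayed bit-identical, and a quarter of the training data already performs
within half a point of the full set — the characteristic steep-then-flat
shape of prompt-tuning learning curves.

The other examples cover the noisy end-to-end pipeline
(`02_synthetic_pipeline.py`) and simulated inter-annotator agreement
(`04_inter_annotator_agreement.py`). A thin CLI (`pdcm-ner`) exposes the
same operations (`split`, `gen-synthetic`, `annotate`, `train-softprompt`,
`predict-softprompt`, `evaluate`, `iaa`, `learning-curve`); every run writes
a manifest beside its outputs.

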