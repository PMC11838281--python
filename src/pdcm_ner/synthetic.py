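"""Synthetic corpora with known gold spans, simulated annotators, and mock
generative taggers with controlled error rates.

The generator does not try to write convincing scientific prose: its job is
to produce schema-conformant documents whose gold annotation is known
*exactly* (every mention is embedded at a recorded offset), with per-type
mention frequencies following a configurable profile shaped like real
curated abstract collections (frequent diagnosis/biomarker/treatment
mentions, rare cancer_grade/cancer_stage), comma-separated biomarker list
mentions, and boundary-prone variants ("PDX" vs "PDX models"). That is
exactly what is needed to exercise the tagging parser, the BIO codec and the
scorer, and to verify that injected error rates are recovered by evaluation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .prompting import extract_query_sentence
from .schema import AnnotationSet, Corpus, Document, EntitySchema, Span, default_schema

__all__ = [
    "FrequencyProfile",
    "ErrorModel",
    "LEXICONS",
    "table2_like_profile",
    "uniform_profile",
    "rare_types_profile",
    "generate_corpus",
    "perturb_annotations",
    "mock_tagger",
    "MockTaggerAdapter",
]

# Surface-form lexicons per entity type; seeded from the curation examples of
# the shipped schema and extended with domain-plausible variants. Surfaces are
# unique to one type so that identical synthetic sentences always imply
# identical gold annotations.
LEXICONS: dict[str, tuple[str, ...]] = {
    "diagnosis": (
        "triple-negative breast cancer", "TNBC", "lung adenocarcinoma",
        "Ewing sarcoma", "colorectal carcinoma", "glioblastoma",
    ),
    "age_category": ("adult", "pediatric", "elderly"),
    "genetic_effect": ("missense mutation", "amplification", "gene rearrangement", "deletion"),
    "model_type": ("PDX", "organoid", "cell line", "xenograft"),
    "molecular_char": ("RNA sequencing", "whole-exome sequencing", "immunohistochemistry", "copy number profiling"),
    "biomarker": ("BRCA1", "IDH1", "KRAS", "TP53", "PTEN", "RB1", "ALK", "EGFR", "MEK", "AR", "BRCA2", "NPM1"),
    "treatment": ("chemotherapy", "PARP-inhibitor", "cisplatin", "radiotherapy", "MEK inhibitor therapy", "surgery"),
    "response_to_treatment": ("reduced tumour growth", "progression-free survival", "complete response", "stable disease"),
    "sample_type": ("tissue fragment", "autopsy specimen", "biopsy", "pleural effusion"),
    "tumour_type": ("primary", "recurrent", "metastatic"),
    "cancer_grade": ("grade 1", "low-grade", "high-grade"),
    "cancer_stage": ("stage I", "stage IV", "T0"),
    "clinical_trial": ("phase II", "NCT02720341", "prospective randomized trial"),
    "host_strain": ("NOD-SCID", "NSG", "nude mice"),
    "model_id": ("PHLC402", "CRC119X", "GBM39"),
}

_OPENERS = (
    "In this study, we characterised",
    "The cohort analysis examined",
    "Histopathological review confirmed",
    "Further experiments investigated",
    "Molecular profiling identified",
    "Preclinical testing evaluated",
)
_CONNECTORS = ("together with", "alongside", "as well as", "in combination with")
_CLOSERS = (
    "in the established models.",
    "across all engrafted samples.",
    "during serial passaging.",
    "in the validation cohort.",
)
_FILLERS = (
    "These findings support further preclinical investigation.",
    "Model establishment followed standard operating procedures.",
    "All experiments were performed in triplicate.",
    "The results were consistent across passages.",
)


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-type expected mentions per abstract, plus surface-shape knobs."""

    rates: Mapping[str, float]
    list_mention_prob: float = 0.3      # chance a biomarker batch is a comma list
    list_types: tuple[str, ...] = ("biomarker",)
    boundary_variant_prob: float = 0.3  # chance of appending a trailing head noun
    boundary_variant_types: tuple[str, ...] = ("model_type",)
    boundary_variant_suffix: str = " models"

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("mention rates must be non-negative")
        for p in (self.list_mention_prob, self.boundary_variant_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


def table2_like_profile() -> FrequencyProfile:
    """Per-abstract mention rates shaped like a curated 100-abstract corpus:
    diagnosis/biomarker/treatment frequent, cancer_grade/cancer_stage rare
    (about 33 mentions per abstract in total)."""
    return FrequencyProfile(
        rates={
            "diagnosis": 5.98, "age_category": 0.19, "genetic_effect": 1.22,
            "model_type": 5.50, "molecular_char": 2.11, "biomarker": 7.84,
            "treatment": 6.33, "response_to_treatment": 1.48, "sample_type": 0.37,
            "tumour_type": 1.08, "cancer_grade": 0.08, "cancer_stage": 0.12,
            "clinical_trial": 0.41, "host_strain": 0.16, "model_id": 0.26,
        }
    )


def uniform_profile(rate: float = 2.0) -> FrequencyProfile:
    return FrequencyProfile(rates={name: rate for name in LEXICONS})


def rare_types_profile() -> FrequencyProfile:
    """Only the rarely-annotated types, for stress-testing sparse scoring."""
    return FrequencyProfile(
        rates={
            "cancer_grade": 1.0, "cancer_stage": 1.0, "host_strain": 1.0,
            "model_id": 1.0, "sample_type": 1.0,
        }
    )


@dataclass(frozen=True)
class ErrorModel:
    """Controlled error rates for simulated annotators and mock taggers."""

    deletion_rate: float = 0.0
    spurious_rate: float = 0.0
    boundary_shift_rate: float = 0.0
    max_shift_tokens: int = 1
    type_confusion_rate: float = 0.0
    confusion_pairs: tuple[tuple[str, str], ...] = (("biomarker", "treatment"),)
    tag_malformation_rate: float = 0.0
    text_drift_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("deletion_rate", "spurious_rate", "boundary_shift_rate",
                     "type_confusion_rate", "tag_malformation_rate", "text_drift_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def confused(self, etype: str) -> str | None:
        for a, b in self.confusion_pairs:
            if etype == a:
                return b
            if etype == b:
                return a
        return None


class _SentenceBuilder:
    """Accumulates text and mention offsets for one sentence."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.spans: list[Span] = []

    def text(self, s: str) -> None:
        self.parts.append(s)
        self.length += len(s)

    def mention(self, surface: str, etype: str) -> None:
        self.spans.append(Span(self.length, self.length + len(surface), etype, surface))
        self.text(surface)

    def build(self) -> tuple[str, list[Span]]:
        return "".join(self.parts), self.spans


def _make_sentence(mentions: Sequence[tuple[str, str]], rng: np.random.Generator,
                   as_list: bool = False) -> tuple[str, list[Span]]:
    b = _SentenceBuilder()
    if as_list:
        b.text("Genomic alterations involved ")
        for k, (surface, etype) in enumerate(mentions):
            if k > 0:
                b.text(", and " if k == len(mentions) - 1 else ", ")
            b.mention(surface, etype)
        b.text(" in most samples.")
    else:
        b.text(str(rng.choice(_OPENERS)) + " ")
        for k, (surface, etype) in enumerate(mentions):
            if k > 0:
                b.text(" " + str(rng.choice(_CONNECTORS)) + " ")
            b.mention(surface, etype)
        b.text(" " + str(rng.choice(_CLOSERS)))
    return b.build()


def generate_corpus(
    schema: EntitySchema | None = None,
    profile: FrequencyProfile | None = None,
    n_docs: int = 10,
    seed: int = 0,
) -> Corpus:
    """Generate ``n_docs`` documents with exactly-known gold annotations.

    Each document is 3-8 template sentences. Per-type mention counts are
    Poisson around the profile rates. Deterministic for a fixed seed.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    schema = schema or default_schema()
    profile = profile or table2_like_profile()
    if not any(r > 0 for r in profile.rates.values()):
        raise ValueError("frequency profile has all-zero rates")
    rng = np.random.default_rng(seed)

    documents: list[Document] = []
    gold_sets: list[AnnotationSet] = []
    for d in range(n_docs):
        mentions: list[tuple[str, str]] = []
        list_batches: list[list[tuple[str, str]]] = []
        for etype in schema.names:
            rate = profile.rates.get(etype, 0.0)
            if rate <= 0:
                continue
            count = int(rng.poisson(rate))
            if count == 0:
                continue
            lexicon = LEXICONS.get(etype, (etype.replace("_", " "),))
            surfaces = [str(rng.choice(lexicon)) for _ in range(count)]
            if etype in profile.boundary_variant_types:
                surfaces = [
                    s + profile.boundary_variant_suffix
                    if rng.random() < profile.boundary_variant_prob else s
                    for s in surfaces
                ]
            batch = [(s, etype) for s in surfaces]
            if (
                etype in profile.list_types
                and len(batch) >= 3
                and rng.random() < profile.list_mention_prob
            ):
                list_batches.append(batch[:6])
                mentions.extend(batch[6:])
            else:
                mentions.extend(batch)
        order = rng.permutation(len(mentions))
        mentions = [mentions[i] for i in order]

        sentences_specs: list[tuple[list[tuple[str, str]], bool]] = [
            (batch, True) for batch in list_batches
        ]
        # pack remaining mentions into sentences of 1-4 mentions
        i = 0
        while i < len(mentions):
            k = int(rng.integers(1, 5))
            sentences_specs.append((mentions[i : i + k], False))
            i += k
        while len(sentences_specs) < 3:
            sentences_specs.append(([], False))
        order = rng.permutation(len(sentences_specs))
        sentences_specs = [sentences_specs[i] for i in order]

        doc_text_parts: list[str] = []
        sentence_intervals: list[tuple[int, int]] = []
        doc_spans: list[Span] = []
        pos = 0
        for ms, as_list in sentences_specs:
            if ms:
                sentence, local_spans = _make_sentence(ms, rng, as_list=as_list)
            else:
                sentence, local_spans = str(rng.choice(_FILLERS)), []
            if doc_text_parts:
                doc_text_parts.append(" ")
                pos += 1
            sentence_intervals.append((pos, pos + len(sentence)))
            doc_spans.extend(s.shifted(pos) for s in local_spans)
            doc_text_parts.append(sentence)
            pos += len(sentence)

        doc_id = f"synthetic-{d:04d}"
        doc = Document(id=doc_id, text="".join(doc_text_parts), sentences=sentence_intervals)
        documents.append(doc)
        # drop exact duplicate (start, end, type) triples, which the data
        # model forbids (possible when one surface is sampled twice and lands
        # adjacent — rare but must not produce invalid gold)
        unique: dict[tuple[int, int, str], Span] = {}
        for s in sorted(doc_spans):
            unique[(s.start, s.end, s.type)] = s
        gold_sets.append(AnnotationSet(doc_id=doc_id, source="gold", spans=sorted(unique.values())))

    return Corpus(documents=documents, annotations={"gold": gold_sets})


# ---------------------------------------------------------------------------
# Simulated annotators


def _shift_boundary(span: Span, doc_text: str, rng: np.random.Generator,
                    max_shift_tokens: int) -> Span:
    """Move one boundary outward to a nearby word edge, preserving overlap."""
    shift = int(rng.integers(1, max_shift_tokens + 1))
    if rng.random() < 0.5:
        # extend end over up to `shift` following words
        e = span.end
        for _ in range(shift):
            while e < len(doc_text) and doc_text[e] == " ":
                e += 1
            while e < len(doc_text) and doc_text[e] not in " .,;":
                e += 1
        if e > span.end:
            return Span(span.start, e, span.type, doc_text[span.start : e])
    s = span.start
    for _ in range(shift):
        while s > 0 and doc_text[s - 1] == " ":
            s -= 1
        while s > 0 and doc_text[s - 1] not in " .,;":
            s -= 1
    if s < span.start:
        return Span(s, span.end, span.type, doc_text[s : span.end])
    return span


def perturb_annotations(
    corpus: Corpus,
    error_model: ErrorModel,
    seed: int,
    source: str = "gold",
    new_source: str = "annotator:sim",
) -> list[AnnotationSet]:
    """Derive a noisy annotator from ``source`` by applying the error model.

    Deletions, type confusions, word-boundary shifts and spurious insertions
    are applied independently per span at the configured rates, so the
    expected TP/FP/FN of the result against the original is available in
    closed form. The output always validates against the documents.
    """
    rng = np.random.default_rng(seed)
    out: list[AnnotationSet] = []
    for doc in corpus.documents:
        gold = corpus.annotations_for(source, doc.id)
        spans: list[Span] = []
        for span in gold.spans:
            if rng.random() < error_model.deletion_rate:
                continue
            new = span
            if rng.random() < error_model.type_confusion_rate:
                other = error_model.confused(new.type)
                if other is not None:
                    new = replace(new, type=other)
            if rng.random() < error_model.boundary_shift_rate:
                new = _shift_boundary(new, doc.text, rng, error_model.max_shift_tokens)
            spans.append(new)
            if rng.random() < error_model.spurious_rate:
                spans.append(_spurious_span(doc, gold.spans, rng))
        unique: dict[tuple[int, int, str], Span] = {}
        for s in sorted(spans):
            unique[(s.start, s.end, s.type)] = s
        out.append(AnnotationSet(doc_id=doc.id, source=new_source, spans=sorted(unique.values())))
    return out


def _spurious_span(doc: Document, gold: Sequence[Span], rng: np.random.Generator) -> Span:
    """A random single-word span over unannotated text, with a random type."""
    words = []
    i = 0
    text = doc.text
    while i < len(text):
        if text[i].isalnum():
            j = i
            while j < len(text) and text[j].isalnum():
                j += 1
            if not any(g.start < j and i < g.end for g in gold):
                words.append((i, j))
            i = j
        else:
            i += 1
    if not words:
        start, end = 0, min(4, len(text))
    else:
        start, end = words[int(rng.integers(len(words)))]
    etype = sorted(LEXICONS)[int(rng.integers(len(LEXICONS)))]
    return Span(start, end, etype, text[start:end])


# ---------------------------------------------------------------------------
# Mock generative tagger


class MockTaggerAdapter:
    """A GeneratorAdapter that answers from the gold corpus with injected noise.

    ``generate`` recovers the query sentence from the prompt, looks up that
    sentence's gold spans, applies the error model (deletion, type confusion,
    boundary shift, tag malformation, text drift) and emits the XML-tagged
    sentence. Noise is derived per sentence from (seed, sentence digest), so
    output is deterministic regardless of call order. Unknown sentences come
    back untagged.
    """

    def __init__(self, corpus: Corpus, error_model: ErrorModel | None = None,
                 seed: int = 0, source: str = "gold", name: str = "mock") -> None:
        self.name = name
        self.error_model = error_model or ErrorModel()
        self.seed = seed
        self._gold_by_sentence: dict[str, list[Span]] = {}
        for doc in corpus.documents:
            gold = corpus.annotations_for(source, doc.id)
            for start, end in doc.sentences:
                sentence = doc.text[start:end]
                local = [
                    s.shifted(-start)
                    for s in gold.spans
                    if s.start >= start and s.end <= end
                ]
                self._gold_by_sentence[sentence] = sorted(local)

    def _rng_for(self, sentence: str) -> np.random.Generator:
        digest = hashlib.blake2b(sentence.encode("utf-8"), digest_size=4).digest()
        return np.random.default_rng((self.seed, int.from_bytes(digest, "big")))

    def generate(self, prompt: str) -> str:
        sentence = extract_query_sentence(prompt)
        if sentence is None:
            return ""
        spans = self._gold_by_sentence.get(sentence)
        if spans is None:
            return sentence
        em = self.error_model
        rng = self._rng_for(sentence)

        kept: list[Span] = []
        malformed: list[Span] = []
        n_spurious = 0
        for span in spans:
            if rng.random() < em.spurious_rate:
                n_spurious += 1
            if rng.random() < em.deletion_rate:
                continue
            if rng.random() < em.type_confusion_rate:
                other = em.confused(span.type)
                if other is not None:
                    span = replace(span, type=other)
            if rng.random() < em.boundary_shift_rate:
                span = _shift_boundary(span, sentence, rng, em.max_shift_tokens)
            if rng.random() < em.tag_malformation_rate:
                malformed.append(span)
            else:
                kept.append(span)
        # spurious tags over untagged words (one expected per gold span at
        # rate spurious_rate, so E[FP] = rate * n_gold in closed form)
        for _ in range(n_spurious):
            extra = _untagged_word_span(sentence, kept + malformed + spans, rng)
            if extra is not None:
                kept.append(extra)

        # emit the sentence with tags inserted right-to-left so offsets hold
        out = sentence
        events: list[tuple[int, int, str, bool]] = [
            (s.start, s.end, s.type, False) for s in kept
        ] + [(s.start, s.end, s.type, True) for s in malformed]
        for start, end, etype, broken in sorted(events, reverse=True):
            if broken:
                out = out[:start] + f"<{etype}>" + out[start:]  # opening tag never closed
            else:
                out = out[:start] + f"<{etype}>" + out[start:end] + f"</{etype}>" + out[end:]

        if rng.random() < em.text_drift_rate:
            out = _drop_untagged_word(out, rng)
        return out


def _untagged_word_span(sentence: str, taken: Sequence[Span],
                        rng: np.random.Generator) -> Span | None:
    """A random word interval disjoint from all taken spans, random type."""
    candidates = []
    i = 0
    while i < len(sentence):
        if sentence[i].isalnum():
            j = i
            while j < len(sentence) and sentence[j].isalnum():
                j += 1
            if not any(t.start < j and i < t.end for t in taken):
                candidates.append((i, j))
            i = j
        else:
            i += 1
    if not candidates:
        return None
    start, end = candidates[int(rng.integers(len(candidates)))]
    etype = sorted(LEXICONS)[int(rng.integers(len(LEXICONS)))]
    return Span(start, end, etype, sentence[start:end])


def _drop_untagged_word(tagged: str, rng: np.random.Generator) -> str:
    """Simulate generation drift: delete one word outside any tag."""
    words = []
    depth = 0
    i = 0
    while i < len(tagged):
        if tagged[i] == "<":
            depth += 1 if not tagged.startswith("</", i) else -1
            while i < len(tagged) and tagged[i] != ">":
                i += 1
            i += 1
            continue
        if tagged[i].isalnum() and depth <= 0:
            j = i
            while j < len(tagged) and tagged[j].isalnum():
                j += 1
            words.append((i, j))
            i = j
        else:
            i += 1
    if not words:
        return tagged
    s, e = words[int(rng.integers(len(words)))]
    while e < len(tagged) and tagged[e] == " ":
        e += 1
    return tagged[:s] + tagged[e:]


def mock_tagger(corpus: Corpus, error_model: ErrorModel | None = None,
                seed: int = 0, name: str = "mock") -> MockTaggerAdapter:
    """Factory mirroring the adapter constructor, for symmetry with the API."""
    return MockTaggerAdapter(corpus, error_model=error_model, seed=seed, name=name)


# ---------------------------------------------------------------------------
# Deterministic cue-word data for soft-prompt recovery experiments


def corpus_to_bio(corpus: Corpus, labels, source: str = "gold"):
    """Convert a corpus into per-sentence (tokens, BIO labels) pairs."""
    from .bio import spans_to_bio, tokenize_with_offsets

    out = []
    for doc in corpus.documents:
        ann = corpus.annotations_for(source, doc.id)
        for start, end in doc.sentences:
            tokens = tokenize_with_offsets(doc.text[start:end])
            local = [s.shifted(-start) for s in ann.spans if s.start >= start and s.end <= end]
            out.append((tokens, spans_to_bio(tokens, local, labels)))
    return out


_CUE_FILLERS = (
    "the", "study", "observed", "results", "in", "samples",
    "analysis", "showed", "with", "cohort",
)


def cue_word_dataset(
    schema: EntitySchema,
    n_sentences: int,
    seed: int = 0,
    entity_prob: float = 0.35,
):
    """Token-classification data whose entities are deterministic cue words.

    Every entity type gets dedicated surface cues (one- and two-token) that
    never occur as filler or under another type, so the token -> label
    mapping is noise-free; what remains to learn is precisely the mapping.
    This is the corpus for parameter-recovery experiments: a trainable
    classifier must approach perfect span F1 on held-out sentences.

    Returns a list of ``(tokens, labels)`` pairs.
    """
    from .bio import LabelSet, spans_to_bio, tokenize_with_offsets

    labels = LabelSet.from_schema(schema)
    names = schema.names
    single_cues = {t: (f"{t}cueA", f"{t}cueB") for t in names}
    double_cues = {t: f"{t}first {t}second" for t in names[:5]}
    rng = np.random.default_rng(seed)

    data = []
    for _ in range(n_sentences):
        words: list[str] = []
        spans: list[Span] = []
        for _ in range(int(rng.integers(6, 12))):
            if rng.random() < entity_prob:
                t = names[int(rng.integers(len(names)))]
                if t in double_cues and rng.random() < 0.4:
                    surface = double_cues[t]
                else:
                    surface = single_cues[t][int(rng.integers(2))]
                start = sum(len(w) + 1 for w in words)
                words.extend(surface.split())
                spans.append(Span(start, start + len(surface), t, surface))
            else:
                words.append(_CUE_FILLERS[int(rng.integers(len(_CUE_FILLERS)))])
        sentence = " ".join(words)
        tokens = tokenize_with_offsets(sentence)
        data.append((tokens, spans_to_bio(tokens, spans, labels)))
    return data
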