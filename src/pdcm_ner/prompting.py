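"""Few-shot direct prompting and recovery of spans from XML-tagged output.

The extraction route implemented here treats entity recognition as text
generation: the model is asked to re-emit the input sentence with every
entity mention wrapped in ``<entity_type>...</entity_type>`` tags, where the
tag vocabulary is exactly the schema's type names. Character offsets are then
recovered by scanning the tagged output left-to-right and counting characters
in tag-stripped coordinates — generative models are unreliable at counting
characters themselves, but stripping tags from their output is exact.

When the generated residual text differs from the source sentence ("drift"),
strict mode rejects the whole sentence, while lenient mode aligns residual to
source by longest-common-subsequence and maps span endpoints through the
alignment, dropping spans whose characters cannot all be aligned.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

from .schema import AnnotationSet, Document, EntitySchema, Span

__all__ = [
    "PromptConfig",
    "GeneratorAdapter",
    "ParseWarning",
    "ParseReport",
    "DEFAULT_INSTRUCTION",
    "build_prompt",
    "parse_tagged_output",
    "map_to_document",
    "extract_document",
    "extract_query_sentence",
    "FileReplayAdapter",
]

logger = logging.getLogger(__name__)

DEFAULT_INSTRUCTION = (
    "You will be given one sentence from a scientific abstract about "
    "patient-derived cancer models. Copy the sentence exactly, but wrap every "
    "entity mention in XML-style tags: mark the start of an entity with "
    "<entity_type> and its end with </entity_type>, where entity_type is one of "
    "the types defined below. Do not change, add or remove any other characters."
)

DEFAULT_TEMPLATE = (
    "{instruction}\n"
    "\n"
    "{definitions}"
    "{examples}"
    "Input: {query}\n"
    "Output:"
)

_QUERY_SUFFIX = "\nOutput:"


@runtime_checkable
class GeneratorAdapter(Protocol):
    """Text-in/text-out contract over any generative model (or a mock)."""

    name: str

    def generate(self, prompt: str) -> str: ...


@dataclass(frozen=True)
class ParseWarning:
    kind: str  # "unbalanced tag" | "unknown tag" | "nested tag" | "malformed tag"
               # | "empty span" | "text drift" | "unaligned span"
    detail: str


@dataclass
class ParseReport:
    """Spans recovered from one tagged sentence, plus everything suspicious."""

    spans: list[Span] = field(default_factory=list)
    warnings: list[ParseWarning] = field(default_factory=list)
    strict_failure: bool = False


@dataclass
class PromptConfig:
    """Configuration of the few-shot prompt.

    ``examples`` are (plain sentence, tagged sentence) pairs; the first
    ``n_examples`` of them are included. Tagged examples must themselves
    parse cleanly against their plain form — a prompt that demonstrates
    malformed tagging is a configuration error.
    """

    instruction: str = DEFAULT_INSTRUCTION
    include_definitions: bool = True
    n_examples: int = 5
    examples: Sequence[tuple[str, str]] = ()
    template: str = DEFAULT_TEMPLATE

    def validate(self, schema: EntitySchema) -> None:
        if self.n_examples > len(self.examples):
            raise ValueError(
                f"n_examples={self.n_examples} but only {len(self.examples)} examples given"
            )
        for sentence, tagged in self.examples[: self.n_examples]:
            report = parse_tagged_output(tagged, sentence, schema, strict=True)
            if report.strict_failure or report.warnings:
                raise ValueError(
                    f"prompt example does not parse cleanly: {tagged!r} "
                    f"({[w.kind for w in report.warnings] or 'text drift'})"
                )


def build_prompt(config: PromptConfig, schema: EntitySchema, query_sentence: str) -> str:
    """Assemble the deterministic prompt: instruction, definitions, examples, query."""
    if not query_sentence:
        raise ValueError("query sentence must be nonempty")
    config.validate(schema)
    definitions = ""
    if config.include_definitions:
        lines = [f"- {t.name}: {t.definition}" for t in schema.types]
        definitions = "Entity definitions:\n" + "\n".join(lines) + "\n\n"
    examples = ""
    if config.n_examples > 0:
        blocks = [
            f"Input: {sentence}\nOutput: {tagged}"
            for sentence, tagged in config.examples[: config.n_examples]
        ]
        examples = "Examples:\n" + "\n\n".join(blocks) + "\n\n"
    return config.template.format(
        instruction=config.instruction,
        definitions=definitions,
        examples=examples,
        query=query_sentence,
    )


def extract_query_sentence(prompt: str) -> str | None:
    """Recover the query sentence from a prompt built by :func:`build_prompt`.

    Used by replay/mock adapters, which must answer from the prompt text alone.
    """
    idx = prompt.rfind("Input: ")
    if idx < 0:
        return None
    tail = prompt[idx + len("Input: ") :].rstrip()
    if not tail.endswith(_QUERY_SUFFIX.rstrip()):
        return None
    return tail[: -len(_QUERY_SUFFIX.rstrip())].rstrip("\n")


# ---------------------------------------------------------------------------
# Tag parsing


def _tag_pattern(schema: EntitySchema) -> re.Pattern[str]:
    # Closed vocabulary: only schema type names are tag candidates; any other
    # angle-bracketed text is literal (abstracts can contain genuine "<").
    names = "|".join(re.escape(n) for n in schema.names)
    return re.compile(rf"<(?P<close>/)?(?P<name>{names})(?P<extra>[^<>]*?)(?P<self>/)?>")


def parse_tagged_output(
    tagged_text: str,
    source_sentence: str,
    schema: EntitySchema,
    strict: bool = False,
) -> ParseReport:
    """Recover sentence-local spans from XML-tagged generator output.

    Scans left-to-right, computing offsets in tag-stripped coordinates. Every
    pathology (unbalanced, nested, attribute-bearing or self-closing tags)
    becomes a warning, never an exception. If the tag-stripped residual does
    not equal ``source_sentence``, strict mode returns ``strict_failure`` with
    no spans; lenient mode aligns residual to source by character LCS and maps
    spans through the alignment (requiring >= 90% of the source characters to
    align, and every character of a surviving span to align).
    """
    report = ParseReport()
    pattern = _tag_pattern(schema)

    stripped_parts: list[str] = []
    stripped_len = 0
    open_tag: tuple[str, int] | None = None  # (type, start in stripped coords)
    raw_spans: list[Span] = []  # offsets in stripped coordinates
    pos = 0
    for m in pattern.finditer(tagged_text):
        literal = tagged_text[pos : m.start()]
        stripped_parts.append(literal)
        stripped_len += len(literal)
        pos = m.end()
        name = m.group("name")
        if m.group("extra") or m.group("self"):
            report.warnings.append(
                ParseWarning("malformed tag", f"{m.group(0)!r} has attributes or is self-closing")
            )
            continue
        if m.group("close"):
            if open_tag is None or open_tag[0] != name:
                report.warnings.append(
                    ParseWarning("unbalanced tag", f"closing {m.group(0)!r} without matching open tag")
                )
                continue
            t, start = open_tag
            open_tag = None
            if start == stripped_len:
                report.warnings.append(ParseWarning("empty span", f"<{t}></{t}> covers no text"))
                continue
            raw_spans.append(Span(start, stripped_len, t, "".join(stripped_parts)[start:stripped_len]))
        else:
            if open_tag is not None:
                report.warnings.append(
                    ParseWarning("nested tag", f"<{name}> opened inside <{open_tag[0]}>; ignored")
                )
                continue
            open_tag = (name, stripped_len)
    tail = tagged_text[pos:]
    stripped_parts.append(tail)
    stripped_len += len(tail)
    if open_tag is not None:
        report.warnings.append(ParseWarning("unbalanced tag", f"<{open_tag[0]}> never closed"))

    residual = "".join(stripped_parts)

    if residual == source_sentence:
        report.spans = raw_spans
        return report

    report.warnings.append(
        ParseWarning("text drift", "tag-stripped output differs from the source sentence")
    )
    if strict:
        report.strict_failure = True
        return report

    mapping = _lcs_mapping(residual, source_sentence)
    if len(mapping) < 0.9 * len(source_sentence):
        report.warnings.append(
            ParseWarning("text drift", "alignment covers < 90% of source characters")
        )
        report.strict_failure = True
        return report
    for span in raw_spans:
        positions = [mapping[i] for i in range(span.start, span.end) if i in mapping]
        if len(positions) != span.end - span.start:
            report.warnings.append(
                ParseWarning("unaligned span", f"dropped {span.type} span {span.text!r}")
            )
            continue
        s, e = positions[0], positions[-1] + 1
        report.spans.append(Span(s, e, span.type, source_sentence[s:e]))
    return report


def _lcs_mapping(a: str, b: str) -> dict[int, int]:
    """Index map a->b along one longest common subsequence of ``a`` and ``b``."""
    m, n = len(a), len(b)
    # O(m*n) DP table of LCS lengths; sentences are short so this is cheap
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        ai = a[i]
        for j in range(n - 1, -1, -1):
            row[j] = nxt[j + 1] + 1 if ai == b[j] else max(nxt[j], row[j + 1])
    mapping: dict[int, int] = {}
    i = j = 0
    while i < m and j < n:
        if a[i] == b[j]:
            mapping[i] = j
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return mapping


def map_to_document(spans: Sequence[Span], sentence_start: int, doc_length: int | None = None) -> list[Span]:
    """Shift sentence-local spans into document coordinates."""
    shifted = [s.shifted(sentence_start) for s in spans]
    if doc_length is not None:
        for s in shifted:
            if s.end > doc_length:
                raise ValueError(
                    f"span {s} exceeds document length {doc_length} after shifting by {sentence_start}"
                )
    return shifted


def extract_document(
    doc: Document,
    adapter: GeneratorAdapter,
    config: PromptConfig,
    schema: EntitySchema,
    strict: bool = False,
) -> AnnotationSet:
    """Run sentence-at-a-time extraction over one document.

    Each sentence is prompted, generated, parsed and mapped to document
    coordinates. Adapter failures and parse warnings are logged per sentence
    and never abort the document.
    """
    if not doc.sentences:
        raise ValueError(f"document {doc.id!r} has no sentence intervals; run the splitter first")
    spans: list[Span] = []
    for idx, (start, end) in enumerate(doc.sentences):
        sentence = doc.text[start:end]
        prompt = build_prompt(config, schema, sentence)
        try:
            completion = adapter.generate(prompt)
        except Exception:
            logger.exception("adapter %s failed on %s sentence %d; skipped", adapter.name, doc.id, idx)
            continue
        report = parse_tagged_output(completion, sentence, schema, strict=strict)
        for w in report.warnings:
            logger.info("%s sentence %d: %s (%s)", doc.id, idx, w.kind, w.detail)
        spans.extend(map_to_document(report.spans, start, doc_length=len(doc.text)))
    return AnnotationSet(doc_id=doc.id, source=f"system:{adapter.name}", spans=spans)


class FileReplayAdapter:
    """Replays pre-recorded completions, enabling offline reproduction of a run.

    The replay file is JSON-lines with objects
    ``{"doc_id": ..., "sentence_index": ..., "sentence": ..., "completion": ...}``.
    Lookup is by the sentence text recovered from the prompt, so the adapter
    honours the plain text-in/text-out generator contract.
    """

    def __init__(self, path: str | Path, name: str = "file-replay") -> None:
        self.name = name
        self._by_sentence: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                self._by_sentence[rec["sentence"]] = rec["completion"]

    def generate(self, prompt: str) -> str:
        query = extract_query_sentence(prompt)
        if query is None or query not in self._by_sentence:
            return query or ""
        return self._by_sentence[query]
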