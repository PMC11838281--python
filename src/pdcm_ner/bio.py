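"""BIO codec: spans <-> per-token labels, plus an offset-preserving tokenizer.

Token classification casts extraction as assigning one label per token: the
first token of a mention gets ``B-<type>``, subsequent tokens ``I-<type>``,
everything else ``O``. A k-type schema therefore yields ``2k + 1`` labels —
31 for the shipped 15-type schema.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Sequence

from .schema import EntitySchema, Span

__all__ = [
    "Token",
    "LabelSet",
    "tokenize_with_offsets",
    "spans_to_bio",
    "bio_to_spans",
    "read_conll",
    "write_conll",
]

_PUNCT = set(string.punctuation)


@dataclass(frozen=True)
class Token:
    """One token with its [start, end) character interval in the sentence."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class LabelSet:
    """Ordered BIO labels: ``O`` first, then B-/I- per schema type in order."""

    labels: tuple[str, ...]

    @classmethod
    def from_schema(cls, schema: EntitySchema) -> "LabelSet":
        labels = ["O"]
        for name in schema.names:
            labels.append(f"B-{name}")
            labels.append(f"I-{name}")
        return cls(labels=tuple(labels))

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels


def tokenize_with_offsets(sentence: str) -> list[Token]:
    """Whitespace tokenization with leading/trailing punctuation detached.

    ``"(ALK),"`` becomes four tokens ``(`` ``ALK`` ``)`` ``,``. Offsets are
    exact: each token's text equals the sentence substring at its interval,
    and concatenating tokens with the skipped whitespace reconstructs the
    sentence. Internal punctuation (hyphens, decimal points) stays attached.
    """
    tokens: list[Token] = []
    i = 0
    n = len(sentence)
    while i < n:
        if sentence[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not sentence[j].isspace():
            j += 1
        # detach leading punctuation
        a, b = i, j
        while a < b and sentence[a] in _PUNCT and b - a > 1:
            tokens.append(Token(sentence[a], a, a + 1))
            a += 1
        # find trailing punctuation run
        t = b
        while t > a + 1 and sentence[t - 1] in _PUNCT:
            t -= 1
        tokens.append(Token(sentence[a:t], a, t))
        for k in range(t, b):
            tokens.append(Token(sentence[k], k, k + 1))
        i = j
    return tokens


def _snap_span(span: Span, tokens: Sequence[Token]) -> tuple[int, int] | None:
    """Token index range [first, last] covering the span, or None if disjoint."""
    covered = [k for k, t in enumerate(tokens) if t.start < span.end and span.start < t.end]
    if not covered:
        return None
    return covered[0], covered[-1]


def spans_to_bio(
    tokens: Sequence[Token],
    spans: Sequence[Span],
    labels: LabelSet,
) -> list[str]:
    """Encode sentence-local spans as one BIO label per token.

    Spans must be non-overlapping. A span boundary falling strictly inside a
    token is snapped outward to the enclosing token boundaries (gold data
    occasionally violates token alignment; snapping loses at most the
    sub-token fringe).
    """
    for i, a in enumerate(spans):
        for b in spans[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"overlapping spans: {a} and {b}")
    out = ["O"] * len(tokens)
    for span in sorted(spans):
        if f"B-{span.type}" not in labels:
            raise KeyError(f"span type {span.type!r} not in label set")
        snapped = _snap_span(span, tokens)
        if snapped is None:
            continue
        first, last = snapped
        out[first] = f"B-{span.type}"
        for k in range(first + 1, last + 1):
            out[k] = f"I-{span.type}"
    return out


def bio_to_spans(tokens: Sequence[Token], labels: Sequence[str]) -> list[Span]:
    """Decode BIO labels back into spans.

    Maximal B-then-I runs of one type become spans from the first token's
    start to the last token's end. Invalid sequences are repaired with the
    IOB2 convention: ``I-x`` without a preceding ``B-x``/``I-x`` (including
    after a different type) opens a new span.
    """
    if len(labels) != len(tokens):
        raise ValueError(f"{len(labels)} labels for {len(tokens)} tokens")
    spans: list[Span] = []
    current: tuple[str, int, int] | None = None  # (type, start_char, end_char)

    def flush() -> None:
        nonlocal current
        if current is not None:
            t, s, e = current
            spans.append(Span(s, e, t, _join_tokens(tokens, s, e)))
            current = None

    for token, label in zip(tokens, labels):
        if label == "O":
            flush()
            continue
        if len(label) < 3 or label[1] != "-" or label[0] not in "BI":
            raise ValueError(f"unknown label {label!r}")
        prefix, etype = label[0], label[2:]
        if prefix == "B" or current is None or current[0] != etype:
            flush()
            current = (etype, token.start, token.end)
        else:
            current = (etype, current[1], token.end)
    flush()
    return spans


def _join_tokens(tokens: Sequence[Token], start: int, end: int) -> str:
    """Surface text of the char interval, reconstructed from token coverage."""
    parts: list[str] = []
    last_end: int | None = None
    for t in tokens:
        if t.start >= start and t.end <= end:
            if last_end is not None and t.start > last_end:
                parts.append(" " * (t.start - last_end))
            parts.append(t.text)
            last_end = t.end
    return "".join(parts)


# ---------------------------------------------------------------------------
# CoNLL-style two-column interchange


def write_conll(sentences: Iterable[tuple[Sequence[Token], Sequence[str]]], path) -> None:
    """Write (tokens, labels) sentences as two-column text, blank-line separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, labels in sentences:
            for token, label in zip(tokens, labels):
                fh.write(f"{token.text}\t{label}\n")
            fh.write("\n")


def read_conll(path) -> list[tuple[list[Token], list[str]]]:
    """Read two-column token/label sentences; offsets are reconstructed
    assuming single spaces between tokens."""
    sentences: list[tuple[list[Token], list[str]]] = []
    tokens: list[Token] = []
    labels: list[str] = []
    pos = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                if tokens:
                    sentences.append((tokens, labels))
                tokens, labels, pos = [], [], 0
                continue
            text, label = line.split("\t")
            tokens.append(Token(text, pos, pos + len(text)))
            labels.append(label)
            pos += len(text) + 1
    if tokens:
        sentences.append((tokens, labels))
    return sentences
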