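"""Rule-based sentence segmentation producing character intervals.

Abstracts are processed one sentence at a time, so segmentation only has to
be deterministic and offset-faithful: every interval indexes directly into
the document text, and all annotation spans stay in document coordinates, so
a boundary placed differently than another splitter would only changes the
windows shown to a model, never the recorded offsets.

A boundary is placed after sentence-final punctuation (``.``, ``!``, ``?``)
that is followed by whitespace and an uppercase letter or a digit, unless the
period terminates a known abbreviation (``et al.``, ``Fig.``, ``vs.``,
``e.g.``, ``i.e.``, ...), a single capital initial ("J. Smith"), or sits
between digits ("3.5 mm").
"""

from __future__ import annotations

__all__ = ["split_sentences", "ABBREVIATIONS"]

#: Lowercased tokens that end with a period without ending a sentence.
ABBREVIATIONS = frozenset(
    {
        "al.", "et al.", "fig.", "figs.", "vs.", "e.g.", "i.e.", "cf.", "etc.",
        "dr.", "prof.", "no.", "nos.", "approx.", "resp.", "ca.", "spp.", "sp.",
        "st.", "jr.", "sr.", "vol.", "suppl.", "ref.", "refs.", "eq.", "eqs.",
    }
)


def _word_ending_at(text: str, i: int) -> str:
    """The whitespace-delimited word whose final character is ``text[i]``."""
    j = i
    while j >= 0 and not text[j].isspace():
        j -= 1
    return text[j + 1 : i + 1]


def _is_boundary(text: str, i: int) -> bool:
    """Would a sentence end after the punctuation character at index ``i``?"""
    c = text[i]
    if c not in ".!?":
        return False
    # must be followed by whitespace then an uppercase letter or digit
    j = i + 1
    if j >= len(text) or not text[j].isspace():
        return False
    while j < len(text) and text[j].isspace():
        j += 1
    if j >= len(text) or not (text[j].isupper() or text[j].isdigit()):
        return False
    if c in "!?":
        return True
    # protect decimals / version tokens: digit '.' digit never splits
    if i > 0 and text[i - 1].isdigit() and i + 1 < len(text) and text[i + 1].isdigit():
        return False
    word = _word_ending_at(text, i)
    if word.lower() in ABBREVIATIONS:
        return False
    # "et al." even when tokenised as two words
    if word.lower() == "al." and text[: i + 1].lower().rstrip().endswith("et al."):
        return False
    # single capital initial, e.g. "J."
    if len(word) == 2 and word[0].isupper() and word[0].isalpha():
        return False
    return True


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sorted, non-overlapping (start, end) intervals.

    Intervals are trimmed of surrounding whitespace; every non-whitespace
    character belongs to exactly one interval. Empty or whitespace-only input
    yields an empty list.
    """
    boundaries = [i + 1 for i in range(len(text)) if _is_boundary(text, i)]
    intervals: list[tuple[int, int]] = []
    prev = 0
    for b in boundaries + [len(text)]:
        seg = text[prev:b]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        start, end = prev + lstrip, b - rstrip
        if start < end:
            intervals.append((start, end))
        prev = b
    return intervals
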