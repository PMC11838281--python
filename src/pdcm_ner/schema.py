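"""Entity schema, span/document/corpus data model, validation and corpus splitting.

The data model is deliberately small and file-friendly:

* :class:`EntitySchema` — the ordered list of entity types (names become XML tag
  names and BIO label suffixes, so ordering is contractual).
* :class:`Span` — one entity mention in 0-based, end-exclusive character
  coordinates of the *document*.
* :class:`AnnotationSet` — all spans for one document from one source
  (``"gold"``, ``"annotator:<k>"`` or ``"system:<name>"``).
* :class:`Corpus` — documents plus annotations plus an optional train/dev/test
  assignment.

Everything round-trips through plain-text formats: YAML for the schema,
JSON-lines for documents and standoff annotations.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "EntityType",
    "EntitySchema",
    "Span",
    "Document",
    "AnnotationSet",
    "Corpus",
    "Violation",
    "default_schema",
    "validate_annotation",
    "split_corpus",
]

SPLIT_NAMES = ("train", "dev", "test")


@dataclass(frozen=True)
class EntityType:
    """One entity type: a tag-safe name plus human-readable metadata."""

    name: str
    definition: str = ""
    examples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("entity type name must be nonempty")
        if any(c.isspace() for c in self.name) or "<" in self.name or ">" in self.name:
            raise ValueError(
                f"entity type name {self.name!r} must not contain whitespace or angle "
                "brackets (names are used as XML tag names)"
            )


@dataclass(frozen=True)
class EntitySchema:
    """Ordered set of entity types; the order defines the BIO label order."""

    types: tuple[EntityType, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.types]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate entity type names: {dupes}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.types)

    def __len__(self) -> int:
        return len(self.types)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> EntityType:
        for t in self.types:
            if t.name == name:
                return t
        raise KeyError(name)

    # ---- file format -----------------------------------------------------
    # One YAML mapping per type, in order:
    #   - name: biomarker
    #     definition: ...
    #     examples: [BRCA1, IDH]

    def to_yaml(self) -> str:
        records = [
            {
                "name": t.name,
                "definition": t.definition,
                "examples": list(t.examples),
            }
            for t in self.types
        ]
        return yaml.safe_dump(records, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, text: str) -> "EntitySchema":
        records = yaml.safe_load(text)
        if not isinstance(records, list):
            raise ValueError("schema file must be a YAML list of type records")
        types = tuple(
            EntityType(
                name=str(r["name"]),
                definition=str(r.get("definition", "")),
                examples=tuple(str(e) for e in r.get("examples", []) or ()),
            )
            for r in records
        )
        return cls(types=types)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "EntitySchema":
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"))


# The 15 attributes of the CancerModels.Org data model used as entity types,
# with their curation definitions and canonical examples.
_DEFAULT_TYPES: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    (
        "diagnosis",
        "Diagnosis at the time of collection of the patient tumour used in the "
        "cancer model",
        ("triple-negative breast cancer", "TNBC"),
    ),
    (
        "age_category",
        "Age category of the patient at the time of tissue sampling",
        ("adult", "pediatric"),
    ),
    (
        "genetic_effect",
        "Any form of chromosomal rearrangement or gene-level changes",
        ("missense", "amplification"),
    ),
    (
        "model_type",
        "Type of patient-derived model",
        ("PDX", "organoid"),
    ),
    (
        "molecular_char",
        "Data or assay generated from or performed on the model in this study",
        ("RNA sequencing", "whole-exome sequencing"),
    ),
    (
        "biomarker",
        "Gene, protein or biological molecule identified in or associated with "
        "patient's/model's tumour",
        ("BRCA1", "IDH", "epidermal growth factor receptor 2"),
    ),
    (
        "treatment",
        "Treatment received by the patient or tested on the model",
        ("surgery", "chemotherapy", "PARP-inhibitor"),
    ),
    (
        "response_to_treatment",
        "Effect of the treatment on the patient's tumour or model",
        ("progression-free survival", "reduced tumour growth"),
    ),
    (
        "sample_type",
        "The type of material used to generate the model or how this material "
        "was obtained",
        ("tissue fragment", "autopsy"),
    ),
    (
        "tumour_type",
        "Collected tumour type used for generating the model",
        ("primary", "recurrent"),
    ),
    (
        "cancer_grade",
        "Quantitative or qualitative grade reflecting how quickly the cancer is "
        "likely to grow",
        ("grade 1", "low-grade"),
    ),
    (
        "cancer_stage",
        "Information about the cancer's extent in the body according to specific "
        "type of cancer staging system",
        ("TNM system", "T0", "stage I"),
    ),
    (
        "clinical_trial",
        "The type of clinical trial or Clinicaltrials.org identifier",
        ("phase II", "prospective randomized clinical trials"),
    ),
    (
        "host_strain",
        "The name of the mouse host strain where the tissue sample was engrafted "
        "for generating the PDX model",
        ("NOD-SCID",),
    ),
    (
        "model_id",
        "ID of the patient-derived cancer model generated in this study",
        ("PHLC402",),
    ),
)


def default_schema() -> EntitySchema:
    """The 15-type patient-derived cancer model schema shipped with the toolkit."""
    return EntitySchema(
        types=tuple(EntityType(n, d, ex) for n, d, ex in _DEFAULT_TYPES)
    )


@dataclass(frozen=True, order=True)
class Span:
    """One entity mention: [start, end) character interval with type and text.

    Coordinates are 0-based and end-exclusive: a 3-character mention starting
    at character 48 is ``Span(48, 51, ...)``.
    """

    start: int
    end: int
    type: str
    text: str

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "type": self.type, "text": self.text}

    @classmethod
    def from_dict(cls, d: dict) -> "Span":
        return cls(start=int(d["start"]), end=int(d["end"]), type=str(d["type"]), text=str(d["text"]))

    def shifted(self, offset: int) -> "Span":
        return Span(self.start + offset, self.end + offset, self.type, self.text)

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Document:
    """One abstract: id, full text, and sentence intervals (document coordinates)."""

    id: str
    text: str
    sentences: list[tuple[int, int]] = field(default_factory=list)

    def sentence_text(self, index: int) -> str:
        s, e = self.sentences[index]
        return self.text[s:e]


@dataclass
class AnnotationSet:
    """All spans for one document from one source."""

    doc_id: str
    source: str
    spans: list[Span] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"doc_id": self.doc_id, "source": self.source, "spans": [s.to_dict() for s in self.spans]},
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "AnnotationSet":
        d = json.loads(line)
        return cls(
            doc_id=str(d["doc_id"]),
            source=str(d["source"]),
            spans=[Span.from_dict(s) for s in d["spans"]],
        )


@dataclass
class Corpus:
    documents: list[Document]
    annotations: dict[str, list[AnnotationSet]] = field(default_factory=dict)
    split_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {d.id for d in self.documents}
        for source, sets in self.annotations.items():
            for ann in sets:
                if ann.doc_id not in ids:
                    raise ValueError(
                        f"annotation source {source!r} references unknown doc_id {ann.doc_id!r}"
                    )

    def document(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.id == doc_id:
                return d
        raise KeyError(doc_id)

    def annotations_for(self, source: str, doc_id: str) -> AnnotationSet:
        for ann in self.annotations.get(source, []):
            if ann.doc_id == doc_id:
                return ann
        return AnnotationSet(doc_id=doc_id, source=source, spans=[])

    def split_documents(self, split: str) -> list[Document]:
        return [d for d in self.documents if self.split_assignment.get(d.id) == split]

    # ---- JSON-lines I/O --------------------------------------------------

    def save_documents(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for d in self.documents:
                fh.write(json.dumps({"id": d.id, "text": d.text}, ensure_ascii=False) + "\n")

    def save_annotations(self, path: str | Path, sources: Sequence[str] | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for source in sources if sources is not None else sorted(self.annotations):
                for ann in self.annotations[source]:
                    fh.write(ann.to_json() + "\n")


def load_documents(path: str | Path) -> list[Document]:
    """Read JSON-lines ``{"id": ..., "text": ...}`` documents."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            docs.append(Document(id=str(d["id"]), text=str(d["text"])))
    return docs


def load_annotations(path: str | Path) -> dict[str, list[AnnotationSet]]:
    """Read JSON-lines standoff annotations, grouped by source."""
    by_source: dict[str, list[AnnotationSet]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            ann = AnnotationSet.from_json(line)
            by_source.setdefault(ann.source, []).append(ann)
    return by_source


@dataclass(frozen=True)
class Violation:
    """One broken invariant for one span: data, not an exception."""

    span: Span
    rule: str
    detail: str = ""


def validate_annotation(doc: Document, ann: AnnotationSet) -> list[Violation]:
    """Check every span of ``ann`` against ``doc``; return the broken rules.

    Rules checked per span: ``start < end`` with ``start >= 0``, the interval
    lies inside the document, ``text`` length equals ``end - start`` and
    ``text`` equals the document substring. Duplicate (start, end, type)
    triples are reported once per extra occurrence.
    """
    violations: list[Violation] = []
    seen: set[tuple[int, int, str]] = set()
    for span in ann.spans:
        if span.start < 0 or span.start >= span.end:
            violations.append(Violation(span, "start < end", f"got [{span.start}, {span.end})"))
            continue
        if span.end > len(doc.text):
            violations.append(
                Violation(span, "within document", f"end {span.end} > document length {len(doc.text)}")
            )
            continue
        actual = doc.text[span.start : span.end]
        if len(span.text) != span.end - span.start or actual != span.text:
            violations.append(
                Violation(span, "text mismatch", f"span text {span.text!r} != document {actual!r}")
            )
        key = (span.start, span.end, span.type)
        if key in seen:
            violations.append(Violation(span, "duplicate span", f"repeated {key}"))
        seen.add(key)
    return violations


def split_corpus(
    corpus: Corpus,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> Corpus:
    """Assign documents to train/dev/test at the given ratios, in place.

    Sizes are ``round(n * r_train)`` and ``round(n * r_dev)`` with the
    remainder going to test, so 100 documents at 60:20:20 give exactly
    60/20/20. Shuffling is a seeded Fisher-Yates over the lexicographically
    sorted document ids, so the assignment depends only on (ids, seed), not
    on input order.
    """
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be non-negative")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    n = len(corpus.documents)
    nonzero = sum(1 for r in ratios if r > 0)
    if n < max(nonzero, 3):
        raise ValueError(f"need at least {max(nonzero, 3)} documents, got {n}")

    ids = sorted(d.id for d in corpus.documents)
    rng = random.Random(seed)
    rng.shuffle(ids)  # CPython's shuffle is Fisher-Yates

    n_train = round(n * ratios[0])
    n_dev = round(n * ratios[1])
    if n_train + n_dev > n:
        n_dev = n - n_train
    assignment: dict[str, str] = {}
    for i, doc_id in enumerate(ids):
        if i < n_train:
            assignment[doc_id] = "train"
        elif i < n_train + n_dev:
            assignment[doc_id] = "dev"
        else:
            assignment[doc_id] = "test"
    corpus.split_assignment = assignment
    return corpus
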