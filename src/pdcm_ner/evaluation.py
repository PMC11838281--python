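"""Span-level scoring: exact/overlapping P-R-F1, inter-annotator agreement,
and the learning-curve experiment.

Two match settings are supported. *Exact* requires identical (start, end,
type); *overlap* gives binary credit for any same-type pair of spans sharing
at least one character — "patient-derived tumor xenograft (PDX)" against the
gold "patient-derived tumor xenograft (PDX) models" is a miss under exact
and a hit under overlap.

Matching is a one-to-one maximum-cardinality matching between gold and
predicted spans (a long prediction can never claim two gold mentions), found
with a deterministic augmenting-path search and cross-checked in the tests
against brute-force enumeration. Each matched pair is one TP; unmatched
predictions are FPs, unmatched gold spans FNs. Scores are reported on the
0-100 scale; pooled rows are micro-averages (summed counts across types).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

from .schema import AnnotationSet, EntitySchema, Span

__all__ = [
    "MatchMode",
    "TypeScore",
    "ScoreReport",
    "match_spans",
    "score",
    "micro_f1_spans",
    "pairwise_iaa",
    "learning_curve",
]


class MatchMode(str, Enum):
    EXACT = "exact"
    OVERLAP = "overlap"


def _compatible(g: Span, p: Span, mode: MatchMode) -> bool:
    if g.type != p.type:
        return False
    if mode is MatchMode.EXACT:
        return g.start == p.start and g.end == p.end
    return g.overlaps(p)


def match_spans(
    gold: Sequence[Span], pred: Sequence[Span], mode: MatchMode
) -> list[tuple[int, int]]:
    """One-to-one maximum-cardinality matching of compatible (gold, pred) pairs.

    Returns (gold index, pred index) pairs. Deterministic: gold spans are
    processed in (start, end) order and candidate predictions tried in
    (start, end) order, with augmenting paths to guarantee maximality.
    """
    gold_order = sorted(range(len(gold)), key=lambda i: (gold[i].start, gold[i].end, i))
    pred_order = sorted(range(len(pred)), key=lambda j: (pred[j].start, pred[j].end, j))
    adjacency = {
        i: [j for j in pred_order if _compatible(gold[i], pred[j], mode)] for i in gold_order
    }
    pred_match: dict[int, int] = {}  # pred index -> gold index

    def try_assign(i: int, visited: set[int]) -> bool:
        for j in adjacency[i]:
            if j in visited:
                continue
            visited.add(j)
            if j not in pred_match or try_assign(pred_match[j], visited):
                pred_match[j] = i
                return True
        return False

    for i in gold_order:
        try_assign(i, set())
    pairs = [(i, j) for j, i in pred_match.items()]
    pairs.sort(key=lambda ij: (gold[ij[0]].start, pred[ij[1]].start, ij))
    return pairs


@dataclass(frozen=True)
class TypeScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class ScoreReport:
    """Per-type and pooled precision/recall/F1 for one evaluation run."""

    mode: MatchMode
    per_type: dict[str, TypeScore] = field(default_factory=dict)
    n_gold: int = 0
    n_pred: int = 0

    @property
    def pooled(self) -> TypeScore:
        return TypeScore(
            tp=sum(s.tp for s in self.per_type.values()),
            fp=sum(s.fp for s in self.per_type.values()),
            fn=sum(s.fn for s in self.per_type.values()),
        )

    def to_dict(self) -> dict:
        def row(s: TypeScore) -> dict:
            return {
                "tp": s.tp, "fp": s.fp, "fn": s.fn,
                "precision": round(s.precision, 2),
                "recall": round(s.recall, 2),
                "f1": round(s.f1, 2),
            }

        return {
            "mode": self.mode.value,
            "n_gold": self.n_gold,
            "n_pred": self.n_pred,
            "per_type": {t: row(s) for t, s in sorted(self.per_type.items())},
            "pooled": row(self.pooled),
        }

    def format_table(self) -> str:
        """Human-readable table with Precision, Recall, F1 columns."""
        lines = [f"{'Entity type':<24}{'Precision':>10}{'Recall':>10}{'F1':>10}"]
        for t, s in sorted(self.per_type.items()):
            lines.append(f"{t:<24}{s.precision:>10.2f}{s.recall:>10.2f}{s.f1:>10.2f}")
        p = self.pooled
        lines.append(f"{'OVERALL (micro)':<24}{p.precision:>10.2f}{p.recall:>10.2f}{p.f1:>10.2f}")
        return "\n".join(lines)


def _group_by_doc(sets: Sequence[AnnotationSet]) -> dict[str, list[Span]]:
    grouped: dict[str, list[Span]] = {}
    for ann in sets:
        grouped.setdefault(ann.doc_id, []).extend(ann.spans)
    return grouped


def score(
    gold: AnnotationSet | Sequence[AnnotationSet],
    pred: AnnotationSet | Sequence[AnnotationSet],
    mode: MatchMode = MatchMode.EXACT,
    schema: EntitySchema | None = None,
) -> ScoreReport:
    """Score predictions against gold, per entity type and pooled (micro).

    Accepts a single document's annotation sets or corpus-level lists keyed
    by doc_id; matching is always computed within one document and one type.
    Types with neither gold nor predicted spans are omitted from per-type
    rows. For single sets, the doc_ids must agree.
    """
    gold_sets = [gold] if isinstance(gold, AnnotationSet) else list(gold)
    pred_sets = [pred] if isinstance(pred, AnnotationSet) else list(pred)
    if isinstance(gold, AnnotationSet) and isinstance(pred, AnnotationSet):
        if gold.doc_id != pred.doc_id:
            raise ValueError(f"doc_id mismatch: {gold.doc_id!r} vs {pred.doc_id!r}")

    gold_by_doc = _group_by_doc(gold_sets)
    pred_by_doc = _group_by_doc(pred_sets)
    types = sorted(
        {s.type for spans in gold_by_doc.values() for s in spans}
        | {s.type for spans in pred_by_doc.values() for s in spans}
    )
    if schema is not None:
        types = [t for t in schema.names if t in types]

    report = ScoreReport(mode=mode)
    report.n_gold = sum(len(v) for v in gold_by_doc.values())
    report.n_pred = sum(len(v) for v in pred_by_doc.values())
    counts = {t: [0, 0, 0] for t in types}  # tp, fp, fn
    for doc_id in sorted(set(gold_by_doc) | set(pred_by_doc)):
        g_spans = gold_by_doc.get(doc_id, [])
        p_spans = pred_by_doc.get(doc_id, [])
        for t in types:
            g = [s for s in g_spans if s.type == t]
            p = [s for s in p_spans if s.type == t]
            if not g and not p:
                continue
            tp = len(match_spans(g, p, mode))
            counts[t][0] += tp
            counts[t][1] += len(p) - tp
            counts[t][2] += len(g) - tp
    report.per_type = {
        t: TypeScore(tp, fp, fn) for t, (tp, fp, fn) in counts.items() if tp + fp + fn > 0
    }
    return report


def micro_f1_spans(
    gold_per_sentence: Sequence[Sequence[Span]],
    pred_per_sentence: Sequence[Sequence[Span]],
    mode: MatchMode = MatchMode.EXACT,
) -> float:
    """Micro F1 (0-100) over parallel per-sentence span lists — the light-weight
    entry point used during soft-prompt training."""
    tp = fp = fn = 0
    for g, p in zip(gold_per_sentence, pred_per_sentence):
        by_type = {s.type for s in g} | {s.type for s in p}
        for t in by_type:
            gt = [s for s in g if s.type == t]
            pt = [s for s in p if s.type == t]
            m = len(match_spans(gt, pt, mode))
            tp += m
            fp += len(pt) - m
            fn += len(gt) - m
    return TypeScore(tp, fp, fn).f1


def pairwise_iaa(
    annotators: Mapping[str, Sequence[AnnotationSet]],
    mode: MatchMode = MatchMode.EXACT,
    schema: EntitySchema | None = None,
) -> dict[str, float]:
    """Pairwise-F1 inter-annotator agreement, averaged over annotator pairs.

    For each unordered pair, one annotator is scored as gold against the
    other (F1 is symmetric under the swap); per-type F1 values are then
    averaged across all pairs. Default mode is exact.
    """
    names = sorted(annotators)
    if len(names) < 2:
        raise ValueError("need at least two annotators")
    doc_sets = [
        {ann.doc_id for ann in annotators[name]} for name in names
    ]
    common = set.intersection(*doc_sets)
    if not common:
        raise ValueError("annotators cover disjoint document sets")

    per_type_scores: dict[str, list[float]] = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sets_a = [ann for ann in annotators[names[a]] if ann.doc_id in common]
            sets_b = [ann for ann in annotators[names[b]] if ann.doc_id in common]
            report = score(sets_a, sets_b, mode=mode, schema=schema)
            for t, s in report.per_type.items():
                per_type_scores.setdefault(t, []).append(s.f1)
    return {t: sum(v) / len(v) for t, v in sorted(per_type_scores.items())}


def learning_curve(
    fractions: Sequence[float],
    trainer: Callable[[Sequence, int], Callable[[Sequence], Sequence[Span]]],
    train_pool: Sequence,
    eval_set: Sequence[tuple[Sequence, Sequence[Span]]],
    seed: int = 0,
    mode: MatchMode = MatchMode.OVERLAP,
) -> list[dict]:
    """Measure performance as a function of training-set size.

    For each fraction, ``ceil(fraction * N)`` training items are subsampled
    with the seed, ``trainer(subset, seed)`` trains a model from scratch and
    returns a predictor mapping an eval input to predicted spans, and the
    predictor is scored against the eval gold spans (micro, the given mode).
    Returns rows ``{fraction, n_sentences, precision, recall, f1}`` sorted by
    fraction.
    """
    import random as _random

    n = len(train_pool)
    rows = []
    for fraction in sorted(fractions):
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction {fraction} outside (0, 1]")
        k = math.ceil(fraction * n)
        if k == 0:
            raise ValueError(f"fraction {fraction} yields zero training items")
        rng = _random.Random(seed)
        subset = [train_pool[i] for i in sorted(rng.sample(range(n), k))]
        predict = trainer(subset, seed)
        tp = fp = fn = 0
        for inputs, gold_spans in eval_set:
            pred_spans = list(predict(inputs))
            types = {s.type for s in gold_spans} | {s.type for s in pred_spans}
            for t in types:
                g = [s for s in gold_spans if s.type == t]
                p = [s for s in pred_spans if s.type == t]
                m = len(match_spans(g, p, mode))
                tp += m
                fp += len(p) - m
                fn += len(g) - m
        s = TypeScore(tp, fp, fn)
        rows.append(
            {
                "fraction": fraction,
                "n_sentences": k,
                "precision": s.precision,
                "recall": s.recall,
                "f1": s.f1,
            }
        )
    return rows
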