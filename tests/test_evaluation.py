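"""Span scoring: matching oracle equivalence, mode ordering, IAA, curves."""

import random

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from pdcm_ner import (
    AnnotationSet,
    MatchMode,
    Span,
    learning_curve,
    match_spans,
    pairwise_iaa,
    score,
)


def _brute_force_max_matching(gold, pred, mode):
    """Independent oracle: exhaustive search for the maximum matching size."""

    def compatible(g, p):
        if g.type != p.type:
            return False
        if mode is MatchMode.EXACT:
            return (g.start, g.end) == (p.start, p.end)
        return g.start < p.end and p.start < g.end

    best = 0

    def recurse(i, used_pred, count):
        nonlocal best
        best = max(best, count)
        if i == len(gold):
            return
        recurse(i + 1, used_pred, count)  # leave gold[i] unmatched
        for j in range(len(pred)):
            if j not in used_pred and compatible(gold[i], pred[j]):
                recurse(i + 1, used_pred | {j}, count + 1)

    recurse(0, frozenset(), 0)
    return best


def _random_spans(rng, n, types=("a", "b")):
    spans = set()
    while len(spans) < n:
        s = rng.randrange(0, 30)
        e = s + rng.randrange(1, 6)
        spans.add((s, e, rng.choice(types)))
    return [Span(s, e, t, "x" * (e - s)) for s, e, t in spans]


class TestMatchSpans:
    def test_pdx_boundary_example(self):
        gold = [Span(0, 44, "model_type", "patient-derived tumor xenograft (PDX) models")]
        pred = [Span(0, 37, "model_type", "patient-derived tumor xenograft (PDX)")]
        assert match_spans(gold, pred, MatchMode.EXACT) == []
        assert match_spans(gold, pred, MatchMode.OVERLAP) == [(0, 0)]

    def test_identical_sets_match_perfectly_in_both_modes(self):
        spans = _random_spans(random.Random(0), 5)
        for mode in MatchMode:
            assert len(match_spans(spans, list(spans), mode)) == 5

    def test_one_pred_cannot_claim_two_gold(self):
        gold = [Span(0, 5, "a", "xxxxx"), Span(6, 10, "a", "xxxx")]
        pred = [Span(0, 10, "a", "x" * 10)]
        pairs = match_spans(gold, pred, MatchMode.OVERLAP)
        assert len(pairs) == 1

    def test_type_identity_required_for_overlap(self):
        gold = [Span(0, 5, "biomarker", "xxxxx")]
        pred = [Span(0, 5, "treatment", "xxxxx")]
        assert match_spans(gold, pred, MatchMode.OVERLAP) == []

    @pytest.mark.parametrize("mode", list(MatchMode))
    def test_agrees_with_brute_force_oracle_on_300_random_instances(self, mode):
        rng = random.Random(20240917)
        for _ in range(300):
            gold = _random_spans(rng, rng.randrange(0, 7))
            pred = _random_spans(rng, rng.randrange(0, 7))
            got = len(match_spans(gold, pred, mode))
            assert got == _brute_force_max_matching(gold, pred, mode)

    def test_agrees_with_scipy_hopcroft_karp_cardinality(self):
        rng = random.Random(5)
        for _ in range(100):
            gold = _random_spans(rng, rng.randrange(1, 7))
            pred = _random_spans(rng, rng.randrange(1, 7))
            adj = np.zeros((len(gold), len(pred)), dtype=np.int8)
            for i, g in enumerate(gold):
                for j, p in enumerate(pred):
                    if g.type == p.type and g.start < p.end and p.start < g.end:
                        adj[i, j] = 1
            matched = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
            assert len(match_spans(gold, pred, MatchMode.OVERLAP)) == int((matched >= 0).sum())

    def test_exact_tp_never_exceeds_overlap_tp(self):
        rng = random.Random(99)
        for _ in range(200):
            gold = _random_spans(rng, rng.randrange(0, 7))
            pred = _random_spans(rng, rng.randrange(0, 7))
            exact = len(match_spans(gold, pred, MatchMode.EXACT))
            overlap = len(match_spans(gold, pred, MatchMode.OVERLAP))
            assert exact <= overlap

    def test_deterministic_tie_break_order(self):
        gold = [Span(0, 4, "a", "xxxx"), Span(5, 9, "a", "xxxx")]
        pred = [Span(2, 6, "a", "xxxx"), Span(3, 8, "a", "xxxx")]
        pairs = match_spans(gold, pred, MatchMode.OVERLAP)
        assert pairs == sorted(pairs)


class TestScore:
    def test_perfect_prediction_scores_100(self):
        spans = [Span(0, 4, "biomarker", "KRAS"), Span(5, 9, "treatment", "chem")]
        gold = AnnotationSet("d1", "gold", spans)
        pred = AnnotationSet("d1", "system:x", list(spans))
        for mode in MatchMode:
            report = score(gold, pred, mode)
            pooled = report.pooled
            assert (pooled.precision, pooled.recall, pooled.f1) == (100.0, 100.0, 100.0)

    def test_empty_prediction_scores_zero(self):
        gold = AnnotationSet("d1", "gold", [Span(0, 4, "biomarker", "KRAS")])
        pred = AnnotationSet("d1", "system:x", [])
        pooled = score(gold, pred, MatchMode.EXACT).pooled
        assert (pooled.precision, pooled.recall, pooled.f1) == (0.0, 0.0, 0.0)

    def test_doc_id_mismatch_is_error(self):
        with pytest.raises(ValueError, match="doc_id mismatch"):
            score(AnnotationSet("d1", "gold", []), AnnotationSet("d2", "s", []))

    def test_precision_recall_swap_symmetry(self):
        rng = random.Random(3)
        a = AnnotationSet("d1", "A", _random_spans(rng, 6))
        b = AnnotationSet("d1", "B", _random_spans(rng, 5))
        ab = score(a, b, MatchMode.OVERLAP).pooled
        ba = score(b, a, MatchMode.OVERLAP).pooled
        assert ab.precision == ba.recall
        assert ab.recall == ba.precision
        assert ab.f1 == pytest.approx(ba.f1)

    def test_counts_are_consistent_per_type(self):
        rng = random.Random(8)
        gold = AnnotationSet("d1", "gold", _random_spans(rng, 6))
        pred = AnnotationSet("d1", "s", _random_spans(rng, 6))
        report = score(gold, pred, MatchMode.OVERLAP)
        for t, s in report.per_type.items():
            assert s.tp + s.fn == sum(1 for sp in gold.spans if sp.type == t)
            assert s.tp + s.fp == sum(1 for sp in pred.spans if sp.type == t)
        pooled = report.pooled
        assert pooled.tp == sum(s.tp for s in report.per_type.values())

    def test_matching_never_crosses_documents(self):
        gold = [AnnotationSet("d1", "gold", [Span(0, 4, "a", "xxxx")])]
        pred = [AnnotationSet("d2", "s", [Span(0, 4, "a", "xxxx")])]
        report = score(gold, pred, MatchMode.EXACT)
        assert report.pooled.tp == 0

    def test_types_absent_everywhere_are_omitted(self, schema):
        gold = AnnotationSet("d1", "gold", [Span(0, 4, "biomarker", "KRAS")])
        pred = AnnotationSet("d1", "s", [Span(0, 4, "biomarker", "KRAS")])
        report = score(gold, pred, MatchMode.EXACT, schema)
        assert set(report.per_type) == {"biomarker"}


class TestPairwiseIAA:
    @staticmethod
    def _annotators(spans_by_annotator):
        return {
            name: [AnnotationSet("d1", name, spans)]
            for name, spans in spans_by_annotator.items()
        }

    def test_three_identical_annotators_agree_100(self):
        spans = [Span(0, 4, "biomarker", "KRAS"), Span(5, 9, "model_id", "P402")]
        iaa = pairwise_iaa(self._annotators({"a1": spans, "a2": list(spans), "a3": list(spans)}))
        assert iaa == {"biomarker": 100.0, "model_id": 100.0}

    def test_type_with_full_agreement_scores_100_amid_disagreement(self):
        common = Span(0, 7, "model_id", "PHLC402")
        annos = self._annotators({
            "a1": [common, Span(10, 14, "biomarker", "KRAS")],
            "a2": [common, Span(20, 24, "biomarker", "PTEN")],
            "a3": [common],
        })
        iaa = pairwise_iaa(annos)
        assert iaa["model_id"] == 100.0
        assert iaa["biomarker"] < 100.0

    def test_hand_computed_disagreement_case(self):
        # a1 has 3 biomarker spans, a2 shares exactly 2 of them and adds 1 of
        # its own: P = 2/3, R = 2/3, F1 = 2/3 -> 66.67
        shared = [Span(0, 4, "biomarker", "xxxx"), Span(10, 14, "biomarker", "xxxx")]
        annos = self._annotators({
            "a1": shared + [Span(20, 24, "biomarker", "xxxx")],
            "a2": shared + [Span(30, 34, "biomarker", "xxxx")],
        })
        iaa = pairwise_iaa(annos)
        assert iaa["biomarker"] == pytest.approx(200 / 3, abs=0.01)

    def test_single_annotator_is_error(self):
        with pytest.raises(ValueError):
            pairwise_iaa(self._annotators({"a1": []}))

    def test_disjoint_documents_is_error(self):
        annos = {
            "a1": [AnnotationSet("d1", "a1", [])],
            "a2": [AnnotationSet("d2", "a2", [])],
        }
        with pytest.raises(ValueError, match="disjoint"):
            pairwise_iaa(annos)


class TestLearningCurve:
    @staticmethod
    def _memorising_trainer(subset, seed):
        """Predicts a span iff its sentence was in the training subset."""
        seen = {id_ for id_, _ in subset}

        def predict(inputs):
            id_ = inputs
            return [Span(0, 4, "a", "xxxx")] if id_ in seen else []

        return predict

    def test_fraction_one_uses_whole_pool_and_rows_sorted(self):
        pool = [(i, None) for i in range(40)]
        eval_set = [(i, [Span(0, 4, "a", "xxxx")]) for i in range(40)]
        rows = learning_curve(
            [1.0, 0.25, 0.5], self._memorising_trainer, pool, eval_set,
            seed=0, mode=MatchMode.EXACT,
        )
        assert [r["fraction"] for r in rows] == [0.25, 0.5, 1.0]
        assert rows[-1]["n_sentences"] == 40
        assert rows[-1]["recall"] == 100.0
        # recall grows with the training fraction for a memorising learner
        assert rows[0]["recall"] <= rows[1]["recall"] <= rows[2]["recall"]

    def test_deterministic_for_fixed_seed(self):
        pool = [(i, None) for i in range(20)]
        eval_set = [(i, [Span(0, 4, "a", "xxxx")]) for i in range(20)]
        args = ([0.3, 0.7], self._memorising_trainer, pool, eval_set)
        assert learning_curve(*args, seed=5) == learning_curve(*args, seed=5)

    def test_zero_yield_fraction_is_error(self):
        with pytest.raises(ValueError):
            learning_curve([0.0], self._memorising_trainer, [(1, None)], [], seed=0)
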