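"""Direct prompting: prompt assembly, tagged-output parsing, offset mapping."""

from functools import lru_cache

import pytest

from pdcm_ner import (
    AnnotationSet,
    Document,
    PromptConfig,
    Span,
    build_prompt,
    extract_document,
    map_to_document,
    parse_tagged_output,
    split_sentences,
    validate_annotation,
)
from pdcm_ner.prompting import extract_query_sentence

EXAMPLES = [
    ("KRAS was mutated.", "<biomarker>KRAS</biomarker> was mutated."),
    ("Treated with cisplatin.", "Treated with <treatment>cisplatin</treatment>."),
    ("PDX models were grown.", "<model_type>PDX models</model_type> were grown."),
    ("A primary tumour.", "A <tumour_type>primary</tumour_type> tumour."),
    ("Diagnosed with TNBC.", "Diagnosed with <diagnosis>TNBC</diagnosis>."),
]


class TestBuildPrompt:
    def test_contains_all_sections_in_order(self, schema):
        config = PromptConfig(examples=EXAMPLES, n_examples=5)
        prompt = build_prompt(config, schema, "The query sentence.")
        i_instr = prompt.index(config.instruction)
        i_defs = prompt.index("Entity definitions:")
        i_ex = prompt.index("Examples:")
        i_q = prompt.rindex("Input: The query sentence.")
        assert i_instr < i_defs < i_ex < i_q
        assert prompt.count("- ") >= 15  # one definition line per type
        assert prompt.count("Output:") == 6  # 5 examples + final query

    def test_zero_shot_degenerate_case(self, schema):
        prompt = build_prompt(PromptConfig(n_examples=0), schema, "Query.")
        assert "Examples:" not in prompt
        assert prompt.rstrip().endswith("Output:")

    def test_deterministic_bytes(self, schema):
        config = PromptConfig(examples=EXAMPLES, n_examples=3)
        assert build_prompt(config, schema, "Q.") == build_prompt(config, schema, "Q.")

    def test_unparseable_example_is_configuration_error(self, schema):
        config = PromptConfig(examples=[("KRAS.", "<biomarker>KRAS.")], n_examples=1)
        with pytest.raises(ValueError, match="parse cleanly"):
            build_prompt(config, schema, "Q.")

    def test_n_examples_exceeding_pool_is_error(self, schema):
        with pytest.raises(ValueError):
            build_prompt(PromptConfig(examples=EXAMPLES[:2], n_examples=5), schema, "Q.")

    def test_empty_query_is_error(self, schema):
        with pytest.raises(ValueError):
            build_prompt(PromptConfig(n_examples=0), schema, "")

    def test_query_recoverable_from_prompt(self, schema):
        config = PromptConfig(examples=EXAMPLES, n_examples=5)
        prompt = build_prompt(config, schema, "The query sentence.")
        assert extract_query_sentence(prompt) == "The query sentence."


class TestParseTaggedOutput:
    def test_first_alk_mention_recovers_printed_offsets(self, alk_text, schema):
        tagged = alk_text.replace("(ALK)", "(<biomarker>ALK</biomarker>)", 1)
        report = parse_tagged_output(tagged, alk_text, schema)
        assert report.spans == [Span(48, 51, "biomarker", "ALK")]
        assert report.warnings == [] and not report.strict_failure

    def test_untagged_identity(self, alk_text, schema):
        report = parse_tagged_output(alk_text, alk_text, schema)
        assert report.spans == [] and report.warnings == []

    def test_unclosed_tag_warns_and_yields_no_span(self, schema):
        report = parse_tagged_output("<biomarker>ALK", "ALK", schema)
        assert report.spans == []
        assert [w.kind for w in report.warnings] == ["unbalanced tag"]

    def test_stray_closing_tag_warns(self, schema):
        report = parse_tagged_output("ALK</biomarker>", "ALK", schema)
        assert report.spans == []
        assert "unbalanced tag" in [w.kind for w in report.warnings]

    def test_unknown_tags_are_literal_text(self, schema):
        src = "Values <2 and <xyz> appear."
        report = parse_tagged_output(src, src, schema)
        assert report.spans == [] and report.warnings == []

    def test_nested_inner_tag_is_stripped_with_warning(self, schema):
        tagged = "<treatment>MEK <biomarker>inhibitor</biomarker> therapy</treatment>"
        src = "MEK inhibitor therapy"
        report = parse_tagged_output(tagged, src, schema)
        kinds = [w.kind for w in report.warnings]
        assert "nested tag" in kinds
        assert [s for s in report.spans if s.type == "treatment"] == [
            Span(0, 21, "treatment", "MEK inhibitor therapy")
        ]

    def test_attribute_and_self_closing_tags_stripped(self, schema):
        src = "ALK here"
        report = parse_tagged_output('<biomarker id="1">ALK</biomarker> here', src, schema)
        assert "malformed tag" in [w.kind for w in report.warnings]
        report2 = parse_tagged_output("<biomarker/>ALK here", src, schema)
        assert "malformed tag" in [w.kind for w in report2.warnings]
        assert report2.spans == []

    def test_empty_pair_warns(self, schema):
        report = parse_tagged_output("<biomarker></biomarker>ALK", "ALK", schema)
        assert [w.kind for w in report.warnings] == ["empty span"]

    def test_strict_mode_rejects_drift(self, schema):
        report = parse_tagged_output(
            "<biomarker>KRAS</biomarker> mutated", "KRAS was mutated", schema, strict=True
        )
        assert report.strict_failure and report.spans == []

    def test_lenient_mode_realigns_after_dropped_word(self, schema):
        source = "one two three a five six KRAS eight nine ten"
        # model dropped the word "a" but tagged KRAS
        tagged = "one two three five six <biomarker>KRAS</biomarker> eight nine ten"
        report = parse_tagged_output(tagged, source, schema, strict=False)
        assert report.spans == [Span(25, 29, "biomarker", "KRAS")]
        assert not report.strict_failure

    def test_lenient_alignment_matches_independent_lcs_oracle(self, schema):
        source = "alpha beta gamma delta epsilon"
        drifted = "alpha beta gamma delta epsilo"  # truncated last word
        tagged = "<diagnosis>alpha beta</diagnosis> gamma delta epsilo"
        report = parse_tagged_output(tagged, source, schema)
        assert _lcs_len("alpha beta gamma delta epsilo", source) >= 0.9 * len(source)
        assert report.spans == [Span(0, 10, "diagnosis", "alpha beta")]

    def test_heavy_drift_becomes_strict_failure(self, schema):
        report = parse_tagged_output(
            "<biomarker>KRAS</biomarker>", "completely different sentence here", schema
        )
        assert report.strict_failure and report.spans == []

    def test_span_with_unalignable_characters_is_dropped(self, schema):
        source = "the KRAS gene"
        tagged = "the <biomarker>KRAZZZ</biomarker> gene mutated in every sample today"
        report = parse_tagged_output(tagged, source, schema)
        assert report.strict_failure or all(s.text != "KRAZZZ" for s in report.spans)

    def test_offsets_independent_of_other_tags(self, alk_text, schema):
        one = alk_text.replace("(ALK)", "(<biomarker>ALK</biomarker>)", 1)
        both = one.replace("not all ALK", "not all <biomarker>ALK</biomarker>")
        r1 = parse_tagged_output(one, alk_text, schema)
        r2 = parse_tagged_output(both, alk_text, schema)
        assert r1.spans[0] == r2.spans[0]

    def test_tag_strip_conservation_span_text_matches_source(self, schema):
        src = "Treated with cisplatin and radiotherapy."
        tagged = (
            "Treated with <treatment>cisplatin</treatment> and "
            "<treatment>radiotherapy</treatment>."
        )
        report = parse_tagged_output(tagged, src, schema)
        for s in report.spans:
            assert s.text == src[s.start : s.end]


@lru_cache(maxsize=None)
def _lcs_len(a: str, b: str) -> int:
    """Independent (naive memoized) LCS length oracle for short strings."""
    if not a or not b:
        return 0
    if a[-1] == b[-1]:
        return _lcs_len(a[:-1], b[:-1]) + 1
    return max(_lcs_len(a[:-1], b), _lcs_len(a, b[:-1]))


class TestMapToDocument:
    def test_second_alk_mention_maps_to_document_offset(self, alk_text, schema):
        intervals = split_sentences(alk_text)
        s2_start, s2_end = intervals[1]
        sentence = alk_text[s2_start:s2_end]
        tagged = sentence.replace("(ALK)", "(<biomarker>ALK</biomarker>)", 1)
        report = parse_tagged_output(tagged, sentence, schema)
        assert report.spans == [Span(141, 144, "biomarker", "ALK")]
        [doc_span] = map_to_document(report.spans, s2_start)
        assert (doc_span.start, doc_span.end) == (323, 326)

    def test_zero_offset_is_identity(self):
        spans = [Span(3, 7, "biomarker", "KRAS")]
        assert map_to_document(spans, 0) == spans

    def test_translation_preserves_order_and_gaps(self):
        spans = [Span(0, 4, "biomarker", "KRAS"), Span(10, 14, "biomarker", "PTEN")]
        shifted = map_to_document(spans, 100)
        assert shifted[1].start - shifted[0].end == spans[1].start - spans[0].end

    def test_exceeding_document_length_is_error(self):
        with pytest.raises(ValueError):
            map_to_document([Span(0, 10, "biomarker", "0123456789")], 95, doc_length=100)


class _EchoGoldAdapter:
    """Echoes each sentence with its gold spans tagged."""

    name = "echo-gold"

    def __init__(self, doc, gold):
        self._map = {}
        for start, end in doc.sentences:
            sentence = doc.text[start:end]
            local = sorted(
                s.shifted(-start) for s in gold.spans if s.start >= start and s.end <= end
            )
            out = sentence
            for s in reversed(local):
                out = out[: s.start] + f"<{s.type}>" + out[s.start : s.end] + f"</{s.type}>" + out[s.end :]
            self._map[sentence] = out

    def generate(self, prompt):
        q = extract_query_sentence(prompt)
        return self._map.get(q, q or "")


class TestExtractDocument:
    @staticmethod
    def _doc_and_gold(alk_text):
        doc = Document(id="d1", text=alk_text, sentences=split_sentences(alk_text))
        gold = AnnotationSet(
            "d1", "gold",
            [Span(48, 51, "biomarker", "ALK"), Span(323, 326, "biomarker", "ALK")],
        )
        return doc, gold

    def test_perfect_tagger_round_trips_gold(self, alk_text, schema):
        doc, gold = self._doc_and_gold(alk_text)
        ann = extract_document(doc, _EchoGoldAdapter(doc, gold), PromptConfig(n_examples=0), schema)
        assert ann.spans == gold.spans
        assert ann.source == "system:echo-gold"
        assert validate_annotation(doc, ann) == []

    def test_untagged_echo_yields_empty_annotation(self, alk_text, schema):
        doc, _ = self._doc_and_gold(alk_text)

        class Echo:
            name = "plain"

            def generate(self, prompt):
                return extract_query_sentence(prompt) or ""

        ann = extract_document(doc, Echo(), PromptConfig(n_examples=0), schema)
        assert ann.spans == []

    def test_failing_adapter_skips_sentence_not_fatal(self, alk_text, schema):
        doc, gold = self._doc_and_gold(alk_text)
        inner = _EchoGoldAdapter(doc, gold)

        class Flaky:
            name = "flaky"
            calls = 0

            def generate(self, prompt):
                Flaky.calls += 1
                if Flaky.calls == 1:
                    raise RuntimeError("boom")
                return inner.generate(prompt)

        ann = extract_document(doc, Flaky(), PromptConfig(n_examples=0), schema)
        # first sentence skipped, second sentence's span still extracted
        assert ann.spans == [Span(323, 326, "biomarker", "ALK")]

    def test_missing_sentences_is_error(self, alk_text, schema):
        doc = Document(id="d1", text=alk_text)
        with pytest.raises(ValueError, match="no sentence intervals"):
            extract_document(doc, _EchoGoldAdapter(doc, AnnotationSet("d1", "gold", [])),
                             PromptConfig(n_examples=0), schema)
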