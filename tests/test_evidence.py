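import pytest

from evitriage.corpus import Document, ParagraphBlock, split_sentences
from evitriage.evidence import (FragmentPolicy, SubfigureRef,
                                caption_for, expand_panel_range,
                                extract_evidence_fragments,
                                find_figure_references, fragments_to_bioc_xml,
                                fragments_to_tsv)

# ---------------------------------------------------------------------------
# reference grammar

# (text, [(figure_id, panels, matched_substring), ...]) — hand-parsed
REFERENCE_CASES = [
    ("no figures here", []),
    ("as shown in Fig. 2B", [(2, ("B",), "Fig. 2B")]),
    ("(Figures 1A and 1C–E)", [(1, ("A",), "Figures 1A"),
                               (1, ("C", "D", "E"), "1C–E")]),
    ("see Figure 10", [(10, (), "Figure 10")]),
    ("results (fig 3a, 4b)", [(3, ("A",), "fig 3a"), (4, ("B",), "4b")]),
    ("Fig. 2A and B were clear", [(2, ("A", "B"), "Fig. 2A and B")]),
    ("in Figs 3 and 4", [(3, (), "Figs 3"), (4, (), "4")]),
    ("configured the system", []),
    ("Fig. 2 A previous study", [(2, (), "Fig. 2")]),
    ("panels (Fig. 5B-D)", [(5, ("B", "C", "D"), "Fig. 5B-D")]),
    ("a figure of merit", []),
    ("Fig. 7A,C shows", [(7, ("A", "C"), "Fig. 7A,C")]),
]


class TestFindFigureReferences:
    @pytest.mark.parametrize("text,expected", REFERENCE_CASES)
    def test_hand_parsed_cases(self, text, expected):
        refs = find_figure_references(text)
        got = [(r.figure_id, r.panels, text[r.span[0]:r.span[1]]) for r in refs]
        assert got == expected

    def test_supplementary_skipped_by_default(self):
        text = "see Fig. S1 for details"
        assert find_figure_references(text) == []
        refs = find_figure_references(text, include_supplementary=True)
        assert len(refs) == 1 and refs[0].supplementary

    def test_spans_in_order_and_in_bounds(self):
        text = "Fig. 1A then Fig. 2B then (Figs 3 and 4C)."
        refs = find_figure_references(text)
        spans = [r.span for r in refs]
        assert spans == sorted(spans)
        assert all(0 <= lo < hi <= len(text) for lo, hi in spans)

    def test_determinism(self):
        text = "Binding (Fig. 1A and 2B–D) was strong."
        assert find_figure_references(text) == find_figure_references(text)


class TestExpandPanelRange:
    @pytest.mark.parametrize("spec,expected", [
        ("A", ["A"]),
        ("B–D", ["B", "C", "D"]),
        ("B-D", ["B", "C", "D"]),
        ("A,C", ["A", "C"]),
        ("a and c", ["A", "C"]),
    ])
    def test_expansion(self, spec, expected):
        assert expand_panel_range(spec) == expected

    def test_descending_range_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            expand_panel_range("D–B")


# ---------------------------------------------------------------------------
# fragment delineation

def _doc(*paragraphs, captions=None):
    return Document(doc_id="d", captions=captions or {},
                    paragraphs=[ParagraphBlock("Results", p)
                                for p in paragraphs])


class TestExtractEvidenceFragments:
    def test_reference_free_doc(self):
        assert extract_evidence_fragments(_doc("Nothing to see.")) == []

    def test_fragment_runs_to_paragraph_end(self):
        doc = _doc("Intro sentence. Binding is shown (Fig. 1A). "
                   "Levels rose over time.")
        frags = extract_evidence_fragments(doc)
        assert len(frags) == 1
        assert frags[0].figure_id == 1 and frags[0].panels == ("A",)
        assert frags[0].text == ("Binding is shown (Fig. 1A). "
                                 "Levels rose over time.")

    def test_boundary_before_new_figure(self):
        doc = _doc("Binding shown in Fig. 1A. It was strong. "
                   "Degradation followed in Fig. 2.")
        frags = extract_evidence_fragments(doc)
        assert len(frags) == 2
        assert frags[0].text == "Binding shown in Fig. 1A. It was strong."
        assert frags[1].text == "Degradation followed in Fig. 2."

    def test_same_key_sentences_merge(self):
        doc = _doc("Fig. 1A shows binding. Fig. 1A also shows kinetics.")
        frags = extract_evidence_fragments(doc)
        assert len(frags) == 1 and len(frags[0].sentences) == 2

    def test_multi_figure_sentence_yields_one_fragment_per_key(self):
        doc = _doc("Binding (Fig. 1A) and decay (Fig. 2) were seen.")
        frags = extract_evidence_fragments(doc)
        keys = {(f.figure_id, f.panels) for f in frags}
        assert keys == {(1, ("A",)), (2, ())}
        # both fragments cover the same single-sentence run
        assert all(len(f.sentences) == 1 for f in frags)

    def test_include_preceding_option(self):
        doc = _doc("Setup sentence. Binding shown (Fig. 1A).")
        default = extract_evidence_fragments(doc)
        wide = extract_evidence_fragments(
            doc, FragmentPolicy(include_preceding=True))
        assert len(default[0].sentences) == 1
        assert len(wide[0].sentences) == 2
        assert wide[0].sentences[0].text == "Setup sentence."

    def test_fragments_stay_within_paragraph(self):
        doc = _doc("Binding shown (Fig. 1A).", "A new paragraph entirely.")
        frags = extract_evidence_fragments(doc)
        assert len(frags) == 1 and len(frags[0].sentences) == 1

    def test_coverage_every_reference_in_exactly_one_fragment(self):
        doc = _doc("Fig. 1A shows X. More on this. Fig. 2B shows Y. "
                   "Then Fig. 1A again. Unrelated end.",
                   "And Fig. 3 here.")
        frags = extract_evidence_fragments(doc)
        for p_idx, block in enumerate(doc.paragraphs):
            for sent in split_sentences(block.text):
                for ref in find_figure_references(sent.text):
                    covering = [
                        f for f in frags
                        if f.paragraph_index == p_idx
                        and (f.figure_id, f.panels) == (ref.figure_id, ref.panels)
                        and any(s.span == sent.span for s in f.sentences)]
                    assert len(covering) == 1

    def test_determinism(self, toy_doc):
        a = extract_evidence_fragments(toy_doc)
        b = extract_evidence_fragments(toy_doc)
        assert [(f.figure_id, f.panels, f.text) for f in a] == \
               [(f.figure_id, f.panels, f.text) for f in b]


class TestCaptionFor:
    def test_whole_caption_with_panel_tag(self, toy_doc):
        ref = SubfigureRef(1, ("A",), (0, 6))
        passage = caption_for(toy_doc, ref)
        assert passage.text == toy_doc.captions[1]
        assert passage.figure_ref == (1, ("A",))
        assert passage.kind.value == "caption"

    def test_missing_figure_raises_with_id(self, toy_doc):
        with pytest.raises(KeyError, match="figure 9"):
            caption_for(toy_doc, SubfigureRef(9, (), (0, 5)))

    def test_multi_panel_ref(self, toy_doc):
        passage = caption_for(toy_doc, SubfigureRef(2, ("B", "C"), (0, 8)))
        assert passage.figure_ref == (2, ("B", "C"))


def test_tsv_export(toy_doc, tmp_path):
    frags = extract_evidence_fragments(toy_doc)
    out = tmp_path / "frags.tsv"
    df = fragments_to_tsv(frags, out)
    assert list(df.columns) == ["doc_id", "figure_id", "panels",
                                "fragment_text"]
    assert len(df) == len(frags) == 2
    assert out.read_text().startswith("doc_id\t")


def test_bioc_export(toy_doc, tmp_path):
    from lxml import etree
    frags = extract_evidence_fragments(toy_doc)
    out = tmp_path / "doc.bioc.xml"
    fragments_to_bioc_xml(toy_doc, frags, out)
    tree = etree.parse(str(out))
    anns = tree.findall(".//annotation")
    assert len(anns) == len(frags)
    loc = anns[0].find("location")
    text = anns[0].findtext("text")
    lo, length = int(loc.get("offset")), int(loc.get("length"))
    assert toy_doc.paragraphs[0].text[lo:lo + length] == text
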