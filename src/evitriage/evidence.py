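"""Figure-reference detection and evidence-fragment delineation.

An *evidence fragment* is the narrative text surrounding a figure reference
that directly describes that figure's experimental evidence. Detection is a
deterministic grammar over the dominant citation styles ("Fig. 2B",
"Figure 1A and 1C–E", "(Figs 3, 4)"); fragments are maximal runs of
sentences within one paragraph that are anchored to the same
(figure, panels) key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO, Union

import pandas as pd
from lxml import etree

from .corpus import Document, Passage, PassageKind, Sentence, split_sentences

__all__ = [
    "SubfigureRef", "EvidenceFragment", "FragmentPolicy",
    "find_figure_references", "expand_panel_range",
    "extract_evidence_fragments", "caption_for",
    "fragments_to_tsv", "fragments_to_bioc_xml",
]

_DASHES = "–—‒-"


@dataclass(frozen=True)
class SubfigureRef:
    """A detected mention of a figure (and optionally its panels)."""
    figure_id: int
    panels: tuple[str, ...]  # sorted, deduplicated; empty = whole figure
    span: tuple[int, int]    # half-open, 0-based character interval
    supplementary: bool = False

    def __post_init__(self):
        if self.figure_id <= 0:
            raise ValueError("figure_id must be positive")
        object.__setattr__(self, "panels",
                           tuple(sorted(set(p.upper() for p in self.panels))))


@dataclass
class EvidenceFragment:
    figure_id: int
    panels: tuple[str, ...]
    sentences: list[Sentence]
    doc_id: str = ""
    paragraph_index: int = -1

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)

    def to_passage(self, position: int = 0) -> Passage:
        return Passage(self.text, PassageKind.EVIDENCE_FRAGMENT,
                       origin=(self.doc_id, position),
                       figure_ref=(self.figure_id, self.panels))


def expand_panel_range(spec: str) -> list[str]:
    """Expand a panel spec like "A", "A,C" or "B–D" to uppercase letters.

    Ranges are inclusive; a descending range is an error.
    """
    out: list[str] = []
    for atom in re.split(r"\s*(?:,|and|&)\s*", spec.strip()):
        if not atom:
            continue
        m = re.fullmatch(rf"([A-Za-z])\s*[{_DASHES}]\s*([A-Za-z])", atom)
        if m:
            lo, hi = m.group(1).upper(), m.group(2).upper()
            if ord(hi) < ord(lo):
                raise ValueError(f"descending panel range {atom!r}")
            out.extend(chr(c) for c in range(ord(lo), ord(hi) + 1))
            continue
        if not re.fullmatch(r"[A-Za-z]", atom):
            raise ValueError(f"bad panel spec {atom!r}")
        out.append(atom.upper())
    return out


# grammar: keyword, then one or more number+panels items. Panel letters must
# sit flush against the figure number so prose ("Fig. 2 A previous study…")
# is not swallowed; continuation items need a leading digit.
_KW = r"fig(?:ure)?s?\.?"
_PANEL = (rf"[A-Za-z](?![A-Za-z])"
          rf"(?:\s*(?:,|and|&|[{_DASHES}])\s*[A-Za-z](?![A-Za-z]))*")
_ITEM = rf"(S?)([1-9]\d{{0,2}})({_PANEL})?"
_SEP = rf"\s*(?:,|;|and|&)\s*(?=S?[1-9])"
_REF_RE = re.compile(rf"(?<![A-Za-z])({_KW})\s*{_ITEM}(?:{_SEP}{_ITEM})*",
                     re.IGNORECASE)
_ITEM_RE = re.compile(_ITEM)


def find_figure_references(text: str,
                           include_supplementary: bool = False
                           ) -> list[SubfigureRef]:
    """Find all figure/panel mentions, in span order.

    Supplementary figures ("Fig. S1") live in a separate namespace and are
    skipped unless ``include_supplementary`` is set.
    """
    refs: list[SubfigureRef] = []
    for m in _REF_RE.finditer(text):
        kw_end = m.end(1)
        first = True
        for im in _ITEM_RE.finditer(text, kw_end, m.end()):
            supp = bool(im.group(1))
            if supp and not include_supplementary:
                first = False
                continue
            panels = (tuple(expand_panel_range(im.group(3)))
                      if im.group(3) else ())
            span = (m.start(), im.end()) if first else (im.start(), im.end())
            refs.append(SubfigureRef(int(im.group(2)), panels, span,
                                     supplementary=supp))
            first = False
    refs.sort(key=lambda r: r.span)
    return refs


@dataclass
class FragmentPolicy:
    """How far a fragment extends around its triggering reference.

    Default: the reference sentence plus following sentences up to the next
    sentence referring to a different (figure, panels) key, or the paragraph
    end. ``include_preceding`` additionally prepends one sentence of context
    when available (and not already claimed by an earlier fragment).
    """
    include_preceding: bool = False
    include_supplementary: bool = False


def extract_evidence_fragments(doc: Document,
                               window: FragmentPolicy | None = None
                               ) -> list[EvidenceFragment]:
    """Delineate one fragment per maximal same-key sentence run.

    Fragments never cross paragraph boundaries, and every detected
    SubfigureRef is covered by exactly one fragment.
    """
    policy = window or FragmentPolicy()
    fragments: list[EvidenceFragment] = []
    for p_idx, block in enumerate(doc.paragraphs):
        sents = split_sentences(block.text)
        keys_per_sent = []
        for s in sents:
            refs = find_figure_references(
                s.text, include_supplementary=policy.include_supplementary)
            keys_per_sent.append(frozenset(
                (r.figure_id, r.panels) for r in refs if not r.supplementary))

        runs: list[tuple[frozenset, int, int]] = []  # (keys, start, stop)
        current_keys: frozenset | None = None
        run_start = 0
        for i, keys in enumerate(keys_per_sent):
            if keys:
                if current_keys is not None and keys != current_keys:
                    runs.append((current_keys, run_start, i))
                    current_keys, run_start = keys, i
                elif current_keys is None:
                    current_keys, run_start = keys, i
            # reference-free sentences extend the current run
        if current_keys is not None:
            runs.append((current_keys, run_start, len(sents)))

        claimed_up_to = -1
        for keys, start, stop in runs:
            if policy.include_preceding and start - 1 > claimed_up_to:
                start -= 1
            claimed_up_to = stop - 1
            for fig_id, panels in sorted(keys):
                fragments.append(EvidenceFragment(
                    fig_id, panels, sents[start:stop],
                    doc_id=doc.doc_id, paragraph_index=p_idx))
    return fragments


def caption_for(doc: Document, ref: SubfigureRef) -> Passage:
    """The whole caption of the referenced figure, tagged with ref's panels.

    Panel-level caption splitting is deliberately not attempted; curated
    records anchor to the designated subfigure, but the caption itself is
    attached as one unit.
    """
    if ref.figure_id not in doc.captions:
        raise KeyError(
            f"document {doc.doc_id!r} has no caption for figure {ref.figure_id}")
    return Passage(doc.captions[ref.figure_id], PassageKind.CAPTION,
                   origin=(doc.doc_id, ref.figure_id),
                   figure_ref=(ref.figure_id, ref.panels))


# --------------------------------------------------------------------------
# exports

def fragments_to_tsv(fragments: list[EvidenceFragment],
                     target: Union[str, Path, TextIO]) -> pd.DataFrame:
    """One row per fragment: doc_id, figure_id, panels, fragment_text."""
    df = pd.DataFrame({
        "doc_id": [f.doc_id for f in fragments],
        "figure_id": [f.figure_id for f in fragments],
        "panels": ["".join(f.panels) for f in fragments],
        "fragment_text": [f.text for f in fragments],
    })
    df.to_csv(target, sep="\t", index=False)
    return df


def fragments_to_bioc_xml(doc: Document, fragments: list[EvidenceFragment],
                          target: Union[str, Path, TextIO]) -> None:
    """BioC-like XML with paragraph passages and fragment span annotations."""
    coll = etree.Element("collection")
    d = etree.SubElement(coll, "document")
    etree.SubElement(d, "id").text = doc.doc_id
    for p_idx, block in enumerate(doc.paragraphs):
        pas = etree.SubElement(d, "passage")
        inf = etree.SubElement(pas, "infon", key="type")
        inf.text = "paragraph"
        etree.SubElement(pas, "offset").text = str(p_idx)
        etree.SubElement(pas, "text").text = block.text
        for a_idx, frag in enumerate(f for f in fragments
                                     if f.paragraph_index == p_idx):
            ann = etree.SubElement(pas, "annotation",
                                   id=f"F{p_idx}.{a_idx}")
            etree.SubElement(ann, "infon", key="figure").text = str(frag.figure_id)
            etree.SubElement(ann, "infon", key="panels").text = "".join(frag.panels)
            lo = frag.sentences[0].span[0]
            hi = frag.sentences[-1].span[1]
            etree.SubElement(ann, "location", offset=str(lo),
                             length=str(hi - lo))
            etree.SubElement(ann, "text").text = frag.text
    xml = etree.tostring(coll, pretty_print=True, encoding="unicode")
    if isinstance(target, (str, Path)):
        Path(target).write_text(xml, encoding="utf-8")
    else:
        target.write(xml)
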