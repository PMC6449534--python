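"""Document data model, tokenization and article readers/writers.

A :class:`Document` holds the pieces of a full-text article that matter for
evidence-centric classification: title, abstract, MeSH terms, ordered body
paragraphs and per-figure captions. Articles are read either from a small
JATS-like XML subset (front/article-title, abstract, kwd-group, body/sec/p,
fig/label/caption) or from a tab-prefixed plain-text dialect used for small
fixtures.

Tokenization follows biomedical conventions: punctuation is split off, but
internal hyphens and digit/letter mixtures stay attached, so entity-like
tokens such as ``IL-2``, ``p53`` and panel labels like ``1A`` survive as
single tokens. Case is preserved here; lowercasing happens only at
embedding-lookup time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, TextIO, Union

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Document", "Passage", "Sentence", "ParagraphBlock", "PassageKind",
    "tokenize", "split_sentences", "read_document", "write_document",
    "write_tokenized_corpus",
]


class PassageKind(str, Enum):
    TITLE = "title"
    ABSTRACT = "abstract"
    MESH = "mesh"
    PARAGRAPH = "paragraph"
    CAPTION = "caption"
    EVIDENCE_FRAGMENT = "evidence_fragment"


@dataclass
class ParagraphBlock:
    """One body paragraph together with the section heading it sits under."""
    section: str
    text: str


@dataclass
class Document:
    doc_id: str
    title: str = ""
    abstract: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    paragraphs: list[ParagraphBlock] = field(default_factory=list)
    captions: dict[int, str] = field(default_factory=dict)
    #: supplementary / roman-numeral figures, keyed by their raw label
    #: (e.g. "S1"); excluded from caption linkage by default.
    supplementary_captions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.doc_id:
            raise ValueError("doc_id must be nonempty")


@dataclass
class Passage:
    """One classifiable unit of text with its provenance."""
    text: str
    kind: PassageKind
    origin: tuple[str, int] = ("", 0)  # (doc_id, position index)
    figure_ref: tuple[int, tuple[str, ...]] | None = None

    def __post_init__(self):
        self.kind = PassageKind(self.kind)
        if self.kind in (PassageKind.CAPTION, PassageKind.EVIDENCE_FRAGMENT):
            if self.figure_ref is None:
                raise ValueError(f"{self.kind.value} passages require a figure_ref")

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.text)


@dataclass
class Sentence:
    text: str
    tokens: list[str]
    span: tuple[int, int]  # half-open character interval in the parent block


# --------------------------------------------------------------------------
# tokenization and sentence splitting

# words keep internal hyphens and apostrophes ("IL-2", "5'-UTR"); every other
# non-space character is its own token.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'‐’]+[A-Za-z0-9]+)*|[^\sA-Za-z0-9]")

# abbreviations whose trailing period does not end a sentence
_ABBREV = {
    "fig", "figs", "eq", "eqs", "ref", "refs", "no", "vs", "ca", "approx",
    "dr", "mr", "mrs", "st", "et", "al", "e.g", "i.e", "cf", "resp",
}

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")
_LAST_WORD_RE = re.compile(r"([A-Za-z]+(?:\.[A-Za-z]+)*)$")


def tokenize(text: str) -> list[str]:
    """Deterministic word/punctuation tokenization (case-preserving)."""
    return _TOKEN_RE.findall(text)


def split_sentences(text: str) -> list[Sentence]:
    """Split a block into sentences with character spans.

    Spans cover every non-whitespace character of the input; a heading with
    no terminal punctuation comes back as a single sentence.
    """
    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        prev = _LAST_WORD_RE.search(text, 0, m.start())
        if m.group().startswith(".") and prev and prev.group(1).lower() in _ABBREV:
            continue
        # a lowercase continuation means mid-sentence punctuation
        rest = text[m.end():].lstrip()
        if rest and rest[0].islower():
            continue
        boundaries.append(m.end())
    sentences: list[Sentence] = []
    start = 0
    for end in boundaries + [len(text)]:
        chunk = text[start:end]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            lo, hi = start + lead, end - trail
            sentences.append(Sentence(text[lo:hi], tokenize(text[lo:hi]), (lo, hi)))
        start = end
    return sentences


# --------------------------------------------------------------------------
# figure-label normalization

_FIG_LABEL_RE = re.compile(
    r"fig(?:ure)?s?\.?\s*(S?)(\d+|[IVXLCDM]+)", re.IGNORECASE)


def normalize_figure_label(label: str) -> tuple[int | None, str | None]:
    """Map a figure label to (figure_id, supplementary_key).

    Plain arabic numbers ("Figure 3.") become integer ids. "S1"-style
    supplementary figures and roman numerals land in a separate namespace
    (returned as the second element) and are excluded from caption linkage.
    """
    m = _FIG_LABEL_RE.search(label)
    if not m:
        stripped = label.strip().rstrip(".")
        if stripped.isdigit():
            return int(stripped), None
        return None, stripped or None
    supp, num = m.group(1), m.group(2)
    if supp:
        return None, f"S{num}"
    if num.isdigit():
        return int(num), None
    return None, num.upper()  # roman numeral namespace


# --------------------------------------------------------------------------
# JATS-subset reader / writer

class ParseError(ValueError):
    """Raised for malformed input streams, naming the offending element."""


_HANDLED_TAGS = {
    "article", "front", "article-meta", "article-id", "title-group",
    "article-title", "abstract", "kwd-group", "kwd", "body", "sec", "title",
    "p", "fig", "label", "caption",
}


def _text_of(el) -> str:
    return re.sub(r"\s+", " ", " ".join(el.itertext())).strip()


def _read_jats(stream: TextIO, doc_id: str | None) -> Document:
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "article":
        raise ParseError(f"expected <article> root, found <{root.tag}>")

    for el in root.iter():
        if isinstance(el.tag, str) and el.tag not in _HANDLED_TAGS:
            logger.info("unhandled tag <%s>: text retained", el.tag)

    id_el = root.find(".//article-meta/article-id")
    if id_el is not None and _text_of(id_el):
        doc_id = _text_of(id_el)  # an explicit article-id wins
    elif doc_id is None:
        doc_id = "unknown"
    title_el = root.find(".//article-meta/title-group/article-title")
    abstract_el = root.find(".//article-meta/abstract")
    if abstract_el is None:
        logger.warning("document %s has no abstract", doc_id)
    mesh = [_text_of(k) for k in root.findall(".//article-meta/kwd-group/kwd")]

    doc = Document(
        doc_id=doc_id,
        title=_text_of(title_el) if title_el is not None else "",
        abstract=_text_of(abstract_el) if abstract_el is not None else "",
        mesh_terms=mesh,
    )

    body = root.find("body")
    if body is not None:
        fig_counter = 0
        for el in body.iter():
            if el.tag == "p":
                anc = {a.tag for a in el.iterancestors()}
                if "fig" in anc or "caption" in anc:
                    continue
                sec_title = ""
                for a in el.iterancestors("sec"):
                    t = a.find("title")
                    if t is not None:
                        sec_title = _text_of(t)
                    break
                doc.paragraphs.append(ParagraphBlock(sec_title, _text_of(el)))
            elif el.tag == "fig":
                fig_counter += 1
                label_el = el.find("label")
                cap_el = el.find("caption")
                cap_text = _text_of(cap_el) if cap_el is not None else ""
                if label_el is not None:
                    fig_id, supp = normalize_figure_label(_text_of(label_el))
                else:
                    fig_id, supp = fig_counter, None
                if fig_id is not None:
                    if fig_id in doc.captions:
                        raise ParseError(f"duplicate figure id {fig_id} in <fig>")
                    doc.captions[fig_id] = cap_text
                elif supp is not None:
                    doc.supplementary_captions[supp] = cap_text
                else:
                    logger.warning("figure with unparseable label dropped into "
                                   "supplementary namespace: %r", _text_of(label_el))
    return doc


def _read_plain(stream: TextIO, doc_id: str | None) -> Document:
    """Fixture dialect: one block per line, tab-prefixed kind tag.

    Tags: ``id``, ``title``, ``abstract``, ``mesh`` (one term per line),
    ``sec`` (sets the current section label), ``p``, ``caption\\t<n>``.
    """
    doc = Document(doc_id=doc_id or "unknown")
    section = ""
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        tag = parts[0]
        if tag == "id":
            doc.doc_id = parts[1]
        elif tag == "title":
            doc.title = parts[1]
        elif tag == "abstract":
            doc.abstract = (doc.abstract + " " + parts[1]).strip()
        elif tag == "mesh":
            doc.mesh_terms.append(parts[1])
        elif tag == "sec":
            section = parts[1]
        elif tag == "p":
            doc.paragraphs.append(ParagraphBlock(section, parts[1]))
        elif tag == "caption":
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: caption needs id and text")
            doc.captions[int(parts[1])] = parts[2]
        else:
            raise ParseError(f"line {lineno}: unknown tag {tag!r}")
    return doc


def read_document(source: Union[str, Path, TextIO], dialect: str = "jats",
                  doc_id: str | None = None) -> Document:
    """Read one article from a file path or text stream."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_document(fh, dialect=dialect,
                                 doc_id=doc_id or Path(source).stem)
    if dialect == "jats":
        return _read_jats(source, doc_id)
    if dialect == "plain":
        return _read_plain(source, doc_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_document(doc: Document, target: Union[str, Path, TextIO],
                   dialect: str = "jats") -> None:
    """Serialize a Document so that re-reading yields an equal Document."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            write_document(doc, fh, dialect=dialect)
        return
    if dialect == "jats":
        root = etree.Element("article")
        front = etree.SubElement(root, "front")
        meta = etree.SubElement(front, "article-meta")
        etree.SubElement(meta, "article-id").text = doc.doc_id
        tg = etree.SubElement(meta, "title-group")
        etree.SubElement(tg, "article-title").text = doc.title
        ab = etree.SubElement(meta, "abstract")
        etree.SubElement(ab, "p").text = doc.abstract
        if doc.mesh_terms:
            kg = etree.SubElement(meta, "kwd-group")
            for term in doc.mesh_terms:
                etree.SubElement(kg, "kwd").text = term
        body = etree.SubElement(root, "body")
        current_sec = None
        current_label = None
        for block in doc.paragraphs:
            if current_sec is None or block.section != current_label:
                current_sec = etree.SubElement(body, "sec")
                if block.section:
                    etree.SubElement(current_sec, "title").text = block.section
                current_label = block.section
            etree.SubElement(current_sec, "p").text = block.text
        for fig_id in sorted(doc.captions):
            fig = etree.SubElement(body, "fig")
            etree.SubElement(fig, "label").text = f"Figure {fig_id}."
            cap = etree.SubElement(fig, "caption")
            etree.SubElement(cap, "p").text = doc.captions[fig_id]
        for key in sorted(doc.supplementary_captions):
            fig = etree.SubElement(body, "fig")
            etree.SubElement(fig, "label").text = f"Figure {key}."
            cap = etree.SubElement(fig, "caption")
            etree.SubElement(cap, "p").text = doc.supplementary_captions[key]
        target.write(etree.tostring(root, pretty_print=True,
                                    encoding="unicode"))
    elif dialect == "plain":
        lines = [f"id\t{doc.doc_id}"]
        if doc.title:
            lines.append(f"title\t{doc.title}")
        if doc.abstract:
            lines.append(f"abstract\t{doc.abstract}")
        lines.extend(f"mesh\t{t}" for t in doc.mesh_terms)
        section = None
        for block in doc.paragraphs:
            if block.section != section:
                lines.append(f"sec\t{block.section}")
                section = block.section
            lines.append(f"p\t{block.text}")
        for fig_id in sorted(doc.captions):
            lines.append(f"caption\t{fig_id}\t{doc.captions[fig_id]}")
        target.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_tokenized_corpus(docs: Iterable[Document],
                           target: Union[str, Path, TextIO]) -> None:
    """Write one tokenized sentence per line, space-separated tokens."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            write_tokenized_corpus(docs, fh)
        return
    for doc in docs:
        blocks = [doc.title, doc.abstract]
        blocks += [b.text for b in doc.paragraphs]
        blocks += [doc.captions[k] for k in sorted(doc.captions)]
        for block in blocks:
            for sent in split_sentences(block):
                if sent.tokens:
                    target.write(" ".join(sent.tokens) + "\n")
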