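"""Parse an article and extract figure references and evidence fragments.

Builds a small JATS-subset article in memory, reads it into a Document,
finds the subfigure references in the narrative, and delineates the
evidence fragments each reference anchors.
"""

import io

from evitriage import (caption_for, extract_evidence_fragments,
                       find_figure_references, read_document)

ARTICLE = """\
<article>
  <front><article-meta>
    <article-id>PMC900001</article-id>
    <title-group><article-title>MDM2 ubiquitinates p53</article-title></title-group>
    <abstract><p>We show MDM2 binds and ubiquitinates p53.</p></abstract>
    <kwd-group><kwd>Proteins</kwd><kwd>Ubiquitination</kwd></kwd-group>
  </article-meta></front>
  <body>
    <sec><title>Results</title>
      <p>MDM2 co-precipitated with p53 (Fig. 1A and 1C–E). Binding was
         dose-dependent. Ubiquitination required the RING domain (Fig. 2B).</p>
    </sec>
    <fig id="F1"><label>Figure 1.</label>
      <caption><p>(A) Co-IP. (C-E) Dose series.</p></caption></fig>
    <fig id="F2"><label>Figure 2.</label>
      <caption><p>(B) RING-mutant ubiquitination assay.</p></caption></fig>
  </body>
</article>
"""

doc = read_document(io.StringIO(ARTICLE), dialect="jats")
print(f"document {doc.doc_id}: {len(doc.paragraphs)} paragraph(s), "
      f"{len(doc.captions)} caption(s)")

text = doc.paragraphs[0].text
print("\nFigure references found in the Results paragraph:")
for ref in find_figure_references(text):
    print(f"  figure {ref.figure_id}, panels {list(ref.panels) or 'whole'}: "
          f"{text[ref.span[0]:ref.span[1]]!r}")

print("\nEvidence fragments (the sentences describing each figure):")
for frag in extract_evidence_fragments(doc):
    print(f"  Fig {frag.figure_id}{''.join(frag.panels)}: {frag.text!r}")
    linked = caption_for(doc, find_figure_references(
        f"Fig. {frag.figure_id}")[0])
    print(f"    linked caption: {linked.text!r}")

# Each fragment is the run of sentences anchored to one (figure, panels)
# key; the caption link attaches the whole figure caption to that evidence.
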