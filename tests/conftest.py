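import io
import textwrap

import pytest

from evitriage.corpus import Document, ParagraphBlock, read_document
from evitriage.embeddings import load_word_vectors

JATS_FIXTURE = textwrap.dedent("""\
    <article>
      <front>
        <article-meta>
          <article-id>PMC0001</article-id>
          <title-group><article-title>MDM2 binds p53</article-title></title-group>
          <abstract><p>We show that MDM2 binds p53 in vitro.</p></abstract>
          <kwd-group><kwd>Proteins</kwd><kwd>Cells</kwd></kwd-group>
        </article-meta>
      </front>
      <body>
        <sec>
          <title>Results</title>
          <p>MDM2 co-precipitated with p53 (Fig. 1A). Binding was specific.</p>
          <p>Degradation followed over time.</p>
        </sec>
        <fig id="F1">
          <label>Figure 1.</label>
          <caption><p>(A) Co-IP of MDM2 and p53. (B) Input controls.</p></caption>
        </fig>
      </body>
    </article>
""")


@pytest.fixture
def jats_doc():
    return read_document(io.StringIO(JATS_FIXTURE), dialect="jats")


@pytest.fixture
def toy_doc():
    """A small hand-built document with two figures and in-text references."""
    return Document(
        doc_id="toy1",
        title="A study of binding",
        abstract="We measured binding. It was strong.",
        mesh_terms=["Proteins", "Cell Line"],
        paragraphs=[
            ParagraphBlock("Results",
                           "We measured binding. The complex formed readily "
                           "(Fig. 1A). Levels rose over time."),
            ParagraphBlock("Results",
                           "Degradation followed in Fig. 2. Controls were "
                           "unchanged."),
        ],
        captions={1: "(A) Binding assay. (B) Controls.",
                  2: "Degradation time course."},
    )


def make_word_vector_file(tokens_vecs, header=False):
    buf = io.StringIO()
    if header:
        dim = len(tokens_vecs[0][1])
        buf.write(f"{len(tokens_vecs)} {dim}\n")
    for tok, vec in tokens_vecs:
        buf.write(tok + " " + " ".join(str(v) for v in vec) + "\n")
    buf.seek(0)
    return buf


@pytest.fixture
def tiny_table():
    """4-token, 4-dimensional embedding table (plus pad)."""
    rows = [("binds", [1.0, 0.0, 0.0, 0.0]),
            ("p53", [0.0, 1.0, 0.0, 0.0]),
            ("mdm2", [0.0, 0.0, 1.0, 0.0]),
            ("the", [0.0, 0.0, 0.0, 1.0])]
    return load_word_vectors(make_word_vector_file(rows),
                             format="wordvec_text_headerless")
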