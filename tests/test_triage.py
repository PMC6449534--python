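import math

import numpy as np
import pytest

from evitriage.corpus import Document
from evitriage.synth import (SynthConfig, generate_triage_corpus,
                             toy_embedding_table, triage_vocabulary)
from evitriage.triage import (AttentionParams, TextSource,
                              TriageConfig, TriageModel, attend,
                              classify_document, encode_passage,
                              select_passages, train_triage)


def brute_force_attention(H, params):
    """Independent oracle: explicit loops, no shared code with attend()."""
    P, E = len(H), len(H[0])
    scores = []
    for i in range(P):
        proj = [math.tanh(sum(H[i][k] * params.W[k][a] for k in range(E))
                          + params.b[a]) for a in range(len(params.b))]
        scores.append(sum(proj[a] * params.v[a] for a in range(len(params.v))))
    m = max(scores)
    exps = [math.exp(s - m) for s in scores]
    z = sum(exps)
    weights = [e / z for e in exps]
    doc_vec = [sum(weights[i] * H[i][k] for i in range(P)) for k in range(E)]
    return np.array(weights), np.array(doc_vec)


def small_config(**kw):
    kw.setdefault("text_source", TextSource.CAPTIONS)
    kw.setdefault("max_len", 16)
    kw.setdefault("conv_filters", 8)
    kw.setdefault("lstm_units", 4)
    kw.setdefault("attention_width", 6)
    kw.setdefault("epochs", 2)
    return TriageConfig(**kw)


@pytest.fixture(scope="module")
def tiny_corpus():
    cfg = SynthConfig(n_docs=60, seed=21, signal_probability=1.0)
    docs, labels = generate_triage_corpus(cfg)
    table = toy_embedding_table(triage_vocabulary(cfg), 12, seed=4)
    return docs, labels, table


class TestSelectPassages:
    def test_captions_in_figure_order(self, toy_doc):
        passages = select_passages(toy_doc, "captions")
        assert len(passages) == 2
        assert all(p.kind.value == "caption" for p in passages)
        assert [p.figure_ref[0] for p in passages] == [1, 2]

    def test_title_single_passage(self, toy_doc):
        passages = select_passages(toy_doc, TextSource.TITLE)
        assert len(passages) == 1
        assert passages[0].text == toy_doc.title

    def test_combined_source_captions_then_fragments(self, toy_doc):
        passages = select_passages(toy_doc, "captions_plus_fragments")
        kinds = [p.kind.value for p in passages]
        assert kinds == ["caption", "caption",
                         "evidence_fragment", "evidence_fragment"]
        positions = [p.origin[1] for p in passages]
        assert positions == sorted(positions)

    def test_all_paragraphs_in_document_order(self, toy_doc):
        passages = select_passages(toy_doc, "all_paragraphs")
        assert [p.text for p in passages] == \
            [b.text for b in toy_doc.paragraphs]

    def test_empty_selection_degenerate_contract(self, caplog):
        doc = Document(doc_id="empty")
        with caplog.at_level("WARNING"):
            passages = select_passages(doc, "captions")
        assert len(passages) == 1 and passages[0].text == ""
        assert "empty selection" in caplog.text

    def test_truncation_at_max_passages(self, toy_doc):
        passages = select_passages(toy_doc, "captions", max_passages=1)
        assert len(passages) == 1 and passages[0].figure_ref[0] == 1

    def test_mesh_phrase_mode(self, toy_doc):
        tokenized = select_passages(toy_doc, "mesh")[0]
        phrases = select_passages(toy_doc, "mesh", mesh_as_phrases=True)[0]
        assert "Cell Line" in tokenized.text
        assert "Cell_Line" in phrases.text


class TestAttend:
    def test_single_passage_identity(self):
        rng = np.random.default_rng(0)
        params = AttentionParams(rng.normal(size=(5, 3)), rng.normal(size=3),
                                 rng.normal(size=3))
        H = rng.normal(size=(1, 5))
        out = attend(H, params)
        assert np.allclose(out.weights, [1.0])
        assert np.allclose(out.doc_vector, H[0])

    def test_identical_vectors_uniform_weights(self):
        rng = np.random.default_rng(1)
        params = AttentionParams(rng.normal(size=(4, 3)), rng.normal(size=3),
                                 rng.normal(size=3))
        H = np.tile(rng.normal(size=(1, 4)), (5, 1))
        out = attend(H, params)
        assert np.allclose(out.weights, 0.2)

    def test_matches_brute_force_oracle_100_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            P = int(rng.integers(3, 11))
            E = int(rng.integers(8, 33))
            A = int(rng.integers(4, 17))
            H = rng.normal(size=(P, E))
            params = AttentionParams(rng.normal(size=(E, A)),
                                     rng.normal(size=A), rng.normal(size=A))
            out = attend(H, params)
            w_ref, v_ref = brute_force_attention(H.tolist(), params)
            assert np.abs(out.weights - w_ref).max() < 1e-6
            assert np.abs(out.doc_vector - v_ref).max() < 1e-6
            assert abs(out.weights.sum() - 1.0) < 1e-6

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        params = AttentionParams(rng.normal(size=(6, 4)), rng.normal(size=4),
                                 rng.normal(size=4))
        H = rng.normal(size=(5, 6))
        perm = rng.permutation(5)
        a = attend(H, params)
        b = attend(H[perm], params)
        assert np.allclose(b.weights, a.weights[perm])
        assert np.allclose(b.doc_vector, a.doc_vector)


class TestEncodePassage:
    def test_zero_input_finite_and_deterministic(self, tiny_corpus):
        _, _, table = tiny_corpus
        model = TriageModel(small_config(), table)
        x = np.zeros((model.config.max_len, table.dim))
        a = encode_passage(model, x)
        b = encode_passage(model, x)
        assert np.isfinite(a).all()
        assert np.array_equal(a, b)

    def test_identical_passages_identical_vectors(self, tiny_corpus):
        docs, _, table = tiny_corpus
        model = TriageModel(small_config(), table)
        ids = model.doc_token_ids(docs[0])
        emb = table.matrix[ids[0]]
        assert np.array_equal(encode_passage(model, emb),
                              encode_passage(model, emb))

    def test_output_width_is_twice_recurrent_units(self, tiny_corpus):
        _, _, table = tiny_corpus
        model = TriageModel(small_config(lstm_units=7), table)
        x = np.zeros((model.config.max_len, table.dim))
        assert encode_passage(model, x).shape == (14,)

    def test_shape_mismatch_rejected(self, tiny_corpus):
        _, _, table = tiny_corpus
        model = TriageModel(small_config(), table)
        with pytest.raises(ValueError, match="shape"):
            encode_passage(model, np.zeros((3, table.dim)))


class TestClassifyDocument:
    def test_probability_in_unit_interval(self, tiny_corpus):
        docs, _, table = tiny_corpus
        model = TriageModel(small_config(), table)
        prob, att = classify_document(model, docs[0])
        assert 0.0 <= prob <= 1.0
        assert abs(att.weights.sum() - 1.0) < 1e-6

    def test_single_passage_gets_full_attention(self, tiny_corpus):
        _, _, table = tiny_corpus
        doc = Document(doc_id="one", captions={1: "a single caption here ."})
        model = TriageModel(small_config(), table)
        _, att = classify_document(model, doc)
        assert np.allclose(att.weights, [1.0])

    def test_model_attention_matches_attend_function(self, tiny_corpus):
        docs, _, table = tiny_corpus
        model = TriageModel(small_config(), table)
        ids = model.doc_token_ids(docs[0])
        _, att = classify_document(model, docs[0])
        from evitriage.nn import autograd as ag
        H = model._encode(ag.Tensor(table.matrix[ids])).data
        ref = attend(H, model.attention_params())
        assert np.allclose(att.weights, ref.weights, atol=1e-9)

    def test_simple_cnn_encoder_for_title_source(self, tiny_corpus):
        docs, _, table = tiny_corpus
        cfg = small_config(text_source="title")
        assert cfg.effective_encoder == "cnn"
        model = TriageModel(cfg, table)
        prob, att = classify_document(model, docs[0])
        assert 0.0 <= prob <= 1.0 and np.allclose(att.weights, [1.0])


class TestTrainTriage:
    def test_single_class_rejected(self, tiny_corpus):
        docs, labels, table = tiny_corpus
        pos = [d for d, y in zip(docs, labels) if y == 1]
        model = TriageModel(small_config(), table)
        with pytest.raises(ValueError, match="classes"):
            train_triage(model, pos, [1] * len(pos))

    def test_reproducible_history(self, tiny_corpus):
        docs, labels, table = tiny_corpus
        hists = []
        for _ in range(2):
            model = TriageModel(small_config(seed=8), table)
            _, hist = train_triage(model, docs, labels)
            hists.append(hist)
        assert hists[0] == hists[1]

    def test_mean_aggregation_ablation_runs(self, tiny_corpus):
        docs, labels, table = tiny_corpus
        model = TriageModel(small_config(aggregation="mean"), table)
        _, hist = train_triage(model, docs, labels)
        assert len(hist["train_loss"]) >= 1
        _, att = classify_document(model, docs[0])
        assert np.allclose(att.weights, att.weights[0])  # uniform
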