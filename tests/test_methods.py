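import numpy as np
import pytest

from evitriage.corpus import Passage, PassageKind
from evitriage.methods import (LabeledPassage, LabelScheme,
                               PassageClassifierConfig, build_passage_model,
                               evaluate_multirestart, group_label,
                               predict_passage, train_passage_classifier)
from evitriage.synth import (MethodSynthConfig, generate_method_corpus,
                             make_grouping_scheme, method_vocabulary,
                             toy_embedding_table)


@pytest.fixture(scope="module")
def separable():
    """Binary corpus where every passage carries its class signal token."""
    cfg = MethodSynthConfig(preset=None, n_classes=2, n_passages=700,
                            signal_probability=1.0, seed=3)
    data, scheme = generate_method_corpus(cfg)
    table = toy_embedding_table(method_vocabulary(cfg), 50, seed=9)
    return cfg, data, scheme, table


def fast_config(**kw):
    kw.setdefault("max_len", 44)
    kw.setdefault("conv_filters", 24)
    kw.setdefault("lstm_units", 24)
    kw.setdefault("dense_width", 32)
    kw.setdefault("learning_rate", 3e-3)
    kw.setdefault("epochs", 15)
    kw.setdefault("early_stopping_patience", 6)
    return PassageClassifierConfig(**kw)


class TestLabelScheme:
    def test_identity_scheme(self):
        scheme = LabelScheme("id", {"a": "a", "b": "b"})
        assert group_label(scheme, "a") == "a"

    def test_many_to_one(self):
        scheme = LabelScheme("s", {"a": "X", "b": "X", "c": "Y"})
        assert group_label(scheme, "b") == "X"
        assert scheme.grouped_labels == ["X", "Y"]

    def test_unknown_code_names_code_and_scheme(self):
        scheme = LabelScheme("myscheme", {"a": "X"})
        with pytest.raises(KeyError, match="'zz'.*'myscheme'"):
            group_label(scheme, "zz")

    def test_tsv_round_trip_with_grouping_cardinalities(self, tmp_path):
        scheme = make_grouping_scheme("participant", 8, 44)
        path = tmp_path / "scheme.tsv"
        scheme.to_tsv(path)
        again = LabelScheme.from_tsv(path)
        assert again.mapping == scheme.mapping
        assert len(again.fine_codes) == 44
        assert len(again.grouped_labels) == 8

    def test_labeled_passage_from_fine(self):
        scheme = LabelScheme("s", {"a": "X"})
        p = Passage("text", PassageKind.CAPTION, figure_ref=(1, ()))
        lp = LabeledPassage.from_fine(p, "a", scheme)
        assert lp.grouped_code == "X"


class TestModelConstruction:
    @pytest.mark.parametrize("arch,n_classes", [("cnn", 2), ("lstm", 17)])
    def test_output_width(self, tiny_table, arch, n_classes):
        cfg = fast_config(arch=arch, max_len=8)
        model = build_passage_model(cfg, tiny_table,
                                    [f"c{i}" for i in range(n_classes)])
        probs = predict_passage(model, ["binds", "p53"])
        assert probs.shape == (n_classes,)
        assert abs(probs.sum() - 1.0) < 1e-6

    def test_same_seed_identical_parameters(self, tiny_table):
        cfg = fast_config(seed=5, max_len=8)
        a = build_passage_model(cfg, tiny_table, ["x", "y"])
        b = build_passage_model(cfg, tiny_table, ["x", "y"])
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.data, pb.data)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="arch"):
            PassageClassifierConfig(arch="transformer")

    def test_dropout_range_enforced_unless_overridden(self):
        with pytest.raises(ValueError, match="dropout"):
            PassageClassifierConfig(dropout=0.9)
        cfg = PassageClassifierConfig(dropout=0.9,
                                      allow_dropout_out_of_range=True)
        assert cfg.dropout == 0.9

    def test_empty_passage_valid_distribution(self, tiny_table):
        model = build_passage_model(fast_config(max_len=8), tiny_table,
                                    ["x", "y"])
        probs = predict_passage(model, [])
        assert np.isfinite(probs).all() and abs(probs.sum() - 1.0) < 1e-6


class TestTraining:
    def test_separable_data_learned(self, separable):
        cfg, data, scheme, table = separable
        model = build_passage_model(fast_config(seed=1), table,
                                    scheme.grouped_labels)
        report = evaluate_multirestart(data, fast_config(seed=1), 1, table)
        assert report.accuracies[0] >= 0.95

    def test_shuffled_labels_at_majority_rate(self, separable):
        cfg, data, scheme, table = separable
        rng = np.random.default_rng(0)
        codes = [p.grouped_code for p in data]
        shuffled = [LabeledPassage(p.passage, p.fine_code, c)
                    for p, c in zip(data, rng.permutation(codes))]
        report = evaluate_multirestart(shuffled, fast_config(seed=1, epochs=8),
                                       1, table)
        majority = max(np.mean([c == codes[0] for c in codes]),
                       1 - np.mean([c == codes[0] for c in codes]))
        assert abs(report.accuracies[0] - majority) <= 0.1

    def test_zero_epochs_leaves_model_unchanged(self, separable):
        _, data, scheme, table = separable
        model = build_passage_model(fast_config(epochs=0), table,
                                    scheme.grouped_labels)
        before = [p.data.copy() for p in model.params()]
        train_passage_classifier(model, data[:100])
        for p, b in zip(model.params(), before):
            assert np.array_equal(p.data, b)

    def test_single_class_input_rejected(self, separable):
        _, data, scheme, table = separable
        model = build_passage_model(fast_config(), table,
                                    scheme.grouped_labels)
        one_class = [p for p in data if p.grouped_code == data[0].grouped_code]
        with pytest.raises(ValueError, match="2 classes"):
            train_passage_classifier(model, one_class[:50])

    def test_frozen_embeddings_bitwise_unchanged(self, separable):
        _, data, scheme, table = separable
        cfg = fast_config(epochs=2, trainable_embeddings=False)
        model = build_passage_model(cfg, table, scheme.grouped_labels)
        before = model.embedding.data.tobytes()
        train_passage_classifier(model, data[:200])
        assert model.embedding.data.tobytes() == before

    def test_trainable_embeddings_do_change(self, separable):
        _, data, scheme, table = separable
        cfg = fast_config(epochs=2, trainable_embeddings=True)
        model = build_passage_model(cfg, table, scheme.grouped_labels)
        before = model.embedding.data.tobytes()
        train_passage_classifier(model, data[:200])
        assert model.embedding.data.tobytes() != before

    def test_forward_outputs_finite_and_normalized(self, separable):
        _, data, scheme, table = separable
        model = build_passage_model(fast_config(), table,
                                    scheme.grouped_labels)
        probs = model.predict_proba(model.encode_batch(data[:32]))
        assert np.isfinite(probs).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestMultiRestart:
    def test_single_restart_std_zero(self, separable):
        _, data, _, table = separable
        report = evaluate_multirestart(data, fast_config(epochs=1), 1, table)
        assert report.std == 0.0

    def test_bit_identical_reports_across_runs(self, separable):
        _, data, _, table = separable
        cfg = fast_config(epochs=2, seed=4)
        a = evaluate_multirestart(data[:300], cfg, 2, table)
        b = evaluate_multirestart(data[:300], cfg, 2, table)
        assert a.accuracies == b.accuracies
        assert np.array_equal(a.confusion, b.confusion)

    def test_restarts_vary_only_by_seed(self, separable):
        _, data, _, table = separable
        report = evaluate_multirestart(data[:300], fast_config(epochs=1, seed=4),
                                       3, table)
        assert report.seeds == [4, 5, 6]

    def test_confusion_rows_sum_to_class_counts(self, separable):
        _, data, _, table = separable
        report = evaluate_multirestart(data, fast_config(epochs=1), 1, table,
                                       test_fraction=0.2)
        y = np.array([report.classes.index(p.grouped_code) for p in data])
        # test split is 20% of each class
        counts = np.bincount(y)
        expected = counts - np.floor(0.8 * counts) - (
            counts - (np.floor(0.8 * counts) + np.floor(0.2 * counts)))
        assert report.confusion.sum() == report.confusion.sum(axis=1).sum()
        assert report.confusion.sum(axis=1).tolist() == [
            int(np.floor(0.2 * c)) for c in counts]

    def test_signal_recovery_monotone_in_p(self):
        """Held-out accuracy is non-decreasing in the planted signal
        probability (within simulation noise), 5 restarts per level."""
        means = []
        for p in (0.2, 0.5, 1.0):
            cfg = MethodSynthConfig(preset=None, n_classes=2, n_passages=600,
                                    signal_probability=p, seed=6)
            data, _ = generate_method_corpus(cfg)
            table = toy_embedding_table(method_vocabulary(cfg), 50, seed=9)
            report = evaluate_multirestart(
                data, fast_config(seed=2, epochs=10), 5, table)
            means.append(report.mean)
        assert means[1] >= means[0] - 0.05
        assert means[2] >= means[1] - 0.05
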