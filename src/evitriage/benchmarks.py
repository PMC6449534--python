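"""Standard synthetic benchmark conditions for the two classification tasks.

These functions pin down the corpus and model configurations used by the
package's own evaluation suite, so tests, examples and scripts all run the
same study conditions:

* **Triage benchmark** — 1000 documents at the 537:451 positive:negative
  class balance, split 800 train / 200 test; signal tokens planted in
  exactly one caption per positive document with per-sentence probability
  0.8; 50-dimensional toy word vectors. The caption-source classifier is
  the CNN-BiLSTM-with-attention network; the abstract-source classifier is
  the no-signal control.
* **Method benchmark** — balanced passage corpora with guaranteed
  (p = 1) class signal, at the grouped-code cardinalities of the curated
  method-annotation task (8 and 17 classes), with 100-dimensional toy word
  vectors; CNN and LSTM heads with per-architecture optimizer settings.

Problem sizes are chosen so a full evaluation runs in minutes on one CPU
core while leaving clear headroom over the recovery thresholds the
generators make achievable.
"""

from __future__ import annotations

from .embeddings import EmbeddingTable
from .methods import PassageClassifierConfig
from .synth import (MethodSynthConfig, SynthConfig, method_vocabulary,
                    toy_embedding_table, triage_vocabulary)
from .triage import TextSource, TriageConfig

__all__ = [
    "TRIAGE_EMBED_DIM", "METHOD_EMBED_DIM", "triage_corpus_config",
    "triage_model_config", "triage_table", "method_corpus_config",
    "method_model_config", "method_table", "EVIDENCE_FIXTURES",
]

#: hand-annotated fixture paragraphs with their expected evidence fragments
#: (figure id, panels, fragment text), covering panel ranges, multi-figure
#: sentences, same-key merging and reference-free text.
EVIDENCE_FIXTURES = [
    ("No references at all here. Just narrative text.", []),
    ("Binding occurred (Fig. 1A). It persisted.",
     [(1, ("A",), "Binding occurred (Fig. 1A). It persisted.")]),
    ("Intro sentence. Results in Fig. 2B–D were strong. More detail follows.",
     [(2, ("B", "C", "D"),
       "Results in Fig. 2B–D were strong. More detail follows.")]),
    ("Fig. 1A shows binding. Fig. 2 shows decay.",
     [(1, ("A",), "Fig. 1A shows binding."),
      (2, (), "Fig. 2 shows decay.")]),
    ("Setup text. We saw binding (Figure 3). It decayed. "
     "Controls in Figure 4A,B.",
     [(3, (), "We saw binding (Figure 3). It decayed."),
      (4, ("A", "B"), "Controls in Figure 4A,B.")]),
    ("Both effects (Fig. 1A and Fig. 2) appeared. They persisted.",
     [(1, ("A",), "Both effects (Fig. 1A and Fig. 2) appeared. They persisted."),
      (2, (), "Both effects (Fig. 1A and Fig. 2) appeared. They persisted.")]),
    ("Fig. 5 shows binding. Fig. 5 also shows kinetics.",
     [(5, (), "Fig. 5 shows binding. Fig. 5 also shows kinetics.")]),
    ("Figs 6 and 7 both matter. The end.",
     [(6, (), "Figs 6 and 7 both matter. The end."),
      (7, (), "Figs 6 and 7 both matter. The end.")]),
    ("Nothing here yet. Then Fig. 8A appears.",
     [(8, ("A",), "Then Fig. 8A appears.")]),
    ("A heading without terminal punctuation", []),
    ("(Figures 1A and 1C–E) show results. Continued discussion.",
     [(1, ("A",), "(Figures 1A and 1C–E) show results. Continued discussion."),
      (1, ("C", "D", "E"),
       "(Figures 1A and 1C–E) show results. Continued discussion.")]),
    ("Fig. 9B was clear. An unrelated middle sentence. Fig. 9B again.",
     [(9, ("B",),
       "Fig. 9B was clear. An unrelated middle sentence. Fig. 9B again.")]),
]

TRIAGE_EMBED_DIM = 50    # GloVe-50-like
METHOD_EMBED_DIM = 100   # FastText-100-like

#: held-out fractions for the triage benchmark (800 train / 200 test)
TRIAGE_TEST_FRACTION = 0.2
TRIAGE_VAL_FRACTION = 0.12

_METHOD_SIZES = {"participant_detection": 1600,
                 "interaction_detection": 2720,
                 "western_blot_yes_no": 800}


def triage_corpus_config(seed: int) -> SynthConfig:
    """The localized-signal triage corpus: signal in one caption per
    positive document, per-sentence planting probability 0.8."""
    return SynthConfig(n_docs=1000, seed=seed, signal_location=("caption",),
                       signal_placement="one", signal_probability=0.8)


def triage_table(corpus_config: SynthConfig, seed: int) -> EmbeddingTable:
    return toy_embedding_table(triage_vocabulary(corpus_config),
                               TRIAGE_EMBED_DIM, seed + 7)


def triage_model_config(source: TextSource | str, seed: int) -> TriageConfig:
    """One training recipe for every text source — only the source (and the
    token budget: captions are short) differs, so source comparisons are
    apples to apples."""
    source = TextSource(source)
    short = source in (TextSource.CAPTIONS, TextSource.EVIDENCE_FRAGMENTS,
                       TextSource.CAPTIONS_PLUS_FRAGMENTS)
    return TriageConfig(text_source=source, max_len=32 if short else 64,
                        seed=seed, learning_rate=3e-3, epochs=25,
                        early_stopping_patience=5)


def method_corpus_config(preset: str, seed: int,
                         signal_probability: float = 1.0) -> MethodSynthConfig:
    return MethodSynthConfig(preset=preset,
                             n_passages=_METHOD_SIZES[preset],
                             signal_probability=signal_probability, seed=seed)


def method_table(corpus_config: MethodSynthConfig, seed: int) -> EmbeddingTable:
    return toy_embedding_table(method_vocabulary(corpus_config),
                               METHOD_EMBED_DIM, seed + 7)


def method_model_config(arch: str, seed: int) -> PassageClassifierConfig:
    """Per-architecture optimizer settings: the CNN trains stably at 3e-3,
    the LSTM needs 1e-2 and more epochs to converge on these corpora."""
    if arch == "cnn":
        return PassageClassifierConfig(arch="cnn", max_len=44, seed=seed,
                                       conv_filters=32, learning_rate=3e-3,
                                       epochs=30, early_stopping_patience=8)
    return PassageClassifierConfig(arch="lstm", max_len=44, seed=seed,
                                   lstm_units=48, learning_rate=1e-2,
                                   epochs=45, early_stopping_patience=10)
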