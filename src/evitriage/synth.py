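"""Synthetic corpora with plantable, localizable class signal.

Real triage and method-classification corpora cannot be redistributed, so
every pipeline stage is exercised on generated articles instead: Zipfian
nonsense background text (which isolates classifier behavior from linguistic
confounds), figure captions consistent with in-text figure references (so
evidence extraction is exercised end to end), and disjoint sets of signal
tokens planted in a chosen text source with controllable probability.

The default class balance is 537:451 positive:negative, matching the size
of the curated triage training set this generator stands in for, so
majority-class baselines are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .corpus import Document, ParagraphBlock, PassageKind
from .embeddings import EmbeddingTable, load_word_vectors
from .methods import LabeledPassage, LabelScheme
from .corpus import Passage

__all__ = [
    "SynthConfig", "MethodSynthConfig", "generate_triage_corpus",
    "generate_method_corpus", "generate_toy_embeddings",
    "toy_embedding_table", "triage_vocabulary", "method_vocabulary",
    "make_grouping_scheme", "METHOD_PRESETS", "POSITIVE_FRACTION",
]

#: curated triage training set size: 537 positive, 451 negative examples
POSITIVE_FRACTION = 537 / (537 + 451)

_LOCATIONS = {"title", "abstract", "mesh", "paragraph", "caption",
              "evidence_fragment"}


@dataclass
class SynthConfig:
    """Knobs for the triage-corpus generator.

    ``signal_probability`` is the chance that each *sentence* of a targeted
    passage receives one signal token (so a 2-sentence targeted caption
    bears signal with probability 1-(1-p)^2; at p=1 every targeted passage
    is guaranteed signal, at p=0 positives and negatives are
    distributionally identical). ``signal_placement`` is "all" (every
    passage of the location kinds is targeted) or "one" (exactly one
    randomly chosen passage per positive document).
    """
    n_docs: int = 988
    positive_fraction: float = POSITIVE_FRACTION
    vocab_size: int = 400
    zipf_exponent: float = 1.05
    signal_tokens: tuple[str, ...] = ("sigwb", "sigcoip", "sigitx")
    signal_location: tuple[str, ...] = ("caption",)
    signal_probability: float = 0.8
    signal_placement: str = "all"
    paragraphs_per_doc: tuple[int, int] = (3, 5)
    sentences_per_paragraph: tuple[int, int] = (2, 4)
    sentence_length: tuple[int, int] = (8, 14)
    caption_sentences: tuple[int, int] = (2, 2)
    figures_per_doc: tuple[int, int] = (2, 3)
    figure_reference_density: float = 1.3
    mesh_terms_per_doc: tuple[int, int] = (3, 6)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0 <= self.signal_probability <= 1:
            raise ValueError("signal_probability must be in [0, 1]")
        if self.signal_placement not in ("all", "one"):
            raise ValueError(f"unknown placement {self.signal_placement!r}")
        unknown = set(self.signal_location) - _LOCATIONS
        if unknown:
            raise ValueError(f"unknown signal locations: {sorted(unknown)}")
        top50 = set(_background_vocab(self.vocab_size)[:50])
        if set(self.signal_tokens) & top50:
            raise ValueError("signal tokens collide with top-50 background tokens")
        needs_figs = {"caption", "evidence_fragment"} & set(self.signal_location)
        if needs_figs and self.figures_per_doc[1] < 1:
            raise ValueError(
                "signal located in captions/fragments but figures_per_doc "
                "allows 0 figures")


def _background_vocab(size: int) -> list[str]:
    return [f"tok{i:04d}" for i in range(size)]


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


_MESH_VOCAB = [f"heading{i:03d}" for i in range(60)]
_PANELS = ("A", "B", "C")


def triage_vocabulary(config: SynthConfig) -> list[str]:
    """Every token the triage generator can emit (for toy embeddings).

    Returned lowercase, since lookup lowercases and typical embedding
    vocabularies are lowercase.
    """
    vocab = _background_vocab(config.vocab_size)
    vocab += list(config.signal_tokens) + _MESH_VOCAB
    vocab += ["fig", ".", "(", ")", ","]
    vocab += [str(i) for i in range(1, config.figures_per_doc[1] + 1)]
    vocab += [f"{i}{p.lower()}" for i in range(1, config.figures_per_doc[1] + 1)
              for p in _PANELS]
    return vocab


def _rand_range(rng, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _sentence(rng, cfg: SynthConfig, bg: list[str], probs: np.ndarray
              ) -> list[str]:
    n = _rand_range(rng, cfg.sentence_length)
    return [bg[i] for i in rng.choice(len(bg), size=n, p=probs)]


def _insert_signal(rng, sentence_tokens: list[str],
                   signal_tokens: Sequence[str]) -> None:
    tok = signal_tokens[int(rng.integers(len(signal_tokens)))]
    pos = int(rng.integers(0, len(sentence_tokens) + 1))
    sentence_tokens.insert(pos, tok)


def generate_triage_corpus(config: SynthConfig
                           ) -> tuple[list[Document], np.ndarray]:
    """Generate (documents, binary labels); a pure function of the config."""
    rng = np.random.default_rng(config.seed)
    bg = _background_vocab(config.vocab_size)
    probs = _zipf_probs(config.vocab_size, config.zipf_exponent)

    n_pos = int(round(config.n_docs * config.positive_fraction))
    labels = np.zeros(config.n_docs, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(config.n_docs)]

    docs: list[Document] = []
    for d in range(config.n_docs):
        positive = bool(labels[d])
        # sentence token lists per passage, grouped by kind
        title = _sentence(rng, config, bg, probs)[:8]
        abstract = [_sentence(rng, config, bg, probs)
                    for _ in range(_rand_range(rng, (2, 3)))]
        mesh = [_MESH_VOCAB[i] for i in
                rng.choice(len(_MESH_VOCAB),
                           size=_rand_range(rng, config.mesh_terms_per_doc),
                           replace=False)]
        n_paras = _rand_range(rng, config.paragraphs_per_doc)
        paragraphs = [[_sentence(rng, config, bg, probs)
                       for _ in range(_rand_range(rng, config.sentences_per_paragraph))]
                      for _ in range(n_paras)]
        n_figs = _rand_range(rng, config.figures_per_doc)
        captions = {f: [_sentence(rng, config, bg, probs)
                        for _ in range(_rand_range(rng, config.caption_sentences))]
                    for f in range(1, n_figs + 1)}

        # in-text references: every figure is mentioned at least once
        ref_sentences: list[list[str]] = []  # sentences bearing a reference
        for f in range(1, n_figs + 1):
            n_refs = max(1, int(rng.poisson(config.figure_reference_density)))
            for _ in range(n_refs):
                panel = _PANELS[int(rng.integers(len(_PANELS)))]
                pi = int(rng.integers(n_paras))
                si = int(rng.integers(len(paragraphs[pi])))
                sent = paragraphs[pi][si]
                pos = int(rng.integers(0, len(sent) + 1))
                sent[pos:pos] = ["(", "Fig.", f"{f}{panel}", ")"]
                ref_sentences.append(sent)

        if positive and config.signal_probability > 0:
            targets: list[list[list[str]]] = []  # passages as sentence lists
            if "title" in config.signal_location:
                targets.append([title])
            if "abstract" in config.signal_location:
                targets.append(abstract)
            if "mesh" in config.signal_location:
                targets.append([mesh])
            if "paragraph" in config.signal_location:
                targets.extend(paragraphs)
            if "caption" in config.signal_location:
                targets.extend(captions.values())
            if "evidence_fragment" in config.signal_location:
                targets.extend([s] for s in ref_sentences)
            if config.signal_placement == "one" and targets:
                targets = [targets[int(rng.integers(len(targets)))]]
            for passage in targets:
                for sent in passage:
                    if rng.random() < config.signal_probability:
                        _insert_signal(rng, sent, config.signal_tokens)

        def render(sents: list[list[str]]) -> str:
            return " ".join(" ".join(s) + " ." for s in sents)

        docs.append(Document(
            doc_id=f"doc{d:05d}",
            title=" ".join(title),
            abstract=render(abstract),
            mesh_terms=mesh,
            paragraphs=[ParagraphBlock("Results", render(p))
                        for p in paragraphs],
            captions={f: render(c) for f, c in captions.items()},
        ))
    return docs, labels


# --------------------------------------------------------------------------
# method-classification corpora

def make_grouping_scheme(name: str, n_groups: int, n_fine: int) -> LabelScheme:
    """A fine→grouped scheme with n_fine codes spread over n_groups."""
    if n_fine < n_groups:
        raise ValueError("need at least one fine code per group")
    mapping = {}
    for j in range(n_fine):
        g = j % n_groups
        mapping[f"{name}:fine{j:02d}"] = f"{name}:grp{g:02d}"
    return LabelScheme(name, mapping)


#: grouped-code cardinalities mirroring the curated-method task:
#: 44 participant-detection codes grouped to 8, 84 interaction-detection
#: codes grouped to 17, plus a binary western-blot head.
METHOD_PRESETS = {
    "participant_detection": (8, 44),
    "interaction_detection": (17, 84),
    "western_blot_yes_no": (2, 2),
}


@dataclass
class MethodSynthConfig:
    """Knobs for the passage-classification corpus generator.

    ``signal_probability`` is the chance a class-c passage contains at
    least one token from class c's signal set.
    """
    preset: str | None = "participant_detection"
    n_classes: int | None = None
    n_passages: int = 800
    signal_probability: float = 1.0
    signal_tokens_per_class: int = 3
    tokens_per_passage: tuple[int, int] = (20, 40)
    vocab_size: int = 400
    zipf_exponent: float = 1.05
    seed: int = 0

    def __post_init__(self):
        if self.preset is not None and self.preset not in METHOD_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"choose from {sorted(METHOD_PRESETS)}")
        if self.k < 2:
            raise ValueError("need k >= 2 classes")
        if not 0 <= self.signal_probability <= 1:
            raise ValueError("signal_probability must be in [0, 1]")
        if self.n_passages < 0:
            raise ValueError("n_passages must be >= 0")

    @property
    def k(self) -> int:
        if self.preset is not None:
            return METHOD_PRESETS[self.preset][0]
        return self.n_classes or 0

    @property
    def n_fine(self) -> int:
        if self.preset is not None:
            return METHOD_PRESETS[self.preset][1]
        return self.k

    def signal_sets(self) -> list[list[str]]:
        sets = [[f"m{c:02d}sig{j}" for j in range(self.signal_tokens_per_class)]
                for c in range(self.k)]
        flat = [t for s in sets for t in s]
        if len(flat) != len(set(flat)):
            raise ValueError("signal sets must be pairwise disjoint")
        return sets


def method_vocabulary(config: MethodSynthConfig) -> list[str]:
    vocab = _background_vocab(config.vocab_size)
    vocab += [t for s in config.signal_sets() for t in s]
    return vocab


def generate_method_corpus(config: MethodSynthConfig
                           ) -> tuple[list[LabeledPassage], LabelScheme]:
    """Generate labeled passages over k grouped classes (balanced)."""
    rng = np.random.default_rng(config.seed)
    scheme = make_grouping_scheme(config.preset or f"k{config.k}",
                                  config.k, config.n_fine)
    groups = scheme.grouped_labels
    fine_by_group = {g: [f for f, gg in scheme.mapping.items() if gg == g]
                     for g in groups}
    bg = _background_vocab(config.vocab_size)
    probs = _zipf_probs(config.vocab_size, config.zipf_exponent)
    sets = config.signal_sets()

    out: list[LabeledPassage] = []
    for i in range(config.n_passages):
        c = i % config.k  # balanced classes
        n = _rand_range(rng, config.tokens_per_passage)
        tokens = [bg[j] for j in rng.choice(len(bg), size=n, p=probs)]
        if rng.random() < config.signal_probability:
            for _ in range(int(rng.integers(1, 3))):
                _insert_signal(rng, tokens, sets[c])
        fine = fine_by_group[groups[c]][int(rng.integers(
            len(fine_by_group[groups[c]])))]
        passage = Passage(" ".join(tokens), PassageKind.EVIDENCE_FRAGMENT,
                          origin=(f"synthpsg{i:05d}", 0),
                          figure_ref=(1, ()))
        out.append(LabeledPassage(passage, fine, groups[c]))
    return out, scheme


# --------------------------------------------------------------------------
# toy word vectors

def generate_toy_embeddings(vocab: Sequence[str], dim: int, seed: int,
                            path: Union[str, Path]) -> Path:
    """Write unit-norm random word vectors in headerless text format."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    lines = []
    for token in vocab:
        v = rng.standard_normal(dim)
        v /= np.linalg.norm(v)
        lines.append(token + " " + " ".join(f"{x:.8f}" for x in v))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def toy_embedding_table(vocab: Sequence[str], dim: int, seed: int,
                        oov_policy: str = "zero") -> EmbeddingTable:
    """In-memory equivalent of generate_toy_embeddings + load_word_vectors."""
    import io
    buf = io.StringIO()
    rng = np.random.default_rng(seed)
    for token in vocab:
        v = rng.standard_normal(dim)
        v /= np.linalg.norm(v)
        buf.write(token + " " + " ".join(f"{x:.8f}" for x in v) + "\n")
    buf.seek(0)
    return load_word_vectors(buf, format="wordvec_text_headerless",
                             oov_policy=oov_policy)
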