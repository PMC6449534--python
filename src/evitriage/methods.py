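"""Passage-level classification of experimental-method codes.

The task: given one passage of evidence text (a figure caption or an
evidence fragment), predict which experimental method it describes. Labels
are PSI-MI-style fine codes grouped into coarser classes by a
:class:`LabelScheme` (e.g. 44 participant-detection codes grouped to 8, 84
interaction-detection codes grouped to 17), or a binary yes/no head for one
common method such as western blotting.

Two deliberately plain architectures are provided, mirroring textbook
examples: a multi-width 1-D CNN with global max pooling, and an LSTM over
the token sequence. Both sit on a (by default frozen) pre-trained embedding
layer, with dropout and L2 regularization as the main capacity controls.
Because random initialization matters at these data sizes, evaluation runs
the classifier several times with different seeds and reports mean ± sample
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .corpus import Passage, tokenize
from .embeddings import EmbeddingTable
from .nn import autograd as ag
from .nn import layers as L
from .utils import stratified_split

__all__ = [
    "LabelScheme", "LabeledPassage", "PassageClassifierConfig",
    "PassageModel", "group_label", "build_passage_model",
    "train_passage_classifier", "predict_passage", "evaluate_multirestart",
    "MultiRestartReport",
]


@dataclass
class LabelScheme:
    """Total mapping from fine method codes to grouped codes."""
    name: str
    mapping: dict[str, str]

    @property
    def grouped_labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @property
    def fine_codes(self) -> list[str]:
        return sorted(self.mapping)

    def group(self, fine: str) -> str:
        try:
            return self.mapping[fine]
        except KeyError:
            raise KeyError(
                f"fine code {fine!r} not in label scheme {self.name!r}") from None

    @classmethod
    def from_tsv(cls, path: Union[str, Path], name: str | None = None
                 ) -> "LabelScheme":
        """Two-column TSV: fine_code<TAB>grouped_code."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["fine", "grouped"], dtype=str)
        return cls(name or Path(path).stem,
                   dict(zip(df["fine"], df["grouped"])))

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(sorted(self.mapping.items())).to_csv(
            path, sep="\t", header=False, index=False)


def group_label(scheme: LabelScheme, fine: str) -> str:
    """Apply a scheme's fine-to-grouped mapping (error on unknown codes)."""
    return scheme.group(fine)


@dataclass
class LabeledPassage:
    passage: Passage
    fine_code: str
    grouped_code: str

    @classmethod
    def from_fine(cls, passage: Passage, fine: str, scheme: LabelScheme
                  ) -> "LabeledPassage":
        return cls(passage, fine, scheme.group(fine))


@dataclass
class PassageClassifierConfig:
    """Hyperparameters for one passage-classification run.

    Dropout is constrained to [0.25, 0.5] — the band that worked for these
    small evidence-text datasets — unless explicitly overridden; L2 defaults
    to 1e-4 and embeddings are frozen by default for the same reason:
    trainable embeddings let the model memorize the training passages.
    """
    arch: str = "cnn"                      # "cnn" | "lstm"
    max_len: int = 300
    conv_filter_widths: tuple[int, ...] = (3, 4, 5)
    conv_filters: int = 64
    lstm_units: int = 128
    dense_width: int = 64
    dropout: float = 0.3
    l2: float = 1e-4
    trainable_embeddings: bool = False
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_patience: int = 3
    class_weighting: bool = False
    seed: int = 0
    allow_dropout_out_of_range: bool = False

    def __post_init__(self):
        if self.arch not in ("cnn", "lstm"):
            raise ValueError(f"unknown arch {self.arch!r}")
        for name in ("max_len", "conv_filters", "lstm_units", "dense_width",
                     "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not (0.25 <= self.dropout <= 0.5) and not self.allow_dropout_out_of_range:
            raise ValueError(
                f"dropout {self.dropout} outside [0.25, 0.5]; set "
                "allow_dropout_out_of_range=True to override")


class PassageModel:
    """A CNN or LSTM passage classifier over an embedding table."""

    def __init__(self, config: PassageClassifierConfig, table: EmbeddingTable,
                 classes: Sequence[str]):
        if len(classes) < 2:
            raise ValueError("at least 2 classes required")
        self.config = config
        self.table = table
        self.classes = list(classes)
        rng = np.random.default_rng(config.seed)
        self.embedding = L.make_param(table.matrix.copy(), is_weight=False)
        self.embedding.requires_grad = config.trainable_embeddings
        d = table.dim
        if config.arch == "cnn":
            self.encoder = L.ConvMaxPool(d, config.conv_filters,
                                         config.conv_filter_widths, rng)
            enc_dim = self.encoder.out_dim
        else:
            self.encoder = L.LSTM(d, config.lstm_units, rng)
            enc_dim = config.lstm_units
        self.hidden = L.Dense(enc_dim, config.dense_width, rng,
                              activation="relu")
        self.out = L.Dense(config.dense_width, len(self.classes), rng)

    def params(self) -> list[ag.Tensor]:
        ps = self.encoder.params() + self.hidden.params() + self.out.params()
        if self.config.trainable_embeddings:
            ps = [self.embedding] + ps
        return ps

    def forward(self, ids: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> ag.Tensor:
        """Logits for a batch of (B, max_len) token-id sequences."""
        x = ag.embedding_lookup(self.embedding, ids)
        if self.config.arch == "lstm":
            lengths = (x.data != 0).any(axis=-1).sum(axis=1)
            h = self.encoder(x, lengths)
        else:
            h = self.encoder(x)
        if train and self.config.dropout > 0:
            assert rng is not None
            h = ag.mul(h, ag.Tensor(
                ag.dropout_mask(h.shape, self.config.dropout, rng)))
        return self.out(self.hidden(h))

    def predict_proba(self, ids: np.ndarray) -> np.ndarray:
        logits = self.forward(np.atleast_2d(ids)).data
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def encode_batch(self, passages: Sequence[LabeledPassage | Passage | list]
                     ) -> np.ndarray:
        """Token-id matrix (N, max_len) for a list of passages."""
        rows = []
        for p in passages:
            if isinstance(p, LabeledPassage):
                tokens = p.passage.tokens
            elif isinstance(p, Passage):
                tokens = p.tokens
            elif isinstance(p, str):
                tokens = tokenize(p)
            else:
                tokens = list(p)
            rows.append(self.table.token_ids(tokens, self.config.max_len))
        return np.asarray(rows) if rows else np.zeros((0, self.config.max_len),
                                                      dtype=np.int64)


def build_passage_model(config: PassageClassifierConfig,
                        table: EmbeddingTable,
                        classes: Sequence[str]) -> PassageModel:
    """Construct a seeded, initialized passage classifier."""
    return PassageModel(config, table, classes)


def train_passage_classifier(model: PassageModel,
                             train: Sequence[LabeledPassage],
                             val_fraction: float = 0.15,
                             config: PassageClassifierConfig | None = None
                             ) -> tuple[PassageModel, dict]:
    """Mini-batch Adam training with early stopping on validation loss.

    Returns the (mutated) model and a history dict of per-epoch metrics.
    With epochs=0 the model is returned untouched.
    """
    cfg = config or model.config
    y = np.array([model.classes.index(p.grouped_code) for p in train])
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = model.encode_batch(train)
    rng = np.random.default_rng(cfg.seed + 1)

    if val_fraction > 0:
        tr_idx, va_idx = stratified_split(y, (1 - val_fraction, val_fraction),
                                          seed=cfg.seed + 2)[:2]
    else:
        tr_idx, va_idx = np.arange(len(y)), np.array([], dtype=int)

    weights = None
    if cfg.class_weighting:
        counts = np.bincount(y[tr_idx], minlength=len(model.classes))
        inv = len(tr_idx) / np.maximum(counts, 1) / len(model.classes)
        weights = inv[y]

    opt = L.Adam(model.params(), lr=cfg.learning_rate, l2=cfg.l2)
    history: dict[str, list] = {k: [] for k in
                                ("train_loss", "train_acc", "val_loss", "val_acc")}
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    patience_left = cfg.early_stopping_patience
    for _epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward(X[idx], train=True, rng=rng)
            sw = weights[idx] if weights is not None else None
            loss, _ = ag.softmax_cross_entropy(logits, y[idx], sample_weight=sw)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        tr_probs = model.predict_proba(X[tr_idx])
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(
            float((tr_probs.argmax(1) == y[tr_idx]).mean()))
        if len(va_idx):
            va_logits = model.forward(X[va_idx])
            va_loss, va_probs = ag.softmax_cross_entropy(va_logits, y[va_idx])
            history["val_loss"].append(float(va_loss.data))
            history["val_acc"].append(
                float((va_probs.argmax(1) == y[va_idx]).mean()))
            if float(va_loss.data) < best_val - 1e-9:
                best_val = float(va_loss.data)
                best_params = [p.data.copy() for p in model.params()]
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_params is not None:  # restore the best-validation weights
        for p, data in zip(model.params(), best_params):
            p.data = data
    return model, history


def predict_passage(model: PassageModel,
                    passage: Passage | Sequence[str] | str) -> np.ndarray:
    """Probability vector over grouped labels (sums to 1; argmax ties break
    to the lowest class index by numpy convention)."""
    ids = model.encode_batch([passage])
    return model.predict_proba(ids)[0]


@dataclass
class MultiRestartReport:
    """Held-out accuracies over randomized restarts of one configuration."""
    accuracies: list[float]
    seeds: list[int]
    classes: list[str]
    confusion: np.ndarray  # last restart, rows = true classes
    config: PassageClassifierConfig | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))


def evaluate_multirestart(dataset: Sequence[LabeledPassage],
                          config: PassageClassifierConfig,
                          n_restarts: int,
                          table: EmbeddingTable,
                          test_fraction: float = 0.15,
                          val_fraction: float = 0.15) -> MultiRestartReport:
    """Train/evaluate ``n_restarts`` times; restarts differ only in seed.

    The stratified train/test split is fixed by ``config.seed`` so restart
    variability reflects initialization and batching alone.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    classes = sorted({p.grouped_code for p in dataset})
    y = np.array([classes.index(p.grouped_code) for p in dataset])
    tr_idx, te_idx = stratified_split(
        y, (1 - test_fraction, test_fraction), seed=config.seed)[:2]
    train_set = [dataset[i] for i in tr_idx]

    accs, seeds = [], []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for r in range(n_restarts):
        seed_r = config.seed + r
        cfg = replace(config, seed=seed_r)
        model = build_passage_model(cfg, table, classes)
        rel_val = val_fraction / (1 - test_fraction)
        train_passage_classifier(model, train_set, val_fraction=rel_val)
        probs = model.predict_proba(model.encode_batch(
            [dataset[i] for i in te_idx]))
        pred = probs.argmax(1)
        accs.append(float((pred == y[te_idx]).mean()))
        seeds.append(seed_r)
        confusion = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y[te_idx], pred):
            confusion[t, p] += 1
    return MultiRestartReport(accs, seeds, classes, confusion, config)
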