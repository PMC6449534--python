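"""Document-level triage: encode selected passages, aggregate with attention.

Whole full-text articles are too long (and too memory-hungry) to classify
naively, so the document is broken into passages drawn from one of eight
text sources — title, abstract, title+abstract, MeSH terms, all body
paragraphs, figure captions, evidence fragments, or captions and fragments
together. Each passage is encoded by a CNN → bidirectional-LSTM encoder
(single-passage sources like title/MeSH use a simple CNN), the per-passage
vectors are aggregated into one document vector by additive attention
(score_i = vᵀ tanh(W h_i + b), softmax-normalized), and a fully connected
layer converts that vector into a relevance probability. The attention
weights are returned for inspection: they say which passages drove the
decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .corpus import Document, Passage, PassageKind
from .embeddings import EmbeddingTable
from .evidence import extract_evidence_fragments
from .nn import autograd as ag
from .nn import layers as L
from .utils import stratified_split

logger = logging.getLogger(__name__)

__all__ = [
    "TextSource", "TriageConfig", "AttentionParams", "AttentionOutput",
    "TriageModel", "select_passages", "encode_passage", "attend",
    "classify_document", "train_triage", "evaluate_triage_multirestart",
    "TriageReport", "default_encoder_for",
]


class TextSource(str, Enum):
    TITLE = "title"
    ABSTRACT = "abstract"
    TITLE_ABSTRACT = "title_abstract"
    MESH = "mesh"
    ALL_PARAGRAPHS = "all_paragraphs"
    CAPTIONS = "captions"
    EVIDENCE_FRAGMENTS = "evidence_fragments"
    CAPTIONS_PLUS_FRAGMENTS = "captions_plus_fragments"


#: single-passage metadata sources get the simple CNN baseline; everything
#: else uses the CNN-BiLSTM passage encoder.
def default_encoder_for(source: TextSource) -> str:
    if source in (TextSource.TITLE, TextSource.MESH):
        return "cnn"
    return "cnn_bilstm"


@dataclass
class TriageConfig:
    text_source: TextSource = TextSource.CAPTIONS
    encoder: str | None = None           # None -> default_encoder_for(source)
    conv_filters: int = 32
    conv_width: int = 3
    lstm_units: int = 16
    attention_width: int = 16
    aggregation: str = "attention"       # "attention" | "mean" (ablation)
    dropout: float = 0.3
    l2: float = 1e-4
    max_passages: int = 64
    max_len: int = 300
    epochs: int = 8
    batch_size: int = 16
    learning_rate: float = 1e-3
    early_stopping_patience: int = 3
    decision_threshold: float = 0.5
    mesh_as_phrases: bool = False
    seed: int = 0
    allow_dropout_out_of_range: bool = False

    def __post_init__(self):
        self.text_source = TextSource(self.text_source)
        enc = self.encoder or default_encoder_for(self.text_source)
        if enc not in ("cnn", "cnn_bilstm"):
            raise ValueError(f"unknown encoder {enc!r}")
        if self.aggregation not in ("attention", "mean"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        for name in ("conv_filters", "conv_width", "lstm_units",
                     "attention_width", "max_passages", "max_len",
                     "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.25 <= self.dropout <= 0.5) and not self.allow_dropout_out_of_range:
            raise ValueError(
                f"dropout {self.dropout} outside [0.25, 0.5]; set "
                "allow_dropout_out_of_range=True to override")

    @property
    def effective_encoder(self) -> str:
        return self.encoder or default_encoder_for(self.text_source)


def select_passages(doc: Document, source: TextSource | str,
                    fragments=None, max_passages: int = 64,
                    mesh_as_phrases: bool = False) -> list[Passage]:
    """Ordered passages of one document for a given text source.

    For fragment-based sources pass the output of
    :func:`~evitriage.evidence.extract_evidence_fragments` (it is computed
    on the fly if omitted). The combined source lists captions first, then
    fragments, each internally in document order. An empty selection yields
    a single empty passage (degenerate contract) with a warning.
    """
    source = TextSource(source)
    did = doc.doc_id
    passages: list[Passage] = []

    def caption_passages():
        return [Passage(doc.captions[k], PassageKind.CAPTION, (did, i),
                        figure_ref=(k, ()))
                for i, k in enumerate(sorted(doc.captions))]

    def fragment_passages(offset=0):
        frs = fragments
        if frs is None:
            frs = extract_evidence_fragments(doc)
        return [f.to_passage(position=offset + i) for i, f in enumerate(frs)]

    if source == TextSource.TITLE:
        passages = [Passage(doc.title, PassageKind.TITLE, (did, 0))]
    elif source == TextSource.ABSTRACT:
        passages = [Passage(doc.abstract, PassageKind.ABSTRACT, (did, 0))]
    elif source == TextSource.TITLE_ABSTRACT:
        text = (doc.title + " . " + doc.abstract).strip(" .")
        passages = [Passage(text, PassageKind.ABSTRACT, (did, 0))]
    elif source == TextSource.MESH:
        terms = ([t.replace(" ", "_") for t in doc.mesh_terms]
                 if mesh_as_phrases else doc.mesh_terms)
        passages = [Passage(" ".join(terms), PassageKind.MESH, (did, 0))]
    elif source == TextSource.ALL_PARAGRAPHS:
        passages = [Passage(b.text, PassageKind.PARAGRAPH, (did, i))
                    for i, b in enumerate(doc.paragraphs)]
    elif source == TextSource.CAPTIONS:
        passages = caption_passages()
    elif source == TextSource.EVIDENCE_FRAGMENTS:
        passages = fragment_passages()
    elif source == TextSource.CAPTIONS_PLUS_FRAGMENTS:
        caps = caption_passages()
        passages = caps + fragment_passages(offset=len(caps))

    passages = [p for p in passages if p.text.strip()]
    if not passages:
        logger.warning("document %s: empty selection for source %s; "
                       "using a single empty passage", did, source.value)
        kind = (PassageKind.CAPTION if source in
                (TextSource.CAPTIONS, TextSource.CAPTIONS_PLUS_FRAGMENTS)
                else PassageKind.PARAGRAPH)
        # figure id 1 is a sentinel for the degenerate empty caption passage
        fr = (1, ()) if kind == PassageKind.CAPTION else None
        passages = [Passage("", kind, (did, 0), figure_ref=fr)]
    if len(passages) > max_passages:
        logger.info("document %s: %d passages truncated to %d",
                    did, len(passages), max_passages)
        passages = passages[:max_passages]
    return passages


@dataclass
class AttentionParams:
    """Parameters of the additive attention scorer."""
    W: np.ndarray  # (E, A)
    b: np.ndarray  # (A,)
    v: np.ndarray  # (A,)


@dataclass
class AttentionOutput:
    weights: np.ndarray     # one nonnegative weight per passage; sums to 1
    doc_vector: np.ndarray  # weighted sum of passage vectors


def attend(passage_vectors: np.ndarray, params: AttentionParams
           ) -> AttentionOutput:
    """Additive attention over a (P, E) stack of passage vectors.

    weights = softmax(vᵀ tanh(W h_i + b)); doc_vector = Σ weight_i · h_i.
    Position-free: permuting the rows permutes the weights identically.
    """
    H = np.asarray(passage_vectors, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("need a (P, E) array with P >= 1")
    scores = np.tanh(H @ params.W + params.b) @ params.v
    scores = scores - scores.max()
    e = np.exp(scores)
    weights = e / e.sum()
    return AttentionOutput(weights=weights, doc_vector=weights @ H)


class TriageModel:
    """CNN(-BiLSTM) passage encoder + attention aggregation + decision layer."""

    def __init__(self, config: TriageConfig, table: EmbeddingTable):
        self.config = config
        self.table = table
        rng = np.random.default_rng(config.seed)
        d = table.dim
        if config.effective_encoder == "cnn_bilstm":
            self.conv = L.Conv1D(d, config.conv_filters, config.conv_width, rng)
            self.bilstm = L.BiLSTM(config.conv_filters, config.lstm_units, rng)
            self.enc_dim = self.bilstm.out_dim
        else:
            self.conv = L.ConvMaxPool(d, config.conv_filters,
                                      (config.conv_width,), rng)
            self.bilstm = None
            self.enc_dim = self.conv.out_dim
        if config.aggregation == "attention":
            self.pool = L.AttentionPool(self.enc_dim, config.attention_width, rng)
        else:
            self.pool = L.MeanPool()
        self.out = L.Dense(self.enc_dim, 2, rng)

    def params(self) -> list[ag.Tensor]:
        ps = self.conv.params()
        if self.bilstm is not None:
            ps += self.bilstm.params()
        return ps + self.pool.params() + self.out.params()

    def attention_params(self) -> AttentionParams:
        if not isinstance(self.pool, L.AttentionPool):
            raise ValueError("model aggregates by mean, not attention")
        return AttentionParams(self.pool.W.data.copy(),
                               self.pool.b.data.copy(),
                               self.pool.v.data.copy().ravel())

    # -- passage preparation ------------------------------------------------

    def doc_token_ids(self, doc: Document, fragments=None) -> np.ndarray:
        cfg = self.config
        passages = select_passages(doc, cfg.text_source, fragments=fragments,
                                   max_passages=cfg.max_passages,
                                   mesh_as_phrases=cfg.mesh_as_phrases)
        return np.stack([self.table.token_ids(p.tokens, cfg.max_len)
                         for p in passages])

    # -- forward passes -----------------------------------------------------

    def _encode(self, x: ag.Tensor) -> ag.Tensor:
        """(N, T, d) embedded passages -> (N, enc_dim) vectors.

        Sequence lengths are inferred from nonzero embedding rows so the
        recurrent readout sits at each passage's last real token.
        """
        if self.bilstm is not None:
            lengths = (x.data != 0).any(axis=-1).sum(axis=1)
            lengths = np.maximum(lengths - self.config.conv_width + 1, 1)
            return self.bilstm(self.conv(x), lengths)
        return self.conv(x)

    def forward_batch(self, doc_ids: Sequence[np.ndarray], train: bool = False,
                      rng: np.random.Generator | None = None):
        """Batch of documents (each a (P_i, T) id array) -> (logits, weights,
        passage mask)."""
        B = len(doc_ids)
        P = max(ids.shape[0] for ids in doc_ids)
        T = self.config.max_len
        ids = np.zeros((B, P, T), dtype=np.int64)
        mask = np.zeros((B, P))
        for i, arr in enumerate(doc_ids):
            ids[i, :arr.shape[0]] = arr
            mask[i, :arr.shape[0]] = 1.0
        emb = self.table.matrix[ids]
        x = ag.Tensor(emb.reshape(B * P, T, self.table.dim))
        H = ag.reshape(self._encode(x), (B, P, self.enc_dim))
        weights, pooled = self.pool(H, mask)
        if train and self.config.dropout > 0:
            assert rng is not None
            pooled = ag.mul(pooled, ag.Tensor(
                ag.dropout_mask(pooled.shape, self.config.dropout, rng)))
        return self.out(pooled), weights, mask

    def predict_proba(self, doc_ids: Sequence[np.ndarray]) -> np.ndarray:
        """P(relevant) for each document in the batch."""
        logits, _, _ = self.forward_batch(doc_ids)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return (e / e.sum(axis=-1, keepdims=True))[:, 1]


def encode_passage(model: TriageModel, embedded: np.ndarray) -> np.ndarray:
    """Encode one (max_len, d) passage-embedding matrix to its vector."""
    embedded = np.asarray(embedded, dtype=np.float64)
    if embedded.shape != (model.config.max_len, model.table.dim):
        raise ValueError(
            f"expected shape ({model.config.max_len}, {model.table.dim}), "
            f"got {embedded.shape}")
    return model._encode(ag.Tensor(embedded[None])).data[0]


def classify_document(model: TriageModel, doc: Document, fragments=None
                      ) -> tuple[float, AttentionOutput]:
    """Relevance probability plus the attention view of one document."""
    ids = model.doc_token_ids(doc, fragments=fragments)
    logits, weights, _ = model.forward_batch([ids])
    z = logits.data[0] - logits.data[0].max()
    e = np.exp(z)
    prob = float(e[1] / e.sum())
    w = weights.data[0]
    emb = model.table.matrix[ids]
    H = model._encode(ag.Tensor(emb)).data
    return prob, AttentionOutput(weights=w, doc_vector=w @ H)


def train_triage(model: TriageModel, docs: Sequence[Document],
                 labels: Sequence[int], val_fraction: float = 0.15,
                 config: TriageConfig | None = None,
                 fragments_by_doc: dict | None = None
                 ) -> tuple[TriageModel, dict]:
    """Train the triage network; returns (model, per-epoch metrics)."""
    cfg = config or model.config
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    doc_ids = [model.doc_token_ids(
        d, fragments=(fragments_by_doc or {}).get(d.doc_id)) for d in docs]
    rng = np.random.default_rng(cfg.seed + 1)
    if val_fraction > 0:
        tr_idx, va_idx = stratified_split(y, (1 - val_fraction, val_fraction),
                                          seed=cfg.seed + 2)[:2]
    else:
        tr_idx, va_idx = np.arange(len(y)), np.array([], dtype=int)

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
            logits, _, _ = model.forward_batch([doc_ids[i] for i in idx],
                                               train=True, rng=rng)
            loss, _ = ag.softmax_cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        tr_p = model.predict_proba([doc_ids[i] for i in tr_idx])
        history["train_acc"].append(float(
            ((tr_p >= cfg.decision_threshold).astype(int) == y[tr_idx]).mean()))
        if len(va_idx):
            va_logits, _, _ = model.forward_batch([doc_ids[i] for i in va_idx])
            va_loss, va_probs = ag.softmax_cross_entropy(va_logits, y[va_idx])
            history["val_loss"].append(float(va_loss.data))
            history["val_acc"].append(float(
                (va_probs.argmax(1) == y[va_idx]).mean()))
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


@dataclass
class TriageReport:
    """Table-style triage result: accuracy mean ± std over restarts."""
    text_source: str
    model_configuration: str
    accuracies: list[float]
    seeds: list[int]
    confusion: np.ndarray
    config: TriageConfig | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))


def evaluate_triage_multirestart(docs: Sequence[Document],
                                 labels: Sequence[int],
                                 config: TriageConfig,
                                 n_restarts: int,
                                 table: EmbeddingTable,
                                 test_fraction: float = 0.15,
                                 val_fraction: float = 0.15,
                                 return_models: bool = False):
    """Stratified 70/15/15 split (by config.seed), then ``n_restarts``
    trainings differing only in seed; reports held-out accuracy mean ± std.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    y = np.asarray(labels, dtype=int)
    tr_idx, te_idx = stratified_split(
        y, (1 - test_fraction, test_fraction), seed=config.seed)[:2]
    train_docs = [docs[i] for i in tr_idx]
    test_docs = [docs[i] for i in te_idx]

    accs, seeds, models = [], [], []
    confusion = np.zeros((2, 2), dtype=int)
    for r in range(n_restarts):
        seed_r = config.seed + r
        cfg = replace(config, seed=seed_r)
        model = TriageModel(cfg, table)
        rel_val = val_fraction / (1 - test_fraction)
        train_triage(model, train_docs, y[tr_idx], val_fraction=rel_val)
        test_ids = [model.doc_token_ids(d) for d in test_docs]
        probs = model.predict_proba(test_ids)
        pred = (probs >= cfg.decision_threshold).astype(int)
        accs.append(float((pred == y[te_idx]).mean()))
        seeds.append(seed_r)
        confusion = np.zeros((2, 2), dtype=int)
        for t, p in zip(y[te_idx], pred):
            confusion[t, p] += 1
        if return_models:
            models.append(model)
    name = ("SimpleCNN" if config.effective_encoder == "cnn" else "CNNBiLSTM")
    if config.aggregation == "attention" and config.text_source in (
            TextSource.ALL_PARAGRAPHS, TextSource.CAPTIONS,
            TextSource.EVIDENCE_FRAGMENTS, TextSource.CAPTIONS_PLUS_FRAGMENTS):
        name += " + attention"
    report = TriageReport(config.text_source.value, name, accs, seeds,
                          confusion, config)
    if return_models:
        return report, models, (tr_idx, te_idx)
    return report
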