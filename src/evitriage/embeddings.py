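"""Pre-trained word-vector tables with explicit OOV and padding contracts.

Tables are read from the standard whitespace-delimited word-vector text
format ("token v1 … vd" per line), with or without a leading "count dim"
header, gzip-transparent. Row 0 is always a reserved all-zeros padding
vector. Lookup lowercases tokens (documents keep their original case);
out-of-vocabulary tokens are resolved by a declared policy:

``zero``
    the padding vector (the default: with a frozen embedding layer an OOV
    gradient would be discarded anyway);
``mean``
    the arithmetic mean of all non-pad rows;
``hash_bucket``
    one of a small set of random but deterministic bucket vectors chosen by
    a stable hash of the token, so distinct OOV tokens stay distinguishable.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingTable", "load_word_vectors", "embed_passage",
           "DEFAULT_MAX_LEN"]

#: passage-level texts of 300 words or less are the sweet spot for these
#: classifiers, so sequences are truncated there by default.
DEFAULT_MAX_LEN = 300

PAD_TOKEN = "<pad>"
N_HASH_BUCKETS = 16
_HASH_SEED = 0x5EED


class FormatError(ValueError):
    """Malformed word-vector file (cites the offending line number)."""


@dataclass
class EmbeddingTable:
    """vocabulary -> dense vector map with pad reserved at row 0."""
    vocab: dict[str, int]          # token -> row index (>= 1)
    matrix: np.ndarray             # (|V|, d) incl. pad/mean/bucket rows
    dim: int
    oov_policy: str = "zero"
    _mean_row: int = field(default=-1, repr=False)
    _bucket_rows: tuple[int, ...] = field(default=(), repr=False)

    def __post_init__(self):
        if self.oov_policy not in ("zero", "mean", "hash_bucket"):
            raise ValueError(f"unknown oov_policy {self.oov_policy!r}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def n_tokens(self) -> int:
        """Vocabulary size including the pad token."""
        return len(self.vocab) + 1

    @property
    def pad_vector(self) -> np.ndarray:
        return self.matrix[0]

    def token_id(self, token: str) -> int:
        """Row index for one (lowercased) token under the OOV policy."""
        idx = self.vocab.get(token.lower())
        if idx is not None:
            return idx
        if self.oov_policy == "zero":
            return 0
        if self.oov_policy == "mean":
            return self._mean_row
        h = int.from_bytes(
            hashlib.blake2b(token.lower().encode("utf-8"), digest_size=8,
                            salt=_HASH_SEED.to_bytes(8, "little")).digest(),
            "little")
        return self._bucket_rows[h % len(self._bucket_rows)]

    def token_ids(self, tokens: Sequence[str], max_len: int) -> np.ndarray:
        """Head-keep truncation to max_len, tail-padded with the pad id 0."""
        if max_len < 1:
            raise ValueError("max_len must be >= 1")
        ids = np.zeros(max_len, dtype=np.int64)
        for i, tok in enumerate(tokens[:max_len]):
            ids[i] = self.token_id(tok)
        return ids


def _build_table(rows: list[tuple[str, np.ndarray]], dim: int,
                 oov_policy: str) -> EmbeddingTable:
    vocab: dict[str, int] = {}
    vecs: list[np.ndarray] = [np.zeros(dim)]
    for token, vec in rows:
        if token in vocab:
            warnings.warn(f"duplicate token {token!r}: keeping first occurrence")
            continue
        vocab[token] = len(vecs)
        vecs.append(vec)
    mean_row = -1
    bucket_rows: tuple[int, ...] = ()
    if oov_policy == "mean":
        mean_row = len(vecs)
        non_pad = np.asarray(vecs[1:]) if len(vecs) > 1 else np.zeros((1, dim))
        vecs.append(non_pad.mean(axis=0))
    elif oov_policy == "hash_bucket":
        rng = np.random.default_rng(_HASH_SEED)
        start = len(vecs)
        for _ in range(N_HASH_BUCKETS):
            vecs.append(rng.standard_normal(dim) / np.sqrt(dim))
        bucket_rows = tuple(range(start, start + N_HASH_BUCKETS))
    return EmbeddingTable(vocab=vocab, matrix=np.asarray(vecs, dtype=np.float64),
                          dim=dim, oov_policy=oov_policy,
                          _mean_row=mean_row, _bucket_rows=bucket_rows)


def load_word_vectors(path: Union[str, Path, io.TextIOBase],
                      format: str = "auto",
                      oov_policy: str = "zero") -> EmbeddingTable:
    """Read a word-vector text file into an :class:`EmbeddingTable`.

    ``format`` is one of ``wordvec_text_with_header``,
    ``wordvec_text_headerless`` or ``auto`` (sniff: a first line of exactly
    two integers is a header). ``.gz`` paths are decompressed transparently.
    Duplicate tokens keep their first occurrence (with a warning);
    inconsistent dimensionality raises :class:`FormatError` citing the line.
    """
    if isinstance(path, (str, Path)):
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt", encoding="utf-8") as fh:
            return load_word_vectors(fh, format=format, oov_policy=oov_policy)

    lines = [ln.rstrip("\n") for ln in path]
    lines = [ln for ln in lines if ln.strip()]
    start = 0
    declared: tuple[int, int] | None = None
    if lines:
        head = lines[0].split()
        is_header = len(head) == 2 and all(p.lstrip("-").isdigit() for p in head)
        if format == "wordvec_text_with_header" or (format == "auto" and is_header):
            if not is_header:
                raise FormatError("line 1: expected 'count dim' header")
            declared = (int(head[0]), int(head[1]))
            start = 1

    rows: list[tuple[str, np.ndarray]] = []
    dim: int | None = declared[1] if declared else None
    for lineno, line in enumerate(lines[start:], start + 1):
        parts = line.split()
        token, values = parts[0], parts[1:]
        if dim is None:
            dim = len(values)
            if dim == 0:
                raise FormatError(f"line {lineno}: no vector values")
        elif len(values) != dim:
            raise FormatError(
                f"line {lineno}: expected {dim} values, found {len(values)}")
        try:
            vec = np.array([float(v) for v in values])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric value ({exc})") from exc
        rows.append((token, vec))
    if dim is None:
        raise FormatError("empty word-vector file")
    if declared and declared[0] != len(rows):
        logger.warning("header declares %d rows, found %d", declared[0], len(rows))
    return _build_table(rows, dim, oov_policy)


def embed_passage(table: EmbeddingTable, tokens: Sequence[str],
                  max_len: int = DEFAULT_MAX_LEN) -> np.ndarray:
    """Dense (max_len, d) matrix for one token sequence.

    Tokens are lowercased then looked up; OOV per the table's policy;
    sequences longer than max_len keep their head; the tail is padded with
    the zero pad vector. A pure function of (table, tokens, max_len).
    """
    return table.matrix[table.token_ids(tokens, max_len)]
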