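"""Medical-concept embeddings: CBOW with negative sampling, in numpy.

Tokens are the codes appearing in patient sequences.  Index 0 is reserved
for padding and index 1 for out-of-vocabulary tokens; both map to the zero
vector and are never updated, so downstream mean pooling is unaffected by
padding.  Training maximises the score of each centre token against the
mean of its context window while pushing down sampled negatives drawn from
the unigram distribution raised to the 3/4 power.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import expit

from .nn import OOV_INDEX, PAD_INDEX

__all__ = ["EmbeddingTable", "CBOWConfig", "pretrain_embeddings"]

PAD_TOKEN = "<pad>"
OOV_TOKEN = "<oov>"


@dataclass
class EmbeddingTable:
    """Token -> vector table with reserved zero rows for padding and OOV."""

    tokens: list
    matrix: np.ndarray  # (len(tokens) + 2, dim); rows 0/1 are zero
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {t: i + 2 for i, t in enumerate(self.tokens)}
        self.matrix[PAD_INDEX] = 0.0
        self.matrix[OOV_INDEX] = 0.0

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.index.get(token, OOV_INDEX)]

    def encode(self, tokens: Iterable[str]) -> np.ndarray:
        return np.array([self.index.get(t, OOV_INDEX) for t in tokens], dtype=np.int32)

    @classmethod
    def random(cls, tokens: Sequence[str], dim: int, seed: int = 0, scale: float = 0.5):
        """Frozen random embeddings (an alternative to pretraining for small
        synthetic vocabularies)."""
        rng = np.random.default_rng(seed)
        mat = rng.standard_normal((len(tokens) + 2, dim)) * scale
        return cls(tokens=list(tokens), matrix=mat)


@dataclass
class CBOWConfig:
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.05
    batch_size: int = 1024
    max_pairs_per_epoch: int = 200_000
    min_count: int = 1
    seed: int = 0


def pretrain_embeddings(
    sequences: Sequence[Sequence[str]],
    dim: int,
    config: Optional[CBOWConfig] = None,
) -> EmbeddingTable:
    """Train CBOW-with-negative-sampling embeddings on code sequences.

    Returns a table of the requested dimension; padding and OOV rows are
    zero vectors.  Deterministic given ``config.seed``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    cfg = config or CBOWConfig()
    counts = Counter(t for seq in sequences for t in seq)
    vocab = sorted(t for t, c in counts.items() if c >= cfg.min_count)
    if not vocab:
        raise ValueError("empty vocabulary")
    index = {t: i + 2 for i, t in enumerate(vocab)}
    V = len(vocab) + 2

    rng = np.random.default_rng(cfg.seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim  # context vectors
    W_out = np.zeros((V, dim))  # centre vectors

    # flatten corpus, track sequence boundaries so windows never cross them
    flat, seq_id = [], []
    for si, seq in enumerate(sequences):
        for t in seq:
            if t in index:
                flat.append(index[t])
                seq_id.append(si)
    flat = np.asarray(flat, dtype=np.int64)
    seq_id = np.asarray(seq_id, dtype=np.int64)
    n_tok = flat.size
    if n_tok < 2:
        # degenerate corpus: return near-zero initialised table
        return EmbeddingTable(tokens=vocab, matrix=np.vstack(
            [np.zeros((2, dim)), W_in[2:]]), index=index)

    # negative-sampling distribution: unigram^0.75 over the vocabulary
    freq = np.zeros(V)
    for t, c in counts.items():
        if t in index:
            freq[index[t]] = c
    neg_p = freq ** 0.75
    neg_p /= neg_p.sum()

    offsets = np.concatenate([np.arange(-cfg.window, 0), np.arange(1, cfg.window + 1)])
    n_pairs = min(cfg.max_pairs_per_epoch, n_tok * 2)
    for _ in range(cfg.epochs):
        centers = rng.integers(0, n_tok, size=n_pairs)
        for start in range(0, n_pairs, cfg.batch_size):
            c_pos = centers[start : start + cfg.batch_size]
            B = c_pos.size
            ctx_pos = c_pos[:, None] + offsets[None, :]
            valid = (ctx_pos >= 0) & (ctx_pos < n_tok)
            ctx_pos = np.clip(ctx_pos, 0, n_tok - 1)
            valid &= seq_id[ctx_pos] == seq_id[c_pos][:, None]
            ctx_idx = flat[ctx_pos]
            w = valid.astype(float)
            n_ctx = np.maximum(w.sum(axis=1), 1.0)
            ctx_vec = (W_in[ctx_idx] * w[..., None]).sum(axis=1) / n_ctx[:, None]

            center_idx = flat[c_pos]
            neg_idx = rng.choice(V, size=(B, cfg.negatives), p=neg_p)
            # positive + negative updates (sigmoid binary objectives)
            tgt = np.concatenate([center_idx[:, None], neg_idx], axis=1)  # (B, 1+neg)
            label = np.zeros((B, 1 + cfg.negatives))
            label[:, 0] = 1.0
            out_vec = W_out[tgt]  # (B, 1+neg, d)
            score = np.einsum("bkd,bd->bk", out_vec, ctx_vec)
            sig = expit(score)
            err = (label - sig) * cfg.learning_rate  # (B, 1+neg)
            d_ctx = np.einsum("bk,bkd->bd", err, out_vec)
            d_out = err[..., None] * ctx_vec[:, None, :]
            np.add.at(W_out, tgt.ravel(), d_out.reshape(-1, dim))
            upd = (d_ctx / n_ctx[:, None])[:, None, :] * w[..., None]
            np.add.at(W_in, ctx_idx.ravel(), upd.reshape(-1, dim))
            W_in[PAD_INDEX] = 0.0
            W_in[OOV_INDEX] = 0.0

    # final embeddings: context vectors (the pooled representation input)
    mat = W_in.copy()
    mat[PAD_INDEX] = 0.0
    mat[OOV_INDEX] = 0.0
    return EmbeddingTable(tokens=vocab, matrix=mat, index=index)
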