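"""Compact numpy implementation of the shared sequence encoder.

Architecture (shared by all three prediction heads):

    token indices -> embedding lookup (rows 0/1 reserved for padding and
    out-of-vocabulary tokens, both fixed at zero) -> per-token fully
    connected layer + ReLU -> global mean pooling over non-padding positions
    -> fully connected layer + ReLU -> linear head.

The head is a single linear map whose output dimension depends on the model
kind: ``n_bins + 1`` softmax logits for the discrete-time network, one
log-odds for the binary classifier, one log-hazard ratio for the deep Cox
model.  Gradients are written by hand; the optimiser is Adam with decoupled
weight decay (applied to weight matrices only, not biases).
"""
from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["EncoderNet", "AdamW"]

PAD_INDEX = 0
OOV_INDEX = 1


class EncoderNet:
    """Encoder + linear head with explicit forward/backward passes."""

    def __init__(
        self,
        embedding_matrix: np.ndarray,
        hidden_dim: int,
        out_dim: int,
        seed: int = 0,
        train_embeddings: bool = False,
        pool_divisor: str = "nonpad",
        max_sequence_length: Optional[int] = None,
    ):
        emb = np.array(embedding_matrix, dtype=float)
        emb[PAD_INDEX] = 0.0
        emb[OOV_INDEX] = 0.0
        self.embedding = emb
        self.train_embeddings = bool(train_embeddings)
        self.pool_divisor = pool_divisor
        self.max_sequence_length = max_sequence_length
        d = emb.shape[1]
        rng = np.random.default_rng(seed)

        def he(shape):
            return rng.standard_normal(shape) * np.sqrt(2.0 / shape[0])

        self.params = {
            "W1": he((d, hidden_dim)),
            "b1": np.zeros(hidden_dim),
            "W2": he((hidden_dim, hidden_dim)),
            "b2": np.zeros(hidden_dim),
            "W3": he((hidden_dim, out_dim)) * 0.1,
            "b3": np.zeros(out_dim),
        }
        if self.train_embeddings:
            self.params["emb"] = self.embedding

    # -- forward -----------------------------------------------------------
    def forward(self, idx: np.ndarray, return_cache: bool = False):
        """Map an index matrix (B, L) to head outputs (B, out_dim)."""
        emb = self.params["emb"] if self.train_embeddings else self.embedding
        x = emb[idx]  # (B, L, d)
        mask = (idx != PAD_INDEX).astype(float)[..., None]  # (B, L, 1)
        pre1 = x @ self.params["W1"] + self.params["b1"]
        h1 = np.maximum(pre1, 0.0) * mask  # padding contributes zeros
        if self.pool_divisor == "fixed":
            denom = np.full((idx.shape[0], 1), float(idx.shape[1]))
        else:
            denom = np.maximum(mask.sum(axis=1), 1.0)  # (B, 1)
        pooled = h1.sum(axis=1) / denom
        pre2 = pooled @ self.params["W2"] + self.params["b2"]
        h2 = np.maximum(pre2, 0.0)
        out = h2 @ self.params["W3"] + self.params["b3"]
        if not return_cache:
            return out
        cache = (idx, x, mask, pre1, denom, pooled, pre2, h2)
        return out, cache

    def representation(self, idx: np.ndarray) -> np.ndarray:
        """Encoder output (post second ReLU), before the head."""
        emb = self.params["emb"] if self.train_embeddings else self.embedding
        x = emb[idx]
        mask = (idx != PAD_INDEX).astype(float)[..., None]
        h1 = np.maximum(x @ self.params["W1"] + self.params["b1"], 0.0) * mask
        if self.pool_divisor == "fixed":
            denom = np.full((idx.shape[0], 1), float(idx.shape[1]))
        else:
            denom = np.maximum(mask.sum(axis=1), 1.0)
        pooled = h1.sum(axis=1) / denom
        return np.maximum(pooled @ self.params["W2"] + self.params["b2"], 0.0)

    # -- backward ----------------------------------------------------------
    def backward(self, cache, dout: np.ndarray) -> dict:
        idx, x, mask, pre1, denom, pooled, pre2, h2 = cache
        g = {}
        g["W3"] = h2.T @ dout
        g["b3"] = dout.sum(axis=0)
        dh2 = dout @ self.params["W3"].T
        dpre2 = dh2 * (pre2 > 0)
        g["W2"] = pooled.T @ dpre2
        g["b2"] = dpre2.sum(axis=0)
        dpooled = dpre2 @ self.params["W2"].T
        dh1 = (dpooled / denom)[:, None, :] * np.ones_like(pre1)
        dpre1 = dh1 * (pre1 > 0) * mask
        g["W1"] = np.einsum("bld,blh->dh", x, dpre1)
        g["b1"] = dpre1.sum(axis=(0, 1))
        if self.train_embeddings:
            dx = dpre1 @ self.params["W1"].T
            demb = np.zeros_like(self.params["emb"])
            np.add.at(demb, idx.ravel(), dx.reshape(-1, dx.shape[-1]))
            demb[PAD_INDEX] = 0.0  # frozen
            demb[OOV_INDEX] = 0.0
            g["emb"] = demb
        return g

    def get_state(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()
        if self.train_embeddings:
            self.embedding = self.params["emb"]


class AdamW:
    """Adam with decoupled weight decay (decay on matrices, not biases)."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, gk in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd > 0 and params[k].ndim > 1:
                params[k] -= self.lr * self.wd * params[k]
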