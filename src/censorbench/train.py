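"""Model training: batching, grid search, early stopping, trained handles.

``train_model`` trains one of the three heads (DTNN / BC / DCPH) over a grid
of (learning rate, weight decay) pairs, early-stopping each candidate on
validation loss and returning the candidate with the lowest validation loss
together with its training log.  Everything is deterministic given the
TrainConfig seed.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import PatientRecord
from .config import EncoderConfig, TrainConfig
from .discrete import DiscreteDistribution, TimeGrid
from .embeddings import CBOWConfig, EmbeddingTable, pretrain_embeddings
from .models import (
    BreslowBaseline,
    bce_loss_batch,
    cox_loss_batch,
    dcph_survival,
    dtnn_loss_batch,
    softmax_distribution,
)
from .nn import AdamW, EncoderNet

MODEL_KINDS = ("DTNN", "BC", "DCPH")

__all__ = ["TrainedModel", "train_model", "build_index_matrix", "MODEL_KINDS"]


def build_index_matrix(
    records: Sequence[PatientRecord], table: EmbeddingTable, max_len: int
) -> np.ndarray:
    """Padded token-index matrix (n, max_len), keeping the most recent codes.

    Sequences longer than ``max_len`` are truncated to the latest events;
    shorter ones are padded with the reserved padding index.
    """
    X = np.zeros((len(records), max_len), dtype=np.int32)
    for i, p in enumerate(records):
        idx = table.encode(p.codes[-max_len:]) if len(p.codes) else []
        X[i, : len(idx)] = idx
    return X


def _targets(records, kind, time_grid):
    times = np.array([p.observed_time for p in records])
    events = np.array([p.event for p in records], dtype=int)
    if kind == "DTNN":
        return time_grid.bin_of(times), events, times
    return None, events, times


def _epoch_loss(net, X, kind, t_bins, events, times, chunk=8192):
    """Full-dataset loss without gradients (chunked forward passes)."""
    logits = np.concatenate(
        [net.forward(X[i : i + chunk]) for i in range(0, len(X), chunk)]
    )
    if kind == "DTNN":
        loss, _ = dtnn_loss_batch(logits, t_bins, events)
    elif kind == "BC":
        loss, _ = bce_loss_batch(logits, events)
    else:
        loss, _ = cox_loss_batch(logits, times, events)
    return loss, logits


@dataclass
class TrainedModel:
    """Handle to a trained head: network, vocabulary, grid and metadata."""

    kind: str
    net: EncoderNet
    table: EmbeddingTable
    encoder_config: EncoderConfig
    time_grid: Optional[TimeGrid] = None
    baseline: Optional[BreslowBaseline] = None
    selected: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def _logits(self, records, chunk=8192) -> np.ndarray:
        X = build_index_matrix(
            records, self.table, self.encoder_config.max_sequence_length
        )
        return np.concatenate(
            [self.net.forward(X[i : i + chunk]) for i in range(0, len(X), chunk)]
        )

    def predict_distribution(self, records) -> DiscreteDistribution:
        if self.kind != "DTNN":
            raise ValueError("distributions are only defined for the DTNN head")
        return softmax_distribution(self._logits(records), self.time_grid)

    def predict_log_hazard(self, records) -> np.ndarray:
        if self.kind != "DCPH":
            raise ValueError("log-hazard ratios are only defined for DCPH")
        return self._logits(records)[:, 0]

    def predict_event_probability(self, records, t: float) -> np.ndarray:
        """Predicted probability of diagnosis by age ``t`` for each patient.

        BC returns its (time-constant) probability; DTNN integrates its bin
        masses up to ``t``; DCPH combines the log-hazard ratio with the
        Breslow baseline.
        """
        logits = self._logits(records)
        if self.kind == "BC":
            from scipy.special import expit

            return expit(logits[:, 0])
        if self.kind == "DTNN":
            dist = softmax_distribution(logits, self.time_grid)
            return dist.event_probability_by(t)
        return np.asarray(dcph_survival(logits[:, 0], self.baseline, t))

    def predict_horizon_probability(self, records) -> np.ndarray:
        """Event probability by the horizon (the natural ranking score)."""
        if self.kind == "DTNN":
            return 1.0 - self.predict_distribution(records).beyond_mass
        t = self.time_grid.e_max if self.time_grid is not None else None
        if self.kind == "DCPH":
            t = t if t is not None else float(self.baseline.times[-1])
        return self.predict_event_probability(records, t)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Single-archive serialization (weights + config + grid-search log)."""
        meta = {
            "kind": self.kind,
            "encoder_config": self.encoder_config.__dict__,
            "time_grid": None
            if self.time_grid is None
            else {"edges": list(self.time_grid.edges), "left": self.time_grid.left},
            "selected": self.selected,
            "history": self.history,
            "tokens": list(self.table.tokens),
        }
        arrays = {f"param_{k}": v for k, v in self.net.params.items()}
        arrays["embedding"] = self.net.embedding
        arrays["table_matrix"] = self.table.matrix
        if self.baseline is not None:
            arrays["baseline_times"] = self.baseline.times
            arrays["baseline_cumhaz"] = self.baseline.cumhaz
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        enc = EncoderConfig(**meta["encoder_config"])
        table = EmbeddingTable(tokens=meta["tokens"], matrix=data["table_matrix"])
        tg = meta["time_grid"]
        time_grid = TimeGrid(edges=tuple(tg["edges"]), left=tg["left"]) if tg else None
        out_dim = (
            (time_grid.n_bins + 1) if meta["kind"] == "DTNN" else 1
        )
        net = EncoderNet(
            data["embedding"],
            enc.hidden_dim,
            out_dim,
            train_embeddings=enc.train_embeddings,
            pool_divisor=enc.pool_divisor,
        )
        for k in list(net.params):
            net.params[k] = data[f"param_{k}"]
        baseline = None
        if "baseline_times" in data:
            baseline = BreslowBaseline.__new__(BreslowBaseline)
            baseline.times = data["baseline_times"]
            baseline.cumhaz = data["baseline_cumhaz"]
        return cls(
            kind=meta["kind"],
            net=net,
            table=table,
            encoder_config=enc,
            time_grid=time_grid,
            baseline=baseline,
            selected=meta["selected"],
            history=meta["history"],
        )


def train_model(
    kind: str,
    train_records: Sequence[PatientRecord],
    val_records: Sequence[PatientRecord],
    train_config: TrainConfig,
    encoder_config: EncoderConfig,
    time_grid: Optional[TimeGrid] = None,
    embeddings="pretrain",
    cbow_config: Optional[CBOWConfig] = None,
) -> TrainedModel:
    """Grid-search training of one head; returns the arg-min candidate.

    ``embeddings`` is "pretrain" (CBOW on the training sequences, frozen),
    "random" (frozen random vectors), or an existing :class:`EmbeddingTable`.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"kind must be one of {MODEL_KINDS}")
    if not train_records or not val_records:
        raise ValueError("empty training or validation cohort")
    if kind == "DTNN" and time_grid is None:
        raise ValueError("DTNN requires a TimeGrid")
    overlap = {p.patient_id for p in train_records} & {
        p.patient_id for p in val_records
    }
    if overlap:
        raise ValueError("train and validation cohorts share patient ids")

    if isinstance(embeddings, EmbeddingTable):
        table = embeddings
    else:
        corpus = [list(p.codes) for p in train_records]
        vocab = sorted({t for seq in corpus for t in seq})
        if not vocab:
            vocab = ["<none>"]
        if embeddings == "pretrain":
            cfg = cbow_config or CBOWConfig(seed=train_config.seed)
            table = pretrain_embeddings(
                corpus if any(corpus) else [vocab], encoder_config.embedding_dim, cfg
            )
        elif embeddings == "random":
            table = EmbeddingTable.random(
                vocab, encoder_config.embedding_dim, seed=train_config.seed
            )
        else:
            raise ValueError("embeddings must be 'pretrain', 'random' or a table")

    L = encoder_config.max_sequence_length
    X_tr = build_index_matrix(train_records, table, L)
    X_va = build_index_matrix(val_records, table, L)
    tb_tr, ev_tr, ti_tr = _targets(train_records, kind, time_grid)
    tb_va, ev_va, ti_va = _targets(val_records, kind, time_grid)
    out_dim = (time_grid.n_bins + 1) if kind == "DTNN" else 1

    seed_rng = np.random.default_rng(train_config.seed)
    candidates = [
        (lr, wd)
        for lr in train_config.learning_rate_grid
        for wd in train_config.weight_decay_grid
    ]
    cand_seeds = seed_rng.integers(0, 2**31 - 1, size=2 * len(candidates))

    best = None
    history = []
    for ci, (lr, wd) in enumerate(candidates):
        net = EncoderNet(
            table.matrix,
            encoder_config.hidden_dim,
            out_dim,
            seed=int(cand_seeds[2 * ci]),
            train_embeddings=encoder_config.train_embeddings,
            pool_divisor=encoder_config.pool_divisor,
            max_sequence_length=L,
        )
        opt = AdamW(net.params, lr=lr, weight_decay=wd)
        shuffle_rng = np.random.default_rng(int(cand_seeds[2 * ci + 1]))
        n = len(X_tr)
        cand_best_val, cand_best_state, cand_best_epoch = np.inf, None, -1
        epochs_log = []
        bad = 0
        for epoch in range(train_config.max_epochs):
            order = shuffle_rng.permutation(n)
            for start in range(0, n, train_config.batch_size):
                sl = order[start : start + train_config.batch_size]
                logits, cache = net.forward(X_tr[sl], return_cache=True)
                if kind == "DTNN":
                    _, dlogits = dtnn_loss_batch(logits, tb_tr[sl], ev_tr[sl])
                elif kind == "BC":
                    _, dlogits = bce_loss_batch(logits, ev_tr[sl])
                else:
                    if ev_tr[sl].sum() == 0:
                        continue  # partial likelihood undefined in this batch
                    _, dlogits = cox_loss_batch(logits, ti_tr[sl], ev_tr[sl])
                grads = net.backward(cache, dlogits)
                opt.step(net.params, grads)
            tr_loss, _ = _epoch_loss(net, X_tr, kind, tb_tr, ev_tr, ti_tr)
            va_loss, _ = _epoch_loss(net, X_va, kind, tb_va, ev_va, ti_va)
            epochs_log.append({"epoch": epoch, "train": tr_loss, "val": va_loss})
            if va_loss < cand_best_val - 1e-9:
                cand_best_val, cand_best_epoch = va_loss, epoch
                cand_best_state = net.get_state()
                bad = 0
            else:
                bad += 1
                if bad > train_config.patience:
                    break
        net.set_state(cand_best_state)
        history.append(
            {
                "learning_rate": lr,
                "weight_decay": wd,
                "best_val_loss": cand_best_val,
                "best_epoch": cand_best_epoch,
                "epochs": epochs_log,
            }
        )
        if best is None or cand_best_val < best[0]:
            best = (cand_best_val, net, {"learning_rate": lr, "weight_decay": wd})

    _, net, selected = best
    baseline = None
    if kind == "DCPH":
        r = np.concatenate(
            [net.forward(X_tr[i : i + 8192])[:, 0] for i in range(0, len(X_tr), 8192)]
        )
        baseline = BreslowBaseline(r, ti_tr, ev_tr)
    return TrainedModel(
        kind=kind,
        net=net,
        table=table,
        encoder_config=encoder_config,
        time_grid=time_grid,
        baseline=baseline,
        selected={**selected, "val_loss": float(best[0])},
        history=history,
    )
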