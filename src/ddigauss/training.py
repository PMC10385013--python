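"""Training loop with sentence-level validation split and early stopping.

The validation split is taken at the *sentence* level (10% by default), so
all candidate instances of one sentence land on the same side and no
pair-level leakage occurs.  Training minimises cross-entropy with Adam;
after every epoch the validation micro-F1 (positive classes pooled) is
logged and the best-on-validation parameter state is returned.  Gaussian
noise and dropout are active only in training passes.  Everything is
reproducible given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .candidates import CandidateInstance
from .corpus_io import CLASS_ORDER, Document, Sentence
from .embeddings import ChannelEmbeddingSet, embed_batch
from .metrics import micro_f1

LABEL_TO_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 3e-4
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    shuffle: bool = True
    target_f1: float | None = None  # optional convergence target

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience > self.max_epochs and self.max_epochs > 0:
            raise ValueError("patience cannot exceed max_epochs")


# ---------------------------------------------------------------------------
# validation split


def _flatten(data) -> list[Sentence]:
    sents: list[Sentence] = []
    for item in data:
        if isinstance(item, Document):
            sents.extend(item.sentences)
        else:
            sents.append(item)
    return sents


def split_validation(train_docs, frac: float = 0.10, seed: int = 0,
                     ) -> tuple[list[Sentence], list[Sentence]]:
    """Sentence-level split into (train, validation) subsets.

    Accepts documents or sentences; returns flat sentence lists.  The
    validation size is ``round(frac * n)`` (at least 1), deterministic
    given the seed.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("validation fraction must lie in (0, 1)")
    sents = _flatten(train_docs)
    n = len(sents)
    if n < 2:
        raise ValueError("need at least 2 sentences to split")
    n_val = max(1, round(frac * n))
    perm = np.random.default_rng(seed).permutation(n)
    val_idx = set(perm[:n_val].tolist())
    train = [s for i, s in enumerate(sents) if i not in val_idx]
    val = [s for i, s in enumerate(sents) if i in val_idx]
    return train, val


# ---------------------------------------------------------------------------
# optimiser


class Adam:
    """Adam with bias correction over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# batchers: adapt instance lists to the two model interfaces


class MCPCNNBatcher:
    """Embeds candidate instances lazily, batch by batch.

    Filtered instances are excluded from the model-visible set and kept
    aside (``extra_gold``): at scoring time they are auto-predicted
    negative so every gold pair is still evaluated.
    """

    def __init__(self, instances: list[CandidateInstance],
                 cset: ChannelEmbeddingSet, for_training: bool = False):
        if for_training:
            visible = [i for i in instances
                       if not (i.filtered and i.label == "negative")]
            hidden: list[CandidateInstance] = []
        else:
            visible = [i for i in instances if not i.filtered]
            hidden = [i for i in instances if i.filtered]
        self.instances = visible
        self.extra_gold = [i.label for i in hidden]
        self.labels = np.array([LABEL_TO_INDEX[i.label] for i in visible])
        self.cset = cset

    def __len__(self):
        return len(self.instances)

    def batch(self, idx: np.ndarray):
        chunk = [self.instances[i] for i in idx]
        X, mask, p1, p2 = embed_batch(chunk, self.cset)
        return X, mask, p1, p2, self.labels[idx]


class RBERTBatcher:
    """Batches entity-marker inputs for the transformer head."""

    def __init__(self, inputs: list):
        self.instances = list(inputs)
        self.extra_gold: list[str] = []
        self.labels = np.array([LABEL_TO_INDEX[b.label] for b in inputs])

    def __len__(self):
        return len(self.instances)

    def batch(self, idx: np.ndarray):
        return [self.instances[i] for i in idx], self.labels[idx]


def predict_labels(model, batcher, batch_size: int = 64) -> list[str]:
    """Predicted class names for every model-visible instance, in order."""
    preds: list[str] = []
    n = len(batcher)
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        batch = batcher.batch(idx)
        _, p = model.loss_and_preds(batch, None, training=False)
        preds.extend(CLASS_ORDER[i] for i in p)
    return preds


def validation_micro_f1(model, batcher, batch_size: int = 64) -> float:
    """Micro-F1 with filtered instances entering as predicted-negative."""
    pred = predict_labels(model, batcher, batch_size)
    gold = [CLASS_ORDER[i] for i in batcher.labels]
    pred = pred + ["negative"] * len(batcher.extra_gold)
    gold = gold + list(batcher.extra_gold)
    if not gold:
        return 0.0
    return micro_f1(pred, gold)


# ---------------------------------------------------------------------------
# training loop


def train_model(model, train_batcher, val_batcher, cfg: TrainConfig,
                ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Adam training with early stopping on validation micro-F1.

    Returns ``(best_state, history)``; the model is left loaded with the
    best-on-validation parameters (ties broken by earliest epoch).  With
    ``max_epochs=0`` the initialization is returned unchanged.  A
    non-finite loss aborts with diagnostics.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_f1, best_state, best_epoch = -1.0, model.get_state(), -1
    since_improvement = 0
    n = len(train_batcher)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = train_batcher.batch(idx)
            opt.zero_grad()
            loss, _ = model.loss_and_preds(batch, rng, training=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch "
                    f"{start // cfg.batch_size}: {loss.data!r}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_f1 = validation_micro_f1(model, val_batcher, cfg.batch_size)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else float("nan"),
            "val_micro_f1": val_f1,
        })
        if val_f1 > best_f1:
            best_f1, best_state, best_epoch = val_f1, model.get_state(), epoch
            since_improvement = 0
        else:
            since_improvement += 1
        if cfg.target_f1 is not None and val_f1 >= cfg.target_f1:
            break
        if since_improvement >= cfg.patience:
            break
    model.set_state(best_state)
    hist = pd.DataFrame(history,
                        columns=["epoch", "train_loss", "val_micro_f1"])
    hist.attrs["best_epoch"] = best_epoch
    return best_state, hist


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model, path, config: dict | None = None) -> None:
    """Single-file checkpoint: parameter arrays plus embedded JSON config."""
    state = model.get_state()
    state["__config__"] = np.frombuffer(
        json.dumps({"version": 1, **(config or {})}).encode(), dtype=np.uint8,
    )
    np.savez(path, **state)


def load_checkpoint(model, path) -> dict:
    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.set_state(state)
    return config
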