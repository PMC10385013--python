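"""End-to-end experiment drivers tying the modules together.

These are the entry points the CLI, the tests and the reproduction script
share: build candidates and channels from a corpus, train a model with a
sentence-level validation split, and score it with the DDI micro-F1
convention (filtered candidates auto-predicted negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import prepare_instances, preprocess_for_bert
from .corpus_io import Document
from .embeddings import build_channel_set
from .mcpcnn import MCPCNN, NoiseConfig
from .rbert import RBERT, HeadConfig, build_vocab
from .synthetic import corpus_vocabulary, generate_channel_embeddings
from .training import (
    MCPCNNBatcher,
    RBERTBatcher,
    TrainConfig,
    split_validation,
    train_model,
    validation_micro_f1,
)


@dataclass
class ExperimentResult:
    model: object
    history: pd.DataFrame
    val_micro_f1: float
    best_val_micro_f1: float
    n_train: int
    n_val: int


def run_mcpcnn_experiment(
    docs: list[Document],
    channels=None,
    k: int = 64,
    n_channels: int = 2,
    max_len: int = 48,
    max_dist: int = 60,
    k_pos: int = 10,
    window_sizes=(3, 5, 7, 9),
    n_filters: int = 128,
    dropout: float = 0.45,
    attention: bool = True,
    noise: NoiseConfig | None = None,
    train_cfg: TrainConfig | None = None,
    val_frac: float = 0.10,
    seed: int = 0,
) -> ExperimentResult:
    """Train the multichannel piecewise CNN on a corpus.

    When ``channels`` is None, seeded synthetic channels over the corpus
    vocabulary are generated (dimensionality ``k``).  Model
    hyperparameters default to the reference setting (batch 64, kernel
    sizes [3,5,7,9], 128 filters, dropout 0.45, Adam 3e-4, noise std 0.1).
    """
    train_cfg = train_cfg or TrainConfig(seed=seed)
    train_sents, val_sents = split_validation(docs, val_frac, seed=seed)
    train_inst = prepare_instances(train_sents, max_dist, max_len)
    val_inst = prepare_instances(val_sents, max_dist, max_len)
    if channels is None:
        vocab = corpus_vocabulary(docs)
        channels = generate_channel_embeddings(vocab, k, n_channels,
                                               seed=seed)
    cset = build_channel_set(channels, max_dist=max_dist, k_pos=k_pos,
                             seed=seed)
    model = MCPCNN(
        width=cset.width, n_channels=cset.n_channels,
        window_sizes=window_sizes, n_filters=n_filters, dropout=dropout,
        attention=attention, noise=noise or NoiseConfig(std=0.1),
        seed=seed,
    )
    train_b = MCPCNNBatcher(train_inst, cset, for_training=True)
    val_b = MCPCNNBatcher(val_inst, cset, for_training=False)
    _, history = train_model(model, train_b, val_b, train_cfg)
    final = validation_micro_f1(model, val_b, train_cfg.batch_size)
    best = float(history["val_micro_f1"].max()) if len(history) else 0.0
    return ExperimentResult(model, history, final, best,
                            len(train_b), len(val_b))


def bert_inputs_from_docs(docs: list[Document], max_len: int = 64):
    sents = [s for d in docs for s in d.sentences]
    inputs = []
    for sent in sents:
        for pair in sent.pairs:
            inputs.append(preprocess_for_bert(sent, pair, max_len=max_len))
    return inputs


def run_rbert_experiment(
    docs: list[Document],
    d: int = 16,
    n_layers: int = 2,
    max_len: int = 64,
    head: HeadConfig | None = None,
    train_cfg: TrainConfig | None = None,
    val_frac: float = 0.10,
    seed: int = 0,
) -> ExperimentResult:
    """Train the entity-marker relation head over the tiny encoder."""
    train_cfg = train_cfg or TrainConfig(batch_size=16, learning_rate=1e-3,
                                         seed=seed)
    train_sents, val_sents = split_validation(docs, val_frac, seed=seed)
    make = lambda sents: [  # noqa: E731
        preprocess_for_bert(s, p, max_len=max_len)
        for s in sents for p in s.pairs
    ]
    train_inputs, val_inputs = make(train_sents), make(val_sents)
    vocab = build_vocab(train_inputs + val_inputs)
    model = RBERT.with_tiny_encoder(vocab, d=d, n_layers=n_layers,
                                    max_len=max_len, cfg=head, seed=seed)
    train_b, val_b = RBERTBatcher(train_inputs), RBERTBatcher(val_inputs)
    _, history = train_model(model, train_b, val_b, train_cfg)
    final = validation_micro_f1(model, val_b, train_cfg.batch_size)
    best = float(history["val_micro_f1"].max()) if len(history) else 0.0
    return ExperimentResult(model, history, final, best,
                            len(train_b), len(val_b))
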