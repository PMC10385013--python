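"""Word-embedding channels and instance embedding.

Each *channel* is an independent word-embedding table (in the original
setting: word2vec models trained on different biomedical corpora, all with
the same dimensionality).  Stacking several channels, in analogy with RGB
image channels, lets a word missing from one table be covered by another,
which shrinks the out-of-vocabulary problem.  On top of the word vector,
every token carries two learned position vectors indexed by its signed
distance to the DRUG1 and DRUG2 anchors, so one embedded row is

    word_vector (k)  +  pos_e1 (k_pos)  +  pos_e2 (k_pos)

concatenated to width ``k + 2*k_pos``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .candidates import PAD_TOKEN, CandidateInstance


@dataclass
class EmbeddingTable:
    vocab: dict[str, int]           # word -> row index; PAD_TOKEN -> 0
    matrix: np.ndarray              # |V| x k, row 0 all-zero (PAD)
    k: int
    name: str = ""

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("embedding dimensionality must be positive")
        if self.matrix.shape[1] != self.k:
            raise ValueError("matrix width does not match k")

    def row(self, word: str) -> np.ndarray | None:
        idx = self.vocab.get(word)
        return None if idx is None else self.matrix[idx]


def load_word2vec_text(path: str | Path, name: str = "") -> EmbeddingTable:
    """Load a word2vec *text* format file (header line ``|V| k``).

    A PAD row of zeros is prepended at index 0.  Duplicate words keep the
    last occurrence (with a warning); a line whose vector length disagrees
    with the header is a parse error naming the line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected header '|V| k'")
        n_words, k = int(header[0]), int(header[1])
        vocab: dict[str, int] = {PAD_TOKEN: 0}
        rows = [np.zeros(k)]
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if not parts or parts == [""]:
                continue
            word, values = parts[0], parts[1:]
            if len(values) != k:
                raise ValueError(
                    f"{path}:{lineno}: expected {k} components for "
                    f"{word!r}, got {len(values)}"
                )
            vec = np.array(values, dtype=float)
            if word in vocab:
                warnings.warn(
                    f"{path}:{lineno}: duplicate word {word!r}, last wins",
                    stacklevel=2,
                )
                rows[vocab[word]] = vec
            else:
                vocab[word] = len(rows)
                rows.append(vec)
    if len(vocab) - 1 != n_words:
        warnings.warn(
            f"{path}: header declares {n_words} words, found {len(vocab) - 1}",
            stacklevel=2,
        )
    return EmbeddingTable(vocab=vocab, matrix=np.stack(rows), k=k,
                          name=name or path.stem)


def save_word2vec_text(table: EmbeddingTable, path: str | Path) -> None:
    words = [(w, i) for w, i in table.vocab.items() if w != PAD_TOKEN]
    words.sort(key=lambda wi: wi[1])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {table.k}\n")
        for word, idx in words:
            vec = " ".join(repr(float(v)) for v in table.matrix[idx])
            fh.write(f"{word} {vec}\n")


@dataclass
class ChannelEmbeddingSet:
    """1-5 word-embedding channels plus the two position tables."""

    channels: list[EmbeddingTable]
    pos_e1: np.ndarray              # (2*max_dist+1) x k_pos
    pos_e2: np.ndarray
    max_dist: int
    k_pos: int
    oov_vectors: list[np.ndarray] = field(default_factory=list)
    oov_policy: str = "shared_gaussian"  # or "zero"

    @property
    def k(self) -> int:
        return self.channels[0].k

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def width(self) -> int:
        return self.k + 2 * self.k_pos


def build_channel_set(tables: list[EmbeddingTable], max_dist: int = 60,
                      k_pos: int = 10, seed: int = 0,
                      oov_policy: str = "shared_gaussian",
                      ) -> ChannelEmbeddingSet:
    """Assemble channels and seeded position/OOV tables.

    Position tables are initialized uniform(-0.05, 0.05); each channel gets
    one shared Gaussian(0, 0.01) OOV vector (or zeros under the ``zero``
    policy).  Deterministic given the seed.
    """
    if not 1 <= len(tables) <= 5:
        raise ValueError("need between 1 and 5 embedding channels")
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"channels have mixed dimensionalities: {sorted(ks)}")
    rng = np.random.default_rng(seed)
    n_pos = 2 * max_dist + 1
    pos_e1 = rng.uniform(-0.05, 0.05, size=(n_pos, k_pos))
    pos_e2 = rng.uniform(-0.05, 0.05, size=(n_pos, k_pos))
    if oov_policy == "shared_gaussian":
        oov = [rng.normal(0.0, 0.01, size=t.k) for t in tables]
    elif oov_policy == "zero":
        oov = [np.zeros(t.k) for t in tables]
    else:
        raise ValueError(f"unknown oov policy {oov_policy!r}")
    return ChannelEmbeddingSet(
        channels=list(tables), pos_e1=pos_e1, pos_e2=pos_e2,
        max_dist=max_dist, k_pos=k_pos, oov_vectors=oov,
        oov_policy=oov_policy,
    )


@dataclass
class EmbeddedSequence:
    """Per-channel numeric view of one padded instance."""

    data: np.ndarray        # n_channels x max_len x (k + 2*k_pos)
    pad_mask: np.ndarray    # max_len, True on real tokens
    p1: int
    p2: int


def embed_instance(inst: CandidateInstance, cset: ChannelEmbeddingSet,
                   dtype=np.float64) -> EmbeddedSequence:
    """Map a padded instance to per-channel matrices.

    PAD rows are all-zero (word and position parts alike); an
    out-of-vocabulary word takes that channel's OOV vector while channels
    that do know the word use their own row.
    """
    if inst.pad_mask is None:
        raise ValueError("instance must be padded first (pad_or_truncate)")
    L, md = len(inst.tokens), cset.max_dist
    out = np.zeros((cset.n_channels, L, cset.width), dtype=dtype)
    d1 = np.clip(inst.dist_e1, -md, md) + md
    d2 = np.clip(inst.dist_e2, -md, md) + md
    for c, table in enumerate(cset.channels):
        for i, (tok, real) in enumerate(zip(inst.tokens, inst.pad_mask)):
            if not real:
                continue
            vec = table.row(tok)
            if vec is None:
                vec = cset.oov_vectors[c]
            out[c, i, : cset.k] = vec
            out[c, i, cset.k : cset.k + cset.k_pos] = cset.pos_e1[d1[i]]
            out[c, i, cset.k + cset.k_pos :] = cset.pos_e2[d2[i]]
    return EmbeddedSequence(
        data=out, pad_mask=np.asarray(inst.pad_mask, dtype=bool),
        p1=inst.p1, p2=inst.p2,
    )


def embed_batch(instances: list[CandidateInstance], cset: ChannelEmbeddingSet,
                dtype=np.float64):
    """Stack a batch: (B, C, L, width) plus masks and anchor arrays."""
    seqs = [embed_instance(i, cset, dtype) for i in instances]
    X = np.stack([s.data for s in seqs])
    mask = np.stack([s.pad_mask for s in seqs])
    p1 = np.array([s.p1 for s in seqs])
    p2 = np.array([s.p2 for s in seqs])
    return X, mask, p1, p2
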