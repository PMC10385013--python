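"""Entity-marker relation head over a pluggable bidirectional encoder.

The relation statement is the triple ``r = (x, e1, e2)``: a token sequence
with two marked entity spans, which partition the sentence into five parts
(three contexts c0/c1/c2 and the two entities).  The head maps the
encoder's hidden states to a fixed-length relation vector h_r by pooling
each part (average, max, self-attention or start pooling), projecting each
pooled vector through an affine+tanh layer, concatenating the enabled
parts and optionally appending an entity-interaction block (elementwise
product or absolute difference).  During training an additive Gaussian
noise layer (std 0.3 by default for this model) precedes dropout/softmax.

The encoder is an *interface*: anything mapping ``(token ids,
entity_pos_ids, attention_mask)`` to an ``n x d`` hidden matrix works.  A
small seeded self-attention encoder ships for CPU experiments and tests;
plugging genuinely pretrained biomedical weights is an optional path that
needs external files.  Entity positional ids (1 on e1, 2 on e2, 0
elsewhere) are added to the encoder's input-embedding pathway and trained
with everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .candidates import BertInput
from .corpus_io import CLASS_ORDER
from .mcpcnn import NoiseConfig, gaussian_noise

_NEG = -1e30


def entity_positional_encoding(bert_input: BertInput) -> list[int]:
    """Recompute the {0,1,2} id sequence from the stored entity spans."""
    (a1, b1), (a2, b2) = bert_input.e1_span, bert_input.e2_span
    if b1 < a1 or b2 < a2:
        raise ValueError("empty entity span")
    if a2 <= b1:
        raise ValueError("overlapping entity spans")
    ids = [0] * len(bert_input.tokens)
    for k in range(a1, b1 + 1):
        ids[k] = 1
    for k in range(a2, b2 + 1):
        ids[k] = 2
    return ids


POOLING_METHODS = ("average", "max", "self_attention", "start")


def pool_segment(H: np.ndarray, span: tuple[int, int], method: str,
                 w: np.ndarray | None = None) -> np.ndarray:
    """Pool hidden rows ``H[span[0]..span[1]]`` into one d-vector.

    ``start`` uses the span's first row ([CLS] pooling is start at 0);
    ``self_attention`` weights rows by softmax(w . row).  An empty span
    (start > end) pools to the zero vector for methods other than start.
    """
    H = np.asarray(H, dtype=float)
    a, b = span
    if method not in POOLING_METHODS:
        raise ValueError(f"unknown pooling method {method!r}")
    if method == "start":
        return H[a].copy()
    if b < a:
        return np.zeros(H.shape[1])
    rows = H[a : b + 1]
    if method == "average":
        return rows.mean(axis=0)
    if method == "max":
        return rows.max(axis=0)
    scores = rows @ (np.zeros(H.shape[1]) if w is None else np.asarray(w))
    scores = scores - scores.max()
    e = np.exp(scores)
    return (e / e.sum()) @ rows


@dataclass
class HeadConfig:
    """Feature-combination switches for the relation head."""

    cls_pooling: str = "start"
    entity_pooling: str = "average"
    context_pooling: str = "average"
    use_cls: bool = True
    use_entities: bool = True
    use_contexts: bool = False
    interaction: str = "none"  # none | dot | absdiff
    d_proj: int | None = None  # defaults to encoder width
    dropout: float = 0.1
    noise: NoiseConfig = field(
        default_factory=lambda: NoiseConfig(std=0.3)
    )
    n_classes: int = len(CLASS_ORDER)

    def __post_init__(self):
        if not (self.use_cls or self.use_entities or self.use_contexts):
            raise ValueError("at least one feature source must be enabled")
        if self.interaction not in ("none", "dot", "absdiff"):
            raise ValueError(f"unknown interaction {self.interaction!r}")

    def n_parts(self) -> int:
        return (1 if self.use_cls else 0) \
            + (2 if self.use_entities else 0) \
            + (3 if self.use_contexts else 0)


# ---------------------------------------------------------------------------
# tiny seeded encoder


class TinyEncoder:
    """Small bidirectional self-attention encoder (single head per layer).

    Input embedding = token embedding + learned absolute position
    embedding + entity positional embedding (3 rows: context/e1/e2); each
    layer applies masked self-attention and a tanh feed-forward block,
    both residual.  No layer normalisation — at this scale training is
    stable without it and the graph stays small.
    """

    def __init__(self, vocab: dict[str, int], d: int = 16,
                 n_layers: int = 2, max_len: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.vocab = vocab
        self.d = d
        self.n_layers = n_layers
        self.max_len = max_len
        V = len(vocab)
        self.tok_emb = ad.parameter(rng.normal(0.0, 0.1, size=(V, d)))
        self.pos_emb = ad.parameter(rng.normal(0.0, 0.1, size=(max_len, d)))
        self.ent_emb = ad.parameter(rng.normal(0.0, 0.1, size=(3, d)))
        self.layers = []
        for _ in range(n_layers):
            self.layers.append({
                "Wq": ad.glorot(rng, (d, d)),
                "Wk": ad.glorot(rng, (d, d)),
                "Wv": ad.glorot(rng, (d, d)),
                "Wo": ad.glorot(rng, (d, d)),
                "W1": ad.glorot(rng, (d, 2 * d)),
                "b1": ad.zeros(2 * d),
                "W2": ad.glorot(rng, (2 * d, d)),
                "b2": ad.zeros(d),
            })

    def parameters(self) -> list[Tensor]:
        params = [self.tok_emb, self.pos_emb, self.ent_emb]
        for layer in self.layers:
            params.extend(layer.values())
        return params

    def token_ids(self, tokens: list[str]) -> np.ndarray:
        unk = self.vocab.get("[UNK]", 0)
        return np.array([self.vocab.get(t, unk) for t in tokens])

    def __call__(self, token_ids: np.ndarray, entity_pos_ids: np.ndarray,
                 attention_mask: np.ndarray) -> Tensor:
        """(B, L) int arrays -> (B, L, d) hidden states."""
        token_ids = np.atleast_2d(token_ids)
        entity_pos_ids = np.atleast_2d(entity_pos_ids)
        attention_mask = np.atleast_2d(attention_mask)
        B, L = token_ids.shape
        x = ad.add(
            ad.add(ad.take_rows(self.tok_emb, token_ids),
                   ad.take_rows(self.ent_emb, entity_pos_ids)),
            self.pos_emb[:L],
        )
        # pairwise mask: queries may only attend to real tokens
        att_offs = np.where(attention_mask[:, None, :].astype(bool), 0.0, _NEG)
        scale = 1.0 / np.sqrt(self.d)
        for layer in self.layers:
            q = ad.matmul(x, layer["Wq"])
            k = ad.matmul(x, layer["Wk"])
            v = ad.matmul(x, layer["Wv"])
            scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 2, 1))), scale)
            attn = ad.softmax(ad.add(scores, Tensor(att_offs)), axis=-1)
            x = ad.add(x, ad.matmul(ad.matmul(attn, v), layer["Wo"]))
            ff = ad.matmul(ad.tanh(ad.add(ad.matmul(x, layer["W1"]),
                                          layer["b1"])), layer["W2"])
            x = ad.add(x, ad.add(ff, layer["b2"]))
        return x


# ---------------------------------------------------------------------------
# relation head


class RBERTHead:
    """Pool / project / combine / classify over encoder hidden states."""

    def __init__(self, d: int, cfg: HeadConfig | None = None, seed: int = 0):
        self.cfg = cfg if cfg is not None else HeadConfig()
        self.d = d
        self.d_proj = self.cfg.d_proj or d
        rng = np.random.default_rng(seed)
        self.proj: dict[str, tuple[Tensor, Tensor]] = {}
        parts = []
        if self.cfg.use_cls:
            parts.append("cls")
        if self.cfg.use_entities:
            parts += ["e1", "e2"]
        if self.cfg.use_contexts:
            parts += ["c0", "c1", "c2"]
        for name in parts:
            self.proj[name] = (ad.glorot(rng, (d, self.d_proj)),
                               ad.zeros(self.d_proj))
        if self.cfg.entity_pooling == "self_attention" \
                or self.cfg.context_pooling == "self_attention":
            self.w_pool = ad.parameter(np.zeros(d))
        else:
            self.w_pool = None
        m = len(parts) * self.d_proj
        if self.cfg.interaction != "none":
            m += d
        self.Ws = ad.glorot(rng, (m, self.cfg.n_classes))
        self.b = ad.zeros(self.cfg.n_classes)
        self.h_r_dim = m

    def parameters(self) -> list[Tensor]:
        params = []
        for W, b in self.proj.values():
            params += [W, b]
        if self.w_pool is not None:
            params.append(self.w_pool)
        params += [self.Ws, self.b]
        return params

    # -- pooling over a batched span mask ---------------------------------
    def _pool(self, H: Tensor, span_mask: np.ndarray, method: str) -> Tensor:
        counts = span_mask.sum(axis=1)
        nonempty = (counts > 0).astype(float)[:, None]
        if method == "average":
            msk = Tensor(span_mask[:, :, None].astype(float))
            total = ad.sum_(ad.mul(H, msk), axis=1)
            denom = np.where(counts > 0, counts, 1.0)[:, None]
            return ad.mul(total, Tensor(nonempty / denom))
        if method == "max":
            offs = np.where(span_mask, 0.0, _NEG)[:, :, None]
            return ad.mul(ad.amax(ad.add(H, Tensor(offs)), axis=1),
                          Tensor(nonempty))
        if method == "self_attention":
            scores = ad.reshape(
                ad.matmul(H, ad.reshape(self.w_pool, (self.d, 1))),
                span_mask.shape,
            )
            offs = np.where(span_mask, 0.0, _NEG)
            alpha = ad.mul(ad.softmax(ad.add(scores, Tensor(offs)), axis=-1),
                           Tensor(span_mask.astype(float)))
            weighted = ad.sum_(ad.mul(H, ad.reshape(
                alpha, (*span_mask.shape, 1))), axis=1)
            return ad.mul(weighted, Tensor(nonempty))
        if method == "start":
            idx = span_mask.argmax(axis=1)  # first True per row
            return H[np.arange(span_mask.shape[0]), idx]
        raise ValueError(f"unknown pooling method {method!r}")

    def _project(self, name: str, vec: Tensor) -> Tensor:
        W, b = self.proj[name]
        return ad.tanh(ad.add(ad.matmul(vec, W), b))

    def combine_features(self, pooled: dict[str, Tensor],
                         h_e1: Tensor | None = None,
                         h_e2: Tensor | None = None) -> Tensor:
        """Concatenate projected parts, append the interaction block."""
        blocks = [self._project(name, vec) for name, vec in pooled.items()]
        if self.cfg.interaction == "dot":
            blocks.append(ad.mul(h_e1, h_e2))
        elif self.cfg.interaction == "absdiff":
            diff = ad.add(h_e1, ad.mul(h_e2, -1.0))
            # |x| via sign(x)*x; the sign is a constant w.r.t. the graph
            blocks.append(ad.mul(diff, np.sign(diff.data)))
        return ad.concat(blocks, axis=-1)

    def forward(self, H: Tensor, spans: dict[str, np.ndarray],
                rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        cfg = self.cfg
        pooled: dict[str, Tensor] = {}
        if cfg.use_cls:
            pooled["cls"] = self._pool(H, spans["cls"], cfg.cls_pooling)
        h_e1 = h_e2 = None
        if cfg.use_entities or cfg.interaction != "none":
            h_e1 = self._pool(H, spans["e1"], cfg.entity_pooling)
            h_e2 = self._pool(H, spans["e2"], cfg.entity_pooling)
        if cfg.use_entities:
            pooled["e1"], pooled["e2"] = h_e1, h_e2
        if cfg.use_contexts:
            for c in ("c0", "c1", "c2"):
                pooled[c] = self._pool(H, spans[c], cfg.context_pooling)
        h_r = self.combine_features(pooled, h_e1, h_e2)
        if training and cfg.noise.std > 0.0:
            delta = gaussian_noise(np.zeros(h_r.shape), cfg.noise, rng,
                                   training)
            h_r = ad.add(h_r, Tensor(delta))
        h_r = ad.dropout(h_r, cfg.dropout, rng, training)
        return ad.add(ad.matmul(h_r, self.Ws), self.b)


# ---------------------------------------------------------------------------
# full model


def _span_masks(inputs: list[BertInput]) -> dict[str, np.ndarray]:
    B = len(inputs)
    L = len(inputs[0].tokens)
    masks = {k: np.zeros((B, L), dtype=bool)
             for k in ("cls", "e1", "e2", "c0", "c1", "c2")}
    for i, bi in enumerate(inputs):
        (a1, b1), (a2, b2) = bi.e1_span, bi.e2_span
        real = int(np.sum(bi.attention_mask))
        masks["cls"][i, 0] = True
        masks["e1"][i, a1 : b1 + 1] = True
        masks["e2"][i, a2 : b2 + 1] = True
        masks["c0"][i, 1 : a1 - 1] = True          # between [CLS] and $
        masks["c1"][i, b1 + 2 : a2 - 1] = True     # between the markers
        masks["c2"][i, b2 + 2 : real - 1] = True   # up to [SEP]
    return masks


class RBERT:
    """Encoder + relation head with a shared parameter list."""

    def __init__(self, encoder: TinyEncoder, head: RBERTHead):
        self.encoder = encoder
        self.head = head

    @classmethod
    def with_tiny_encoder(cls, vocab: dict[str, int], d: int = 16,
                          n_layers: int = 2, max_len: int = 128,
                          cfg: HeadConfig | None = None,
                          seed: int = 0) -> "RBERT":
        enc = TinyEncoder(vocab, d=d, n_layers=n_layers, max_len=max_len,
                          seed=seed)
        return cls(enc, RBERTHead(d, cfg, seed=seed + 1))

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.head.parameters()

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = state[f"p{i}"].copy()

    def forward_inputs(self, inputs: list[BertInput],
                       rng: np.random.Generator | None = None,
                       training: bool = False) -> Tensor:
        tok = np.stack([self.encoder.token_ids(b.tokens) for b in inputs])
        ent = np.stack([b.entity_pos_ids for b in inputs])
        att = np.stack([b.attention_mask for b in inputs])
        H = self.encoder(tok, ent, att)
        return self.head.forward(H, _span_masks(inputs), rng, training)

    def loss_and_preds(self, batch: tuple, rng, training: bool):
        inputs, y = batch
        logits = self.forward_inputs(inputs, rng, training)
        return ad.cross_entropy_logits(logits, y), logits.data.argmax(-1)


def rbert_forward(bert_input: BertInput, model: RBERT,
                  rng: np.random.Generator | None = None,
                  training: bool = False) -> np.ndarray:
    """Probability vector over the five classes for one input."""
    logits = model.forward_inputs([bert_input], rng, training)
    return ad.softmax(logits, axis=-1).data[0]


def build_vocab(inputs_or_tokens) -> dict[str, int]:
    """Vocabulary over token lists / BertInputs, with [UNK] at index 0."""
    vocab = {"[UNK]": 0}
    for item in inputs_or_tokens:
        tokens = item.tokens if isinstance(item, BertInput) else item
        for t in tokens:
            if t not in vocab:
                vocab[t] = len(vocab)
    return vocab
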