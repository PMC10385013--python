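"""Multichannel piecewise CNN for DDI classification.

Computation graph: embedded channels -> (optional) input attention ->
multichannel convolution with several window sizes -> piecewise max
pooling over the three segments delimited by the DRUG1/DRUG2 anchors ->
concatenation -> (training-only) additive Gaussian noise -> dropout ->
affine softmax over the five classes.

Channels are treated as a depth axis, in analogy with RGB images: one
filter of window size *h* spans all channels jointly, i.e. its weight
vector has ``n_channels * h * width`` components.  Piecewise pooling keeps
the coarse sentence structure that a single global max would discard: a
feature-map position *i* (a window starting at token *i*) belongs to the
left segment iff ``i <= p1``, the middle segment iff ``p1 < i <= p2`` and
the right segment otherwise; an empty segment pools to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import autodiff as ad
from .autodiff import Tensor
from .corpus_io import CLASS_ORDER
from .embeddings import ChannelEmbeddingSet, embed_batch

_NEG = -1e30


# ---------------------------------------------------------------------------
# Gaussian-noise layer


@dataclass
class NoiseConfig:
    """Additive Gaussian perturbation applied during training only.

    Two schemes are exposed:

    * ``pre_classifier`` (default): plain Normal(0, std) added to the
      pooled feature vector just before dropout/softmax; std defaults to
      0.1 for the CNN model (0.3 suits the transformer head).
    * ``embedding``: the word-insertion scheme — each embedded component
      is selected with probability ``elem_prob`` and receives a draw from
      a truncated Normal(0, std) restricted to ``trunc_range``.
    """

    std: float = 0.1
    elem_prob: float = 1.0
    trunc_range: tuple[float, float] = (0.0, 0.3)
    site: str = "pre_classifier"  # embedding | pre_classifier | both
    train_only: bool = True

    def __post_init__(self):
        if self.std < 0:
            raise ValueError("noise std must be non-negative")
        lo, hi = self.trunc_range
        if lo > hi:
            raise ValueError("truncation range must satisfy lo <= hi")
        if not 0.0 <= self.elem_prob <= 1.0:
            raise ValueError("elem_prob must lie in [0, 1]")

    @classmethod
    def word_insertion_scheme(cls) -> "NoiseConfig":
        """Truncated-normal scheme: sigma=1, range [0, 0.3], prob 0.3."""
        return cls(std=1.0, elem_prob=0.3, trunc_range=(0.0, 0.3),
                   site="embedding")


def truncated_normal_moments(cfg: NoiseConfig) -> tuple[float, float]:
    """Closed-form (mean, variance) of one truncated-normal draw."""
    lo, hi = cfg.trunc_range
    a, b = lo / cfg.std, hi / cfg.std
    mean, var = stats.truncnorm.stats(a, b, loc=0.0, scale=cfg.std,
                                      moments="mv")
    return float(mean), float(var)


def gaussian_noise(v: np.ndarray, cfg: NoiseConfig,
                   rng: np.random.Generator, training: bool,
                   site: str | None = None) -> np.ndarray:
    """Perturb ``v`` additively; bit-identical passthrough when inactive.

    ``site`` selects the scheme for this call (defaults to ``cfg.site``);
    the embedding site draws truncated normals, the pre-classifier site
    plain normals.  Deterministic given the generator state.
    """
    if (cfg.train_only and not training) or cfg.std == 0.0:
        return v
    site = site or cfg.site
    v = np.asarray(v, dtype=float)
    if cfg.elem_prob < 1.0:
        mask = rng.random(v.shape) < cfg.elem_prob
    else:
        mask = np.ones(v.shape, dtype=bool)
    if site == "embedding":
        lo, hi = cfg.trunc_range
        draws = stats.truncnorm.rvs(
            lo / cfg.std, hi / cfg.std, scale=cfg.std,
            size=v.shape, random_state=rng,
        )
    else:
        draws = rng.normal(0.0, cfg.std, size=v.shape)
    return v + np.where(mask, draws, 0.0)


# ---------------------------------------------------------------------------
# standalone reference operations (NumPy, forward only)


@dataclass
class FeatureMap:
    """One filter's response map: length n-h+1 for window size h."""

    values: np.ndarray
    h: int


@dataclass
class ConvFilterBank:
    """Filters of several window sizes over the joint channel depth.

    ``weights[h]`` has shape (n_channels*h*width, n_filters): component
    order is channel-major, then window row, then embedding dimension.
    """

    window_sizes: list[int]
    n_filters: int
    weights: dict[int, Tensor]
    biases: dict[int, Tensor]
    nonlinearity: str = "tanh"

    @classmethod
    def create(cls, width: int, n_channels: int,
               window_sizes=(3, 5, 7, 9), n_filters: int = 128,
               nonlinearity: str = "tanh", seed: int = 0,
               ) -> "ConvFilterBank":
        rng = np.random.default_rng(seed)
        weights = {
            h: ad.glorot(rng, (n_channels * h * width, n_filters))
            for h in window_sizes
        }
        biases = {h: ad.zeros(n_filters) for h in window_sizes}
        return cls(list(window_sizes), n_filters, weights, biases,
                   nonlinearity)

    def apply_nonlinearity(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(x) if self.nonlinearity == "tanh" else x


def _im2col(seq: np.ndarray, h: int) -> np.ndarray:
    """(C, L, W) -> (P, C*h*W) with P = L-h+1, matching the bank layout."""
    C, L, W = seq.shape
    P = L - h + 1
    win = np.concatenate([seq[:, i : i + P, :] for i in range(h)], axis=-1)
    return win.transpose(1, 0, 2).reshape(P, C * h * W)


def convolve(seq: np.ndarray, bank: ConvFilterBank) -> list[FeatureMap]:
    """Reference convolution over one embedded sequence (C, L, W).

    Returns one :class:`FeatureMap` per filter, window sizes in bank
    order.  Errors when the sequence is shorter than a window.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim == 2:
        seq = seq[None]
    L = seq.shape[1]
    maps: list[FeatureMap] = []
    for h in bank.window_sizes:
        if L < h:
            raise ValueError(f"sequence length {L} < window size {h}")
        scores = _im2col(seq, h) @ bank.weights[h].data + bank.biases[h].data
        act = bank.apply_nonlinearity(scores)
        maps.extend(FeatureMap(act[:, f], h) for f in range(bank.n_filters))
    return maps


def piecewise_max_pool(fmap, p1: int, p2: int) -> tuple[float, float, float]:
    """Segment maxima of a feature map around the two anchor coordinates.

    Segments are ``[0..p1]``, ``[p1+1..p2]``, ``[p2+1..end]`` in map
    coordinates; an empty segment yields 0.
    """
    values = fmap.values if isinstance(fmap, FeatureMap) else np.asarray(fmap)
    if not 0 <= p1 < p2:
        raise ValueError(f"anchors must satisfy 0 <= p1 < p2, got {p1}, {p2}")
    segs = (values[: p1 + 1], values[p1 + 1 : p2 + 1], values[p2 + 1 :])
    return tuple(float(s.max()) if s.size else 0.0 for s in segs)


def attention_weights(seq: np.ndarray, pad_mask: np.ndarray,
                      W: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Input-level additive attention over token rows.

    ``score_i = v . tanh(W-projected row i)``; masked softmax over non-pad
    tokens (pads get exactly 0).  ``seq`` is (L, width) — for multichannel
    input pass the channel mean.
    """
    seq = np.asarray(seq, dtype=float)
    pad_mask = np.asarray(pad_mask, dtype=bool)
    if not pad_mask.any():
        raise ValueError("attention over an all-pad input")
    scores = np.tanh(seq @ W) @ v
    scores = np.where(pad_mask, scores, _NEG)
    scores -= scores.max()
    e = np.exp(scores) * pad_mask
    return e / e.sum()


@dataclass
class ClassifierParams:
    """Affine softmax head ``o = z W + d`` with Bernoulli dropout on z."""

    Ws: Tensor
    d: Tensor
    dropout: float = 0.45

    @classmethod
    def create(cls, m: int, n_classes: int = 5, dropout: float = 0.45,
               seed: int = 0) -> "ClassifierParams":
        rng = np.random.default_rng(seed)
        return cls(ad.glorot(rng, (m, n_classes)), ad.zeros(n_classes),
                   dropout)


def classify(z: np.ndarray, params: ClassifierParams,
             rng: np.random.Generator | None = None,
             training: bool = False) -> np.ndarray:
    """Reference dropout+softmax classification of a feature vector."""
    z = np.asarray(z, dtype=float)
    Ws, d = params.Ws.data, params.d.data
    if z.shape[-1] != Ws.shape[0]:
        raise ValueError(
            f"feature length {z.shape[-1]} does not match classifier "
            f"input {Ws.shape[0]}"
        )
    if training and params.dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - params.dropout
        z = z * (rng.random(z.shape) < keep) / keep
    o = z @ Ws + d
    o = o - o.max(axis=-1, keepdims=True)
    e = np.exp(o)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# trainable model


class MCPCNN:
    """Trainable multichannel piecewise CNN (pure NumPy + autodiff)."""

    def __init__(self, width: int, n_channels: int,
                 window_sizes=(3, 5, 7, 9), n_filters: int = 128,
                 n_classes: int = len(CLASS_ORDER), dropout: float = 0.45,
                 attention: bool = True,
                 noise: NoiseConfig | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.width = width
        self.n_channels = n_channels
        self.window_sizes = list(window_sizes)
        self.n_filters = n_filters
        self.n_classes = n_classes
        self.dropout_rate = dropout
        self.attention = attention
        self.noise = noise if noise is not None else NoiseConfig()
        self.bank = ConvFilterBank.create(
            width, n_channels, window_sizes, n_filters,
            seed=int(rng.integers(2**31)),
        )
        if attention:
            self.W_att = ad.glorot(rng, (width, width))
            self.v_att = ad.zeros(width)  # zero init => exact no-op start
        m = 3 * n_filters * len(self.window_sizes)
        self.clf = ClassifierParams.create(
            m, n_classes, dropout, seed=int(rng.integers(2**31)),
        )

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = []
        for h in self.window_sizes:
            params += [self.bank.weights[h], self.bank.biases[h]]
        if self.attention:
            params += [self.W_att, self.v_att]
        params += [self.clf.Ws, self.clf.d]
        return params

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = state[f"p{i}"].copy()

    # -- forward -----------------------------------------------------------
    def _attention_scale(self, X: np.ndarray, mask: np.ndarray) -> Tensor:
        """Per-token weights, rescaled so uniform attention is identity."""
        B, _, L, _ = X.shape
        xbar = Tensor(X.mean(axis=1))                       # (B, L, W)
        scores = ad.matmul(ad.tanh(ad.matmul(xbar, self.W_att)),
                           ad.reshape(self.v_att, (self.width, 1)))
        scores = ad.reshape(scores, (B, L))
        offs = np.where(mask, 0.0, _NEG)
        alpha = ad.softmax(scores + Tensor(offs), axis=-1)
        alpha = ad.mul(alpha, Tensor(mask.astype(float)))   # pads exactly 0
        counts = mask.sum(axis=1, keepdims=True).astype(float)
        return ad.mul(alpha, Tensor(counts))

    def forward_batch(self, X: np.ndarray, mask: np.ndarray,
                      p1: np.ndarray, p2: np.ndarray,
                      rng: np.random.Generator | None = None,
                      training: bool = False) -> Tensor:
        """Logits (B, n_classes) for an embedded batch (B, C, L, width)."""
        B, C, L, W = X.shape
        Xt = Tensor(X)
        if self.attention:
            alpha = self._attention_scale(X, mask)
            Xt = ad.mul(Xt, ad.reshape(alpha, (B, 1, L, 1)))
        if (training and self.noise.site in ("embedding", "both")
                and self.noise.std > 0.0):
            delta = gaussian_noise(np.zeros_like(X), self.noise, rng,
                                   training, site="embedding")
            delta *= mask[:, None, :, None]  # pads stay zero
            Xt = ad.add(Xt, Tensor(delta))
        pooled = []
        pos = np.arange(L)  # map coordinate = window start token index
        for h in self.window_sizes:
            P = L - h + 1
            win = ad.sliding_windows(Xt, h, axis=2)          # (B,C,P,hW)
            win = ad.transpose(win, (0, 2, 1, 3))            # (B,P,C,hW)
            win = ad.reshape(win, (B, P, C * h * W))
            z = ad.tanh(ad.add(ad.matmul(win, self.bank.weights[h]),
                               self.bank.biases[h]))         # (B,P,F)
            i = pos[:P][None, :]
            seg_masks = [
                i <= p1[:, None],
                (i > p1[:, None]) & (i <= p2[:, None]),
                i > p2[:, None],
            ]
            for sm in seg_masks:
                offs = np.where(sm, 0.0, _NEG)[:, :, None]
                seg = ad.amax(ad.add(z, Tensor(offs)), axis=1)  # (B,F)
                nonempty = sm.any(axis=1).astype(float)[:, None]
                pooled.append(ad.mul(seg, Tensor(nonempty)))
        zvec = ad.concat(pooled, axis=-1)                    # (B, 3*F*|H|)
        if (training and self.noise.site in ("pre_classifier", "both")
                and self.noise.std > 0.0):
            delta = gaussian_noise(np.zeros(zvec.shape), self.noise, rng,
                                   training, site="pre_classifier")
            zvec = ad.add(zvec, Tensor(delta))
        zvec = ad.dropout(zvec, self.dropout_rate, rng, training)
        return ad.add(ad.matmul(zvec, self.clf.Ws), self.clf.d)

    def loss_and_preds(self, batch, rng, training: bool):
        X, mask, p1, p2, y = batch
        logits = self.forward_batch(X, mask, p1, p2, rng, training)
        return ad.cross_entropy_logits(logits, y), logits.data.argmax(-1)

    def predict_proba(self, X, mask, p1, p2) -> np.ndarray:
        logits = self.forward_batch(X, mask, p1, p2, training=False)
        return ad.softmax(logits, axis=-1).data


def mcpcnn_forward(instance, cset: ChannelEmbeddingSet, model: MCPCNN,
                   rng: np.random.Generator | None = None,
                   training: bool = False) -> np.ndarray:
    """Probability vector over the five classes for one padded instance."""
    X, mask, p1, p2 = embed_batch([instance], cset)
    logits = model.forward_batch(X, mask, p1, p2, rng, training)
    return ad.softmax(logits, axis=-1).data[0]
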