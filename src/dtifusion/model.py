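"""The four-channel multi-view DTI network.

A (protein, drug) pair is viewed through up to four parallel channels:

* **protein CNN** — embed the k-mer token ids (m x u), run 1-D
  convolutions of several kernel sizes along the token axis, ReLU, and
  global max pooling, selecting the strongest local motif match anywhere
  in the sequence;
* **protein transformer** — embed the same ids into a d_model-wide
  representation, add sinusoidal positional encodings, pass through
  N encoder blocks (multi-head scaled dot-product attention + a
  position-wise feed-forward with residual connections and layer
  normalization), then global max pooling;
* **drug CNN** — the character-token analogue of the protein CNN;
* **drug fingerprint** — dense ReLU layers on the 2048-bit radius-2
  circular fingerprint.

Enabled channel outputs are concatenated and passed through a dense head
ending in a single sigmoid unit: the predicted interaction probability.

Padding id 0 is masked everywhere: pad embeddings are zeroed, pad keys
are excluded from attention, and pooling ignores windows/positions made
of padding only, so extending an input with extra padding never changes
the output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .vocab import Vocabulary

NEG_INF = -1e9

CHANNEL_NAMES = ("protein_cnn", "protein_transformer", "drug_cnn", "drug_fingerprints")


class ConfigError(ValueError):
    """Inconsistent model configuration."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setup).

    ``protein_length``/``drug_length`` (m, v) fix the encoded input
    lengths; ``protein_embedding_dim``/``drug_embedding_dim`` (u, j) the
    embedding widths; the transformer runs ``n_layers`` encoder blocks
    of ``n_heads`` heads at width ``d_model`` (divisible by n_heads).
    """

    protein_length: int = 800  # m
    drug_length: int = 100  # v
    protein_embedding_dim: int = 20  # u
    drug_embedding_dim: int = 10  # j
    n_layers: int = 4
    n_heads: int = 5
    d_model: int = 20
    d_ff: int = 80
    protein_conv_filters: int = 64
    protein_kernel_sizes: tuple[int, ...] = (4, 8, 12)
    drug_conv_filters: int = 32
    drug_kernel_sizes: tuple[int, ...] = (2, 4, 6)
    fingerprint_units: tuple[int, ...] = (128,)
    dense_units: tuple[int, ...] = (128,)
    embedding_dropout_rate: float = 0.1
    l2_lambda: float = 1e-5
    norm_style: str = "post"  # "post" (residual then LayerNorm) or "pre"
    channels_enabled: tuple[str, ...] = CHANNEL_NAMES
    share_protein_embeddings: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigError(f"d_model={self.d_model} not divisible by n_heads={self.n_heads}")
        unknown = set(self.channels_enabled) - set(CHANNEL_NAMES)
        if unknown:
            raise ConfigError(f"unknown channel(s) {sorted(unknown)}")
        if not ({"protein_cnn", "protein_transformer"} & set(self.channels_enabled)):
            raise ConfigError("at least one protein channel must be enabled")
        if not ({"drug_cnn", "drug_fingerprints"} & set(self.channels_enabled)):
            raise ConfigError("at least one drug channel must be enabled")
        if not 0 <= self.embedding_dropout_rate < 1:
            raise ConfigError("embedding_dropout_rate must be in [0, 1)")
        if self.norm_style not in ("post", "pre"):
            raise ConfigError("norm_style must be 'post' or 'pre'")
        if isinstance(self.channels_enabled, list):
            self.channels_enabled = tuple(self.channels_enabled)

    def with_channels(self, channels: tuple[str, ...]) -> "ModelConfig":
        cfg = ModelConfig(**{**asdict(self), "channels_enabled": tuple(channels)})
        return cfg

    def channel_output_width(self, channel: str) -> int:
        """Width the channel contributes to the fusion concatenation."""
        if channel == "protein_cnn":
            return self.protein_conv_filters * len(self.protein_kernel_sizes)
        if channel == "protein_transformer":
            return self.d_model
        if channel == "drug_cnn":
            return self.drug_conv_filters * len(self.drug_kernel_sizes)
        if channel == "drug_fingerprints":
            return self.fingerprint_units[-1] if self.fingerprint_units else 2048
        raise ConfigError(f"unknown channel {channel!r}")


# ---------------------------------------------------------------------
# attention primitives
# ---------------------------------------------------------------------


@dataclass
class AttentionWeights:
    """Projection matrices of one multi-head attention block.

    ``w_q/w_k/w_v`` are (d_model, d_model); head ``i`` uses column block
    ``[i*d_k:(i+1)*d_k]`` of each, so the per-head projections are the
    reshaped slices. ``w_o`` maps the concatenated heads back to d_model.
    """

    w_q: Tensor
    w_k: Tensor
    w_v: Tensor
    w_o: Tensor
    n_heads: int

    @property
    def d_k(self) -> int:
        return self.w_q.shape[1] // self.n_heads


@dataclass
class FeedForwardWeights:
    """Two affine maps with a rectifier between: ReLU(x W1 + b1) W2 + b2."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor


def scaled_dot_attention(q, k, v, mask_bias: np.ndarray | None = None):
    """softmax(Q Kᵀ / sqrt(d_k)) V.

    Accepts numpy arrays or Tensors with arbitrary leading batch axes;
    the last two axes are (sequence, d_k). ``mask_bias`` (broadcastable
    to the logit shape, large-negative at masked keys) is added to the
    logits before the softmax. Each attention row is a probability
    distribution over keys.
    """
    numpy_in = not isinstance(q, Tensor)
    q, k, v = ag.as_tensor(q), ag.as_tensor(k), ag.as_tensor(v)
    d_k = q.shape[-1]
    if k.shape[-1] != d_k:
        raise ValueError(f"Q and K key dims differ: {d_k} vs {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("K and V sequence lengths differ")
    # scaling Q up front is algebraically identical to scaling the
    # logits and touches a d_k-wide array instead of an L x L one
    q = q * (1.0 / np.sqrt(d_k))
    logits = q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)
    out = ag.softmax(logits, axis=-1, bias=mask_bias) @ v
    return out.data if numpy_in else out


def multi_head_attention(x, weights: AttentionWeights, mask_bias: np.ndarray | None = None):
    """Concat(head_1..head_n) W_O over per-head projected Q, K, V.

    ``x`` is (B, L, d_model) (a single (L, d_model) matrix is promoted).
    Output has the same sequence length and width as the input.
    """
    numpy_in = not isinstance(x, Tensor)
    x = ag.as_tensor(x)
    squeeze = x.ndim == 2
    if squeeze:
        x = x.reshape(1, *x.shape)
    B, L, D = x.shape
    h = weights.n_heads
    if D % h != 0:
        raise ConfigError(f"d_model={D} not divisible by n_heads={h}")
    d_k = D // h

    def split_heads(t: Tensor) -> Tensor:
        return t.reshape(B, L, h, d_k).transpose(0, 2, 1, 3)  # (B, h, L, d_k)

    q = split_heads(x @ weights.w_q)
    k = split_heads(x @ weights.w_k)
    v = split_heads(x @ weights.w_v)
    heads = scaled_dot_attention(q, k, v, mask_bias)  # (B, h, L, d_k)
    merged = heads.transpose(0, 2, 1, 3).reshape(B, L, D)
    out = merged @ weights.w_o
    if squeeze:
        out = out.reshape(L, D)
    return out.data if numpy_in else out


def feed_forward(x, weights: FeedForwardWeights):
    """Position-wise FFN: ReLU(x W1 + b1) W2 + b2."""
    numpy_in = not isinstance(x, Tensor)
    x = ag.as_tensor(x)
    out = ag.relu(x @ weights.w1 + weights.b1) @ weights.w2 + weights.b2
    return out.data if numpy_in else out


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """The standard fixed sine/cosine positional encoding table."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


# ---------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Variance-scaled (Glorot) normal initialization."""
    fan_in = int(np.prod(shape[:-1]))
    fan_out = shape[-1]
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)


class MultiViewDTI:
    """Trainable multi-view network over encoded (protein, drug) pairs."""

    def __init__(self, config: ModelConfig, protein_vocab_rows: int, drug_vocab_rows: int):
        self.config = config
        self.protein_vocab_rows = protein_vocab_rows
        self.drug_vocab_rows = drug_vocab_rows
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        c = config

        def param(name: str, shape: tuple[int, ...], zero: bool = False) -> Tensor:
            t = Tensor(np.zeros(shape) if zero else _glorot(rng, shape), requires_grad=True)
            self.params[name] = t
            return t

        enabled = set(c.channels_enabled)
        fusion_width = 0
        if "protein_cnn" in enabled:
            param("protein_cnn.embed", (protein_vocab_rows, c.protein_embedding_dim))
            for ks in c.protein_kernel_sizes:
                param(f"protein_cnn.conv{ks}.w", (ks * c.protein_embedding_dim, c.protein_conv_filters))
                param(f"protein_cnn.conv{ks}.b", (c.protein_conv_filters,), zero=True)
            fusion_width += c.protein_conv_filters * len(c.protein_kernel_sizes)
        if "protein_transformer" in enabled:
            if c.share_protein_embeddings and "protein_cnn" in enabled:
                if c.d_model != c.protein_embedding_dim:
                    raise ConfigError("shared protein embeddings need d_model == protein_embedding_dim")
            else:
                param("protein_transformer.embed", (protein_vocab_rows, c.d_model))
            for layer in range(c.n_layers):
                pre = f"protein_transformer.layer{layer}"
                for w in ("w_q", "w_k", "w_v", "w_o"):
                    param(f"{pre}.attn.{w}", (c.d_model, c.d_model))
                param(f"{pre}.ffn.w1", (c.d_model, c.d_ff))
                param(f"{pre}.ffn.b1", (c.d_ff,), zero=True)
                param(f"{pre}.ffn.w2", (c.d_ff, c.d_model))
                param(f"{pre}.ffn.b2", (c.d_model,), zero=True)
                for ln in ("ln1", "ln2"):
                    g = Tensor(np.ones(c.d_model), requires_grad=True)
                    self.params[f"{pre}.{ln}.gamma"] = g
                    param(f"{pre}.{ln}.beta", (c.d_model,), zero=True)
            fusion_width += c.d_model
        if "drug_cnn" in enabled:
            param("drug_cnn.embed", (drug_vocab_rows, c.drug_embedding_dim))
            for ks in c.drug_kernel_sizes:
                param(f"drug_cnn.conv{ks}.w", (ks * c.drug_embedding_dim, c.drug_conv_filters))
                param(f"drug_cnn.conv{ks}.b", (c.drug_conv_filters,), zero=True)
            fusion_width += c.drug_conv_filters * len(c.drug_kernel_sizes)
        if "drug_fingerprints" in enabled:
            width = 2048
            for li, units in enumerate(c.fingerprint_units):
                param(f"drug_fingerprints.dense{li}.w", (width, units))
                param(f"drug_fingerprints.dense{li}.b", (units,), zero=True)
                width = units
            fusion_width += width
        width = fusion_width
        for li, units in enumerate(c.dense_units):
            param(f"head.dense{li}.w", (width, units))
            param(f"head.dense{li}.b", (units,), zero=True)
            width = units
        param("head.out.w", (width, 1))
        param("head.out.b", (1,), zero=True)
        self._pos_protein = sinusoidal_positions(c.protein_length, c.d_model)

    # -- bookkeeping --------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def weight_matrices(self) -> list[Tensor]:
        """Trainable weight matrices (for the L2 penalty); biases and
        layer-norm gains/offsets are excluded."""
        return [t for name, t in self.params.items()
                if t.data.ndim >= 2 and ".ln" not in name]

    def parameter_count(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def channel_parameter_count(self, channel: str) -> int:
        return int(sum(t.data.size for name, t in self.params.items()
                       if name.startswith(channel + ".")))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            missing = set(self.params) ^ set(state)
            raise ConfigError(f"state dict mismatch on keys {sorted(missing)}")
        for name, arr in state.items():
            self.params[name].data = np.asarray(arr, dtype=np.float64).copy()

    # -- forward pieces -----------------------------------------------

    def _layer_norm(self, x: Tensor, prefix: str) -> Tensor:
        gamma = self.params[f"{prefix}.gamma"]
        beta = self.params[f"{prefix}.beta"]
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        return centered * ((var + 1e-5) ** -0.5) * gamma + beta

    def _spatial_dropout(self, emb: Tensor, training: bool,
                         rng: np.random.Generator | None) -> Tensor:
        """Zero whole embedding dimensions per sequence (training only)."""
        rate = self.config.embedding_dropout_rate
        if not training or rate == 0.0 or rng is None:
            return emb
    # inverted dropout: scale kept channels so the expectation is unchanged
        B, _, D = emb.shape
        keep = (rng.random((B, 1, D)) >= rate) / (1.0 - rate)
        return ag.mul_constant(emb, keep)

    def _cnn_channel(self, name: str, ids: np.ndarray, emb_dim: int,
                     kernel_sizes: tuple[int, ...], training: bool,
                     rng: np.random.Generator | None) -> Tensor:
        real = (ids != 0)
        emb = ag.embedding(self.params[f"{name}.embed"], ids)
        emb = ag.mul_constant(emb, real[:, :, None].astype(float))
        emb = self._spatial_dropout(emb, training, rng)
        real_len = real.sum(axis=1)  # (B,)
        pooled = []
        for ks in kernel_sizes:
            windows = ag.unfold(emb, ks)  # (B, Lo, ks*emb_dim)
            conv = ag.relu(windows @ self.params[f"{name}.conv{ks}.w"]
                           + self.params[f"{name}.conv{ks}.b"])
            lo = ids.shape[1] - ks + 1
            # a window is real if it touches at least one real token
            valid = np.arange(lo)[None, :] < real_len[:, None]
            conv = ag.add_constant(conv, np.where(valid, 0.0, NEG_INF)[:, :, None])
            pooled.append(conv.max(axis=1))
        return ag.concat(pooled, axis=-1)

    def _transformer_channel(self, ids: np.ndarray, training: bool,
                             rng: np.random.Generator | None) -> Tensor:
        c = self.config
        real = (ids != 0)
        table = (self.params["protein_cnn.embed"]
                 if c.share_protein_embeddings and "protein_cnn" in set(c.channels_enabled)
                 else self.params["protein_transformer.embed"])
        x = ag.embedding(table, ids)
        x = ag.mul_constant(x, real[:, :, None].astype(float))
        x = ag.add_constant(x, self._pos_protein[None, : ids.shape[1], :])
        x = self._spatial_dropout(x, training, rng)
        # mask pad keys out of every attention row
        key_bias = np.where(real, 0.0, NEG_INF)[:, None, None, :]  # (B,1,1,L)
        for layer in range(c.n_layers):
            pre = f"protein_transformer.layer{layer}"
            attn_w = AttentionWeights(
                w_q=self.params[f"{pre}.attn.w_q"], w_k=self.params[f"{pre}.attn.w_k"],
                w_v=self.params[f"{pre}.attn.w_v"], w_o=self.params[f"{pre}.attn.w_o"],
                n_heads=c.n_heads,
            )
            ffn_w = FeedForwardWeights(
                w1=self.params[f"{pre}.ffn.w1"], b1=self.params[f"{pre}.ffn.b1"],
                w2=self.params[f"{pre}.ffn.w2"], b2=self.params[f"{pre}.ffn.b2"],
            )
            if c.norm_style == "post":
                x = self._layer_norm(x + multi_head_attention(x, attn_w, key_bias), f"{pre}.ln1")
                x = self._layer_norm(x + feed_forward(x, ffn_w), f"{pre}.ln2")
            else:
                x = x + multi_head_attention(self._layer_norm(x, f"{pre}.ln1"), attn_w, key_bias)
                x = x + feed_forward(self._layer_norm(x, f"{pre}.ln2"), ffn_w)
        x = ag.add_constant(x, np.where(real, 0.0, NEG_INF)[:, :, None])
        return x.max(axis=1)  # (B, d_model)

    @staticmethod
    def _trim(ids: np.ndarray, min_length: int) -> np.ndarray:
        longest = int((ids != 0).sum(axis=1).max(initial=0))
        return ids[:, : max(longest, min_length)]

    # -- forward ------------------------------------------------------

    def forward(self, protein_ids: np.ndarray, drug_ids: np.ndarray,
                fingerprints: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Interaction probabilities in (0, 1), shape (batch,)."""
        c = self.config
        enabled = set(c.channels_enabled)
        # outputs are padding-invariant, so trimming each batch to its
        # longest real sequence is exact and saves most of the compute
        protein_ids = self._trim(protein_ids, max(c.protein_kernel_sizes))
        drug_ids = self._trim(drug_ids, max(c.drug_kernel_sizes))
        feats: list[Tensor] = []
        if "protein_cnn" in enabled:
            feats.append(self._cnn_channel("protein_cnn", protein_ids,
                                           c.protein_embedding_dim,
                                           c.protein_kernel_sizes, training, rng))
        if "protein_transformer" in enabled:
            feats.append(self._transformer_channel(protein_ids, training, rng))
        if "drug_cnn" in enabled:
            feats.append(self._cnn_channel("drug_cnn", drug_ids,
                                           c.drug_embedding_dim,
                                           c.drug_kernel_sizes, training, rng))
        if "drug_fingerprints" in enabled:
            x = ag.as_tensor(fingerprints.astype(np.float64))
            for li in range(len(c.fingerprint_units)):
                x = ag.relu(x @ self.params[f"drug_fingerprints.dense{li}.w"]
                            + self.params[f"drug_fingerprints.dense{li}.b"])
            feats.append(x)
        h = ag.concat(feats, axis=-1) if len(feats) > 1 else feats[0]
        for li in range(len(c.dense_units)):
            h = ag.relu(h @ self.params[f"head.dense{li}.w"] + self.params[f"head.dense{li}.b"])
        logits = h @ self.params["head.out.w"] + self.params["head.out.b"]
        return ag.sigmoid(logits.reshape(logits.shape[0]))

    def predict(self, dataset, batch_size: int = 64) -> np.ndarray:
        """Probabilities for an :class:`~dtifusion.encode.EncodedDataset`.

        Samples are scored in length-sorted batches (outputs are
        padding-invariant, so this only reduces wasted computation) and
        returned in the original order.
        """
        n = len(dataset)
        order = np.argsort((dataset.protein_ids != 0).sum(axis=1), kind="stable")
        scores = np.zeros(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            scores[idx] = self.forward(dataset.protein_ids[idx], dataset.drug_ids[idx],
                                       dataset.fingerprints[idx]).data
        return scores


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------


def vocabulary_hash(vocab: Vocabulary) -> str:
    payload = json.dumps({"kind": vocab.kind, "tokens": list(vocab.tokens)})
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(path: str | Path, model: MultiViewDTI,
                    protein_vocab: Vocabulary, drug_vocab: Vocabulary) -> None:
    """Weights + config + vocabulary fingerprints in one npz file."""
    meta = {
        "config": asdict(model.config),
        "protein_vocab_rows": model.protein_vocab_rows,
        "drug_vocab_rows": model.drug_vocab_rows,
        "protein_vocab_hash": vocabulary_hash(protein_vocab),
        "drug_vocab_hash": vocabulary_hash(drug_vocab),
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path,
                    protein_vocab: Vocabulary | None = None,
                    drug_vocab: Vocabulary | None = None) -> MultiViewDTI:
    """Rebuild a model from :func:`save_checkpoint` output.

    If vocabularies are supplied their fingerprints are checked against
    the ones stored at save time, catching checkpoint/vocabulary
    mismatches early.
    """
    with np.load(path, allow_pickle=False) as bundle:
        meta = json.loads(str(bundle["__meta__"]))
        state = {k[len("param/"):]: bundle[k] for k in bundle.files if k.startswith("param/")}
    cfg_dict = meta["config"]
    for key in ("protein_kernel_sizes", "drug_kernel_sizes", "fingerprint_units",
                "dense_units", "channels_enabled"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = ModelConfig(**cfg_dict)
    if protein_vocab is not None and vocabulary_hash(protein_vocab) != meta["protein_vocab_hash"]:
        raise ConfigError("protein vocabulary does not match the checkpoint")
    if drug_vocab is not None and vocabulary_hash(drug_vocab) != meta["drug_vocab_hash"]:
        raise ConfigError("drug vocabulary does not match the checkpoint")
    model = MultiViewDTI(cfg, meta["protein_vocab_rows"], meta["drug_vocab_rows"])
    model.load_state_dict(state)
    return model
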