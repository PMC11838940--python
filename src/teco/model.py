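"""The transformer-based encounter-level outcome (TECO) network.

Architecture: an affine embedding of the per-interval feature vector into
``d_model`` dimensions, a parameter-free sinusoidal encoding of each
interval's offset relative to the prediction anchor (added to the
embedding), a stack of post-norm transformer encoder layers (multi-head
self-attention and a GELU feed-forward block, each followed by a residual
connection and layer norm; no final stack norm), pooling at the anchor
position, and an affine 2-class head under a softmax.

The default configuration (6 layers, 8 heads, d_model=512, d_ff=2048,
feature_dim=24, 2 classes) has exactly 18,928,130 trainable parameters,
which :func:`count_parameters_formula` reproduces in closed form.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import CheckpointError, ConfigurationError
from .preprocess import FeatureSchema, WindowSample, collate

_MASK_NEG = -1e9


@dataclass(frozen=True)
class TECOConfig:
    """Architecture hyperparameters; defaults are the selected model."""

    n_layers: int = 6
    n_heads: int = 8
    d_model: int = 512
    d_ff: int = 2048
    dropout: float = 0.0
    activation: str = "gelu"  # "gelu" | "relu"
    n_classes: int = 2
    feature_dim: int = 24
    max_relative_offset: int = 384  # 96 h of 15-minute intervals
    pooling: str = "anchor"  # "anchor" | "mean"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError(f"dropout must be in [0,1), got {self.dropout}")
        if self.feature_dim < 1:
            raise ConfigurationError("feature_dim must be >= 1")
        if self.activation not in ("gelu", "relu"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.pooling not in ("anchor", "mean"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")


def positional_encode(rel_offsets: np.ndarray, d_model: int) -> np.ndarray:
    """Sinusoidal encoding of anchor-relative interval offsets.

    Offsets must be integers <= 0 (intervals before the anchor); the encoding
    is the standard alternating sine/cosine frequency ladder evaluated at
    ``|offset|``, so the anchor interval (offset 0) maps to sines 0 and
    cosines 1.
    """
    off = np.asarray(rel_offsets)
    if np.any(off > 0):
        raise ValueError("relative offsets must be <= 0 (positions before the anchor)")
    pos = np.abs(off).astype(float)[..., None]
    half = (d_model + 1) // 2
    freq = 1.0 / np.power(10000.0, 2.0 * np.arange(half, dtype=float) / d_model)
    angles = pos * freq
    out = np.empty(off.shape + (d_model,), dtype=float)
    out[..., 0::2] = np.sin(angles)
    out[..., 1::2] = np.cos(angles[..., : d_model // 2])
    return out


class TECOModel:
    """The network: parameter store plus forward pass on padded batches."""

    def __init__(self, config: TECOConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(seed)
        self.training = False
        c = config
        self._add("embed_W", self._glorot(c.feature_dim, c.d_model))
        self._add("embed_b", np.zeros(c.d_model))
        for l in range(c.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                self._add(f"layer{l}.{name}", self._glorot(c.d_model, c.d_model))
                self._add(f"layer{l}.{name[1]}b", np.zeros(c.d_model))
            self._add(f"layer{l}.ln1_g", np.ones(c.d_model))
            self._add(f"layer{l}.ln1_b", np.zeros(c.d_model))
            self._add(f"layer{l}.W1", self._glorot(c.d_model, c.d_ff))
            self._add(f"layer{l}.b1", np.zeros(c.d_ff))
            self._add(f"layer{l}.W2", self._glorot(c.d_ff, c.d_model))
            self._add(f"layer{l}.b2", np.zeros(c.d_model))
            self._add(f"layer{l}.ln2_g", np.ones(c.d_model))
            self._add(f"layer{l}.ln2_b", np.zeros(c.d_model))
        self._add("head_W", self._glorot(c.d_model, c.n_classes))
        self._add("head_b", np.zeros(c.n_classes))

    def _glorot(self, fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return self._rng.uniform(-limit, limit, size=(fan_in, fan_out))

    def _add(self, name: str, data: np.ndarray) -> None:
        self.params[name] = Tensor(data, requires_grad=True)

    # -- weight bookkeeping -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state or state[k].shape != v.data.shape:
                raise CheckpointError(f"state mismatch for parameter {k!r}")
            v.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # -- forward ------------------------------------------------------------
    def _affine(self, x: Tensor, w: str, b: str) -> Tensor:
        return ag.add(ag.matmul(x, self.params[w]), self.params[b])

    def forward(self, features: np.ndarray, offsets: np.ndarray, mask: np.ndarray) -> Tensor:
        """Logits for a padded batch.

        ``features`` is (B, S, F); ``offsets`` (B, S) holds anchor-relative
        interval offsets (<= 0); ``mask`` (B, S) is True at real positions.
        Padded key positions receive a large negative attention bias, so
        outputs at real positions are unaffected by padding.
        """
        c = self.config
        B, S, F = features.shape
        if F != c.feature_dim:
            raise ConfigurationError(
                f"feature dimension {F} does not match config feature_dim={c.feature_dim}"
            )
        x = self._affine(Tensor(features), "embed_W", "embed_b")
        x = ag.add_const(x, positional_encode(np.where(mask, offsets, 0), c.d_model))
        attn_bias = np.where(mask, 0.0, _MASK_NEG)[:, None, None, :]
        dh = c.d_model // c.n_heads

        def split_heads(t: Tensor) -> Tensor:
            return ag.transpose(ag.reshape(t, (B, S, c.n_heads, dh)), (0, 2, 1, 3))

        act = ag.gelu if c.activation == "gelu" else ag.relu
        for l in range(c.n_layers):
            q = split_heads(self._affine(x, f"layer{l}.Wq", f"layer{l}.qb"))
            k = split_heads(self._affine(x, f"layer{l}.Wk", f"layer{l}.kb"))
            v = split_heads(self._affine(x, f"layer{l}.Wv", f"layer{l}.vb"))
            scores = ag.scale(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
            attn = ag.softmax(ag.add_const(scores, attn_bias), axis=-1)
            attn = ag.dropout(attn, c.dropout, self._rng, self.training)
            ctx = ag.reshape(ag.transpose(ag.matmul(attn, v), (0, 2, 1, 3)), (B, S, c.d_model))
            out = self._affine(ctx, f"layer{l}.Wo", f"layer{l}.ob")
            out = ag.dropout(out, c.dropout, self._rng, self.training)
            x = ag.layer_norm(
                ag.add(x, out), self.params[f"layer{l}.ln1_g"], self.params[f"layer{l}.ln1_b"]
            )
            ff = act(self._affine(x, f"layer{l}.W1", f"layer{l}.b1"))
            ff = self._affine(ff, f"layer{l}.W2", f"layer{l}.b2")
            ff = ag.dropout(ff, c.dropout, self._rng, self.training)
            x = ag.layer_norm(
                ag.add(x, ff), self.params[f"layer{l}.ln2_g"], self.params[f"layer{l}.ln2_b"]
            )
        if c.pooling == "anchor":
            pooled = ag.gather_rows(x, mask.sum(axis=1) - 1)
        else:
            m = mask[..., None].astype(float)
            pooled = ag.scale(ag.sum_(ag.mul(x, Tensor(m)), axis=1), 1.0)
            pooled = ag.mul(pooled, Tensor(1.0 / mask.sum(axis=1, keepdims=True)))
        return self._affine(pooled, "head_W", "head_b")

    def predict_proba(
        self, windows: list[WindowSample], batch_size: int = 64
    ) -> np.ndarray:
        """Probability of death for each window (softmax class 1)."""
        self.training = False
        probs = np.empty(len(windows))
        for start in range(0, len(windows), batch_size):
            chunk = windows[start : start + batch_size]
            feats, offsets, mask, _ = collate(chunk)
            logits = self.forward(feats, offsets, mask)
            z = logits.data - logits.data.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs[start : start + len(chunk)] = (e / e.sum(axis=1, keepdims=True))[:, 1]
        return probs


def build_model(config: TECOConfig | None = None, seed: int = 0) -> TECOModel:
    """Instantiate the network; same seed gives identical initial weights."""
    return TECOModel(config or TECOConfig(), seed=seed)


def count_parameters(model: TECOModel) -> int:
    """Count trainable parameters by enumerating every weight array."""
    return int(sum(p.data.size for p in model.params.values()))


def count_parameters_formula(config: TECOConfig) -> int:
    """Closed-form trainable parameter count of the architecture.

    embedding (F*d + d) + per layer [attention in-projections (3d^2 + 3d) +
    out-projection (d^2 + d) + feed-forward (d*d_ff + d_ff + d_ff*d + d) +
    two layer norms (4d)] times n_layers + head (d*C + C).
    """
    d, dff, F, C, L = (
        config.d_model,
        config.d_ff,
        config.feature_dim,
        config.n_classes,
        config.n_layers,
    )
    per_layer = (3 * d * d + 3 * d) + (d * d + d) + (d * dff + dff) + (dff * d + d) + 4 * d
    return (F * d + d) + L * per_layer + (d * C + C)


# -- checkpointing -----------------------------------------------------------


def schema_hash(schema: FeatureSchema) -> str:
    payload = json.dumps(asdict(schema), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(
    model: TECOModel,
    schema: FeatureSchema,
    path,
    metadata: dict | None = None,
) -> None:
    """Serialize weights + config + feature schema + metadata to one archive."""
    meta = {
        "config": asdict(model.config),
        "schema": asdict(schema),
        "schema_hash": schema_hash(schema),
        "metadata": metadata or {},
    }
    arrays = {f"param::{k}": v.data for k, v in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expect_schema: FeatureSchema | None = None):
    """Load a checkpoint; refuses to load under a mismatched feature schema."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        state = {k[len("param::") :]: z[k] for k in z.files if k.startswith("param::")}
    def _tupled(d: dict) -> dict:
        return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    schema = FeatureSchema(**_tupled(meta["schema"]))
    if expect_schema is not None and schema_hash(expect_schema) != meta["schema_hash"]:
        raise CheckpointError("checkpoint feature schema does not match the data schema")
    model = build_model(TECOConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, schema, meta["metadata"]
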