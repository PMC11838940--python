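"""Optimization recipe, repeated holdout splitting, and sub-model training.

The recipe: SGD with momentum 0.9, initial learning rate 0.01 halved every
50 epochs, batch size 32, gradient norm clipped at 1.0, at most 500 epochs,
stopping early once the validation loss has not moved by more than 1e-4 over
the trailing 100 epochs.  Splitting is repeated 20-fold 80/20 holdout at the
encounter level.  One sub-model is trained per prediction horizon.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateLabelError
from .model import TECOConfig, TECOModel, build_model
from .preprocess import WindowSample, collate
from . import autograd as ag


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; defaults are the reference recipe."""

    max_epochs: int = 500
    batch_size: int = 32
    lr0: float = 0.01
    momentum: float = 0.9
    lr_halving_period: int = 50
    grad_clip: float = 1.0
    early_stop_tol: float = 1e-4
    early_stop_patience: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.batch_size, self.lr_halving_period,
               self.early_stop_patience) <= 0 or self.lr0 <= 0 or self.grad_clip <= 0:
            raise ConfigurationError("all training hyperparameters must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ConfigurationError("early_stop_patience must be <= max_epochs")


@dataclass
class SplitPlan:
    """Repeated encounter-level holdout partitions."""

    splits: list[tuple[list[str], list[str]]]
    seed: int

    def __len__(self) -> int:
        return len(self.splits)

    def __getitem__(self, i: int) -> tuple[list[str], list[str]]:
        return self.splits[i]


def make_splits(
    encounter_ids: list[str],
    n_splits: int = 20,
    train_frac: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Independent uniform 80/20 partitions, reproducible from the seed."""
    ids = list(encounter_ids)
    if len(ids) < 2:
        raise ConfigurationError("need at least 2 encounters to split")
    n_train = int(round(train_frac * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    root = np.random.SeedSequence(seed)
    splits = []
    for child in root.spawn(n_splits):
        perm = np.random.default_rng(child).permutation(len(ids))
        train = sorted(ids[i] for i in perm[:n_train])
        val = sorted(ids[i] for i in perm[n_train:])
        splits.append((train, val))
    return SplitPlan(splits=splits, seed=seed)


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step-decay schedule: lr0 * 0.5 ** floor(epoch / halving_period)."""
    if epoch < 0:
        raise ConfigurationError("epoch must be >= 0")
    return config.lr0 * 0.5 ** (epoch // config.lr_halving_period)


@dataclass
class TrainHistory:
    """Per-epoch traces and the stopping outcome of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)  # post-clip, per step
    stop_epoch: int = 0
    stop_reason: str = "max_epochs"
    best_epoch: int = 0
    best_val_loss: float = float("inf")


def _dataset_loss(model: TECOModel, windows: list[WindowSample], batch_size: int) -> float:
    model.training = False
    total, n = 0.0, 0
    for start in range(0, len(windows), batch_size):
        chunk = windows[start : start + batch_size]
        feats, offsets, mask, labels = collate(chunk)
        logits = model.forward(feats, offsets, mask)
        loss = ag.cross_entropy_logits(logits, labels)
        total += float(loss.data) * len(chunk)
        n += len(chunk)
    return total / n


def _clip_gradients(model: TECOModel, max_norm: float) -> tuple[float, float]:
    """Global-norm clipping; returns (pre-clip, post-clip) norms."""
    sq = 0.0
    for p in model.params.values():
        if p.grad is not None:
            sq += float((p.grad * p.grad).sum())
    norm = np.sqrt(sq)
    if norm > max_norm:
        factor = max_norm / norm
        for p in model.params.values():
            if p.grad is not None:
                p.grad *= factor
        return norm, max_norm
    return norm, norm


def train_submodel(
    windows: list[WindowSample],
    split: tuple[list[str], list[str]],
    teco_config: TECOConfig,
    train_config: TrainConfig,
    grad_hook=None,
    val_loss_stream: list[float] | None = None,
) -> tuple[TECOModel, TrainHistory]:
    """Train one sub-model on one split; returns best-validation weights.

    ``grad_hook(step, pre_clip_norm, post_clip_norm)`` is called after every
    clipping step (used to assert the clipping contract).
    ``val_loss_stream``, when given, replaces the computed validation losses
    (used to exercise the early-stopping rule in isolation).
    """
    train_ids, val_ids = set(split[0]), set(split[1])
    train_w = [w for w in windows if w.encounter_id in train_ids]
    val_w = [w for w in windows if w.encounter_id in val_ids]
    if len({w.label for w in train_w}) < 2:
        raise DegenerateLabelError("training windows contain a single outcome class")
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed))
    model = build_model(teco_config, seed=int(rng.integers(2**31)))
    velocity = {k: np.zeros_like(p.data) for k, p in model.params.items()}
    history = TrainHistory()
    best_state = model.state_dict()
    step = 0
    for epoch in range(train_config.max_epochs):
        lr = lr_at_epoch(epoch, train_config)
        order = rng.permutation(len(train_w))
        model.training = True
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), train_config.batch_size):
            batch = [train_w[i] for i in order[start : start + train_config.batch_size]]
            feats, offsets, mask, labels = collate(batch)
            model.zero_grad()
            loss = ag.cross_entropy_logits(model.forward(feats, offsets, mask), labels)
            loss.backward()
            pre, post = _clip_gradients(model, train_config.grad_clip)
            if grad_hook is not None:
                grad_hook(step, pre, post)
            history.grad_norms.append(post)
            for k, p in model.params.items():
                velocity[k] = train_config.momentum * velocity[k] + p.grad
                p.data -= lr * velocity[k]
            epoch_loss += float(loss.data) * len(batch)
            n_seen += len(batch)
            step += 1
        if val_loss_stream is not None:
            val_loss = val_loss_stream[epoch]
        elif val_w:
            val_loss = _dataset_loss(model, val_w, train_config.batch_size)
        else:
            val_loss = epoch_loss / n_seen
        history.train_loss.append(epoch_loss / n_seen)
        history.val_loss.append(val_loss)
        history.learning_rate.append(lr)
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = model.state_dict()
        history.stop_epoch = epoch + 1
        p = train_config.early_stop_patience
        if epoch + 1 >= p:
            window = history.val_loss[-p:]
            if max(window) - min(window) <= train_config.early_stop_tol:
                history.stop_reason = "early_stop"
                break
    model.load_state_dict(best_state)
    model.training = False
    return model, history


@dataclass
class RegistryEntry:
    model: TECOModel
    history: TrainHistory
    horizon_h: int
    split_index: int
    seed: int
    config_hash: str
    n_train_windows: int


class SubmodelRegistry:
    """Lookup of trained sub-models keyed by (horizon, split index)."""

    def __init__(self) -> None:
        self._entries: dict[tuple[int, int], RegistryEntry] = {}

    def add(self, entry: RegistryEntry) -> None:
        self._entries[(entry.horizon_h, entry.split_index)] = entry

    def get(self, horizon_h: int, split_index: int) -> RegistryEntry:
        return self._entries[(horizon_h, split_index)]

    def __len__(self) -> int:
        return len(self._entries)

    def keys(self):
        return self._entries.keys()

    def hashes(self) -> dict[str, str]:
        return {f"{h}:{s}": e.config_hash for (h, s), e in sorted(self._entries.items())}


def _config_hash(teco_config: TECOConfig, train_config: TrainConfig, seed: int) -> str:
    payload = json.dumps(
        {"model": asdict(teco_config), "train": asdict(train_config), "seed": seed},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def derive_seed(base_seed: int, *context: int) -> int:
    """Deterministic sub-seed (< 2**31) from a base seed and integer context."""
    return int(
        np.random.SeedSequence([int(base_seed), *map(int, context)]).generate_state(1)[0]
        % (2**31)
    )


def train_all_horizons(
    windows_by_horizon: dict[int, list[WindowSample]],
    split_plan: SplitPlan,
    teco_config: TECOConfig,
    train_config: TrainConfig,
) -> SubmodelRegistry:
    """Train one sub-model per (horizon, split); seeds fan out deterministically."""
    registry = SubmodelRegistry()
    for horizon_h, windows in sorted(windows_by_horizon.items()):
        for s, split in enumerate(split_plan.splits):
            seed = derive_seed(train_config.seed, horizon_h, s)
            cfg = TrainConfig(**{**asdict(train_config), "seed": seed})
            model, history = train_submodel(windows, split, teco_config, cfg)
            registry.add(
                RegistryEntry(
                    model=model,
                    history=history,
                    horizon_h=horizon_h,
                    split_index=s,
                    seed=seed,
                    config_hash=_config_hash(teco_config, cfg, seed),
                    n_train_windows=sum(1 for w in windows if w.encounter_id in set(split[0])),
                )
            )
    return registry
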