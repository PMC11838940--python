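"""Splitting, learning-rate schedule, early stopping, clipping, determinism."""

import numpy as np
import pytest

from teco.errors import ConfigurationError, DegenerateLabelError
from teco.model import TECOConfig
from teco.preprocess import WindowSample
from teco.training import (
    TrainConfig,
    lr_at_epoch,
    make_splits,
    train_all_horizons,
    train_submodel,
)


def test_splits_are_disjoint_and_sized():
    plan = make_splits([f"e{i}" for i in range(10)], n_splits=5, seed=1)
    for train, val in plan.splits:
        assert len(train) == 8 and len(val) == 2
        assert not set(train) & set(val)
        assert sorted(train + val) == sorted(f"e{i}" for i in range(10))


def test_splits_reproducible_from_seed():
    ids = [f"e{i}" for i in range(25)]
    assert make_splits(ids, 4, seed=7).splits == make_splits(ids, 4, seed=7).splits
    assert make_splits(ids, 4, seed=7).splits != make_splits(ids, 4, seed=8).splits


def test_validation_membership_expectation():
    # each id lands in validation in Binomial(20, 0.2) splits: mean 4
    ids = [f"e{i}" for i in range(100)]
    counts = np.zeros(100)
    n_seeds = 20
    for seed in range(n_seeds):
        plan = make_splits(ids, n_splits=20, seed=seed)
        for _, val in plan.splits:
            for v in val:
                counts[int(v[1:])] += 1
    mean_appearances = counts.mean() / n_seeds
    assert mean_appearances == pytest.approx(4.0, abs=0.3)


def test_too_few_encounters_rejected():
    with pytest.raises(ConfigurationError):
        make_splits(["only"], n_splits=2)


@pytest.mark.parametrize(
    "epoch, expected",
    [(0, 0.01), (49, 0.01), (50, 0.005), (99, 0.005), (100, 0.0025), (125, 0.0025),
     (150, 0.00125)],
)
def test_learning_rate_schedule(epoch, expected):
    assert lr_at_epoch(epoch, TrainConfig()) == pytest.approx(expected)


def _toy_windows(n=40, seq=3, F=4, seed=0, separation=3.0):
    """Linearly separable toy windows: class mean shift on feature 0."""
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(n):
        label = i % 2
        feats = rng.normal(size=(seq, F)) * 0.3
        feats[:, 0] += separation * (label - 0.5)
        windows.append(
            WindowSample(
                encounter_id=f"t{i}", t_pred=100.0, horizon_h=24,
                features=feats, rel_offsets=np.arange(-seq + 1, 1), label=label,
            )
        )
    return windows


_TOY_CFG = TECOConfig(n_layers=1, n_heads=1, d_model=8, d_ff=16, feature_dim=4)


def _toy_split(windows, frac=0.8):
    ids = [w.encounter_id for w in windows]
    k = int(frac * len(ids))
    return ids[:k], ids[k:]


def test_training_loss_decreases_on_separable_toy():
    windows = _toy_windows()
    cfg = TrainConfig(max_epochs=10, early_stop_patience=10, seed=1)
    _, hist = train_submodel(windows, _toy_split(windows), _TOY_CFG, cfg)
    assert hist.train_loss[-1] < hist.train_loss[0]
    assert all(np.diff(hist.train_loss[:10]) < 0)  # strictly decreasing early on


def test_constant_validation_stream_stops_at_patience():
    windows = _toy_windows(n=12)
    cfg = TrainConfig(max_epochs=150, early_stop_patience=100, seed=1)
    _, hist = train_submodel(
        windows, _toy_split(windows), _TOY_CFG, cfg, val_loss_stream=[0.5] * 150
    )
    assert hist.stop_epoch == 100
    assert hist.stop_reason == "early_stop"


def test_early_stop_never_fires_before_patience():
    windows = _toy_windows(n=12)
    cfg = TrainConfig(max_epochs=30, early_stop_patience=25, seed=1)
    _, hist = train_submodel(
        windows, _toy_split(windows), _TOY_CFG, cfg, val_loss_stream=[0.5] * 30
    )
    assert hist.stop_epoch >= 25


def test_history_is_deterministic_and_lr_trace_matches_schedule():
    windows = _toy_windows()
    cfg = TrainConfig(max_epochs=6, early_stop_patience=6, lr_halving_period=2, seed=5)
    _, h1 = train_submodel(windows, _toy_split(windows), _TOY_CFG, cfg)
    _, h2 = train_submodel(windows, _toy_split(windows), _TOY_CFG, cfg)
    assert h1.train_loss == h2.train_loss and h1.val_loss == h2.val_loss
    assert h1.learning_rate == [lr_at_epoch(e, cfg) for e in range(len(h1.learning_rate))]


def test_gradient_clipping_bounds_every_step():
    windows = _toy_windows(separation=8.0)
    seen = []
    cfg = TrainConfig(max_epochs=4, early_stop_patience=4, seed=2)
    train_submodel(
        windows, _toy_split(windows), _TOY_CFG, cfg,
        grad_hook=lambda step, pre, post: seen.append((pre, post)),
    )
    assert seen, "hook must fire"
    assert all(post <= cfg.grad_clip + 1e-6 for _, post in seen)
    assert any(pre > cfg.grad_clip for pre, _ in seen)  # clipping was actually exercised


def test_single_class_training_labels_rejected():
    windows = [w for w in _toy_windows() if w.label == 1]
    with pytest.raises(DegenerateLabelError):
        train_submodel(
            windows, _toy_split(windows), _TOY_CFG,
            TrainConfig(max_epochs=2, early_stop_patience=2),
        )


def test_train_all_horizons_registry():
    windows = _toy_windows(n=30)
    plan_ids = [w.encounter_id for w in windows]
    from teco.training import make_splits as ms

    plan = ms(plan_ids, n_splits=2, seed=3)
    cfg = TrainConfig(max_epochs=2, early_stop_patience=2, seed=11)
    wbh = {0: windows, 24: windows}
    reg1 = train_all_horizons(wbh, plan, _TOY_CFG, cfg)
    assert len(reg1) == 4
    assert set(reg1.keys()) == {(0, 0), (0, 1), (24, 0), (24, 1)}
    entry = reg1.get(24, 1)
    assert entry.n_train_windows == len(set(plan.splits[1][0]))
    reg2 = train_all_horizons(wbh, plan, _TOY_CFG, cfg)
    assert reg1.hashes() == reg2.hashes()
    for key in reg1.keys():
        h, s = key
        np.testing.assert_array_equal(
            reg1.get(h, s).model.params["embed_W"].data,
            reg2.get(h, s).model.params["embed_W"].data,
        )
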