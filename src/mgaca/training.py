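"""Training protocol: split, batch generation, schedule, optimization.

The protocol follows the published setup: a 75/25 train/validation split with
random state 42, mini-batches of 32 image/mask pairs scaled to [0, 1] at
128x128, the Adam optimizer at an initial learning rate of 0.001, a
reduce-on-plateau schedule (factor 0.2, patience 2 epochs, floor 1e-5) on the
validation loss, and early stopping with patience 10 epochs. The training
objective is the combined BCE + Dice loss.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import metrics
from .masks import DatasetManifest, load_mask_image, load_slice_image, prepare_pair
from .nn import autodiff as ad
from .nn.optim import Adam


@dataclass(frozen=True)
class TrainConfig:
    split_fraction: float = 0.25      # validation share
    split_seed: int = 42
    batch_size: int = 32
    initial_lr: float = 0.001
    plateau_factor: float = 0.2
    plateau_patience: int = 2
    min_lr: float = 0.00001
    min_delta: float = 0.0
    early_stop_patience: int = 10
    max_epochs: int = 100
    global_seed: int = 0
    target_size: tuple = (128, 128)
    shuffle: bool = True

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie strictly in (0, 1)")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie strictly in (0, 1)")
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr cannot exceed initial_lr")


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray


class TrainingDiverged(RuntimeError):
    pass


def split_dataset(n_items: int, config: TrainConfig | None = None) -> SplitIndices:
    """Random train/validation split; validation gets ceil(fraction * N)."""
    config = config or TrainConfig()
    if n_items < 2:
        raise ValueError(f"need at least 2 items to split, got {n_items}")
    train_idx, val_idx = train_test_split(
        np.arange(n_items), test_size=config.split_fraction,
        random_state=config.split_seed, shuffle=True)
    return SplitIndices(train=np.asarray(train_idx),
                        validation=np.asarray(val_idx))


def load_pair(manifest: DatasetManifest, index: int, target_size):
    image_path, mask_path = manifest.entries[index][:2]
    image = load_slice_image(image_path)
    mask = load_mask_image(mask_path)
    x, y = prepare_pair(image, mask, target_size)
    return x, y[..., None].astype(np.float32)


def batch_generator(manifest: DatasetManifest, indices,
                    config: TrainConfig | None = None, rng=None,
                    shuffle: bool | None = None):
    """Yield (image batch, mask batch) arrays for one epoch.

    Images are float32 in [0, 1] with shape (<=B, h, w, 3); masks are binary
    float32 with shape (<=B, h, w, 1). Order is reshuffled per epoch by the
    caller-supplied rng when shuffling is enabled.
    """
    config = config or TrainConfig()
    if shuffle is None:
        shuffle = config.shuffle
    indices = np.asarray(indices)
    if shuffle:
        rng = rng or np.random.default_rng(config.global_seed)
        indices = rng.permutation(indices)
    for start in range(0, len(indices), config.batch_size):
        chunk = indices[start:start + config.batch_size]
        xs, ys = zip(*(load_pair(manifest, int(i), config.target_size)
                       for i in chunk))
        yield np.stack(xs), np.stack(ys)


def bce_dice_loss_var(truth: ad.Var, probs: ad.Var,
                      eps: float = metrics.DICE_EPS,
                      clip: float = metrics.BCE_CLIP) -> ad.Var:
    """Differentiable combined BCE + soft-Dice loss on the autodiff graph."""
    pc = ad.clip(probs, clip, 1.0 - clip)
    bce = -ad.mean_all(ad.mul(truth, ad.log(pc))
                       + ad.mul(1.0 - truth, ad.log(1.0 - pc)))
    inter = ad.sum_all(ad.mul(truth, probs))
    dice = 1.0 - (2.0 * inter + eps) / (ad.sum_all(truth)
                                        + ad.sum_all(probs) + eps)
    return bce + dice


class PlateauScheduler:
    """Reduce the learning rate by `factor` after `patience` epochs without
    improvement of the monitored loss, clamped at `min_lr`."""

    def __init__(self, initial_lr, factor=0.2, patience=2, min_lr=1e-5,
                 min_delta=0.0):
        self.lr = float(initial_lr)
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.min_delta = min_delta
        self.best = np.inf
        self.wait = 0

    def step(self, monitored_loss: float) -> float:
        if monitored_loss < self.best - self.min_delta:
            self.best = monitored_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait > self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.wait = 0
        return self.lr


def lr_schedule_step(recent_val_losses, current_lr,
                     config: TrainConfig | None = None) -> float:
    """Stateless plateau rule: reduce when the tail of the loss stream shows
    no improvement for more than `plateau_patience` epochs."""
    config = config or TrainConfig()
    losses = list(recent_val_losses)
    window = config.plateau_patience + 1
    if len(losses) < window + 1:
        return current_lr
    best_before = min(losses[:-window])
    if min(losses[-window:]) < best_before - config.min_delta:
        return current_lr
    return max(current_lr * config.plateau_factor, config.min_lr)


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)  # dicts per epoch
    best_epoch: int = -1
    stopped_epoch: int = -1
    best_state: dict | None = None

    def column(self, key):
        return [e[key] for e in self.epochs]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.epochs)


def _as_batches(data, config, rng, shuffle, training):
    """Normalize (X, Y) arrays or (manifest, indices) into batch streams."""
    if isinstance(data, tuple) and isinstance(data[0], np.ndarray):
        x, y = data
        idx = np.arange(len(x))
        if shuffle:
            idx = rng.permutation(idx)
        for start in range(0, len(idx), config.batch_size):
            sel = idx[start:start + config.batch_size]
            yield x[sel], y[sel]
    else:
        manifest, indices = data
        yield from batch_generator(manifest, indices, config, rng=rng,
                                   shuffle=shuffle)


def _dataset_loss(net, data, config, rng):
    """Mean per-batch combined loss in inference mode."""
    losses, weights = [], []
    for xb, yb in _as_batches(data, config, rng, shuffle=False, training=False):
        probs = net.forward(xb, training=False)
        losses.append(float(bce_dice_loss_var(ad.constant(yb), probs).data))
        weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def train(net, train_data, config: TrainConfig | None = None, val_data=None,
          n_steps: int | None = None, verbose: bool = False) -> TrainingHistory:
    """Optimize the combined BCE + Dice loss with Adam.

    ``train_data`` (and optional ``val_data``) is either an ``(X, Y)`` array
    pair or a ``(manifest, indices)`` pair. The plateau schedule and early
    stopping monitor the validation loss (training loss when no validation
    data is given). ``n_steps`` caps the total number of optimizer steps,
    for short mechanism checks.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.global_seed)
    optimizer = Adam(net.parameters(), lr=config.initial_lr)
    scheduler = PlateauScheduler(config.initial_lr, config.plateau_factor,
                                 config.plateau_patience, config.min_lr,
                                 config.min_delta)
    history = TrainingHistory()
    best_loss = np.inf
    wait = 0
    steps_done = 0

    for epoch in range(config.max_epochs):
        epoch_losses, epoch_sizes = [], []
        for xb, yb in _as_batches(train_data, config, rng, shuffle=config.shuffle,
                                  training=True):
            optimizer.zero_grad()
            probs = net.forward(xb, training=True)
            loss = bce_dice_loss_var(ad.constant(yb), probs)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {steps_done} "
                    f"(lr={optimizer.lr:g})")
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
            epoch_sizes.append(len(xb))
            steps_done += 1
            if n_steps is not None and steps_done >= n_steps:
                break
        train_loss = float(np.average(epoch_losses, weights=epoch_sizes))
        if val_data is not None:
            monitored = _dataset_loss(net, val_data, config, rng)
        else:
            monitored = train_loss
        record = {"epoch": epoch, "train_loss": train_loss,
                  "val_loss": monitored, "lr": optimizer.lr}
        history.epochs.append(record)
        if verbose:
            print(f"epoch {epoch}: train {train_loss:.4f} "
                  f"monitored {monitored:.4f} lr {optimizer.lr:g}")
        if monitored < best_loss - config.min_delta:
            best_loss = monitored
            history.best_epoch = epoch
            history.best_state = copy.deepcopy(net.state_dict())
            wait = 0
        else:
            wait += 1
        optimizer.lr = scheduler.step(monitored)
        if n_steps is not None and steps_done >= n_steps:
            history.stopped_epoch = epoch
            break
        if wait >= config.early_stop_patience:
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = config.max_epochs - 1
    if history.best_state is not None:
        net.load_state_dict(history.best_state)
    return history
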