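"""Training recipe: l1 loss, Adam, whole-volume batches.

The reference recipe minimises the mean-absolute (l1) difference between the
network output and the high-resolution ground truth with Adam at learning
rate 1e-3, batches of two whole volumes, for 200 epochs.  Desk-scale runs
use the same loop with smaller volumes, fewer epochs and a smaller network,
set through :class:`TrainConfig` — the recipe itself is unchanged.  An l2
(mean-squared) objective is available as the comparator loss.

Whole volumes are batched (no patch extraction); gradients of the batch
members are averaged.  All shuffling and weight initialization is seeded, so
a run is exactly reproducible from (dataset, configs, seed) on one platform.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .dataset import PairedDataset
from .model import Network, NetworkConfig, build_network
from .nn import Adam
from .volume import Volume

__all__ = ["TrainConfig", "TrainReport", "l1_loss", "l2_loss", "fit"]

_F32 = np.float32


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_volumes: int = 2
    loss: str = "l1"
    seed: int = 0
    validation_fraction: float = 0.0
    checkpoint_every: int = 0  # 0 = only final
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.batch_volumes < 1:
            raise ValueError(f"batch_volumes must be >= 1, got {self.batch_volumes}")
        if self.loss not in ("l1", "l2"):
            raise ValueError(f"loss must be 'l1' or 'l2', got {self.loss!r}")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError(f"validation_fraction must be in [0, 1), got {self.validation_fraction}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainReport:
    config: dict
    net_config: dict
    epoch_loss: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    wall_time_s: float = 0.0
    checkpoint_path: str | None = None
    train_item_ids: list[str] = field(default_factory=list)
    val_item_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(str(path), "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")


def l1_loss(pred, truth) -> float:
    """Mean absolute voxel difference."""
    a = pred.data if isinstance(pred, Volume) else np.asarray(pred)
    b = truth.data if isinstance(truth, Volume) else np.asarray(truth)
    _check_shapes(a, b)
    return float(np.mean(np.abs(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))))


def l2_loss(pred, truth) -> float:
    """Mean squared voxel difference (the comparator objective)."""
    a = pred.data if isinstance(pred, Volume) else np.asarray(pred)
    b = truth.data if isinstance(truth, Volume) else np.asarray(truth)
    _check_shapes(a, b)
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return float(np.mean(d * d))


def _loss_and_grad(loss: str, pred: np.ndarray, truth: np.ndarray):
    d = pred.astype(np.float64) - truth.astype(np.float64)
    n = d.size
    if loss == "l1":
        return float(np.mean(np.abs(d))), (np.sign(d) / n).astype(_F32)
    return float(np.mean(d * d)), (2.0 * d / n).astype(_F32)


def fit(
    dataset: PairedDataset,
    net_config: NetworkConfig,
    train_config: TrainConfig,
    *,
    checkpoint_path=None,
) -> tuple[Network, TrainReport]:
    """Train a network on paired (low, high) volumes.

    The held-out validation split (``validation_fraction`` of the items,
    chosen by a seeded permutation) is scored with SSIM and MSE after every
    epoch.  Aborts with a diagnostic if the loss turns non-finite.
    """
    from .metrics import mse as _mse
    from .metrics import ssim as _ssim

    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    shapes = {it.lr.shape for it in dataset} | {it.hr.shape for it in dataset}
    if len(shapes) != 1:
        raise ValueError(f"dataset pairs are not shape-consistent: {sorted(shapes)}")

    rng = np.random.default_rng(train_config.seed)
    n = len(dataset)
    n_val = int(round(train_config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx = sorted(perm[:n_val].tolist())
    train_idx = sorted(perm[n_val:].tolist())
    if not train_idx:
        raise ValueError("validation_fraction leaves no training items")

    net = build_network(net_config)
    opt = Adam(
        net.params(),
        lr=train_config.learning_rate,
        beta1=train_config.beta1,
        beta2=train_config.beta2,
        eps=train_config.eps,
    )
    report = TrainReport(
        config=train_config.to_dict(),
        net_config=net_config.to_dict(),
        train_item_ids=[dataset[i].item_id for i in train_idx],
        val_item_ids=[dataset[i].item_id for i in val_idx],
    )

    t0 = time.perf_counter()
    for epoch in range(train_config.epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_volumes):
            batch = order[start : start + train_config.batch_volumes]
            net.zero_grad()
            batch_loss = 0.0
            for j in batch:
                item = dataset[int(j)]
                out = net.forward(np.asarray(item.lr.data, dtype=_F32))
                loss, g = _loss_and_grad(train_config.loss, out, np.asarray(item.hr.data, dtype=_F32))
                net.backward(g / len(batch))
                batch_loss += loss / len(batch)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // train_config.batch_volumes}"
                )
            opt.step()
            epoch_losses.append(batch_loss)
        report.epoch_loss.append(float(np.mean(epoch_losses)))

        if val_idx:
            ssims, mses = [], []
            for j in val_idx:
                item = dataset[int(j)]
                sr = net.apply(np.asarray(item.lr.data, dtype=_F32)).astype(np.float64)
                ssims.append(_ssim(Volume(sr, item.hr.spacing), item.hr))
                mses.append(_mse(Volume(sr, item.hr.spacing), item.hr))
            report.val_ssim.append(float(np.mean(ssims)))
            report.val_mse.append(float(np.mean(mses)))

        if (
            checkpoint_path is not None
            and train_config.checkpoint_every
            and (epoch + 1) % train_config.checkpoint_every == 0
        ):
            net.provenance = {"train_item_ids": report.train_item_ids, "epoch": epoch + 1}
            net.save(checkpoint_path)

    report.wall_time_s = time.perf_counter() - t0
    net.provenance = {
        "train_item_ids": report.train_item_ids,
        "epochs": train_config.epochs,
        "train_seed": train_config.seed,
    }
    if checkpoint_path is not None:
        net.save(checkpoint_path)
        report.checkpoint_path = str(checkpoint_path)
    return net, report
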