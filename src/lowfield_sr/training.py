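"""Patch-based supervised training of the super-resolution network.

The network learns the inverse of the k-space degradation from aligned
patch pairs: noisy 16x16 low-resolution inputs against noise-free 32x32
high-resolution targets. Mean-squared error is the default objective;
l1 and HFEN (high-frequency error norm — the relative l2 norm of the
Laplacian-of-Gaussian filtered difference, emphasizing edges) are available
as alternatives. Optimization is Adam with a fixed learning rate; the model
returned is the checkpoint with the smallest validation loss.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import ModelConfig, SRDenseNet
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "PatchDataset",
    "log_kernel",
    "loss_value",
    "loss_and_grad",
    "train",
    "select_best_epoch",
    "save_checkpoint",
    "load_checkpoint",
]

LOSSES = ("mse", "l1", "hfen")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults mirror the reference protocol: Adam at learning rate 1e-3,
    batches of 20 patch pairs, MSE objective, best-on-validation selection
    over up to 74 epochs.
    """

    loss: str = "mse"
    learning_rate: float = 1e-3
    batch_size: int = 20
    max_epochs: int = 74
    seed: int = 0
    checkpoint_every: int = 0
    patience: int | None = None
    hfen_kernel_size: int = 15
    hfen_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}, got {self.loss!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class PatchDataset:
    """Training and validation patch pairs as (n, h, w) arrays."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray

    def __post_init__(self) -> None:
        if len(self.X_train) != len(self.y_train) or len(self.X_val) != len(self.y_val):
            raise ValueError("input/target lengths differ")


@dataclass
class TrainHistory:
    """One record per completed epoch plus a config echo."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.val_loss)

    @property
    def best_epoch(self) -> int:
        return select_best_epoch(self)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": np.arange(len(self.val_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "wall_time_s": self.wall_time,
            }
        ).to_csv(path, index=False)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(
            yaml.safe_dump(
                {
                    "seed": self.seed,
                    "config": self.config,
                    "train_loss": [float(x) for x in self.train_loss],
                    "val_loss": [float(x) for x in self.val_loss],
                    "wall_time_s": [float(x) for x in self.wall_time],
                },
                sort_keys=True,
            )
        )


# -- losses -------------------------------------------------------------------


def log_kernel(size: int = 15, sigma: float = 1.5) -> np.ndarray:
    """Laplacian-of-Gaussian kernel, mean-subtracted so it annihilates constants."""
    if size < 3 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    r = np.arange(size) - size // 2
    xx, yy = np.meshgrid(r, r)
    r2 = xx**2 + yy**2
    s2 = sigma**2
    k = -(1.0 / (np.pi * s2**2)) * (1.0 - r2 / (2 * s2)) * np.exp(-r2 / (2 * s2))
    return k - k.mean()


def _sym_pad_filter(x: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Correlate each image of a (..., H, W) stack with symmetric padding."""
    from scipy.ndimage import correlate

    flat = x.reshape(-1, x.shape[-2], x.shape[-1])
    out = np.empty_like(flat, dtype=float)
    for i, img in enumerate(flat):
        out[i] = correlate(img.astype(float), kern, mode="reflect")
    return out.reshape(x.shape)


def _sym_pad_filter_adjoint(g: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_sym_pad_filter` (pad-then-correlate transposed).

    The adjoint of valid correlation is full convolution, and the adjoint of
    symmetric padding folds padded borders back onto their mirror sources.
    """
    from scipy.signal import convolve2d

    p = kern.shape[0] // 2
    H, W = g.shape[-2], g.shape[-1]
    # index map of symmetric padding: padded index -> source index
    idx_r = np.pad(np.arange(H), p, mode="symmetric")
    idx_c = np.pad(np.arange(W), p, mode="symmetric")
    flat = g.reshape(-1, H, W)
    out = np.zeros_like(flat, dtype=float)
    for i, img in enumerate(flat):
        full = convolve2d(img.astype(float), kern, mode="full")  # (H+2p, W+2p)
        np.add.at(out[i], (idx_r[:, None], idx_c[None, :]), full)
    return out.reshape(g.shape)


def _check_pair(prediction: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(prediction, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {t.shape}")
    return p, t


def loss_value(
    kind: str,
    prediction: np.ndarray,
    target: np.ndarray,
    hfen_kernel_size: int = 15,
    hfen_sigma: float = 1.5,
) -> float:
    """Evaluate a training objective on matching prediction/target stacks."""
    return loss_and_grad(kind, prediction, target, hfen_kernel_size, hfen_sigma)[0]


def loss_and_grad(
    kind: str,
    prediction: np.ndarray,
    target: np.ndarray,
    hfen_kernel_size: int = 15,
    hfen_sigma: float = 1.5,
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the prediction."""
    p, t = _check_pair(prediction, target)
    d = p - t
    n = d.size
    if kind == "mse":
        return float(np.mean(d**2)), 2.0 * d / n
    if kind == "l1":
        return float(np.mean(np.abs(d))), np.sign(d) / n
    if kind == "hfen":
        kern = log_kernel(hfen_kernel_size, hfen_sigma)
        ld = _sym_pad_filter(d, kern)
        lt = _sym_pad_filter(t, kern)
        denom = float(np.linalg.norm(lt.ravel()))
        num = float(np.linalg.norm(ld.ravel()))
        if denom == 0.0:
            raise ValueError("HFEN undefined: LoG of target is identically zero")
        if num == 0.0:
            return 0.0, np.zeros_like(d)
        grad = _sym_pad_filter_adjoint(ld, kern) / (num * denom)
        return num / denom, grad
    raise ValueError(f"unknown loss kind {kind!r}")


# -- training loop --------------------------------------------------------------


def _epoch_loss(model: SRDenseNet, X, y, cfg: TrainConfig) -> float:
    """Mean loss over a patch set (no parameter updates)."""
    total, count = 0.0, 0
    for i in range(0, len(X), cfg.batch_size):
        xb, yb = X[i : i + cfg.batch_size], y[i : i + cfg.batch_size]
        pred = model.forward(xb)
        v = loss_value(cfg.loss, pred[:, 0], yb, cfg.hfen_kernel_size, cfg.hfen_sigma)
        total += v * len(xb)
        count += len(xb)
    return total / count


def train(
    model: SRDenseNet,
    dataset: PatchDataset,
    cfg: TrainConfig | None = None,
    checkpoint_dir: str | Path | None = None,
) -> tuple[SRDenseNet, TrainHistory]:
    """Train on shuffled patch batches; return the best-on-validation model.

    One epoch is one seeded-shuffled pass over the training patches. After
    each epoch the validation loss is recorded; on return the model carries
    the weights of the epoch with the smallest validation loss (earliest on
    ties). Bit-reproducible given the config seed on a fixed device.
    """
    cfg = cfg or TrainConfig()
    if len(dataset.X_train) == 0 or len(dataset.X_val) == 0:
        raise ValueError("train and validation patch sets must be non-empty")
    history = TrainHistory(seed=cfg.seed, config={**asdict(cfg), "model": asdict(model.cfg)})
    if cfg.max_epochs == 0:
        return model, history

    X, y = np.asarray(dataset.X_train, np.float32), np.asarray(dataset.y_train, np.float32)
    Xv, yv = np.asarray(dataset.X_val, np.float32), np.asarray(dataset.y_val, np.float32)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    t0 = time.perf_counter()

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X))
        total, count = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            out = model.forward_node(X[idx])
            v, g = loss_and_grad(
                cfg.loss, out.value[..., 0], y[idx], cfg.hfen_kernel_size, cfg.hfen_sigma
            )
            if not np.isfinite(v):
                raise RuntimeError(
                    f"non-finite {cfg.loss} loss ({v}) at epoch {epoch}, step {i // cfg.batch_size}"
                )
            opt.zero_grad()
            out.backward(g[..., None].astype(np.float32))
            opt.step()
            del out  # release the tape before building the next one
            total += v * len(idx)
            count += len(idx)
        val = _epoch_loss(model, Xv, yv, cfg)
        history.train_loss.append(total / count)
        history.val_loss.append(val)
        history.wall_time.append(time.perf_counter() - t0)
        if val < best_val:
            best_val = val
            best_state = model.state_dict()
            best_epoch = epoch
        if checkpoint_dir and cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(
                Path(checkpoint_dir) / f"epoch{epoch:04d}.npz", model, cfg, epoch, history, opt
            )
        if cfg.patience is not None and epoch - best_epoch >= cfg.patience:
            break

    model.load_state_dict(best_state)
    return model, history


def select_best_epoch(history: TrainHistory) -> int:
    """Index of the epoch with minimal validation loss; earliest wins ties."""
    if len(history.val_loss) == 0:
        raise ValueError("empty training history")
    return int(np.argmin(history.val_loss))


# -- checkpoints -----------------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    model: SRDenseNet,
    cfg: TrainConfig,
    epoch: int,
    history: TrainHistory,
    opt: Adam | None = None,
) -> None:
    """Single-file archive: config echo, weights, optimizer state, loss history."""
    payload = {
        "meta": json.dumps(
            {
                "model_config": asdict(model.cfg),
                "train_config": asdict(cfg),
                "epoch": epoch,
                "seed": model.seed,
                "val_loss": [float(v) for v in history.val_loss],
                "train_loss": [float(v) for v in history.train_loss],
            }
        )
    }
    for k, v in model.state_dict().items():
        payload[f"param/{k}"] = v
    if opt is not None:
        payload["opt/t"] = np.array(opt.t)
        for i, (m, v) in enumerate(zip(opt.m, opt.v)):
            payload[f"opt/m{i}"] = m
            payload[f"opt/v{i}"] = v
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[SRDenseNet, dict]:
    """Rebuild the model from a checkpoint; returns (model, metadata)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        state = {k[len("param/") :]: z[k] for k in z.files if k.startswith("param/")}
    mcfg = dict(meta["model_config"])
    model = SRDenseNet(ModelConfig(**mcfg), seed=meta.get("seed", 0))
    model.load_state_dict(state)
    return model, meta
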