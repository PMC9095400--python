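"""Supervised desk-scale training of the learned denoisers.

Networks are fitted by mini-batch gradient descent (Adam by default) on
an MSE loss.  Residual-learning models (the improved UNet) are trained
against the noise map ``e = b - a``; direct-prediction models (plain
UNet, flat CNN) against the clean image ``b``.  All pixel values are on
the [0, 1] scale inside the network.

Runs are fully reproducible: parameter initialisation, data order and
crop positions are all derived from the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .metrics import psnr
from .models import DenoiserModel, denoise_batch
from .nn import functional as F
from .phantom import NoisySample

__all__ = ["TrainConfig", "TrainResult", "train", "validation_psnr"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    loss: str = "auto"          # mse_on_residual | mse_on_image | auto
    optimizer: str = "adam"     # adam | sgd
    seed: int = 0
    patch_size: int = 32        # training crop side; full images if larger

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.loss not in ("auto", "mse_on_residual", "mse_on_image"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    model: DenoiserModel
    loss_history: list[float] = field(default_factory=list)
    val_psnr_history: list[float] = field(default_factory=list)


def _resolve_loss(model: DenoiserModel, config: TrainConfig) -> str:
    if config.loss != "auto":
        want_residual = config.loss == "mse_on_residual"
        if want_residual != model.residual_learning:
            raise ValueError(
                f"loss {config.loss!r} does not match the model's "
                f"{'residual' if model.residual_learning else 'direct'} "
                "prediction mode")
        return config.loss
    return "mse_on_residual" if model.residual_learning else "mse_on_image"


def _stack(samples, idx, rng, patch: int):
    """Assemble (noisy, target-clean) [0,1] batches with random crops."""
    xs, ys = [], []
    for i in idx:
        a = samples[i].noisy.pixels
        b = samples[i].clean.pixels
        h, w = a.shape
        if patch < min(h, w):
            r = int(rng.integers(0, h - patch + 1))
            c = int(rng.integers(0, w - patch + 1))
            a = a[r:r + patch, c:c + patch]
            b = b[r:r + patch, c:c + patch]
        xs.append(a)
        ys.append(b)
    peak = samples[0].clean.peak
    return (np.stack(xs)[:, None] / peak, np.stack(ys)[:, None] / peak)


def validation_psnr(model: DenoiserModel, samples, idx) -> float:
    """Mean PSNR of the model's clean estimates on the given samples."""
    outs = denoise_batch(model, [samples[i].noisy for i in idx])
    vals = [psnr(out, samples[i].clean) for out, i in zip(outs, idx)]
    return float(np.mean(vals))


def train(model: DenoiserModel, samples: list[NoisySample],
          config: TrainConfig, train_idx=None, val_idx=None) -> TrainResult:
    """Fit ``model`` in place and return it with per-epoch histories.

    ``train_idx``/``val_idx`` default to an 80/20 head/tail split.  A
    final check that validation PSNR beats the noisy input's PSNR is
    logged as a quality gate (warning on failure, never an error).
    """
    if not samples:
        raise ValueError("dataset must be non-empty")
    n = len(samples)
    if train_idx is None or val_idx is None:
        n_val = max(1, int(round(0.2 * n))) if n > 1 else 0
        train_idx = list(range(n - n_val))
        val_idx = list(range(n - n_val, n))
    loss_kind = _resolve_loss(model, config)

    params = model.net.parameters()
    if config.optimizer == "adam":
        opt = nn.Adam(params, lr=config.learning_rate)
    else:
        opt = nn.SGD(params, lr=config.learning_rate)

    rng = np.random.default_rng(config.seed)
    result = TrainResult(model=model)
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_idx[k] for k in order[start:start + config.batch_size]]
            xb, yb = _stack(samples, batch, rng, config.patch_size)
            xt = nn.Tensor(xb)
            out = model.net(xt)
            if loss_kind == "mse_on_residual":
                loss = F.mse_loss(out, yb - xb)     # target: e = b - a
            else:
                loss = F.mse_loss(out, yb)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {lval}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(lval)
        result.loss_history.append(float(np.mean(epoch_losses)))
        if val_idx:
            result.val_psnr_history.append(
                validation_psnr(model, samples, val_idx))
        log.info("epoch %d/%d loss=%.6f val_psnr=%s", epoch + 1,
                 config.epochs, result.loss_history[-1],
                 f"{result.val_psnr_history[-1]:.3f}" if val_idx else "n/a")

    model.trained = True
    if val_idx:
        noisy_psnr = float(np.mean(
            [psnr(samples[i].noisy, samples[i].clean) for i in val_idx]))
        if result.val_psnr_history[-1] < noisy_psnr:
            log.warning("quality gate: validation PSNR %.3f below noisy-input "
                        "PSNR %.3f", result.val_psnr_history[-1], noisy_psnr)
        else:
            log.info("quality gate passed: %.3f dB vs noisy %.3f dB",
                     result.val_psnr_history[-1], noisy_psnr)
    return result
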