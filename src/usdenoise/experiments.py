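"""The repository's pinned desk-scale experiment.

One reproducible end-to-end run sized for a single CPU: a 200-phantom
64x64 speckle corpus at noise level sigma = 1.0, 30 training epochs for
each learned denoiser (improved UNet, plain UNet, flat CNN), followed by
the four-method x five-sigma benchmark grids on a fresh 50-image
evaluation corpus.  All sub-seeds derive from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .benchmark import (DEFAULT_SIGMAS, BenchmarkTable,
                        paired_bootstrap_delta, run_benchmark)
from .metrics import psnr
from .models import (ArchitectureSpec, DenoiserModel, build_model,
                     build_plain_cnn, build_plain_unet)
from .phantom import NoiseSpec, make_dataset
from .training import TrainConfig, TrainResult, train, validation_psnr

__all__ = ["DeskScaleRun", "desk_scale_training", "benchmark_grids"]

log = logging.getLogger(__name__)

TRAIN_SIGMA = 1.0
N_TRAIN_IMAGES = 200
N_EPOCHS = 30
N_EVAL_IMAGES = 50


@dataclass
class DeskScaleRun:
    """Trained models plus the validation summary of the pinned run."""

    models: dict[str, DenoiserModel]
    results: dict[str, TrainResult]
    noisy_val_psnr: float
    val_psnr: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def desk_scale_training(seed: int = 0, epochs: int = N_EPOCHS,
                        n_images: int = N_TRAIN_IMAGES,
                        sigma: float = TRAIN_SIGMA,
                        noise_model: str = "multiplicative_speckle",
                        methods=("improved_unet", "unet", "cnn")) -> DeskScaleRun:
    """Train the learned denoisers under the pinned study conditions."""
    data_seed, init_a, init_b, init_c, train_seed = _subseeds(seed, 5)
    noise = NoiseSpec(model=noise_model, sigma=sigma)
    samples, tr, va = make_dataset(n_images, noise, seed=data_seed)
    noisy_val = float(np.mean(
        [psnr(samples[i].noisy, samples[i].clean) for i in va]))

    builders = {
        "improved_unet": lambda: build_model(
            ArchitectureSpec.improved_unet(2, 8, init_seed=init_a)),
        "unet": lambda: build_plain_unet(2, 8, init_seed=init_b),
        "cnn": lambda: build_plain_cnn(5, 16, init_seed=init_c),
    }
    run = DeskScaleRun(models={}, results={}, noisy_val_psnr=noisy_val,
                       seed=seed)
    for name in methods:
        model = builders[name]()
        cfg = TrainConfig(epochs=epochs, seed=train_seed)
        log.info("desk-scale training: %s (%d params)", name,
                 model.n_parameters())
        res = train(model, samples, cfg, tr, va)
        run.models[name] = model
        run.results[name] = res
        run.val_psnr[name] = validation_psnr(model, samples, va)
    return run


def benchmark_grids(run: DeskScaleRun, sigmas=DEFAULT_SIGMAS,
                    n_images: int = N_EVAL_IMAGES,
                    include_identity: bool = True,
                    noise_model: str = "multiplicative_speckle"
                    ) -> tuple[BenchmarkTable, BenchmarkTable]:
    """Four-method grids (plus the identity floor) on a fresh corpus.

    The evaluation corpus seed is derived from the run seed but distinct
    from the training corpus seed, so train and eval phantoms are
    disjoint.  The trained checkpoints are shared across sigmas.
    """
    methods = ["nlmeans"] + list(run.models)
    if include_identity:
        methods = ["identity"] + methods
    eval_seed = _subseeds(run.seed + 1, 1)[0]
    pt, st = run_benchmark(methods, sigmas, n_images=n_images,
                           seed=eval_seed, checkpoints=dict(run.models),
                           noise=NoiseSpec(model=noise_model))
    # the improved-vs-plain ordering is training-dependent at desk scale:
    # report it with a paired bootstrap interval instead of asserting it
    if {"improved_unet", "unet"} <= set(pt.methods):
        for sigma in pt.sigmas:
            delta, (lo, hi) = paired_bootstrap_delta(
                pt, "improved_unet", "unet", sigma, seed=eval_seed)
            log.info("improved_unet - unet PSNR at sigma=%.1f: %+.3f dB "
                     "(95%% CI %+.3f .. %+.3f)", sigma, delta, lo, hi)
    return pt, st
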