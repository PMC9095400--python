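"""Benchmark harness: method x noise-level PSNR/SSIM grids.

Reproduces the *structure* of the standard comparison — four denoising
methods (NL-means, flat CNN, plain UNet, improved UNet) evaluated at
five noise standard deviations (0.5, 1, 1.5, 2, 2.5) — on a synthetic
phantom corpus.  An ``identity`` pseudo-method (no denoising) is
available as a floor reference.  PSNR and SSIM grids are computed from
the same cached denoised outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import psnr, ssim
from .models import DenoiserModel, denoise_batch
from .nlmeans import NLMeansParams, nl_means
from .phantom import NoiseSpec, PhantomSpec, make_dataset

__all__ = [
    "DEFAULT_SIGMAS", "BenchmarkTable", "run_benchmark",
    "write_table", "read_table", "paired_bootstrap_delta",
]

log = logging.getLogger(__name__)

DEFAULT_SIGMAS = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass
class BenchmarkTable:
    """A complete methods x sigmas grid of one mean metric."""

    metric: str                       # "PSNR" | "SSIM"
    methods: list[str]
    sigmas: list[float]
    cells: np.ndarray                 # shape (len(methods), len(sigmas))
    n_images: int
    seed: int
    per_image: dict = field(default_factory=dict)   # (method, sigma) -> list

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.float64)
        if self.cells.shape != (len(self.methods), len(self.sigmas)):
            raise ValueError("cells shape does not match methods x sigmas")
        if np.any(np.isnan(self.cells)):
            raise ValueError("benchmark grid has missing cells")

    def cell(self, method: str, sigma: float) -> float:
        return float(self.cells[self.methods.index(method),
                                self.sigmas.index(sigma)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.methods,
                            columns=[str(s) for s in self.sigmas])


def _method_callable(name: str, checkpoints: dict, sigma: float,
                     noise: NoiseSpec):
    """Resolve a method name to a batch denoising callable."""
    if name == "identity":
        return lambda noisies: noisies
    if name == "nlmeans":
        if noise.model == "additive_gaussian":
            sigma_px = sigma * noise.scale
        else:
            # effective absolute noise scale for speckle on mid-grey tissue
            sigma_px = sigma * noise.mult_scale * 128.0
        params = NLMeansParams.for_noise_sigma(sigma_px)
        return lambda noisies: [nl_means(im, params) for im in noisies]
    model = checkpoints.get(name) or checkpoints.get((name, sigma))
    if model is None:
        raise KeyError(f"no checkpoint for method {name!r} at sigma {sigma}")
    return lambda noisies, m=model: denoise_batch(m, noisies)


def run_benchmark(methods: list[str], sigmas=DEFAULT_SIGMAS,
                  n_images: int = 50, seed: int = 0,
                  checkpoints: dict[str, DenoiserModel] | None = None,
                  noise: NoiseSpec | None = None,
                  phantom_spec: PhantomSpec | None = None,
                  ssim_mode: str = "global"):
    """Evaluate each method at each sigma on a fresh evaluation corpus.

    ``checkpoints`` maps a learned method name (or ``(name, sigma)``
    pair for per-sigma models) to a trained :class:`DenoiserModel`.
    The corpus clean images are shared across sigmas; noise is redrawn
    per sigma from seeds derived from ``seed``.  Returns
    ``(psnr_table, ssim_table)`` computed from the same outputs.
    """
    checkpoints = checkpoints or {}
    noise = noise or NoiseSpec()
    sigmas = list(sigmas)
    p_cells = np.full((len(methods), len(sigmas)), np.nan)
    s_cells = np.full_like(p_cells, np.nan)
    per_image_p: dict = {}
    per_image_s: dict = {}

    master = np.random.default_rng(seed)
    sigma_seeds = master.integers(0, 2 ** 31 - 1, size=len(sigmas))
    for j, sigma in enumerate(sigmas):
        nspec = replace(noise, sigma=sigma, seed=int(sigma_seeds[j]))
        samples, _, _ = make_dataset(n_images, nspec, seed=seed,
                                     phantom_spec=phantom_spec)
        noisies = [s.noisy for s in samples]
        cleans = [s.clean for s in samples]
        for i, name in enumerate(methods):
            fn = _method_callable(name, checkpoints, sigma, noise)
            outs = fn(noisies)
            pv = [psnr(o, c) for o, c in zip(outs, cleans)]
            sv = [ssim(o, c, mode=ssim_mode) for o, c in zip(outs, cleans)]
            p_cells[i, j] = np.mean(pv)
            s_cells[i, j] = np.mean(sv)
            per_image_p[(name, sigma)] = pv
            per_image_s[(name, sigma)] = sv
            log.info("benchmark: %s @ sigma=%.2f PSNR=%.3f SSIM=%.4f",
                     name, sigma, p_cells[i, j], s_cells[i, j])

    pt = BenchmarkTable("PSNR", list(methods), sigmas, p_cells, n_images,
                        seed, per_image_p)
    st = BenchmarkTable("SSIM", list(methods), sigmas, s_cells, n_images,
                        seed, per_image_s)
    return pt, st


def paired_bootstrap_delta(table: BenchmarkTable, method_a: str,
                           method_b: str, sigma: float, n_boot: int = 2000,
                           seed: int = 0, alpha: float = 0.05):
    """Bootstrap CI for the per-image mean difference (a - b) at one sigma."""
    va = np.asarray(table.per_image[(method_a, sigma)])
    vb = np.asarray(table.per_image[(method_b, sigma)])
    diff = va - vb
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diff), size=(n_boot, len(diff)))
    means = diff[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(diff.mean()), (float(lo), float(hi))


def write_table(table: BenchmarkTable, path) -> None:
    """CSV grid (method rows, sigma columns) + JSON provenance sidecar.

    Infinite PSNR cells are rendered as ``inf`` and parse back."""
    df = table.to_frame()
    df.index.name = "method"
    df.to_csv(path, float_format="%.6f")
    sidecar = {
        "metric": table.metric,
        "n_images": table.n_images,
        "seed": table.seed,
        "sigmas": table.sigmas,
        "methods": table.methods,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_table(path) -> BenchmarkTable:
    df = pd.read_csv(path, index_col=0)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    return BenchmarkTable(
        metric=sidecar["metric"],
        methods=list(df.index),
        sigmas=[float(c) for c in df.columns],
        cells=df.to_numpy(),
        n_images=sidecar["n_images"],
        seed=sidecar["seed"],
    )
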