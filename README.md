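# usdenoise

Speckle-style noise removal for 2-D grayscale ultrasound-like images,
built around a **residual-learning improved UNet**, with everything
needed to exercise and evaluate it end-to-end on synthetic data: a
cyst-phantom simulator, PSNR/SSIM metrics, classical (non-local means)
and learned (plain UNet, flat CNN) baselines, a method × noise-level
benchmark harness, and a small module for clinical outcome arithmetic
from printed group summary tables.

It is aimed at people studying denoisers for coherent-imaging noise —
where ground truth is unobtainable clinically and methods are compared
on simulated corpora with known clean references.

## The model

Noise is decomposed as

    a + e = b,

with `a` the noisy image, `b` the clean image, and `e = b − a` the
correction restoring it. The network is trained to predict the noise
map (`D(a) ≈ e`), so the clean estimate is `b̂ = a + D(a)` — residual
learning. The architecture is a UNet codec in which

- max pooling is replaced by **stride-2 convolutions** (each level
  halves H×W and doubles the channel count),
- feature extraction uses **residual blocks**: two 3×3 convolutions
  with a per-channel **PReLU** (`x ↦ x` if `x > 0`, `t_f·x` otherwise)
  between them, plus an identity skip,
- encoder features are re-injected into the decoder twice: by the usual
  concatenating skip connections *and* by an additive feature-recovery
  branch (residual block + 1×1 convolution, superimposed element-wise),
- a two-layer reconstruction head maps decoder features to the
  single-channel noise map.

Quality is scored by `PSNR = 10·log₁₀((2ⁿ−1)²/MSE)` in dB and by SSIM
`(2u_X u_Y + C₁)(2σ_XY + C₂) / ((u_X² + u_Y² + C₁)(σ_X² + σ_Y² + C₂))`.

Everything runs on a compact numpy reverse-mode autodiff engine
(`usdenoise.nn`) — no deep-learning framework required.

## Worked example

```python
from usdenoise import NoiseSpec, TrainConfig, make_dataset, psnr, train
from usdenoise.models import ArchitectureSpec, build_model, denoise

samples, tr, va = make_dataset(100, NoiseSpec(sigma=1.0, seed=0), seed=1)
model = build_model(ArchitectureSpec.improved_unet(depth=2, base_channels=8))
result = train(model, samples, TrainConfig(epochs=20, seed=3), tr, va)

held_out = samples[va[0]]
restored = denoise(model, held_out.noisy)
print(f"noisy    PSNR: {psnr(held_out.noisy, held_out.clean):.2f} dB")
print(f"restored PSNR: {psnr(restored, held_out.clean):.2f} dB")
```

This is `examples/03_denoise_improved_unet.py` (about a minute on one
CPU); it prints

```
improved UNet: 54261 parameters
loss: 0.0119 -> 0.0024
noisy    PSNR: 19.16 dB
restored PSNR: 27.23 dB
```

— the restored image is ~8 dB closer to the clean phantom than the
noisy input after even this abbreviated run. The other scripts in `examples/` cover phantom simulation
(`01`), the metrics (`02`), the NL-means baseline (`04`, ~5 dB gain
with no training), the benchmark grid (`05`) and the clinical summary
arithmetic (`06`, complication rates 8% vs 16%, total satisfaction 98%
vs 93%, hospital-stay t = −4.07, p < 1e−4).

A thin CLI wraps the same functions:

```bash
usdenoise simulate --n 100 --sigma 1.0 --model speckle --seed 42 --out corpus/
usdenoise train --config train.yaml --out model.npz
usdenoise denoise --method nlmeans --in noisy.png --out clean.png
usdenoise evaluate --ref clean.png --test denoised.png
usdenoise benchmark --out results/
usdenoise clinical-summary
```

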