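"""PSNR and SSIM on closed-form cases.

PSNR = 10 log10((2^n - 1)^2 / MSE) dB for n-bit images; SSIM combines
luminance, contrast and covariance into one similarity score in [-1, 1]
(1 only for identical images).
"""

import numpy as np

from usdenoise import mse, psnr, ssim

x = np.zeros((4, 4))
print(f"MSE = 1      -> PSNR = {psnr(x, np.ones((4, 4))):.4f} dB")   # 48.1308
print(f"MSE = 255^2  -> PSNR = {psnr(x, np.full((4, 4), 255.0)):.4f} dB")  # 0

r = np.random.default_rng(0)
a = r.uniform(0, 255, (8, 8))
print(f"SSIM(X, X)   = {ssim(a, a):.6f}")          # exactly 1
b = np.clip(a + r.normal(0, 40, a.shape), 0, 255)
print(f"SSIM(X, X+noise) = {ssim(a, b):.4f}  (global mode)")
print(f"               = {ssim(a, b, mode='windowed'):.4f}  (8x8 windows)")
print(f"hand check: MSE of the pair = {mse(a, b):.2f}")
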