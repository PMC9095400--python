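"""Generate a cyst phantom, corrupt it with speckle, inspect the triple.

The phantom mimics a B-mode view of an ovarian cyst: a dark elliptical
cavity with a few bright floaters inside, surrounded by brighter tissue
texture.  Noise follows the a + e = b convention: `a` is the noisy
image, `b` the clean one, and `e = b - a` the correction that restores
it — the quantity the residual-learning denoiser is trained to predict.
"""

import numpy as np

from usdenoise import NoiseSpec, PhantomSpec, add_noise, generate_phantom, psnr

clean = generate_phantom(PhantomSpec(seed=42))
print(f"phantom: {clean.height}x{clean.width}, "
      f"range [{clean.pixels.min():.0f}, {clean.pixels.max():.0f}]")

sample = add_noise(clean, NoiseSpec(model="multiplicative_speckle",
                                    sigma=1.0, seed=7))
residual = np.abs(sample.noisy.pixels + sample.noise - sample.clean.pixels)
print(f"max |a + e - b| = {residual.max():.2e}   (exact by construction)")
print(f"noisy-input PSNR at sigma 1.0: "
      f"{psnr(sample.noisy, sample.clean):.2f} dB")
# ~19 dB: heavy speckle. Denoisers are scored by how far above this
# floor they lift the PSNR against the known clean phantom.
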