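"""Denoising network architectures.

Three learned denoisers share one interface:

* **Improved UNet** — encoder/decoder with strided-convolution
  downsampling, residual blocks with PReLU, an additive feature-recovery
  branch (RDUB) alongside the usual concatenating skip connections, a
  multi-layer reconstruction head (Recon), and *residual learning*: the
  network predicts the noise map ``e`` and the clean estimate is
  ``b_hat = a + e_hat`` (the ``a + e = b`` convention of the phantom
  module).
* **Plain UNet** — the classic codec: 2x2 max pooling, double 3x3
  convolutions with ReLU, concatenating skip connections, direct
  prediction of the clean image.
* **Plain CNN** — a flat stack of 3x3 convolutions with no
  down/upsampling and no skips, direct prediction.

Every downsampling level halves the spatial dimensions and doubles the
channel count; inputs whose sides are not multiples of ``2**depth`` are
reflect-padded and the output cropped back (or rejected in strict mode).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .phantom import GrayImage

__all__ = [
    "ArchitectureSpec", "DenoiserModel", "ResidualBlock",
    "build_model", "build_plain_unet", "build_plain_cnn", "denoise",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class ArchitectureSpec:
    """Configuration of a UNet-style denoiser.

    ``depth`` is the number of downsampling levels; ``base_channels``
    the channel count at full resolution (doubled at each level).
    """

    depth: int = 2
    base_channels: int = 8
    downsample: str = "stride_conv"          # or "max_pool"
    use_residual_blocks: bool = True
    use_rdub: bool = True
    use_recon: bool = True
    prelu_shared: bool = False
    residual_learning: bool = True
    init_seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.downsample not in ("stride_conv", "max_pool"):
            raise ValueError(f"unknown downsample mode {self.downsample!r}")

    @classmethod
    def improved_unet(cls, depth: int = 2, base_channels: int = 8,
                      init_seed: int = 0) -> "ArchitectureSpec":
        """The full improved preset: strided conv, residual blocks, RDUB, Recon."""
        return cls(depth=depth, base_channels=base_channels,
                   downsample="stride_conv", use_residual_blocks=True,
                   use_rdub=True, use_recon=True, residual_learning=True,
                   init_seed=init_seed)

    @classmethod
    def plain_unet(cls, depth: int = 2, base_channels: int = 8,
                   init_seed: int = 0) -> "ArchitectureSpec":
        """The traditional preset: max pooling, plain blocks, direct prediction."""
        return cls(depth=depth, base_channels=base_channels,
                   downsample="max_pool", use_residual_blocks=False,
                   use_rdub=False, use_recon=False, residual_learning=False,
                   init_seed=init_seed)


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with PReLU between, plus an identity skip.

    The second convolution is zero-initialised so the block starts as
    the identity map; without this, stacks of He-initialised additive
    branches can blow the forward pass up for unlucky seeds.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 prelu_shared: bool = False):
        self.channels = channels
        self.conv1 = nn.Conv2d(channels, channels, 3, rng=rng)
        self.act = nn.PReLU(channels, shared=prelu_shared)
        self.conv2 = nn.Conv2d(channels, channels, 3, zero_init=True)

    def forward(self, x):
        if x.data.shape[1] != self.channels:
            raise ValueError(
                f"residual block expects {self.channels} channels, "
                f"got {x.data.shape[1]}")
        return x + self.conv2(self.act(self.conv1(x)))


class _ConvAct(nn.Module):
    """conv3x3 + activation (PReLU or ReLU), optionally strided."""

    def __init__(self, cin, cout, rng, stride=1, use_prelu=True,
                 prelu_shared=False):
        self.conv = nn.Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.act_prelu = nn.PReLU(cout, shared=prelu_shared) if use_prelu else None

    def forward(self, x):
        x = self.conv(x)
        return self.act_prelu(x) if self.act_prelu else F.relu(x)


class _DoubleConv(nn.Module):
    """The classic UNet block: (conv3x3 + ReLU) x 2."""

    def __init__(self, cin, cout, rng):
        self.a = _ConvAct(cin, cout, rng, use_prelu=False)
        self.b = _ConvAct(cout, cout, rng, use_prelu=False)

    def forward(self, x):
        return self.b(self.a(x))


class _MaxPoolDown(nn.Module):
    """max-pool 2x2 then a channel-doubling conv (the traditional site)."""

    def __init__(self, cin, cout, rng):
        self.conv = _ConvAct(cin, cout, rng, use_prelu=False)

    def forward(self, x):
        return self.conv(F.max_pool2x2(x))


class _RDUB(nn.Module):
    """Feature-recovery branch: residual block on the encoder map at a
    level, a 1x1 channel-matching conv, superimposed (added element-wise)
    onto the decoder map of the same level."""

    def __init__(self, channels, rng, prelu_shared=False):
        self.block = ResidualBlock(channels, rng, prelu_shared)
        # zero-init: the branch fades in during training
        self.match = nn.Conv2d(channels, channels, 1, zero_init=True)

    def forward(self, x):
        return self.match(self.block(x))


class _ReconHead(nn.Module):
    """Reconstruction head: conv3x3 (C -> C//2), PReLU, conv3x3 (-> 1)."""

    def __init__(self, channels, rng, prelu_shared=False):
        mid = max(channels // 2, 1)
        self.conv1 = nn.Conv2d(channels, mid, 3, rng=rng)
        self.act = nn.PReLU(mid, shared=prelu_shared)
        # zero-init: the predicted noise map starts at exactly zero, so a
        # freshly built residual-learning model is the identity denoiser
        self.final = nn.Conv2d(mid, 1, 3, zero_init=True)

    def forward(self, x):
        return self.final(self.act(self.conv1(x)))


class _UNet(nn.Module):
    """Shared UNet skeleton configured by an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        d = spec.depth
        ch = [spec.base_channels * 2 ** k for k in range(d + 1)]
        res = spec.use_residual_blocks
        shared = spec.prelu_shared

        def level_block(c):
            if res:
                return ResidualBlock(c, rng, shared)
            return _DoubleConv(c, c, rng)

        self.stem = _ConvAct(1, ch[0], rng, use_prelu=res, prelu_shared=shared)
        self.enc_blocks = [level_block(ch[k]) for k in range(d)]
        if spec.downsample == "stride_conv":
            self.downs = [_ConvAct(ch[k], ch[k + 1], rng, stride=2,
                                   use_prelu=res, prelu_shared=shared)
                          for k in range(d)]
        else:
            self.downs = [_MaxPoolDown(ch[k], ch[k + 1], rng) for k in range(d)]
        self.bottleneck = level_block(ch[d])
        self.upconvs = [_ConvAct(ch[k + 1], ch[k], rng, use_prelu=res,
                                 prelu_shared=shared) for k in range(d)]
        self.fuses = [_ConvAct(2 * ch[k], ch[k], rng, use_prelu=res,
                               prelu_shared=shared) for k in range(d)]
        self.dec_blocks = [level_block(ch[k]) for k in range(d)]
        self.rdubs = ([_RDUB(ch[k], rng, shared) for k in range(d)]
                      if spec.use_rdub else None)
        if spec.use_recon:
            self.head = _ReconHead(ch[0], rng, shared)
        else:
            self.head = nn.Conv2d(ch[0], 1, 3, rng=rng)

    def forward(self, x):
        d = self.spec.depth
        x = self.stem(x)
        skips = []
        for k in range(d):
            x = self.enc_blocks[k](x)
            skips.append(x)
            x = self.downs[k](x)
        x = self.bottleneck(x)
        # (H, W, C) per encoder level incl. bottleneck, for introspection
        self.last_encoder_shapes = [
            (s.data.shape[2], s.data.shape[3], s.data.shape[1]) for s in skips
        ] + [(x.data.shape[2], x.data.shape[3], x.data.shape[1])]
        for k in reversed(range(d)):
            x = self.upconvs[k](F.upsample_nearest2x(x))
            x = self.fuses[k](F.concat_channels(x, skips[k]))
            x = self.dec_blocks[k](x)
            if self.rdubs is not None:
                x = x + self.rdubs[k](skips[k])
        return self.head(x)

    def feature_shapes(self, height: int, width: int):
        """Encoder feature-map shapes (H, W, C) per level, by the
        halve/double rule, for introspection."""
        d, c0 = self.spec.depth, self.spec.base_channels
        return [(height >> k, width >> k, c0 << k) for k in range(d + 1)]

    @property
    def final_conv(self) -> nn.Conv2d:
        """The last convolution producing the output image/residual."""
        return self.head.final if isinstance(self.head, _ReconHead) else self.head


class _FlatCNN(nn.Module):
    """Flat stack of 3x3 conv + ReLU layers; direct clean-image prediction."""

    def __init__(self, depth: int, channels: int, init_seed: int = 0):
        if depth < 2:
            raise ValueError("plain CNN needs depth >= 2")
        rng = np.random.default_rng(init_seed)
        self.depth = depth
        self.channels = channels
        self.body = [
            _ConvAct(1 if k == 0 else channels, channels, rng, use_prelu=False)
            for k in range(depth - 1)
        ]
        self.final = nn.Conv2d(channels, 1, 3, rng=rng)

    def forward(self, x):
        for layer in self.body:
            x = layer(x)
        return self.final(x)

    @property
    def final_conv(self) -> nn.Conv2d:
        return self.final


@dataclass
class DenoiserModel:
    """A network plus the metadata needed to run and store it."""

    kind: str                      # "improved_unet" | "unet" | "cnn"
    net: nn.Module
    residual_learning: bool
    spec: dict                     # architecture config as plain dict
    trained: bool = False

    @property
    def pad_multiple(self) -> int:
        return 2 ** self.spec.get("depth", 0) if self.kind != "cnn" else 1

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_model(spec: ArchitectureSpec) -> DenoiserModel:
    """Build a UNet-style denoiser from its architecture spec."""
    net = _UNet(spec)
    kind = "improved_unet" if spec.downsample == "stride_conv" else "unet"
    return DenoiserModel(kind=kind, net=net,
                         residual_learning=spec.residual_learning,
                         spec=asdict(spec))


def build_plain_unet(depth: int = 2, base_channels: int = 8,
                     init_seed: int = 0) -> DenoiserModel:
    """The traditional max-pool UNet comparator (direct prediction)."""
    return build_model(ArchitectureSpec.plain_unet(depth, base_channels, init_seed))


def build_plain_cnn(depth: int = 5, channels: int = 16,
                    init_seed: int = 0) -> DenoiserModel:
    """Flat convolutional comparator (direct prediction, no skips)."""
    net = _FlatCNN(depth, channels, init_seed)
    return DenoiserModel(kind="cnn", net=net, residual_learning=False,
                         spec={"kind": "cnn", "depth": depth,
                               "channels": channels, "init_seed": init_seed})


def _pad_to_multiple(arr: np.ndarray, m: int, strict: bool):
    h, w = arr.shape
    ph = (-h) % m
    pw = (-w) % m
    if (ph or pw) and strict:
        raise ValueError(f"input {h}x{w} not divisible by {m} (strict mode)")
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)), mode="reflect")
    return arr, (h, w)


def forward_raw(model: DenoiserModel, pixels: np.ndarray,
                strict: bool = False, peak: float = 255.0) -> np.ndarray:
    """Run the network on a [0, peak] float image; return the *unclipped*
    clean estimate on the same scale (residual added when applicable)."""
    x, (h, w) = _pad_to_multiple(np.asarray(pixels, float), model.pad_multiple,
                                 strict)
    with nn.no_grad():
        t = nn.Tensor(x[None, None] / peak)
        out = model.net(t).data[0, 0].astype(np.float64) * peak
    if model.residual_learning:
        out = x + out                 # b_hat = a + e_hat, original scale
    return out[:h, :w]


def denoise(model: DenoiserModel, noisy: GrayImage,
            quantize: bool = True) -> GrayImage:
    """Produce the clean estimate for one noisy image.

    Output is clipped to the valid range; with ``quantize`` it is also
    rounded to integer intensities for storage.
    """
    out = forward_raw(model, noisy.pixels, peak=noisy.peak)
    out = np.clip(out, 0.0, noisy.peak)
    img = GrayImage(out, bit_depth=noisy.bit_depth)
    return img.quantize() if quantize else img


def denoise_batch(model: DenoiserModel, images: list[GrayImage],
                  quantize: bool = False) -> list[GrayImage]:
    """Denoise same-shape images in one forward pass (falls back to
    per-image passes for mixed shapes)."""
    if not images:
        return []
    shapes = {im.pixels.shape for im in images}
    if len(shapes) > 1:
        return [denoise(model, im, quantize=quantize) for im in images]
    peak = images[0].peak
    m = model.pad_multiple
    stack = np.stack([im.pixels for im in images])
    h, w = stack.shape[1:]
    ph, pw = (-h) % m, (-w) % m
    if ph or pw:
        stack = np.pad(stack, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    with nn.no_grad():
        out = model.net(nn.Tensor(stack[:, None] / peak)).data[:, 0]
    out = out.astype(np.float64) * peak
    if model.residual_learning:
        out = stack + out
    out = np.clip(out[:, :h, :w], 0.0, peak)
    res = [GrayImage(o, bit_depth=images[0].bit_depth) for o in out]
    return [r.quantize() for r in res] if quantize else res


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: DenoiserModel, path) -> None:
    """Single-file checkpoint: JSON header + parameter arrays (npz)."""
    header = json.dumps({"kind": model.kind, "spec": model.spec,
                         "residual_learning": model.residual_learning,
                         "trained": model.trained})
    arrays = {f"p{i:04d}": a for i, a in enumerate(model.net.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> DenoiserModel:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        arrays = [z[k] for k in sorted(z.files) if k.startswith("p")]
    if header["kind"] == "cnn":
        s = header["spec"]
        model = build_plain_cnn(s["depth"], s["channels"], s["init_seed"])
    else:
        model = build_model(ArchitectureSpec(**header["spec"]))
    model.net.load_state_arrays(arrays)
    model.trained = header["trained"]
    return model
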