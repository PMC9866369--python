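"""FCRN and U-Net encoder–decoder architectures for density regression.

Both families map a single-channel image to a same-sized single-channel
density map and differ only in how the encoder/decoder blocks are wired:

* FCRN — VGG-style: block *i* of the downsampling path holds *i*
  convolution+ReLU layers followed by 2x2 max-pooling (so depth grows
  1, 2, 3, ...); a 1x1-convolution bottleneck plays the role of a fully
  connected layer; the upsampling path is a stack of UpConv units
  (stride-2 transposed convolution, ReLU, convolution).
* U-Net — two 3x3 convolution+ReLU layers per block, with skip
  connections concatenating each encoder resolution into the decoder.

Feature maps start at ``base_channels`` and are multiplied by
``channel_growth`` at every pooling step, mirrored on the way up. All
convolutions are same-padded so the spatial shape is preserved end to
end; the final 1x1 convolution maps to one channel and an optional ReLU
keeps predicted densities non-negative. Weights use seeded orthogonal
initialization; no batch norm, no dropout, no pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import F32, Conv2d, ConvTranspose2x2, Layer, MaxPool2, ReLU, Sequential


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a counting network.

    Parameters
    ----------
    family:
        ``"fcrn"`` or ``"unet"``.
    n_blocks:
        Number of downsampling blocks (equals upsampling blocks). Input
        spatial dims must be divisible by ``2**n_blocks``.
    kernel_sizes:
        Allowed odd convolution sizes. FCRN uses the largest in its first
        block and the smallest elsewhere; U-Net uses the smallest throughout.
    base_channels:
        Feature maps in the first block.
    channel_growth:
        Channel multiplier applied at each pooling step.
    output_activation:
        ``"relu"`` (default; non-negative densities) or ``"linear"``.
    """

    family: str = "unet"
    n_blocks: int = 3
    kernel_sizes: tuple[int, ...] = (3, 5)
    base_channels: int = 32
    channel_growth: int = 2
    output_activation: str = "relu"

    def __post_init__(self):
        if self.family not in ("fcrn", "unet"):
            raise ValueError(f"family must be 'fcrn' or 'unet', got {self.family!r}")
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.base_channels < 1:
            raise ValueError(f"base_channels must be >= 1, got {self.base_channels}")
        if not self.kernel_sizes or any(k < 1 or k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError(f"kernel sizes must be odd and >= 1, got {self.kernel_sizes}")
        if self.output_activation not in ("relu", "linear"):
            raise ValueError(
                f"output_activation must be 'relu' or 'linear', got {self.output_activation!r}"
            )

    @property
    def divisor(self) -> int:
        """Required divisor of input spatial dimensions."""
        return 2 ** self.n_blocks

    def channels_at(self, level: int) -> int:
        """Feature maps at downsampling level ``level`` (0-based)."""
        return self.base_channels * self.channel_growth ** level


class _FCRNNet(Layer):
    """n_blocks Conv units (i convs each + pool), 1x1 bottleneck, n_blocks
    UpConv units (deconv, ReLU, conv), final 1x1 projection."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        k_small = min(spec.kernel_sizes)
        k_large = max(spec.kernel_sizes)
        down: list[Layer] = []
        cin = 1
        for b in range(spec.n_blocks):
            cout = spec.channels_at(b)
            for j in range(b + 1):
                k = k_large if b == 0 and j == 0 else k_small
                down += [Conv2d(cin, cout, k, rng), ReLU()]
                cin = cout
            down.append(MaxPool2())
        c_bott = spec.channels_at(spec.n_blocks)
        bottleneck = [Conv2d(cin, c_bott, 1, rng), ReLU()]
        up: list[Layer] = []
        cin = c_bott
        for b in range(spec.n_blocks - 1, -1, -1):
            cout = spec.channels_at(b)
            up += [ConvTranspose2x2(cin, cout, rng), ReLU(), Conv2d(cout, cout, k_small, rng)]
            cin = cout
        head: list[Layer] = [Conv2d(cin, 1, 1, rng)]
        if spec.output_activation == "relu":
            head.append(ReLU())
        self.body = Sequential(*down, *bottleneck, *up, *head)

    def params_grads(self):
        return self.body.params_grads()

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, dy):
        return self.body.backward(dy)


class _UNetNet(Layer):
    """Contracting path (two convs + pool per block), two-conv bridge,
    expanding path (up-conv, skip concatenation, two convs), 1x1 head."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        k = min(spec.kernel_sizes)
        self.n_blocks = spec.n_blocks
        self.enc: list[Sequential] = []
        self.pools: list[MaxPool2] = []
        cin = 1
        for b in range(spec.n_blocks):
            cout = spec.channels_at(b)
            self.enc.append(
                Sequential(Conv2d(cin, cout, k, rng), ReLU(), Conv2d(cout, cout, k, rng), ReLU())
            )
            self.pools.append(MaxPool2())
            cin = cout
        c_bridge = spec.channels_at(spec.n_blocks)
        self.bridge = Sequential(
            Conv2d(cin, c_bridge, k, rng), ReLU(), Conv2d(c_bridge, c_bridge, k, rng), ReLU()
        )
        self.ups: list[ConvTranspose2x2] = []
        self.dec: list[Sequential] = []
        cin = c_bridge
        for b in range(spec.n_blocks - 1, -1, -1):
            cout = spec.channels_at(b)
            self.ups.append(ConvTranspose2x2(cin, cout, rng))
            self.dec.append(
                Sequential(
                    Conv2d(2 * cout, cout, k, rng), ReLU(), Conv2d(cout, cout, k, rng), ReLU()
                )
            )
            cin = cout
        head: list[Layer] = [Conv2d(cin, 1, 1, rng)]
        if spec.output_activation == "relu":
            head.append(ReLU())
        self.head = Sequential(*head)
        self._skip_channels = [spec.channels_at(b) for b in range(spec.n_blocks)]

    @property
    def n_skips(self) -> int:
        return self.n_blocks

    def params_grads(self):
        out = []
        for seq in self.enc:
            out.extend(seq.params_grads())
        out.extend(self.bridge.params_grads())
        for up, dec in zip(self.ups, self.dec):
            out.extend(up.params_grads())
            out.extend(dec.params_grads())
        out.extend(self.head.params_grads())
        return out

    def forward(self, x):
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bridge.forward(x)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=-1)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, dy):
        dy = self.head.backward(dy)
        # decoder stage i consumed the skip from encoder block n_blocks-1-i
        skip_grads: list[np.ndarray] = [None] * self.n_blocks  # type: ignore[list-item]
        for i in range(self.n_blocks - 1, -1, -1):
            dec, up = self.dec[i], self.ups[i]
            dcat = dec.backward(dy)
            c_skip = self._skip_channels[self.n_blocks - 1 - i]
            skip_grads[self.n_blocks - 1 - i] = dcat[..., :c_skip]
            dy = up.backward(np.ascontiguousarray(dcat[..., c_skip:]))
        dy = self.bridge.backward(dy)
        for b in range(self.n_blocks - 1, -1, -1):
            dy = self.pools[b].backward(dy)
            dy = self.enc[b].backward(dy + skip_grads[b])
        return dy


@dataclass
class NetworkHandle:
    """A built, trainable image-to-density-map network."""

    spec: ArchitectureSpec
    net: Layer
    parameter_count: int = field(init=False)

    def __post_init__(self):
        self.parameter_count = int(sum(p.size for p, _ in self.net.params_grads()))
        if self.parameter_count <= 0:
            raise ValueError("network has no parameters")


def build_fcrn(spec: ArchitectureSpec, seed: int = 0) -> NetworkHandle:
    """Build the FCRN variant. ``spec.family`` must be ``"fcrn"``."""
    if spec.family != "fcrn":
        raise ValueError(f"build_fcrn requires family='fcrn', got {spec.family!r}")
    return NetworkHandle(spec, _FCRNNet(spec, np.random.default_rng(seed)))


def build_unet(spec: ArchitectureSpec, seed: int = 0) -> NetworkHandle:
    """Build the U-Net variant. ``spec.family`` must be ``"unet"``."""
    if spec.family != "unet":
        raise ValueError(f"build_unet requires family='unet', got {spec.family!r}")
    return NetworkHandle(spec, _UNetNet(spec, np.random.default_rng(seed)))


def build_network(spec: ArchitectureSpec, seed: int = 0) -> NetworkHandle:
    """Dispatch to :func:`build_fcrn` / :func:`build_unet` on ``spec.family``."""
    return build_fcrn(spec, seed) if spec.family == "fcrn" else build_unet(spec, seed)


def _as_batch(images: np.ndarray) -> np.ndarray:
    """Coerce (N,H,W) or (N,H,W,1) float input to NHWC float32."""
    x = np.asarray(images, dtype=F32)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[-1] != 1:
        raise ValueError(f"expected a batch of single-channel images, got shape {images.shape}")
    return np.ascontiguousarray(x)


def forward(handle: NetworkHandle, images: np.ndarray) -> np.ndarray:
    """Predict density maps for a batch of images.

    Accepts (N, H, W) or (N, H, W, 1); returns (N, H, W) float32 maps.
    H and W must be divisible by ``2**n_blocks``.
    """
    x = _as_batch(images)
    d = handle.spec.divisor
    _, h, w, _ = x.shape
    if h % d or w % d:
        raise ValueError(
            f"input spatial dims {h}x{w} must be divisible by {d} "
            f"(2**n_blocks with n_blocks={handle.spec.n_blocks})"
        )
    return handle.net.forward(x)[..., 0]


def save_checkpoint(handle: NetworkHandle, path) -> None:
    """Serialize spec + parameters to an .npz checkpoint (bit-exact round trip)."""
    arrays = {f"param_{i}": p for i, (p, _) in enumerate(handle.net.params_grads())}
    np.savez(
        path,
        family=np.array(handle.spec.family),
        n_blocks=np.array(handle.spec.n_blocks),
        kernel_sizes=np.array(handle.spec.kernel_sizes),
        base_channels=np.array(handle.spec.base_channels),
        channel_growth=np.array(handle.spec.channel_growth),
        output_activation=np.array(handle.spec.output_activation),
        **arrays,
    )


def load_checkpoint(path) -> NetworkHandle:
    """Rebuild a network from :func:`save_checkpoint` output."""
    with np.load(path) as z:
        spec = ArchitectureSpec(
            family=str(z["family"]),
            n_blocks=int(z["n_blocks"]),
            kernel_sizes=tuple(int(k) for k in z["kernel_sizes"]),
            base_channels=int(z["base_channels"]),
            channel_growth=int(z["channel_growth"]),
            output_activation=str(z["output_activation"]),
        )
        handle = build_network(spec, seed=0)
        for i, (p, _) in enumerate(handle.net.params_grads()):
            p[...] = z[f"param_{i}"]
    return handle
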