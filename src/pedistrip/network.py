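"""Configurable 3D U-Net and the skull-stripping inference path.

The network is a standard encoder–decoder with skip connections: at each
resolution level two 3x3x3 convolutions with leaky-ReLU activations, 2x
max-pool downsampling between encoder levels, nearest-neighbor upsampling
followed by a convolution on the way back up, and a final 1x1x1 projection
to either two softmax channels (brain, background) or one linear channel
predicting a signed distance transform.

Forward and backward passes are written directly in numpy. Convolutions run
as im2col + BLAS matmul; the input gradient of a same-padded correlation is
itself a same-padded correlation with spatially flipped, channel-transposed
kernels, so backprop reuses the same primitive. Arrays are channels-last
(D, H, W, C), float32 throughout. Everything is deterministic given the
initialization seed and single-threaded execution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import BrainMask, IntensityVolume

OUTPUT_MODES = ("softmax_2ch", "sdt_1ch")
BRAIN_CHANNEL, BACKGROUND_CHANNEL = 0, 1


class UNetConfigError(ValueError):
    pass


@dataclass(frozen=True)
class UNetConfig:
    n_levels: int = 7
    convs_per_level: int = 2
    kernel: int = 3
    base_channels: int = 16
    channel_cap: int = 256
    leaky_slope: float = 0.2
    output_mode: str = "softmax_2ch"
    in_channels: int = 1
    up_kernel: int = 3  # kernel of the conv after nearest upsampling (1 or 3)
    # softmax mode: logits pass through B*tanh(z/B), which caps them at ±B so
    # the softmax cannot saturate to exact 0/1 in float32 — overlap-loss
    # gradients then never vanish and collapsed states remain escapable.
    # 0 disables the bound. Ignored in SDT mode (regression is unbounded).
    logit_bound: float = 10.0
    # per-channel instance normalization after each trunk convolution keeps
    # activation scales bounded at any learning rate; "none" gives the plain
    # conv trunk
    norm: str = "instance"

    def __post_init__(self):
        if self.n_levels < 1:
            raise UNetConfigError("n_levels must be >= 1")
        if self.base_channels < 1 or self.in_channels < 1:
            raise UNetConfigError("channel counts must be positive")
        if self.kernel != 3:
            raise UNetConfigError("only 3x3x3 kernels are supported")
        if self.up_kernel not in (1, 3):
            raise UNetConfigError("up_kernel must be 1 or 3")
        if self.norm not in ("instance", "none"):
            raise UNetConfigError("norm must be 'instance' or 'none'")
        if self.output_mode not in OUTPUT_MODES:
            raise UNetConfigError(f"output_mode must be one of {OUTPUT_MODES}")

    @property
    def out_channels(self) -> int:
        return 2 if self.output_mode == "softmax_2ch" else 1

    def channels_at(self, level: int) -> int:
        return min(self.base_channels * 2**level, self.channel_cap)

    def check_grid(self, shape) -> None:
        div = 2 ** (self.n_levels - 1)
        for s in shape:
            cur = s
            for level in range(1, self.n_levels):
                if cur % 2:
                    raise UNetConfigError(
                        f"grid extent {s} is not divisible by 2 at level {level} "
                        f"(need multiples of {div})"
                    )
                cur //= 2


# ---------------------------------------------------------------------------
# primitives


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3^3 correlation; w: (Cin, 3, 3, 3, Cout).

    Computed as 27 shifted (N, Cin) @ (Cin, Cout) matmuls, which avoids
    materializing the full im2col patch matrix.
    """
    cin, _, _, _, cout = w.shape
    d, h, wd, _ = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
    y = np.empty((d * h * wd, cout), dtype=np.float32)
    y[:] = b
    for kz in range(3):
        for ky in range(3):
            for kx in range(3):
                xs = xp[kz : kz + d, ky : ky + h, kx : kx + wd].reshape(-1, cin)
                y += xs @ w[:, kz, ky, kx, :]
    return y.reshape(d, h, wd, cout)


def conv3x3_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray, need_dx: bool = True
) -> Tuple[Optional[np.ndarray], np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of a same-padded 3^3 correlation.

    The input gradient is the correlation of dy with spatially flipped,
    channel-transposed kernels — the same shifted-matmul primitive.
    ``need_dx=False`` (first layer: the image needs no gradient) skips it.
    """
    cin, _, _, _, cout = w.shape
    d, h, wd, _ = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
    dyp = np.pad(dy, ((1, 1), (1, 1), (1, 1), (0, 0))) if need_dx else None
    dyf = dy.reshape(-1, cout)
    dw = np.empty_like(w)
    dxf = np.zeros((d * h * wd, cin), dtype=np.float32) if need_dx else None
    for kz in range(3):
        for ky in range(3):
            for kx in range(3):
                xs = xp[kz : kz + d, ky : ky + h, kx : kx + wd].reshape(-1, cin)
                dw[:, kz, ky, kx, :] = xs.T @ dyf
                if need_dx:
                    dys = dyp[
                        2 - kz : 2 - kz + d, 2 - ky : 2 - ky + h, 2 - kx : 2 - kx + wd
                    ]
                    dxf += dys.reshape(-1, cout) @ w[:, kz, ky, kx, :].T
    db = dyf.sum(axis=0)
    dx = dxf.reshape(d, h, wd, cin) if need_dx else None
    return dx, dw, db


def conv1x1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    return x @ w + b


def conv1x1_backward(x, w, dy):
    d, h, wd, cin = x.shape
    dw = x.reshape(-1, cin).T @ dy.reshape(-1, w.shape[1])
    db = dy.reshape(-1, w.shape[1]).sum(axis=0)
    return dy @ w.T, dw, db


def leaky_forward(x: np.ndarray, slope: float):
    mask = x > 0
    return np.where(mask, x, slope * x), mask


def leaky_backward(dy: np.ndarray, mask: np.ndarray, slope: float) -> np.ndarray:
    return np.where(mask, dy, slope * dy)


def maxpool2_forward(x: np.ndarray):
    d, h, w, c = x.shape
    blocks = (
        x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c)
        .transpose(0, 2, 4, 6, 1, 3, 5)
        .reshape(d // 2, h // 2, w // 2, c, 8)
    )
    idx = blocks.argmax(axis=-1)
    pooled = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def maxpool2_backward(dy: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    d, h, w, c = in_shape
    blocks = np.zeros((d // 2, h // 2, w // 2, c, 8), dtype=dy.dtype)
    np.put_along_axis(blocks, idx[..., None], dy[..., None], axis=-1)
    return (
        blocks.reshape(d // 2, h // 2, w // 2, c, 2, 2, 2)
        .transpose(0, 4, 1, 5, 2, 6, 3)
        .reshape(d, h, w, c)
    )


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(np.repeat(x, 2, 0), 2, 1), 2, 2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    d, h, w, c = dy.shape
    return dy.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(1, 3, 5))


def instance_norm_forward(x: np.ndarray, eps: float = 1e-5):
    """Per-channel standardization over the spatial axes (no affine)."""
    mu = x.mean(axis=(0, 1, 2))
    var = x.var(axis=(0, 1, 2))
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    y = (x - mu) * inv
    return y.astype(np.float32), inv


def instance_norm_backward(dy: np.ndarray, y: np.ndarray, inv: np.ndarray) -> np.ndarray:
    """Gradient through per-channel standardization."""
    m1 = dy.mean(axis=(0, 1, 2))
    m2 = (dy * y).mean(axis=(0, 1, 2))
    return (inv * (dy - m1 - y * m2)).astype(np.float32)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the network


class UNet:
    """Parameter container plus forward/backward passes."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        self.params: Dict[str, np.ndarray] = {}
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 90210]))
        self._cache = None

        def add_conv(name, cin, cout, kernel=3, zero=False):
            fan_in = cin * kernel**3
            std = np.sqrt(2.0 / fan_in)
            shape = (cin, 3, 3, 3, cout) if kernel == 3 else (cin, cout)
            if zero:  # neutral initial prediction avoids early softmax saturation
                self.params[f"{name}_W"] = np.zeros(shape, dtype=np.float32)
            else:
                self.params[f"{name}_W"] = rng.normal(0, std, size=shape).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        c = config
        prev = c.in_channels
        for lvl in range(c.n_levels):
            for i in range(c.convs_per_level):
                add_conv(f"enc{lvl}_conv{i}", prev, c.channels_at(lvl))
                prev = c.channels_at(lvl)
        for lvl in range(c.n_levels - 2, -1, -1):
            add_conv(f"up{lvl}", c.channels_at(lvl + 1), c.channels_at(lvl),
                     kernel=c.up_kernel)
            prev = 2 * c.channels_at(lvl)
            for i in range(c.convs_per_level):
                add_conv(f"dec{lvl}_conv{i}", prev, c.channels_at(lvl))
                prev = c.channels_at(lvl)
        add_conv("out", c.channels_at(0), c.out_channels, kernel=1, zero=True)

    # -- bookkeeping

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()

    # -- passes

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (D, H, W) or (D, H, W, Cin) -> logits/SDT (D, H, W, out_ch)."""
        c = self.config
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[-1] != c.in_channels:
            raise UNetConfigError(
                f"expected {c.in_channels} input channels, got {x.shape[-1]}"
            )
        c.check_grid(x.shape[:3])
        x = x.astype(np.float32, copy=False)
        cache = {"input": x, "skips": [], "pool_idx": [], "pool_shapes": []}

        use_norm = c.norm == "instance"

        def block(prefix, h):
            acts = []
            for i in range(c.convs_per_level):
                w = self.params[f"{prefix}_conv{i}_W"]
                b = self.params[f"{prefix}_conv{i}_b"]
                pre = conv3x3_forward(h, w, b)
                if use_norm:
                    ynorm, inv = instance_norm_forward(pre)
                else:
                    ynorm, inv = pre, None
                out, mask = leaky_forward(ynorm, c.leaky_slope)
                acts.append((h, ynorm if use_norm else None, inv, mask))
                h = out
            cache[prefix] = acts
            return h

        h = x
        for lvl in range(c.n_levels - 1):
            h = block(f"enc{lvl}", h)
            cache["skips"].append(h)
            cache["pool_shapes"].append(h.shape)
            h, idx = maxpool2_forward(h)
            cache["pool_idx"].append(idx)
        h = block(f"enc{c.n_levels - 1}", h)

        for lvl in range(c.n_levels - 2, -1, -1):
            up = upsample2_forward(h)
            w, b = self.params[f"up{lvl}_W"], self.params[f"up{lvl}_b"]
            pre = (
                conv3x3_forward(up, w, b)
                if c.up_kernel == 3
                else conv1x1_forward(up, w, b)
            )
            if use_norm:
                upnorm, upinv = instance_norm_forward(pre)
            else:
                upnorm, upinv = pre, None
            upact, upmask = leaky_forward(upnorm, c.leaky_slope)
            cache[f"up{lvl}"] = (up, upnorm if use_norm else None, upinv, upmask)
            h = np.concatenate([cache["skips"][lvl], upact], axis=-1)
            h = block(f"dec{lvl}", h)

        cache["pre_out"] = h
        logits = conv1x1_forward(h, self.params["out_W"], self.params["out_b"])
        if c.output_mode == "softmax_2ch" and c.logit_bound > 0:
            t = np.tanh(logits / c.logit_bound)
            cache["logit_tanh"] = t
            logits = c.logit_bound * t
        self._cache = cache
        return logits

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradient of a scalar loss w.r.t. every parameter, given d(loss)/d(logits)."""
        if self._cache is None:
            raise RuntimeError("backward() requires a preceding forward()")
        c = self.config
        cache = self._cache
        grads: Dict[str, np.ndarray] = {}

        dlogits = dlogits.astype(np.float32)
        if "logit_tanh" in cache:
            t = cache["logit_tanh"]
            dlogits = dlogits * (1.0 - t * t)
        dh, dwo, dbo = conv1x1_backward(
            cache["pre_out"], self.params["out_W"], dlogits
        )
        grads["out_W"], grads["out_b"] = dwo, dbo

        def block_backward(prefix, dh):
            acts = cache[prefix]
            for i in range(c.convs_per_level - 1, -1, -1):
                h_in, ynorm, inv, mask = acts[i]
                dpre = leaky_backward(dh, mask, c.leaky_slope)
                if inv is not None:
                    dpre = instance_norm_backward(dpre, ynorm, inv)
                need_dx = not (prefix == "enc0" and i == 0)  # image gets no grad
                dh, dw, db = conv3x3_backward(
                    h_in, self.params[f"{prefix}_conv{i}_W"], dpre, need_dx=need_dx
                )
                grads[f"{prefix}_conv{i}_W"] = dw
                grads[f"{prefix}_conv{i}_b"] = db
            return dh

        dskips = [None] * max(c.n_levels - 1, 0)
        for lvl in range(0, c.n_levels - 1):
            dh = block_backward(f"dec{lvl}", dh)
            nskip = cache["skips"][lvl].shape[-1]
            dskip, dupact = dh[..., :nskip], dh[..., nskip:]
            dskips[lvl] = dskip
            up, upnorm, upinv, upmask = cache[f"up{lvl}"]
            dpre = leaky_backward(dupact, upmask, c.leaky_slope)
            if upinv is not None:
                dpre = instance_norm_backward(dpre, upnorm, upinv)
            if c.up_kernel == 3:
                dup, dw, db = conv3x3_backward(up, self.params[f"up{lvl}_W"], dpre)
            else:
                dup, dw, db = conv1x1_backward(up, self.params[f"up{lvl}_W"], dpre)
            grads[f"up{lvl}_W"], grads[f"up{lvl}_b"] = dw, db
            dh = upsample2_backward(dup)

        dh = block_backward(f"enc{c.n_levels - 1}", dh)
        for lvl in range(c.n_levels - 2, -1, -1):
            dh = maxpool2_backward(dh, cache["pool_idx"][lvl], cache["pool_shapes"][lvl])
            dh = dh + dskips[lvl]
            dh = block_backward(f"enc{lvl}", dh)
        return grads


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct a U-Net with seeded He-initialized parameters."""
    return UNet(config, seed=seed)


def unet_param_count(config: UNetConfig) -> int:
    """Closed-form parameter total from convolution arithmetic."""
    c = config
    total = 0

    def conv(cin, cout, k=3):
        return cin * k**3 * cout + cout

    prev = c.in_channels
    for lvl in range(c.n_levels):
        for _ in range(c.convs_per_level):
            total += conv(prev, c.channels_at(lvl))
            prev = c.channels_at(lvl)
    for lvl in range(c.n_levels - 2, -1, -1):
        total += conv(c.channels_at(lvl + 1), c.channels_at(lvl), k=c.up_kernel)
        prev = 2 * c.channels_at(lvl)
        for _ in range(c.convs_per_level):
            total += conv(prev, c.channels_at(lvl))
            prev = c.channels_at(lvl)
    total += conv(c.channels_at(0), c.out_channels, k=1)
    return total


# ---------------------------------------------------------------------------
# inference


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img, dtype=np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


def predict(unet: UNet, image: IntensityVolume):
    """Run the network on a min-max-normalized image; returns probs or SDT."""
    logits = unet.forward(_normalize(np.asarray(image.data, dtype=np.float32)))
    if unet.config.output_mode == "softmax_2ch":
        return softmax_channels(logits)
    return logits[..., 0]


def predict_mask(unet: UNet, image: IntensityVolume, threshold: float = 0.5) -> BrainMask:
    """Brain mask from the network output.

    Softmax mode thresholds the brain-channel probability; SDT mode takes
    voxels with predicted distance < 0 (negative-inside convention).
    """
    out = predict(unet, image)
    if unet.config.output_mode == "softmax_2ch":
        mask = out[..., BRAIN_CHANNEL] > threshold
    else:
        mask = out < 0
    return BrainMask(mask, image.affine)


def skull_strip(unet: UNet, image: IntensityVolume, threshold: float = 0.5) -> IntensityVolume:
    """Voxelwise product of the image with its predicted brain mask."""
    mask = predict_mask(unet, image, threshold=threshold)
    return IntensityVolume(image.data * mask.data, image.affine)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, unet: UNet, extra: Optional[dict] = None) -> None:
    meta = {"config": asdict(unet.config), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in unet.params.items()}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ), **arrays)


def load_checkpoint(path) -> Tuple[UNet, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = UNetConfig(**meta["config"])
        net = UNet(cfg, seed=0)
        for k in list(net.params):
            net.params[k] = z[f"param/{k}"]
    return net, meta.get("extra", {})
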