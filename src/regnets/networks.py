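"""Image-to-image network functions with hand-written forward/backward passes.

The reconstruction maps in this package compose a linear spectral part with a
parameterized image-to-image function U_theta.  The default architecture is a
small encoder-decoder with skip connections (U-net style, no residual
connection): repeated 3x3 convolution + ReLU blocks, 2x2 average-pool
downsampling, nearest-neighbour upsampling, channel concatenation with the
matching encoder feature map, and a final 1x1 convolution back to one
channel.  Forward and backward passes are implemented directly in numpy
(im2col matrix products), which is plenty for the image sizes used here and
keeps evaluation bit-deterministic.

All networks accept a single image (H, W) or a batch (B, H, W) and return
the same leading shape.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkFunction",
    "ConvEncoderDecoder",
    "LinearNetwork",
    "CallableNetwork",
    "ZeroNetwork",
    "lipschitz_estimate",
]


# ---------------------------------------------------------------------------
# layers (batch tensors of shape (B, C, H, W))


class _Conv:
    """k x k convolution with 'same' zero padding (single precision)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, dtype=np.float32):
        fan_in = cin * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k = k

    @property
    def params(self) -> List[np.ndarray]:
        return [self.w, self.b]

    def forward(self, x):
        k, p = self.k, self.k // 2
        bsz, cin, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            bsz * h * w, cin * k * k
        )
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T + self.b
        y = out.reshape(bsz, h, w, -1).transpose(0, 3, 1, 2)
        return y, (cols, x.shape)

    def backward(self, dy, cache):
        cols, xshape = cache
        bsz, cin, h, w = xshape
        k, p = self.k, self.k // 2
        cout = self.w.shape[0]
        dyc = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        dw = (dyc.T @ cols).reshape(self.w.shape)
        db = dyc.sum(axis=0)
        wmat = self.w.reshape(cout, -1)
        dcols = (dyc @ wmat).reshape(bsz, h, w, cin, k, k)
        dxp = np.zeros((bsz, cin, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        dx = dxp[:, :, p : p + h, p : p + w] if p else dxp
        return dx, [dw, db]


class _ReLU:
    params: List[np.ndarray] = []

    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, mask):
        return dy * mask, []


def _pool2(x):
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_back(dy):
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_back(dy):
    b, c, h, w = dy.shape
    return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# network functions


class NetworkFunction:
    """Base class: a deterministic parameterized map from images to images."""

    architecture: str = "abstract"
    trainable: bool = False

    def get_params(self) -> List[np.ndarray]:
        return []

    def set_params(self, params: Sequence[np.ndarray]) -> None:
        for p, q in zip(self.get_params(), params):
            p[...] = q

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.get_params()))

    def _forward_batch(self, x: np.ndarray) -> np.ndarray:  # (B, H, W)
        raise NotImplementedError

    def forward_cached(self, x: np.ndarray):
        """Forward pass keeping the caches needed for a later backward pass."""
        raise NotImplementedError(f"{self.architecture} is not trainable")

    def backward_cached(self, grad_out: np.ndarray, ctx) -> List[np.ndarray]:
        """Parameter gradients for a cached forward pass."""
        raise NotImplementedError(f"{self.architecture} is not trainable")

    def forward_backward(
        self, x: np.ndarray, grad_out: np.ndarray
    ) -> Tuple[np.ndarray, List[np.ndarray]]:
        y, ctx = self.forward_cached(x)
        return y, self.backward_cached(grad_out, ctx)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            return self._forward_batch(x[None])[0]
        if x.ndim == 3:
            return self._forward_batch(x)
        raise ValueError(f"expected (H, W) or (B, H, W) input, got shape {x.shape}")


class ConvEncoderDecoder(NetworkFunction):
    """Encoder-decoder with skip connections (U-net style, no residual).

    Parameters
    ----------
    scales:
        Number of pooling steps; input side length must be divisible by
        2**scales.
    base_channels:
        Channel count at the finest scale; doubled at each coarser scale.
    seed:
        Seed for He-normal weight initialization.
    """

    trainable = True

    def __init__(
        self, scales: int = 2, base_channels: int = 8, seed: int = 0, dtype=np.float32
    ):
        rng = np.random.default_rng(seed)
        self.scales = scales
        self.base_channels = base_channels
        self.dtype = np.dtype(dtype)
        self.architecture = f"conv-encoder-decoder(scales={scales}, base={base_channels})"
        ch = [base_channels * 2**s for s in range(scales + 1)]
        self.down = []
        cin = 1
        for s in range(scales):
            self.down.append(self._double(cin, ch[s], rng))
            cin = ch[s]
        self.bottleneck = self._double(cin, ch[scales], rng)
        self.up = []
        for s in reversed(range(scales)):
            self.up.append(self._double(ch[s + 1] + ch[s], ch[s], rng))
        self.final = _Conv(ch[0], 1, 1, rng, self.dtype)
        self._layers = [l for blk in (*self.down, self.bottleneck, *self.up) for l in blk]
        self._layers.append(self.final)

    def _double(self, cin, cout, rng):
        d = self.dtype
        return [_Conv(cin, cout, 3, rng, d), _ReLU(), _Conv(cout, cout, 3, rng, d), _ReLU()]

    def get_params(self) -> List[np.ndarray]:
        return [p for l in self._layers for p in l.params]

    def _run_block(self, block, x, caches: Optional[list]):
        for layer in block:
            x, c = layer.forward(x)
            if caches is not None:
                caches.append(c)
        return x

    def _forward(self, x4, caches: Optional[list] = None):
        if x4.shape[2] % 2**self.scales or x4.shape[3] % 2**self.scales:
            raise ValueError(
                f"image side must be divisible by {2**self.scales} "
                f"for {self.scales} pooling scales"
            )
        skips = []
        h = x4
        for blk in self.down:
            h = self._run_block(blk, h, caches)
            skips.append(h)
            h = _pool2(h)
        h = self._run_block(self.bottleneck, h, caches)
        for blk, skip in zip(self.up, reversed(skips)):
            h = _up2(h)
            h = np.concatenate([skip, h], axis=1)
            h = self._run_block(blk, h, caches)
        y, c = self.final.forward(h)
        if caches is not None:
            caches.append(c)
        return y, skips

    def _forward_batch(self, x: np.ndarray) -> np.ndarray:
        y, _ = self._forward(x[:, None].astype(self.dtype))
        return y[:, 0]

    def forward_cached(self, x):
        x = np.asarray(x, dtype=self.dtype)
        caches = []
        y, skips = self._forward(x[:, None], caches)
        return y[:, 0], (caches, skips)

    def backward_cached(self, grad_out, ctx):
        caches, skips = ctx
        grad_out = np.asarray(grad_out, dtype=self.dtype)
        # replay backward in reverse layer order, mirroring the forward graph
        it = len(caches) - 1
        layer_grads: List[List[np.ndarray]] = [None] * len(self._layers)

        def back_block(block, dy, base_idx):
            nonlocal it
            for off, layer in zip(range(len(block) - 1, -1, -1), reversed(block)):
                dy, g = layer.backward(dy, caches[it])
                it -= 1
                layer_grads[base_idx + off] = g
            return dy

        # layer index bookkeeping
        idx = 0
        block_index = []
        for blk in (*self.down, self.bottleneck, *self.up):
            block_index.append(idx)
            idx += len(blk)
        final_idx = idx

        dy = grad_out[:, None] if grad_out.ndim == 3 else grad_out
        dh, g = self.final.backward(dy, caches[it])
        it -= 1
        layer_grads[final_idx] = g

        n_down = len(self.down)
        skip_grads = [None] * n_down
        for u, blk in zip(range(len(self.up) - 1, -1, -1), reversed(self.up)):
            dh = back_block(blk, dh, block_index[n_down + 1 + u])
            s = n_down - 1 - u
            ch_skip = skips[s].shape[1]
            skip_grads[s] = dh[:, :ch_skip]
            dh = _up2_back(dh[:, ch_skip:])
        dh = back_block(self.bottleneck, dh, block_index[n_down])
        for s in range(n_down - 1, -1, -1):
            # dh is the grad w.r.t. the pooled output of level s
            dh = _pool2_back(dh) + skip_grads[s]
            dh = back_block(self.down[s], dh, block_index[s])
        return [g for lg in layer_grads for g in lg]


class LinearNetwork(NetworkFunction):
    """Affine map on flattened images: y = reshape(W x + b).

    Useful as an analytically tractable trainable network (MAE loss in a
    linear model is convex).
    """

    trainable = True

    def __init__(self, grid_n: int, seed: int = 0, init_scale: float = 0.01):
        d = grid_n * grid_n
        rng = np.random.default_rng(seed)
        self.grid_n = grid_n
        self.w = rng.normal(0.0, init_scale / np.sqrt(d), size=(d, d))
        self.b = np.zeros(d)
        self.architecture = f"linear({d}x{d})"

    def get_params(self):
        return [self.w, self.b]

    def _forward_batch(self, x):
        bsz = x.shape[0]
        flat = x.reshape(bsz, -1)
        return (flat @ self.w.T + self.b).reshape(x.shape)

    def forward_cached(self, x):
        x = np.asarray(x, dtype=float)
        flat = x.reshape(x.shape[0], -1)
        out = flat @ self.w.T + self.b
        return out.reshape(x.shape), flat

    def backward_cached(self, grad_out, flat):
        gy = np.asarray(grad_out, dtype=float).reshape(flat.shape[0], -1)
        return [gy.T @ flat, gy.sum(axis=0)]


class CallableNetwork(NetworkFunction):
    """Wrap an arbitrary image-to-image callable (not trainable)."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], name: str = "callable"):
        self.fn = fn
        self.architecture = name

    def _forward_batch(self, x):
        out = np.stack([np.asarray(self.fn(img), dtype=float) for img in x])
        if out.shape != x.shape:
            raise ValueError("network output shape must equal input shape")
        return out


class ZeroNetwork(CallableNetwork):
    def __init__(self):
        super().__init__(np.zeros_like, name="zero")


def lipschitz_estimate(
    network: NetworkFunction,
    shape: Tuple[int, int],
    n_pairs: int = 200,
    seed: int = 0,
    scale: float = 1.0,
) -> float:
    """Empirical Lipschitz bound: max ||U(x1)-U(x2)|| / ||x1-x2|| over seeded pairs."""
    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(n_pairs):
        x1 = rng.normal(0.0, scale, size=shape)
        x2 = x1 + rng.normal(0.0, scale * 0.1, size=shape)
        num = float(np.linalg.norm(network(x1) - network(x2)))
        den = float(np.linalg.norm(x1 - x2))
        if den > 0:
            best = max(best, num / den)
    return best
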