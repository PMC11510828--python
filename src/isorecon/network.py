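"""3D wide-activation super-resolution network with weighted channel
concatenation.

The network maps a fused low-resolution volume (already interpolated to the
isotropic grid) to the high-resolution volume of the same shape.  It has
three phases:

* feature extraction: one 3x3x3 convolution, no activation;
* nonlinear mapping: ``n`` cascaded concatenation blocks.  Each block runs a
  wide-activation branch Conv(C -> e*C) -> ReLU -> Conv(e*C -> C), scales the
  identity branch by a learnable scalar ``pi`` and the nonlinear branch by a
  learnable scalar ``lam``, concatenates the two along channels and mixes
  them with a 1x1x1 convolution carrying no activation (a joint linear
  attention over linear and nonlinear features).  When the 1x1x1 kernel is
  the stacked pair of identity matrices and ``pi = lam = 1`` the block
  degenerates exactly to a residual connection;
* reconstruction: a global residual skip adds the shallow features to the
  deep features, followed by two 3x3x3 convolutions.

All convolutions are zero-padded with stride 1, so spatial shape is
preserved end to end and the network handles arbitrary (including
fractional) scaling factors — the scale is absorbed by the spline
interpolation upstream.  Network depth is ``3 n + 4`` convolutional layers
along the longest input-output path.

Everything here is plain NumPy.  The fast convolution lowers to an im2col
GEMM; :func:`conv3d_reference` is a literal nested-loop evaluation of the
same operation kept as an independent oracle for tests.  Gradients are
hand-derived per layer (`backward` methods), which is all the training loop
needs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = [
    "ModelConfig", "Conv3d", "ConcatBlock", "SRNetwork",
    "conv3d_reference", "cb_forward", "model_depth", "count_parameters",
    "save_checkpoint", "load_checkpoint",
]


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults give the full-scale model: 16 blocks, 32 base channels
    expanded 4x inside the wide activation, 3x3x3 kernels everywhere except
    the 1x1x1 channel-fusion convolution.
    """

    n_blocks: int = 16
    base_channels: int = 32
    expansion: int = 4
    kernel_extract: int = 3
    kernel_cb: int = 3
    kernel_fuse: int = 1
    kernel_recon: int = 3
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if self.base_channels < 1 or self.expansion < 1:
            raise ValueError("base_channels and expansion must be >= 1")
        for k in (self.kernel_extract, self.kernel_cb, self.kernel_fuse,
                  self.kernel_recon):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def model_depth(cfg: ModelConfig) -> int:
    """Longest conv path from input to output: 3 layers per block (two wide
    convs + the fusion conv) plus extraction and the two reconstruction
    layers and the final mapping — ``3 n + 4`` in total."""
    return 3 * cfg.n_blocks + 4


# ---------------------------------------------------------------------------
# reference convolution (test oracle)

def conv3d_reference(v: np.ndarray, w: np.ndarray, b: np.ndarray,
                     activation: bool = False) -> np.ndarray:
    """Literal nested-loop 3D convolution with zero padding and stride 1.

    ``v`` has shape (H, W, D, C_in); ``w`` has shape (Kh, Kw, Kd, C_in,
    C_out); ``b`` has shape (C_out,).  Voxel (x, y, z) of output channel m
    sums ``w[i,j,k,n,m] * v[x+i-Kh//2, y+j-Kw//2, z+k-Kd//2, n]`` over all
    kernel offsets and input channels, treating out-of-range samples as
    zero, then adds ``b[m]`` and optionally applies a ReLU.  Quadratically
    slow on purpose; use :class:`Conv3d` for real work.
    """
    v = np.asarray(v, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    kh, kw, kd, c_in, c_out = w.shape
    if v.ndim != 4 or v.shape[3] != c_in:
        raise ValueError(
            f"input shape {v.shape} incompatible with kernel {w.shape}")
    H, W, D, _ = v.shape
    out = np.zeros((H, W, D, c_out))
    for m in range(c_out):
        for x in range(H):
            for y in range(W):
                for z in range(D):
                    acc = 0.0
                    for n in range(c_in):
                        for i in range(kh):
                            xi = x + i - kh // 2
                            if not 0 <= xi < H:
                                continue
                            for j in range(kw):
                                yj = y + j - kw // 2
                                if not 0 <= yj < W:
                                    continue
                                for k in range(kd):
                                    zk = z + k - kd // 2
                                    if 0 <= zk < D:
                                        acc += w[i, j, k, n, m] * v[xi, yj, zk, n]
                    out[x, y, z, m] = acc + b[m]
    if activation:
        out = np.maximum(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# fast layers with hand-derived gradients
#
# Feature tensors are batched channels-last: (B, H, W, D, C).  A k^3
# convolution is evaluated as k^3 shifted GEMMs over the zero-padded input
# — each shift is a large contiguous-run copy followed by a
# (B*H*W*D, C_in) @ (C_in, C_out) product, which keeps the whole batch in
# one BLAS call per kernel tap and avoids the scattered im2col gather.


def _ensure_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    if x.ndim == 4:
        return x[None], True
    if x.ndim != 5:
        raise ValueError(f"expected (B,H,W,D,C) or (H,W,D,C), got {x.shape}")
    return x, False


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))


class Conv3d:
    """Zero-padded stride-1 3D convolution (shift-and-GEMM).

    Evaluated as k^3 shifted (B*H*W*D, C_in) @ (C_in, C_out) products over
    the zero-padded input — one per kernel tap — which avoids materializing
    the k^3-times-larger im2col patch matrix.  Kernel layout is
    (k, k, k, C_in, C_out), matching :func:`conv3d_reference`.
    """

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, gain: float = 2.0):
        fan_in = c_in * k**3
        std = np.sqrt(gain / fan_in)
        self.w = rng.normal(0.0, std, (k, k, k, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out, self.k = c_in, c_out, k

    def _offsets(self):
        k = self.k
        return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]

    def forward(self, x: np.ndarray, want_cache: bool = False,
                relu: bool = False):
        """``x`` is (B, H, W, D, C_in) (or unbatched 4D).  Returns
        ``(y, cache)`` with ``y`` of the same spatial shape."""
        x, squeeze = _ensure_batch(x)
        B, H, W, D, _ = x.shape
        xp = _pad_spatial(x, self.k // 2)
        n = B * H * W * D
        yflat = np.broadcast_to(self.b, (n, self.c_out)).copy()
        tmp = np.empty((n, self.c_out), dtype=np.float32)
        for (i, j, l) in self._offsets():
            block = xp[:, i:i + H, j:j + W, l:l + D, :].reshape(n, self.c_in)
            np.dot(block, self.w[i, j, l], out=tmp)
            yflat += tmp
        y = yflat.reshape(B, H, W, D, self.c_out)
        mask = None
        if relu:
            mask = y > 0
            y *= mask
        cache = (xp, x.shape, mask) if want_cache else None
        if squeeze:
            y = y[0]
        return y, cache

    def backward(self, g: np.ndarray, cache):
        """Gradients wrt input, weights and bias given the gradient ``g``
        of the (post-ReLU, if any) output.

        The data gradient of a zero-padded stride-1 convolution is itself
        such a convolution of ``g`` with the spatially flipped kernel and
        swapped channel roles, so it reuses the same GEMM loop; the weight
        gradient per tap is the shifted-input / output-gradient product.
        """
        xp, x_shape, mask = cache
        B, H, W, D, _ = x_shape
        if mask is not None:
            g = np.where(mask, g, np.float32(0.0))
        n = B * H * W * D
        gflat = g.reshape(n, self.c_out)
        gb = gflat.sum(axis=0)
        gw = np.empty_like(self.w)
        gp = _pad_spatial(g.reshape(B, H, W, D, self.c_out), self.k // 2)
        gxflat = np.zeros((n, self.c_in), dtype=np.float32)
        tmp = np.empty((n, self.c_in), dtype=np.float32)
        k1 = self.k - 1
        for (i, j, l) in self._offsets():
            block = xp[:, i:i + H, j:j + W, l:l + D, :].reshape(n, self.c_in)
            np.dot(block.T, gflat, out=gw[i, j, l])
            gblock = gp[:, i:i + H, j:j + W, l:l + D, :].reshape(n, self.c_out)
            np.dot(gblock, self.w[k1 - i, k1 - j, k1 - l].T, out=tmp)
            gxflat += tmp
        gx = gxflat.reshape(B, H, W, D, self.c_in)
        return gx, gw, gb


class ConcatBlock:
    """One 3D concatenation block (wide activation + weighted channel
    concatenation).  ``pi`` scales the identity branch, ``lam`` the
    nonlinear branch; both start at 1.0."""

    def __init__(self, c: int, expansion: int, k_cb: int, k_fuse: int,
                 rng: np.random.Generator):
        self.conv_expand = Conv3d(c, expansion * c, k_cb, rng, gain=2.0)
        self.conv_reduce = Conv3d(expansion * c, c, k_cb, rng, gain=1.0)
        self.fuse = Conv3d(2 * c, c, k_fuse, rng, gain=1.0)
        self.pi = np.float32(1.0)
        self.lam = np.float32(1.0)
        self.c = c

    def forward(self, x: np.ndarray, want_cache: bool = False):
        x, squeeze = _ensure_batch(x)
        a, ca = self.conv_expand.forward(x, want_cache, relu=True)
        h, ch = self.conv_reduce.forward(a, want_cache)
        z = np.concatenate([self.pi * x, self.lam * h], axis=-1)
        y, cf = self.fuse.forward(z, want_cache)
        cache = (x, h, ca, ch, cf) if want_cache else None
        if squeeze:
            y = y[0]
        return y, cache

    def backward(self, g: np.ndarray, cache):
        x, h, ca, ch, cf = cache
        gz, gwf, gbf = self.fuse.backward(g, cf)
        g_id, g_nl = gz[..., :self.c], gz[..., self.c:]
        gpi = np.float32(np.sum(g_id * x, dtype=np.float64))
        glam = np.float32(np.sum(g_nl * h, dtype=np.float64))
        gh = self.lam * g_nl
        ga, gwr, gbr = self.conv_reduce.backward(gh, ch)
        gx_nl, gwe, gbe = self.conv_expand.backward(ga, ca)
        gx = self.pi * g_id + gx_nl
        grads = {"expand.w": gwe, "expand.b": gbe, "reduce.w": gwr,
                 "reduce.b": gbr, "fuse.w": gwf, "fuse.b": gbf,
                 "pi": gpi, "lam": glam}
        return gx, grads


def cb_forward(block: ConcatBlock, x: np.ndarray) -> np.ndarray:
    """Forward pass of one concatenation block (functional form)."""
    y, _ = block.forward(x)
    return y


class SRNetwork:
    """The full super-resolution network.

    Input and output are single-channel volumes of identical spatial shape.
    """

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        c = self.cfg.base_channels
        self.extract = Conv3d(self.cfg.in_channels, c, self.cfg.kernel_extract,
                              rng, gain=1.0)
        self.blocks = [ConcatBlock(c, self.cfg.expansion, self.cfg.kernel_cb,
                                   self.cfg.kernel_fuse, rng)
                       for _ in range(self.cfg.n_blocks)]
        self.recon1 = Conv3d(c, c, self.cfg.kernel_recon, rng, gain=1.0)
        self.recon2 = Conv3d(c, self.cfg.out_channels, self.cfg.kernel_recon,
                             rng, gain=1.0)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        params = {"extract.w": self.extract.w, "extract.b": self.extract.b}
        for i, blk in enumerate(self.blocks):
            params[f"block{i}.expand.w"] = blk.conv_expand.w
            params[f"block{i}.expand.b"] = blk.conv_expand.b
            params[f"block{i}.reduce.w"] = blk.conv_reduce.w
            params[f"block{i}.reduce.b"] = blk.conv_reduce.b
            params[f"block{i}.fuse.w"] = blk.fuse.w
            params[f"block{i}.fuse.b"] = blk.fuse.b
            params[f"block{i}.pi"] = blk.pi
            params[f"block{i}.lam"] = blk.lam
        params["recon1.w"] = self.recon1.w
        params["recon1.b"] = self.recon1.b
        params["recon2.w"] = self.recon2.w
        params["recon2.b"] = self.recon2.b
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.extract.w = np.asarray(params["extract.w"], np.float32)
        self.extract.b = np.asarray(params["extract.b"], np.float32)
        for i, blk in enumerate(self.blocks):
            blk.conv_expand.w = np.asarray(params[f"block{i}.expand.w"], np.float32)
            blk.conv_expand.b = np.asarray(params[f"block{i}.expand.b"], np.float32)
            blk.conv_reduce.w = np.asarray(params[f"block{i}.reduce.w"], np.float32)
            blk.conv_reduce.b = np.asarray(params[f"block{i}.reduce.b"], np.float32)
            blk.fuse.w = np.asarray(params[f"block{i}.fuse.w"], np.float32)
            blk.fuse.b = np.asarray(params[f"block{i}.fuse.b"], np.float32)
            blk.pi = np.float32(params[f"block{i}.pi"])
            blk.lam = np.float32(params[f"block{i}.lam"])
        self.recon1.w = np.asarray(params["recon1.w"], np.float32)
        self.recon1.b = np.asarray(params["recon1.b"], np.float32)
        self.recon2.w = np.asarray(params["recon2.w"], np.float32)
        self.recon2.b = np.asarray(params["recon2.b"], np.float32)

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _as_feature(x: np.ndarray) -> tuple[np.ndarray, bool]:
        """(H,W,D) or (B,H,W,D) volume -> (B,H,W,D,1) feature tensor."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            return x[None, ..., None], True
        if x.ndim == 4:
            return x[..., None], False
        raise ValueError(f"expected a 3D volume or a batch of them, got {x.shape}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a (H, W, D) volume (or a (B, H, W, D) batch) to an output of
        the same shape."""
        x, squeeze = self._as_feature(x)
        x0, _ = self.extract.forward(x)
        xi = x0
        for blk in self.blocks:
            xi, _ = blk.forward(xi)
        r1, _ = self.recon1.forward(x0 + xi)
        y, _ = self.recon2.forward(r1)
        y = y[..., 0]
        return y[0] if squeeze else y

    def forward_backward(self, x: np.ndarray, grad_fn):
        """Forward pass plus full backprop.

        ``grad_fn(y)`` must return ``(loss, dloss_dy)`` for the
        (B, H, W, D) prediction ``y``.  Returns ``(y, loss, grads)`` with
        ``grads`` keyed like :meth:`parameters`.
        """
        x, _ = self._as_feature(x)
        x0, c_ex = self.extract.forward(x, want_cache=True)
        xi = x0
        block_caches = []
        for blk in self.blocks:
            xi, cache = blk.forward(xi, want_cache=True)
            block_caches.append(cache)
        s = x0 + xi
        r1, c_r1 = self.recon1.forward(s, want_cache=True)
        y4, c_r2 = self.recon2.forward(r1, want_cache=True)
        y = y4[..., 0]

        loss, gy = grad_fn(y)
        gy = np.asarray(gy, np.float32)
        if gy.ndim == 3:
            gy = gy[None]
        grads: dict[str, np.ndarray] = {}
        g, gw, gb = self.recon2.backward(gy[..., None], c_r2)
        grads["recon2.w"], grads["recon2.b"] = gw, gb
        gs, gw, gb = self.recon1.backward(g, c_r1)
        grads["recon1.w"], grads["recon1.b"] = gw, gb
        g = gs  # flows into xn
        for i in reversed(range(len(self.blocks))):
            g, bg = self.blocks[i].backward(g, block_caches[i])
            for k, v in bg.items():
                grads[f"block{i}.{k}"] = v
        g = g + gs  # global residual skip: x0 receives both paths
        _, gw, gb = self.extract.backward(g, c_ex)
        grads["extract.w"], grads["extract.b"] = gw, gb
        return y, loss, grads


def count_parameters(m: SRNetwork) -> int:
    """Exact number of learnable scalars (kernels, biases, pi and lam)."""
    return int(sum(np.asarray(p).size for p in m.parameters().values()))


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(m: SRNetwork, path: str | Path) -> None:
    """Serialize weights plus the embedded ModelConfig to an .npz file."""
    arrays = {k: np.asarray(v) for k, v in m.parameters().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(m.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> SRNetwork:
    with np.load(path) as npz:
        cfg = ModelConfig(**json.loads(bytes(npz["__config__"]).decode()))
        params = {k: npz[k] for k in npz.files if k != "__config__"}
    m = SRNetwork(cfg)
    m.set_parameters(params)
    return m
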