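"""Simulation of orthogonal thick-slice scans and their fusion.

The sample-generation pipeline mirrors how anisotropic clinical scans arise
from an underlying isotropic object:

1. ``downsample_axis`` reduces one axis by a factor ``r`` (the ratio of
   slice thickness to in-plane voxel size), modelling the partial volume
   effect: each thick slice is a weighted average of the thin slices it
   spans, with a box window of width ``r`` whose extent grows with the
   slice thickness.  Integer and fractional ``r`` share one code path.
2. ``upsample_axis`` brings a scan back to the isotropic grid by cubic
   spline interpolation along the degraded axis.
3. ``fuse_scans`` averages the upsampled scans voxelwise.  This is the
   CubeAvg baseline; with a single scan it degenerates to plain spline
   interpolation of that scan.
4. ``add_rician_noise`` corrupts magnitude data the way MR magnitude images
   are corrupted: the noisy voxel is the magnitude of the complex signal
   plus i.i.d. Gaussian noise on the real and imaginary channels.  The
   noise level sigma is quoted on a 0-255 display scale and applied to
   [0, 1]-normalized volumes as sigma/255.

``extract_training_cubes`` and ``augment_flip`` turn a fused-LR/HR volume
pair into aligned training cubes with flip augmentation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.interpolate import CubicSpline

from .volume import Volume

__all__ = [
    "AnisotropicScan", "OrthogonalScanSet", "TrainingPair",
    "downsample_axis", "upsample_axis", "crop_to_factor",
    "simulate_orthogonal_scans", "fuse_scans", "add_rician_noise",
    "extract_training_cubes", "augment_flip",
]


@dataclasses.dataclass
class AnisotropicScan:
    """A scan degraded along one axis by scaling factor ``factor`` (> 1)."""

    volume: Volume
    axis: int
    factor: float

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValueError(f"axis must be 0, 1 or 2, got {self.axis}")
        if self.factor <= 1:
            raise ValueError(f"factor must be > 1, got {self.factor}")


@dataclasses.dataclass
class OrthogonalScanSet:
    """One to three anisotropic scans with pairwise-distinct degraded axes."""

    scans: list[AnisotropicScan]
    factor: float
    parent_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not 1 <= len(self.scans) <= 3:
            raise ValueError(f"need 1-3 scans, got {len(self.scans)}")
        axes = [s.axis for s in self.scans]
        if len(set(axes)) != len(axes):
            raise ValueError(f"degraded axes must be pairwise distinct, got {axes}")


@dataclasses.dataclass
class TrainingPair:
    """A fused-LR cube and its HR cube cut from identical coordinates."""

    lr_cube: np.ndarray
    hr_cube: np.ndarray
    origin: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.lr_cube.shape != self.hr_cube.shape:
            raise ValueError("lr and hr cubes must share a shape")


def _box_weights(n_in: int, n_out: int, r: float) -> np.ndarray:
    """(n_out, n_in) matrix of overlap weights of a width-``r`` box window
    centred on each output slice position; rows sum to 1."""
    w = np.zeros((n_out, n_in), dtype=np.float64)
    for j in range(n_out):
        center = (j + 0.5) * r - 0.5
        lo, hi = center - r / 2.0, center + r / 2.0
        i0 = max(0, int(math.floor(lo + 0.5)))
        i1 = min(n_in - 1, int(math.ceil(hi - 0.5)))
        for i in range(i0, i1 + 1):
            overlap = min(hi, i + 0.5) - max(lo, i - 0.5)
            if overlap > 0:
                w[j, i] = overlap
    w /= w.sum(axis=1, keepdims=True)
    return w


def downsample_axis(v: Volume, axis: int, r: float) -> Volume:
    """Reduce one axis by factor ``r`` with a box partial-volume window.

    The output length is ``round(L / r)``; each output slice is the
    normalized overlap-weighted average of the input slices inside a window
    of width ``r`` centred on its position.  Spacing along ``axis`` is
    multiplied by ``r``.
    """
    if r <= 1:
        raise ValueError(f"scaling factor must be > 1, got {r}")
    n_in = v.data.shape[axis]
    if r > n_in:
        raise ValueError(f"factor {r} exceeds axis length {n_in}")
    n_out = int(round(n_in / r))
    w = _box_weights(n_in, n_out, float(r)).astype(np.float32)
    data = np.moveaxis(np.tensordot(w, np.moveaxis(v.data, axis, 0), axes=1), 0, axis)
    spacing = list(v.spacing)
    spacing[axis] *= r
    return Volume(data, tuple(spacing), v.intensity_range)


def upsample_axis(v: Volume, axis: int, target_len: int) -> Volume:
    """Cubic-spline interpolate one axis up to ``target_len`` samples.

    Input slice ``i`` is placed at target coordinate ``(i + 0.5) * rho - 0.5``
    with ``rho = target_len / current_len`` (aligned extents), so a request
    for the current length is the identity.
    """
    n_in = v.data.shape[axis]
    if target_len < n_in:
        raise ValueError(f"target_len {target_len} < current length {n_in}")
    if target_len == n_in:
        return v.copy()
    rho = target_len / n_in
    src = (np.arange(n_in) + 0.5) * rho - 0.5
    dst = np.arange(target_len, dtype=np.float64)
    moved = np.moveaxis(v.data.astype(np.float64), axis, 0)
    cs = CubicSpline(src, moved, axis=0)
    data = np.moveaxis(cs(dst), 0, axis).astype(np.float32)
    spacing = list(v.spacing)
    spacing[axis] *= n_in / target_len
    return Volume(data, tuple(spacing), v.intensity_range)


def crop_to_factor(v: Volume, r: float) -> Volume:
    """Crop each axis to the largest leading extent that divides cleanly by
    ``r`` (``round(m * r)`` voxels for the largest integer ``m``), so the
    down/up round trip is unambiguous."""
    slices = []
    for length in v.data.shape:
        m = int(math.floor(length / r))
        if m < 1:
            raise ValueError(f"axis of length {length} too short for factor {r}")
        slices.append(slice(0, int(round(m * r))))
    return Volume(v.data[tuple(slices)], v.spacing, v.intensity_range)


def simulate_orthogonal_scans(y: Volume, r: float,
                              axes: tuple[int, ...] = (0, 1, 2)) -> OrthogonalScanSet:
    """Simulate up to three orthogonal thick-slice scans of ``y``.

    ``y`` is cropped with :func:`crop_to_factor` first; compare downstream
    reconstructions against ``crop_to_factor(y, r)``.
    """
    axes = tuple(axes)
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate axes in {axes}")
    if not axes or any(a not in (0, 1, 2) for a in axes):
        raise ValueError(f"axes must be a non-empty subset of (0, 1, 2), got {axes}")
    if r <= 1:
        raise ValueError(f"scaling factor must be > 1, got {r}")
    cropped = crop_to_factor(y, r)
    scans = [AnisotropicScan(downsample_axis(cropped, a, r), a, r) for a in axes]
    return OrthogonalScanSet(scans, float(r), cropped.data.shape)


def fuse_scans(s: OrthogonalScanSet,
               target_shape: tuple[int, int, int] | None = None) -> Volume:
    """Upsample each scan along its degraded axis and average voxelwise
    (the CubeAvg baseline, also the network input)."""
    if not s.scans:
        raise ValueError("cannot fuse an empty scan set")
    if target_shape is None:
        target_shape = s.parent_shape
    ups = []
    for scan in s.scans:
        up = upsample_axis(scan.volume, scan.axis, target_shape[scan.axis])
        if up.data.shape != tuple(target_shape):
            raise ValueError(
                f"scan degraded on axis {scan.axis} has shape {up.data.shape}, "
                f"expected {tuple(target_shape)}")
        ups.append(up)
    data = np.mean([u.data for u in ups], axis=0, dtype=np.float64).astype(np.float32)
    return Volume(data, ups[0].spacing, s.scans[0].volume.intensity_range)


def add_rician_noise(v: Volume, sigma: float, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> Volume:
    """Make magnitude data Rician-distributed with noise SD ``sigma`` quoted
    on the 0-255 scale: out = sqrt((v + g1)^2 + g2^2) with g1, g2 i.i.d.
    N(0, (sigma/255)^2).  ``sigma=0`` returns the volume unchanged."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return v.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    s = sigma / 255.0
    g1 = rng.normal(0.0, s, size=v.data.shape)
    g2 = rng.normal(0.0, s, size=v.data.shape)
    data = np.sqrt((v.data + g1) ** 2 + g2**2).astype(np.float32)
    return Volume(data, v.spacing, v.intensity_range)


def extract_training_cubes(x: Volume, y: Volume, cube_size: int = 24,
                           n: int = 1, seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           origins: list[tuple[int, int, int]] | None = None,
                           ) -> list[TrainingPair]:
    """Cut ``n`` aligned LR/HR cube pairs at uniformly random valid origins
    (with replacement).  Explicit ``origins`` override the random draw."""
    if x.data.shape != y.data.shape:
        raise ValueError(f"shape mismatch: {x.data.shape} vs {y.data.shape}")
    if any(s < cube_size for s in x.data.shape):
        raise ValueError(
            f"volume shape {x.data.shape} smaller than cube size {cube_size}")
    if origins is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        hi = [s - cube_size + 1 for s in x.data.shape]
        origins = [tuple(int(rng.integers(0, h)) for h in hi) for _ in range(n)]
    pairs = []
    for o in origins:
        sl = tuple(slice(c, c + cube_size) for c in o)
        pairs.append(TrainingPair(x.data[sl].copy(), y.data[sl].copy(), tuple(o)))
    return pairs


def augment_flip(p: TrainingPair, flip_mask: tuple[bool, bool, bool]) -> TrainingPair:
    """Flip both cubes along the masked axes; applying the same mask twice
    restores the original pair."""
    axes = tuple(i for i, f in enumerate(flip_mask) if f)
    if not axes:
        return TrainingPair(p.lr_cube.copy(), p.hr_cube.copy(), p.origin)
    return TrainingPair(np.flip(p.lr_cube, axes).copy(),
                        np.flip(p.hr_cube, axes).copy(), p.origin)
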