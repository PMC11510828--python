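"""Synthetic isotropic phantoms for end-to-end testing without data downloads.

A phantom is a piecewise-smooth volume: a constant background, a handful of
randomly placed and oriented ellipsoids of distinct tissue-like intensities,
and optionally a few small hyperintense lesion blobs (emulating, e.g.,
multiple-sclerosis lesions), all lightly Gaussian-smoothed.  Ellipsoid
boundaries give intensity edges with gradient components along every axis,
so through-plane blurring is observable whichever axis is degraded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import Volume

__all__ = ["PhantomSpec", "make_phantom", "make_phantom_set"]

_BACKGROUND = 0.15
_LESION_BOOST = 0.25


@dataclasses.dataclass
class PhantomSpec:
    """Recipe for one phantom; the seed fully determines the output."""

    size: tuple[int, int, int] = (64, 64, 64)
    n_structures: int = 8
    lesion_count: int = 0
    smoothness: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        self.size = tuple(int(s) for s in self.size)
        if len(self.size) != 3 or min(self.size) < 8:
            raise ValueError(f"size must be >= 8 per axis, got {self.size}")
        if self.n_structures < 0 or self.lesion_count < 0:
            raise ValueError("structure and lesion counts must be >= 0")
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def make_phantom(spec: PhantomSpec, return_info: bool = False):
    """Generate one phantom volume with values in ``[0, 1]``.

    With ``return_info=True`` also returns a dict describing the placed
    structures and lesions (used by tests to probe lesion contrast).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.size
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                                indexing="ij"), axis=-1)  # (H,W,D,3)
    data = np.full(shape, _BACKGROUND, dtype=np.float64)

    structures = []
    for _ in range(spec.n_structures):
        center = rng.uniform([0.2 * s for s in shape], [0.8 * s for s in shape])
        semi = rng.uniform([0.10 * s for s in shape], [0.35 * s for s in shape])
        rot = _random_rotation(rng)
        intensity = rng.uniform(0.25, 0.70)
        d = (grid - center) @ rot.T
        mask = np.sum((d / semi) ** 2, axis=-1) <= 1.0
        data[mask] = intensity  # later structures paint over earlier ones
        structures.append(dict(center=center, semi_axes=semi, intensity=intensity))

    lesions = []
    for _ in range(spec.lesion_count):
        radius = rng.uniform(2.0, 4.0)
        margin = radius + 2.0
        center = rng.uniform([margin] * 3, [s - margin for s in shape])
        dist2 = np.sum((grid - center) ** 2, axis=-1)
        data[dist2 <= radius**2] += _LESION_BOOST
        lesions.append(dict(center=center, radius=radius))

    if spec.smoothness > 0:
        data = gaussian_filter(data, spec.smoothness, mode="nearest")
    data = np.clip(data, 0.0, 1.0)
    vol = Volume(data.astype(np.float32), intensity_range=(0.0, 1.0))
    if return_info:
        return vol, dict(structures=structures, lesions=lesions)
    return vol


def make_phantom_set(n: int, spec: PhantomSpec | None = None,
                     base_seed: int = 0) -> list[Volume]:
    """Generate ``n`` phantoms with seeds ``base_seed .. base_seed + n - 1``."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if spec is None:
        spec = PhantomSpec()
    out = []
    for i in range(n):
        s = dataclasses.replace(spec, seed=base_seed + i)
        out.append(make_phantom(s))
    return out
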