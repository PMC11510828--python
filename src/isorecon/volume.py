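"""3D volume container and NIfTI I/O.

Axis convention used throughout the package: array axes ``(0, 1, 2)``
correspond to the Sagittal, Coronal and Axial slice-select directions.
A scan "degraded along axis 0" is therefore a sagittal thick-slice
acquisition, and so on.  All volumes are stored as 32-bit floats and are
normalized to a canonical intensity range (``[0, 1]`` by default) before
simulation or training, which fixes the scale on which the Rician noise
standard deviation and the PSNR data range are defined.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "UnsupportedImageError", "read_volume", "write_volume",
           "normalize_intensity"]


class UnsupportedImageError(ValueError):
    """Raised for images that are not plain 3D scalar volumes."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing metadata.

    Parameters
    ----------
    data:
        3D float32 array of intensities (arbitrary units).
    spacing:
        Per-axis voxel edge length in millimetres.
    intensity_range:
        The ``(lo, hi)`` range the data has been normalized to, or ``None``
        if the volume has not been normalized.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise UnsupportedImageError(
                f"expected a 3D scalar volume, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.intensity_range)


def read_volume(path: str | Path) -> Volume:
    """Read a 3D scalar NIfTI-1 volume.

    The array is returned in the file's native axis order; spacing is taken
    from the header zooms.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedImageError
        If the file is not parseable as NIfTI or is not a 3D scalar image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(path)
    except nib.filebasedimages.ImageFileError as exc:
        raise UnsupportedImageError(f"not a readable NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    squeezed = np.squeeze(data)
    if squeezed.ndim != 3:
        raise UnsupportedImageError(
            f"expected a 3D scalar image, file has shape {data.shape}")
    if np.iscomplexobj(squeezed):
        raise UnsupportedImageError("complex-valued images are not supported")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(squeezed.astype(np.float32), spacing)


def write_volume(v: Volume, path: str | Path) -> None:
    """Write ``v`` as a NIfTI-1 file readable by :func:`read_volume`."""
    path = Path(path)
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(v.data.astype(np.float32), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, path)


def normalize_intensity(v: Volume, lo: float = 0.0, hi: float = 1.0) -> Volume:
    """Affinely rescale intensities so the volume min maps to ``lo`` and the
    max to ``hi``.  A constant volume maps entirely to ``lo``.  Idempotent
    and monotone."""
    if hi <= lo:
        raise ValueError(f"need hi > lo, got lo={lo}, hi={hi}")
    data = v.data.astype(np.float64)
    dmin, dmax = float(data.min()), float(data.max())
    if dmax == dmin:
        out = np.full(data.shape, lo, dtype=np.float64)
    else:
        # float64 throughout: a near-degenerate range would overflow float32
        out = (data - dmin) * ((hi - lo) / (dmax - dmin)) + lo
        out = np.clip(out, min(lo, hi), max(lo, hi))
    return Volume(out.astype(np.float32), v.spacing, intensity_range=(lo, hi))
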