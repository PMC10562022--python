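"""HU-valued CT volumes on uniform axial-aligned grids: NIfTI I/O, clipping, resampling.

A :class:`CTVolume` is the currency of the whole pipeline: a 3-D float32
grid of Hounsfield units with (x, y, z) voxel spacing in millimetres and a
world-space origin. The third array axis is the axial (slice) axis. World
position of voxel ``i`` is ``origin + i * spacing`` — no direction-cosine
support; volumes are assumed axis-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

HU_MIN = -1024.0
HU_MAX = 3071.0


class FormatError(ValueError):
    """Raised when an on-disk image violates the expected layout."""


@dataclass
class CTVolume:
    """3-D scalar grid in HU with spacing/origin metadata.

    Parameters
    ----------
    voxels
        3-D array of Hounsfield units; cast to float32.
    spacing_mm
        Positive (x, y, z) voxel spacing in millimetres.
    origin_mm
        World coordinate of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3-D grid, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise FormatError("grid dimensions must be >= 1 along every axis")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing components must be > 0, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        """Number of axial slices (third axis)."""
        return self.voxels.shape[2]

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing_mm, self.origin_mm)

    def like(self, voxels: np.ndarray) -> "CTVolume":
        """New volume sharing this volume's grid metadata."""
        return CTVolume(voxels, self.spacing_mm, self.origin_mm)


def _affine(spacing: tuple[float, ...], origin: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI; spacing/origin go into the affine diagonal/translation."""
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), _affine(vol.spacing_mm, vol.origin_mm))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> CTVolume:
    """Read a 3-D NIfTI image as a CTVolume (voxel values interpreted as HU).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FormatError
        If the image is not a 3-D scalar grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D scalar image, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return CTVolume(data, spacing, origin)


def clip_hu(vol: CTVolume, lo: float = HU_MIN, hi: float = HU_MAX) -> CTVolume:
    """Clamp every voxel to the full CT HU data range [-1024, 3071]."""
    return vol.like(np.clip(vol.voxels, lo, hi))


def resample_volume(
    vol: CTVolume,
    target_spacing_mm: tuple[float, float, float],
    interpolation: str = "linear",
) -> CTVolume:
    """Resample onto a uniform grid with the requested spacing.

    The output grid size along each axis is ``ceil(n_in * spacing_in /
    spacing_out)`` so the physical extent is preserved to within one output
    voxel. Sample points are mapped through world coordinates
    (``origin + index * spacing``); values outside the input grid take the
    nearest edge value.

    Parameters
    ----------
    interpolation
        ``"linear"`` for images, ``"nearest"`` for label maps and masks.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be > 0, got {target}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if target == vol.spacing_mm:
        return vol.copy()

    in_shape = vol.shape
    out_shape = tuple(
        int(np.ceil(in_shape[a] * vol.spacing_mm[a] / target[a])) for a in range(3)
    )
    # index in input grid of each output sample: world -> input index space
    grids = np.meshgrid(
        *[np.arange(n) * target[a] / vol.spacing_mm[a] for a, n in enumerate(out_shape)],
        indexing="ij",
    )
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        vol.voxels, np.stack(grids), order=order, mode="nearest", output=np.float32
    )
    return CTVolume(out.reshape(out_shape), target, vol.origin_mm)
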