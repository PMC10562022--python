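"""Otsu auto-thresholding, body-mask extraction, and treatment-couch removal.

The body mask separates anatomy from everything else in the scan: voxels
above an Otsu threshold are foreground candidates, the largest 3-D
connected component (the patient) is kept, internal cavities (bowel gas,
bladder air) are filled slice-wise, and any component disconnected from the
body — most importantly the treatment couch — is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cutsct.volume_io import CTVolume, HU_MIN


class DegenerateInputError(ValueError):
    """Raised when an input has no usable signal (constant image, empty mask)."""


@dataclass(frozen=True)
class OtsuResult:
    threshold: float
    between_class_variance: float
    n_bins: int


@dataclass
class BodyMask:
    """Binary grid marking anatomy; same shape/spacing as its source volume."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(np.uint8)
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask voxels must be exactly {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> OtsuResult:
    """Otsu's histogram threshold maximizing between-class variance.

    The value range is divided into ``n_bins`` equal-width bins; every
    interior bin edge is a candidate threshold and the edge maximizing
    ``w0 * w1 * (mu0 - mu1)**2`` is returned (ties broken by the smallest
    qualifying edge). Values >= the threshold are "above".

    Raises
    ------
    DegenerateInputError
        If the input is constant (fewer than two distinct values).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0 or np.min(values) == np.max(values):
        raise DegenerateInputError("Otsu threshold needs at least two distinct values")
    lo, hi = float(values.min()), float(values.max())
    hist, edges = np.histogram(values, bins=int(n_bins), range=(lo, hi))
    n = hist.sum()
    p = hist / n
    centers = 0.5 * (edges[:-1] + edges[1:])
    # class 0 = bins strictly below the candidate edge k (k = 1..n_bins-1)
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_total - m[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    # smallest edge among (numerically) tied maxima
    vmax = sigma_b.max()
    k = int(np.argmax(sigma_b >= vmax - 1e-12 * abs(vmax)))
    return OtsuResult(
        threshold=float(edges[k + 1]),
        between_class_variance=float(sigma_b[k]),
        n_bins=int(n_bins),
    )


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def extract_body_mask(vol: CTVolume, n_bins: int = 256) -> BodyMask:
    """Extract the body as the largest Otsu-foreground component, couch excluded.

    Steps: Otsu threshold on all voxels; keep the largest 6-connected 3-D
    component of the above-threshold set; fill internal cavities slice by
    slice. Anything not connected to the body in 3-D (the treatment couch,
    detached clutter) is dropped.
    """
    thr = otsu_threshold(vol.voxels, n_bins=n_bins).threshold
    fg = vol.voxels >= thr
    if not fg.any():
        raise DegenerateInputError("no foreground voxels above the Otsu threshold")
    labels, n_comp = ndimage.label(fg, structure=_STRUCT6)
    if n_comp == 0:
        raise DegenerateInputError("no connected foreground component")
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_comp + 1))
    body = labels == (int(np.argmax(sizes)) + 1)
    filled = np.empty_like(body)
    for z in range(body.shape[2]):
        filled[:, :, z] = ndimage.binary_fill_holes(body[:, :, z])
    return BodyMask(filled, vol.spacing_mm)


def apply_mask(vol: CTVolume, mask: BodyMask, fill: float = HU_MIN) -> CTVolume:
    """Set voxels outside the mask to ``fill`` (air by default); keep the rest."""
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    out = np.where(mask.voxels.astype(bool), vol.voxels, np.float32(fill))
    return vol.like(out)
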