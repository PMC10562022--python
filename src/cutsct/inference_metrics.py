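"""Slice-wise volume translation and the evaluation suite: MAE, RMSE, SSIM, FID, folds.

MAE and RMSE are the arithmetic and quadratic means of voxel-wise HU
errors over the body mask. SSIM is the global-statistics form

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with the conventional constants c1 = (0.01 L)^2, c2 = (0.03 L)^2 over the
full HU dynamic range L = 4095, computed from population moments over the
mask. FID is the Frechet distance between Gaussian fits of deep-feature
distributions of two image sets; the pluggable extractor uses a seeded
fixed random projection by default (an Inception-v3 backend is defined but
requires pretrained weights at runtime). Cross-validation results are
summarized as mean with standard error (sample SD / sqrt(k)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cutsct.hu_codec import (
    HUPartition, ChannelizedSlice, partition_edges,
    encode_slice, decode_slice, channels_to_unit, unit_to_channels,
)
from cutsct.networks import Generator
from cutsct.nn.autograd import Tensor, no_grad
from cutsct.preprocess import BodyMask, DegenerateInputError, apply_mask
from cutsct.volume_io import CTVolume, HU_MIN


class CapabilityError(RuntimeError):
    """An optional runtime capability (pretrained backend) is unavailable."""


@dataclass(frozen=True)
class SSIMParams:
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 4095.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


@dataclass
class MetricsReport:
    """Per-volume MAE/RMSE/SSIM plus set-level FID."""

    mae_hu: float
    rmse_hu: float
    ssim: float
    n_voxels: int
    fid: float | None = None

    def __post_init__(self) -> None:
        if self.mae_hu > self.rmse_hu + 1e-9:
            raise ValueError("MAE cannot exceed RMSE")


@dataclass(frozen=True)
class FoldSummary:
    values: tuple[float, ...]
    mean: float
    se: float

    @property
    def k(self) -> int:
        return len(self.values)


def translate_volume(
    vol: CTVolume,
    gen: Generator,
    mask: BodyMask,
    part: HUPartition | None = None,
) -> CTVolume:
    """Translate a clipped, masked volume slice by slice through the generator.

    Each axial slice is channel-encoded, mapped to the network's [-1, 1]
    domain, passed through the generator in evaluation mode, decoded back
    to HU, and the body mask is re-applied with air fill. The output grid
    is identical to the input grid.
    """
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    part = part or partition_edges()
    gen.eval()
    out = np.empty_like(vol.voxels)
    with no_grad():
        for z in range(vol.n_slices):
            cs = encode_slice(vol.voxels[:, :, z], part)
            x = Tensor(channels_to_unit(cs.channels)[None])
            y = gen(x)
            ch = unit_to_channels(y.data[0])
            out[:, :, z] = decode_slice(ChannelizedSlice(ch), part)
    sct = vol.like(out)
    return apply_mask(sct, mask, fill=HU_MIN)


def _masked_pair(a: CTVolume, b: CTVolume, mask: BodyMask) -> tuple[np.ndarray, np.ndarray]:
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("volume/mask grids disagree")
    m = mask.voxels.astype(bool)
    if not m.any():
        raise DegenerateInputError("empty mask")
    return a.voxels[m].astype(np.float64), b.voxels[m].astype(np.float64)


def mae(a: CTVolume, b: CTVolume, mask: BodyMask) -> float:
    """Mean absolute HU error over mask voxels."""
    xa, xb = _masked_pair(a, b, mask)
    return float(np.mean(np.abs(xa - xb)))


def rmse(a: CTVolume, b: CTVolume, mask: BodyMask) -> float:
    """Quadratic mean of voxel-wise HU errors over mask voxels."""
    xa, xb = _masked_pair(a, b, mask)
    return float(np.sqrt(np.mean((xa - xb) ** 2)))


def ssim(a: CTVolume, b: CTVolume, mask: BodyMask,
         params: SSIMParams = SSIMParams()) -> float:
    """Global-statistics structural similarity over mask voxels."""
    xa, xb = _masked_pair(a, b, mask)
    if xa.size < 2:
        raise DegenerateInputError("SSIM needs at least 2 mask voxels")
    mu_x, mu_y = xa.mean(), xb.mean()
    var_x, var_y = xa.var(), xb.var()          # population (n) moments
    cov = ((xa - mu_x) * (xb - mu_y)).mean()
    c1, c2 = params.c1, params.c2
    return float(
        ((2 * mu_x * mu_y + c1) * (2 * cov + c2))
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def fid(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Frechet distance between Gaussian fits of two feature sets.

    ``||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^(1/2))`` with the
    trace term evaluated through symmetric eigendecompositions
    (Tr((S_a S_b)^(1/2)) = Tr((S_a^(1/2) S_b S_a^(1/2))^(1/2))), clamping
    tiny negative eigenvalues to zero. Covariances use the n-1 denominator.
    """
    fa = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    fb = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise DegenerateInputError("FID needs at least 2 feature vectors per set")
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    sa = np.cov(fa, rowvar=False)
    sb = np.cov(fb, rowvar=False)
    sa, sb = np.atleast_2d(sa), np.atleast_2d(sb)

    wa, va = np.linalg.eigh(sa)
    sqrt_sa = (va * np.sqrt(np.clip(wa, 0.0, None))) @ va.T
    m = sqrt_sa @ sb @ sqrt_sa
    wm = np.linalg.eigvalsh((m + m.T) / 2.0)
    tr_sqrt = np.sqrt(np.clip(wm, 0.0, None)).sum()
    d2 = float(np.sum((mu_a - mu_b) ** 2) + np.trace(sa) + np.trace(sb) - 2.0 * tr_sqrt)
    return max(d2, 0.0)


def feature_extractor(
    images: list[np.ndarray] | np.ndarray,
    backend: str = "fixed-projection",
    out_dim: int = 64,
    pool_size: int = 16,
    seed: int = 1234,
) -> np.ndarray:
    """Per-image feature vectors for FID.

    ``fixed-projection``: each 2-D image is average-pooled to a
    ``pool_size`` square, standardized, and passed through a seeded
    Gaussian random linear projection to ``out_dim`` — deterministic
    across processes and download-free. ``inception-imagenet`` denotes the
    2048-d deepest-pooling features of an ImageNet-pretrained Inception
    v3; it requires pretrained weights at runtime and raises
    :class:`CapabilityError` when they are unavailable.
    """
    if backend == "inception-imagenet":
        raise CapabilityError(
            "Inception-v3 weights are not available in this runtime; "
            "use backend='fixed-projection'."
        )
    if backend != "fixed-projection":
        raise ValueError(f"unknown feature backend {backend!r}")
    imgs = [np.asarray(im, dtype=np.float64) for im in images]
    rng = np.random.default_rng(seed)
    proj = rng.normal(0.0, 1.0 / pool_size, size=(pool_size * pool_size, out_dim))
    feats = np.empty((len(imgs), out_dim))
    for i, im in enumerate(imgs):
        if im.ndim == 3:  # channelized slice: decode-free luminance proxy
            im = im.mean(axis=0)
        zoomed = ndimage.zoom(im, (pool_size / im.shape[0], pool_size / im.shape[1]),
                              order=1, mode="nearest", grid_mode=True)
        v = zoomed.ravel()
        v = (v - v.mean()) / (v.std() + 1e-8)
        feats[i] = v @ proj
    return feats


def volume_fid(a: CTVolume, b: CTVolume, mask_a: BodyMask, mask_b: BodyMask,
               seed: int = 1234) -> float:
    """Set-level FID between the masked axial slices of two volumes."""
    sa = [apply_mask(a, mask_a).voxels[:, :, z] for z in range(a.n_slices)]
    sb = [apply_mask(b, mask_b).voxels[:, :, z] for z in range(b.n_slices)]
    return fid(feature_extractor(sa, seed=seed), feature_extractor(sb, seed=seed))


def evaluate_volume(pred: CTVolume, truth: CTVolume, mask: BodyMask,
                    ssim_params: SSIMParams = SSIMParams()) -> MetricsReport:
    """Per-volume MAE/RMSE/SSIM report over mask voxels."""
    return MetricsReport(
        mae_hu=mae(pred, truth, mask),
        rmse_hu=rmse(pred, truth, mask),
        ssim=ssim(pred, truth, mask, ssim_params),
        n_voxels=mask.n_foreground,
    )


def aggregate_folds(values: list[float] | tuple[float, ...]) -> FoldSummary:
    """Cross-validation mean with standard error (sample SD / sqrt(k))."""
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise DegenerateInputError("fold aggregation needs k >= 2 values")
    arr = np.asarray(vals)
    return FoldSummary(vals, float(arr.mean()),
                       float(arr.std(ddof=1) / np.sqrt(len(vals))))
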