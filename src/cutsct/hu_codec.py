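"""Three-segment HU <-> three-channel 8-bit codec.

The full CT number range [-1024, 3071] is partitioned into equal segments
([-1024, 341], [341, 1706], [1706, 3071] for the default three-way split)
and each segment is rescaled to [0, 255] in its own 8-bit channel. A pixel
fills channels in a saturating ("thermometer") scheme: channels below its
segment read 255, channels above read 0, and the channel owning the
segment holds the rescaled fractional position. This keeps the encoding
monotone in HU and makes decoding an affine function of the channel sum,
so the full HU dynamic range survives 8-bit quantization with a bounded
round-trip error (half of one quantization step, ~2.68 HU for the default
partition).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass(frozen=True)
class HUPartition:
    """Ordered HU segment edges [e0 < e1 < ... < eN]."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        if len(self.edges) < 2:
            raise ValueError("a partition needs at least two edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError(f"edges must be strictly increasing, got {self.edges}")

    @property
    def n_segments(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(b - a for a, b in zip(self.edges, self.edges[1:]))


@dataclass
class ChannelizedSlice:
    """n_segments x H x W uint8 grid; channel 0 carries the lowest HU segment."""

    channels: np.ndarray

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels)
        if ch.ndim != 3:
            raise ValueError(f"channels must be 3-D (C, H, W), got ndim={ch.ndim}")
        if ch.min() < 0 or ch.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.channels = ch.astype(np.uint8)

    @property
    def n_segments(self) -> int:
        return self.channels.shape[0]


def partition_edges(lo: float = HU_MIN, hi: float = HU_MAX, n_segments: int = 3) -> HUPartition:
    """Equal-width partition of [lo, hi] into n_segments segments."""
    if hi <= lo:
        raise ValueError(f"hi must exceed lo, got ({lo}, {hi})")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    edges = [lo + k * (hi - lo) / n_segments for k in range(n_segments + 1)]
    return HUPartition(tuple(edges))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # numpy's round() is round-half-to-even; the codec pins half-away-from-zero
    # so the quantization bound is exact and platform-independent
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def encode_slice(hu: np.ndarray, part: HUPartition) -> ChannelizedSlice:
    """Encode a 2-D HU grid into saturating per-segment 8-bit channels.

    Channel ``c`` at each pixel is ``round(255 * clip((h - e_c) /
    (e_{c+1} - e_c), 0, 1))``; out-of-range values saturate.
    """
    hu = np.asarray(hu, dtype=np.float64)
    if hu.ndim != 2:
        raise ValueError(f"expected a 2-D HU grid, got ndim={hu.ndim}")
    edges = np.asarray(part.edges)
    frac = (hu[None, :, :] - edges[:-1, None, None]) / np.diff(edges)[:, None, None]
    ch = _round_half_away(255.0 * np.clip(frac, 0.0, 1.0))
    return ChannelizedSlice(ch.astype(np.uint8))


def decode_slice(cs: ChannelizedSlice, part: HUPartition) -> np.ndarray:
    """Decode saturating channels back to HU: ``e0 + sum_c (v_c/255) * width_c``."""
    ch = np.asarray(cs.channels, dtype=np.float64)
    if ch.shape[0] != part.n_segments:
        raise ValueError(
            f"channel count {ch.shape[0]} != partition segments {part.n_segments}"
        )
    if ch.min() < 0 or ch.max() > 255:
        raise ValueError("channel values out of [0, 255]")
    widths = np.asarray(part.widths)
    return part.edges[0] + np.tensordot(widths, ch / 255.0, axes=(0, 0))


# Channel values occupy [-UNIT_SCALE, UNIT_SCALE] rather than the full span of
# the generator's bounded tanh output. The saturating codec needs exact channel
# extremes (0 and 255) for in-segment pixels, and a tanh can only reach +-1
# asymptotically; leaving headroom keeps the extremes expressible at finite
# pre-activations (and with live gradients), which removes a systematic
# one-sided decode bias.
UNIT_SCALE = 0.9


def channels_to_unit(ch: np.ndarray) -> np.ndarray:
    """Map uint8 channels to the network's bounded float domain."""
    return (np.asarray(ch, dtype=np.float32) / 127.5 - 1.0) * UNIT_SCALE


def unit_to_channels(x: np.ndarray) -> np.ndarray:
    """Map bounded network outputs back to uint8 channels (clipped, rounded)."""
    u = np.asarray(x, dtype=np.float64) / UNIT_SCALE
    v = _round_half_away(np.clip((u + 1.0) * 127.5, 0.0, 255.0))
    return v.astype(np.uint8)


def save_preview_png(cs: ChannelizedSlice, path: str | Path) -> None:
    """Export a channelized slice as an 8-bit RGB PNG (low segment -> R)."""
    from PIL import Image

    if cs.n_segments != 3:
        raise ValueError("PNG preview requires exactly 3 channels")
    rgb = np.moveaxis(cs.channels, 0, -1)
    Image.fromarray(rgb, mode="RGB").save(str(path))
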