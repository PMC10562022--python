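"""Translation networks: ResNet generator, 70x70 patch discriminator, patch projector.

The generator is the familiar residual encoder-decoder used for unpaired
image translation (7x7 stem, two stride-2 downsampling convolutions, nine
residual blocks, two stride-2 transposed convolutions, 7x7 head, reflection
padding, instance normalization without learned affine, biases on every
convolution, tanh output). The discriminator is the 70x70-receptive-field
patch classifier (4x4 kernels, strides 2,2,2,1,1) returning a spatial map
of patch scores. The projector is a per-tap two-layer perceptron mapping
encoder patch vectors to unit-normalized 256-d embeddings for the
contrastive loss.

With the default specs the trainable-parameter counts are exact:
generator 11,378,179; discriminator 2,764,737; projector 560,384.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cutsct.nn import (
    Module, Sequential, Conv2d, ConvTranspose2d, Linear,
    InstanceNorm2d, ReLU, LeakyReLU, Tanh, ReflectionPad2d,
)
from cutsct.nn.autograd import Tensor, l2_normalize_rows, sample_spatial

INIT_SCALE = 0.02


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 3
    out_channels: int = 3
    base_filters: int = 64
    n_resblocks: int = 9
    norm: str = "instance-no-affine"
    padding: str = "reflection"

    def validate(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1 or self.base_filters < 1:
            raise ValueError("channel counts must be positive")
        if self.n_resblocks < 1:
            raise ValueError("n_resblocks must be >= 1")
        if self.norm != "instance-no-affine" or self.padding != "reflection":
            raise ValueError("unsupported norm/padding variant")


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 3
    base_filters: int = 64
    n_layers: int = 3
    norm: str = "instance-no-affine"

    def validate(self) -> None:
        if self.in_channels < 1 or self.base_filters < 1 or self.n_layers < 1:
            raise ValueError("invalid discriminator spec")


@dataclass(frozen=True)
class ProjectorSpec:
    tap_layer_ids: tuple[int, ...] = (0, 4, 8, 12, 16)
    tap_channel_dims: tuple[int, ...] = (3, 128, 256, 256, 256)
    width: int = 256

    def validate(self) -> None:
        if len(self.tap_layer_ids) != len(self.tap_channel_dims):
            raise ValueError("tap ids and dims must align")
        if self.width < 1 or any(d < 1 for d in self.tap_channel_dims):
            raise ValueError("invalid projector dims")


class _ResBlock(Module):
    def __init__(self, ch: int, rng):
        super().__init__()
        self.body = Sequential(
            Conv2d(ch, ch, 3, pad=1, pad_mode="reflect", rng=rng),
            InstanceNorm2d(), ReLU(),
            Conv2d(ch, ch, 3, pad=1, pad_mode="reflect", rng=rng),
            InstanceNorm2d(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return x + self.body(x)


class Generator(Module):
    """Residual encoder-decoder translator with encoder feature taps.

    Tap ids follow the conventional flattened-layer numbering of the
    reference architecture: 0 is the raw input, 4 and 8 the two
    downsampling stages, 12 and 16 residual blocks one and two thirds of
    the way through the encoder.
    """

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        nf = spec.base_filters
        self.stem = Sequential(
            ReflectionPad2d(3),
            Conv2d(spec.in_channels, nf, 7, rng=rng),
            InstanceNorm2d(), ReLU(),
        )
        self.down1 = Sequential(
            Conv2d(nf, 2 * nf, 3, stride=2, pad=1, rng=rng), InstanceNorm2d(), ReLU()
        )
        self.down2 = Sequential(
            Conv2d(2 * nf, 4 * nf, 3, stride=2, pad=1, rng=rng), InstanceNorm2d(), ReLU()
        )
        self.blocks = Sequential(*[_ResBlock(4 * nf, rng) for _ in range(spec.n_resblocks)])
        self.up1 = Sequential(
            ConvTranspose2d(4 * nf, 2 * nf, rng=rng), InstanceNorm2d(), ReLU()
        )
        self.up2 = Sequential(
            ConvTranspose2d(2 * nf, nf, rng=rng), InstanceNorm2d(), ReLU()
        )
        self.head = Sequential(
            ReflectionPad2d(3), Conv2d(nf, spec.out_channels, 7, rng=rng), Tanh()
        )
        n = spec.n_resblocks
        b1 = max(0, n // 3 - 1)
        b2 = min(n - 1, max(b1 + 1, (7 * n) // 9 - 1)) if n > 1 else b1
        self._tap_blocks = {12: b1, 16: b2}

    @property
    def tap_channel_dims(self) -> dict[int, int]:
        nf = self.spec.base_filters
        return {0: self.spec.in_channels, 4: 2 * nf, 8: 4 * nf, 12: 4 * nf, 16: 4 * nf}

    def encode(self, x: Tensor, taps: tuple[int, ...]) -> dict[int, Tensor]:
        """Run the encoder, returning activations at the requested taps."""
        known = self.tap_channel_dims
        for t in taps:
            if t not in known:
                raise ValueError(f"unknown tap id {t}; known: {sorted(known)}")
        feats: dict[int, Tensor] = {}
        if 0 in taps:
            feats[0] = x
        h = self.stem(x)
        h = self.down1(h)
        if 4 in taps:
            feats[4] = h
        h = self.down2(h)
        if 8 in taps:
            feats[8] = h
        for i, blk in enumerate(self.blocks.mods):
            h = blk(h)
            if 12 in taps and i == self._tap_blocks[12]:
                feats[12] = h
            if 16 in taps and i == self._tap_blocks[16]:
                feats[16] = h
        feats[-1] = h  # bottleneck, used to continue decoding
        return feats

    def decode(self, h: Tensor) -> Tensor:
        h = self.up1(h)
        h = self.up2(h)
        return self.head(h)

    def forward(self, x: Tensor) -> Tensor:
        feats = self.encode(x, ())
        return self.decode(feats[-1])

    def forward_with_taps(self, x: Tensor, taps: tuple[int, ...]) -> tuple[Tensor, dict[int, Tensor]]:
        """One pass returning both the translation and the encoder tap features."""
        feats = self.encode(x, tuple(taps))
        out = self.decode(feats.pop(-1))
        return out, feats


class Discriminator(Module):
    """PatchGAN: spatial map of real/fake scores over overlapping patches."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        nf = spec.base_filters
        mods: list[Module] = [Conv2d(spec.in_channels, nf, 4, stride=2, pad=1, rng=rng),
                              LeakyReLU(0.2)]
        mult = 1
        for n in range(1, spec.n_layers):
            prev, mult = mult, min(2 ** n, 8)
            mods += [Conv2d(nf * prev, nf * mult, 4, stride=2, pad=1, rng=rng),
                     InstanceNorm2d(), LeakyReLU(0.2)]
        prev, mult = mult, min(2 ** spec.n_layers, 8)
        mods += [Conv2d(nf * prev, nf * mult, 4, stride=1, pad=1, rng=rng),
                 InstanceNorm2d(), LeakyReLU(0.2),
                 Conv2d(nf * mult, 1, 4, stride=1, pad=1, rng=rng)]
        self.body = Sequential(*mods)

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class PatchProjector(Module):
    """Per-tap two-layer perceptron with unit-normalized outputs."""

    def __init__(self, spec: ProjectorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.heads: dict[int, Sequential] = {}
        for tap, dim in zip(spec.tap_layer_ids, spec.tap_channel_dims):
            head = Sequential(Linear(dim, spec.width, rng=rng), ReLU(),
                              Linear(spec.width, spec.width, rng=rng))
            self.heads[tap] = head
            self._children[f"head{tap}"] = head

    def forward(self, tap: int, patches: Tensor) -> Tensor:
        if tap not in self.heads:
            raise ValueError(f"no projection head for tap {tap}")
        return l2_normalize_rows(self.heads[tap](patches))

    def __call__(self, tap: int, patches: Tensor) -> Tensor:
        return self.forward(tap, patches)


def projector_spec_for(gen: Generator, width: int = 256,
                       taps: tuple[int, ...] = (0, 4, 8, 12, 16)) -> ProjectorSpec:
    """Projector spec whose tap dims match a generator's encoder taps."""
    dims = gen.tap_channel_dims
    return ProjectorSpec(tuple(taps), tuple(dims[t] for t in taps), width)


def build_generator(spec: GeneratorSpec = GeneratorSpec(), seed: int = 0) -> Generator:
    return Generator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec = DiscriminatorSpec(), seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed)


def build_projector(spec: ProjectorSpec = ProjectorSpec(), seed: int = 0) -> PatchProjector:
    return PatchProjector(spec, seed)


def count_parameters(net: Module | None) -> int:
    """Exact count of trainable scalars in a built network (0 for empty)."""
    if net is None:
        return 0
    return net.n_parameters()


def extract_features(gen: Generator, x: Tensor, taps: tuple[int, ...]) -> dict[int, Tensor]:
    """Encoder activations at the requested taps; tap 0 is the input itself."""
    feats = gen.encode(x, tuple(taps))
    return {t: feats[t] for t in taps}


def sample_patches(
    features: dict[int, Tensor],
    n_patches: int,
    locations: dict[int, np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[int, Tensor], dict[int, np.ndarray]]:
    """Draw patch vectors at uniform spatial locations without replacement.

    When ``locations`` is supplied (pairing output queries with input
    positives at identical positions) it is reused exactly; otherwise fresh
    locations are drawn per tap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[int, Tensor] = {}
    locs: dict[int, np.ndarray] = {}
    for tap, feat in features.items():
        _, _, H, W = feat.shape
        grid = H * W
        if locations is not None:
            idx = locations[tap]
        else:
            if n_patches > grid:
                raise ValueError(f"n_patches={n_patches} exceeds grid size {grid} at tap {tap}")
            idx = rng.permutation(grid)[:n_patches]
        out[tap] = sample_spatial(feat, idx)
        locs[tap] = idx
    return out, locs
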