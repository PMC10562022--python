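"""Unpaired adversarial training: folds, learning-rate schedule, the loop, checkpoints.

Training consumes two shuffled, unpaired streams of channel-encoded axial
slices (the CBCT-like source domain and the FBCT-like target domain). Each
iteration draws one slice from each stream, updates the patch
discriminator on (real y, fake G(x)), then updates the generator and
projector jointly on the adversarial term plus the two contrastive terms.
Both optimizers are Adam with momentum pair (0.5, 0.999); the learning
rate is constant for the first phase and decays linearly to exactly zero
over the second. Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from cutsct.networks import (
    Generator, Discriminator, PatchProjector,
    GeneratorSpec, DiscriminatorSpec,
    build_generator, build_discriminator, build_projector, projector_spec_for,
)
from cutsct.nn import Adam
from cutsct.nn.autograd import Tensor, no_grad
from cutsct.objectives import (
    NCEConfig, ObjectiveWeights, adversarial_loss,
    multilayer_nce_loss, total_objective,
)


@dataclass(frozen=True)
class TrainConfig:
    """Schedule, optimizer, and loss settings for one training run.

    The learning-rate schedule is a constant phase of ``epochs_constant``
    epochs followed by a linear decay to exactly zero over
    ``epochs_decay`` epochs (3 + 3 by default).
    """

    epochs_constant: int = 3
    epochs_decay: int = 3
    base_lr: float = 2e-4
    batch_size: int = 1
    seed: int = 0
    augment_flip: bool = False
    nce: NCEConfig = field(default_factory=NCEConfig)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)

    def __post_init__(self) -> None:
        if self.epochs_constant < 0 or self.epochs_decay < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.epochs_constant + self.epochs_decay < 1:
            raise ValueError("at least one epoch required")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be > 0")

    @property
    def total_epochs(self) -> int:
        return self.epochs_constant + self.epochs_decay


@dataclass(frozen=True)
class FoldSplit:
    """Patient-level k-fold partition: fold i holds a disjoint patient set."""

    folds: tuple[tuple[str, ...], ...]
    volume_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.folds:
            for pid in f:
                if pid in seen:
                    raise ValueError(f"patient {pid} appears in two folds")
                seen.add(pid)

    @property
    def k(self) -> int:
        return len(self.folds)


def make_patient_folds(
    patients: dict[str, int] | list[str], k: int = 5, seed: int = 0
) -> FoldSplit:
    """Random patient-level partition into k near-equal folds.

    ``patients`` maps patient id -> number of volumes (replans included);
    a plain list means one volume each. All volumes of one patient land in
    one fold, so no patient leaks across folds.
    """
    if not isinstance(patients, dict):
        patients = {p: 1 for p in patients}
    ids = sorted(patients)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of patients {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, pid in enumerate(perm):
        folds[i % k].append(pid)
    counts = tuple(sum(patients[p] for p in f) for f in folds)
    return FoldSplit(tuple(tuple(f) for f in folds), counts)


def lr_at(epoch: float, cfg: TrainConfig) -> float:
    """Learning rate at a (possibly fractional) epoch position."""
    total = cfg.total_epochs
    if epoch < 0 or epoch > total:
        raise ValueError(f"epoch {epoch} outside [0, {total}]")
    if epoch < cfg.epochs_constant or cfg.epochs_decay == 0:
        return cfg.base_lr
    frac = (epoch - cfg.epochs_constant) / cfg.epochs_decay
    return cfg.base_lr * (1.0 - frac)


@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator
    projector: PatchProjector
    loss_log: list[dict]
    checkpoint_dir: Path | None


def save_checkpoint(path: str | Path, gen: Generator, disc: Discriminator,
                    proj: PatchProjector, cfg: TrainConfig, epoch: int) -> None:
    """Persist weights plus the full specs, config, and seed (npz + json sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for prefix, net in (("G", gen), ("D", disc), ("H", proj)):
        for k, v in net.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    np.savez(path, **arrays)
    meta = {
        "generator_spec": asdict(gen.spec),
        "discriminator_spec": asdict(disc.spec),
        "projector_spec": {"tap_layer_ids": list(proj.spec.tap_layer_ids),
                           "tap_channel_dims": list(proj.spec.tap_channel_dims),
                           "width": proj.spec.width},
        "config": _cfg_dict(cfg),
        "epoch": epoch,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def _cfg_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d


def load_checkpoint(path: str | Path) -> tuple[Generator, Discriminator, PatchProjector, dict]:
    """Rebuild the three networks from a checkpoint; validates spec consistency."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    gen = build_generator(GeneratorSpec(**meta["generator_spec"]))
    disc = build_discriminator(DiscriminatorSpec(**meta["discriminator_spec"]))
    proj = build_projector(projector_spec_for(gen,
                                              width=meta["projector_spec"]["width"],
                                              taps=tuple(meta["projector_spec"]["tap_layer_ids"])))
    if list(proj.spec.tap_channel_dims) != meta["projector_spec"]["tap_channel_dims"]:
        raise ValueError("checkpoint projector dims inconsistent with generator spec")
    with np.load(path) as z:
        for prefix, net in (("G", gen), ("D", disc), ("H", proj)):
            state = {k[len(prefix) + 1:]: z[k] for k in z.files if k.startswith(prefix + "/")}
            net.load_state_dict(state)
    return gen, disc, proj, meta


def train(
    cbct_slices: list[np.ndarray],
    fbct_slices: list[np.ndarray],
    cfg: TrainConfig,
    gen_spec: GeneratorSpec = GeneratorSpec(),
    disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
    nce_taps: tuple[int, ...] = (0, 4, 8, 12, 16),
    checkpoint_dir: str | Path | None = None,
    iterations_per_epoch: int | None = None,
) -> TrainResult:
    """Run the unpaired training loop on channel-encoded [-1, 1] slices.

    Parameters
    ----------
    cbct_slices, fbct_slices
        Lists of (3, H, W) float arrays in [-1, 1] (masked, clipped,
        channel-encoded source/target slices). The two lists are unpaired
        and independently shuffled every epoch.
    iterations_per_epoch
        Cap on iterations per epoch; defaults to the source-stream length.

    Returns
    -------
    TrainResult with trained networks and a per-iteration loss log
    (step, lr, l_d, l_gan, l_nce_x, l_nce_y, total).
    """
    if not cbct_slices or not fbct_slices:
        raise ValueError("both slice streams must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(gen_spec, seed=int(rng.integers(2**31)))
    disc = build_discriminator(disc_spec, seed=int(rng.integers(2**31)))
    proj = build_projector(projector_spec_for(gen, taps=nce_taps),
                           seed=int(rng.integers(2**31)))

    opt_d = Adam(disc.parameters(), lr=cfg.base_lr)
    opt_g = Adam(gen.parameters() + proj.parameters(), lr=cfg.base_lr)

    n_iter = iterations_per_epoch or len(cbct_slices)
    log: list[dict] = []
    step = 0
    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None

    for epoch in range(cfg.total_epochs):
        lr = lr_at(epoch, cfg)
        opt_d.lr = lr
        opt_g.lr = lr
        x_order = rng.permutation(len(cbct_slices))
        y_order = rng.permutation(len(fbct_slices))
        for it in range(n_iter):
            x_np = cbct_slices[x_order[it % len(cbct_slices)]]
            y_np = fbct_slices[y_order[it % len(fbct_slices)]]
            if cfg.augment_flip:
                if rng.random() < 0.5:
                    x_np = x_np[:, :, ::-1].copy()
                if rng.random() < 0.5:
                    y_np = y_np[:, :, ::-1].copy()
            x = Tensor(x_np[None])
            y = Tensor(y_np[None])

            # discriminator update on (real y, detached fake)
            with no_grad():
                fake_det = gen(x).detach()
            d_real = adversarial_loss(disc(y), True)
            d_fake = adversarial_loss(disc(fake_det), False)
            loss_d = 0.5 * (d_real + d_fake)
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()

            # generator + projector update; discriminator weights frozen
            for p in disc.parameters():
                p.requires_grad = False
            fake, feats_x = gen.forward_with_taps(x, nce_taps)
            l_gan = adversarial_loss(disc(fake), True)
            l_nce_x = multilayer_nce_loss(gen, proj, x, fake, cfg.nce, rng,
                                          nce_taps, feats_src=feats_x)
            idt, feats_y = gen.forward_with_taps(y, nce_taps)
            l_nce_y = multilayer_nce_loss(gen, proj, y, idt, cfg.nce, rng,
                                          nce_taps, feats_src=feats_y)
            loss_g = total_objective(l_gan, l_nce_x, l_nce_y, cfg.weights)
            opt_g.zero_grad()
            loss_g.backward()
            opt_g.step()
            for p in disc.parameters():
                p.requires_grad = True

            rec = {"step": step, "epoch": epoch, "lr": lr,
                   "l_d": loss_d.item(), "l_gan": l_gan.item(),
                   "l_nce_x": l_nce_x.item(), "l_nce_y": l_nce_y.item(),
                   "total": loss_g.item()}
            if not all(np.isfinite(v) for v in rec.values()):
                raise FloatingPointError(f"non-finite loss at step {step}: {rec}")
            log.append(rec)
            step += 1
        if ckpt_dir is not None:
            save_checkpoint(ckpt_dir / f"epoch_{epoch + 1}.ckpt.npz",
                            gen, disc, proj, cfg, epoch + 1)
            (ckpt_dir / "loss_log.jsonl").write_text(
                "\n".join(json.dumps(r) for r in log) + "\n")

    gen.eval(); disc.eval(); proj.eval()
    return TrainResult(gen, disc, proj, log, ckpt_dir)
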