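"""One-call scaled end-to-end experiment: simulate, train, translate, evaluate.

Generates a seeded unpaired phantom cohort, trains the contrastive
translator on the training patients' slices, translates the held-out
patients' degraded volumes, and reports masked MAE of the degraded inputs
and of the synthetic CTs against the clean ground truth, plus training
health indicators (finite losses, output variance across inputs).

The default problem size is a deliberately reduced version of the full
pipeline so the whole experiment runs in minutes on one CPU core: 10
phantom patients on 32x32x16 grids, a 8-filter/2-block generator with a
single-downsampling patch discriminator (keeping the patch receptive
field local relative to the image, as in the full-size design), and the
3 + 3 constant/decay epoch schedule. See docs/methods.md for the
reasoning behind these sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cutsct.hu_codec import channels_to_unit, encode_slice, partition_edges
from cutsct.inference_metrics import mae, translate_volume
from cutsct.networks import DiscriminatorSpec, GeneratorSpec
from cutsct.objectives import NCEConfig
from cutsct.phantom_sim import DegradeParams, PhantomSpec, make_unpaired_dataset
from cutsct.preprocess import apply_mask, extract_body_mask
from cutsct.training import TrainConfig, train
from cutsct.volume_io import clip_hu

DEFAULT_PHANTOM = PhantomSpec(shape=(32, 32, 16), spacing_mm=(8.0, 8.0, 8.0))
DEFAULT_GEN = GeneratorSpec(base_filters=8, n_resblocks=2)
DEFAULT_DISC = DiscriminatorSpec(base_filters=16, n_layers=1)


@dataclass
class EndToEndResult:
    mae_input: float          # masked MAE(degraded CBCT, clean truth), HU
    mae_translated: float     # masked MAE(synthetic CT, clean truth), HU
    per_volume_input: list[float]
    per_volume_translated: list[float]
    output_variance: float    # variance of sCT volume means across eval inputs
    losses_finite: bool
    n_eval_volumes: int
    n_iterations: int

    @property
    def improved(self) -> bool:
        return self.mae_translated < self.mae_input


def encoded_training_slices(dataset) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Mask, clip and channel-encode the unpaired training streams."""
    part = partition_edges()

    def enc(vol):
        mask = extract_body_mask(vol)
        masked = apply_mask(clip_hu(vol), mask)
        return [
            channels_to_unit(encode_slice(masked.voxels[:, :, z], part).channels)
            for z in range(vol.n_slices)
        ]

    cbct, fbct = [], []
    for rec in dataset.patients:
        if rec.role != "train":
            continue
        cbct += enc(rec.cbct)
        fbct += enc(rec.clean)
    return cbct, fbct


def run_end_to_end(
    seed: int = 1,
    n_patients: int = 10,
    phantom: PhantomSpec = DEFAULT_PHANTOM,
    degrade: DegradeParams = DegradeParams(),
    gen_spec: GeneratorSpec = DEFAULT_GEN,
    disc_spec: DiscriminatorSpec = DEFAULT_DISC,
    base_lr: float = 2e-4,
    n_patches: int = 64,
    iterations_per_epoch: int = 128,
) -> EndToEndResult:
    """Run the full pipeline once at the scaled problem size."""
    seed = int(seed) % (2**31)
    ds = make_unpaired_dataset(n_patients, phantom, degrade, seed=seed)
    cbct_slices, fbct_slices = encoded_training_slices(ds)
    cfg = TrainConfig(seed=seed, base_lr=base_lr, nce=NCEConfig(n_patches=n_patches))
    result = train(cbct_slices, fbct_slices, cfg, gen_spec, disc_spec,
                   iterations_per_epoch=iterations_per_epoch)
    losses_finite = all(
        np.isfinite(v) for rec in result.loss_log for v in rec.values()
    )

    mae_in, mae_out, sct_means = [], [], []
    for rec in ds.patients:
        if rec.role != "eval":
            continue
        degraded = clip_hu(rec.eval_cbct)
        in_mask = extract_body_mask(degraded)
        truth_mask = extract_body_mask(rec.clean)
        sct = translate_volume(apply_mask(degraded, in_mask), result.generator, in_mask)
        mae_in.append(mae(degraded, rec.clean, truth_mask))
        mae_out.append(mae(sct, rec.clean, truth_mask))
        sct_means.append(float(sct.voxels[in_mask.voxels.astype(bool)].mean()))

    return EndToEndResult(
        mae_input=float(np.mean(mae_in)),
        mae_translated=float(np.mean(mae_out)),
        per_volume_input=mae_in,
        per_volume_translated=mae_out,
        output_variance=float(np.var(sct_means)),
        losses_finite=losses_finite,
        n_eval_volumes=len(mae_in),
        n_iterations=len(result.loss_log),
    )
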