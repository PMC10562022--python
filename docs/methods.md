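# Methods

This note documents the models, numerical choices, and design decisions
behind `cutsct`, and what the synthetic-phantom experiments do and do not
demonstrate.

## The translation model

The pipeline learns a mapping G from a source domain X of CBCT-like axial
slices to a target domain Y of FBCT-quality slices using *unpaired* data.
Three networks are trained jointly:

- **Generator G** — residual encoder–decoder: 7×7 convolution stem
  (64 filters), two stride-2 downsampling convolutions (128, 256), nine
  256-channel residual blocks, two stride-2 transposed convolutions
  (128, 64), 7×7 output convolution, reflection padding, instance
  normalization without learned affine parameters, biases on all
  convolutions, bounded tanh output. 11,378,179 trainable parameters.
- **Discriminator D** — patch classifier with 4×4 kernels and strides
  2, 2, 2, 1, 1 (3→64→128→256→512→1), instance norm on the middle
  layers, leaky rectifier slope 0.2. Its output is a spatial map of patch
  scores with a 70×70-pixel receptive field, not a scalar. 2,764,737
  parameters.
- **Projector H** — one two-layer perceptron (width 256, rectifier
  between) per encoder tap, outputs unit-normalized. Taps sit at the raw
  input (3 channels), the two downsampling stages (128, 256), and two
  residual blocks (256, 256); 560,384 parameters total.

The objective is

L = L_GAN(G, D, X, Y) + λ_X·L_PatchNCE(G, H, X) + λ_Y·L_PatchNCE(G, H, Y),  λ_X = λ_Y = 1.

L_GAN is the least-squares form: D is trained on 0.5·[(D(y) − 1)² +
D(G(x))²], G on (D(G(x)) − 1)². L_PatchNCE draws N patch locations per
encoder tap from the *output's* feature grids and reuses the same
locations on the source, so each query (output patch embedding) must
select its positional positive among the other in-image patches — an
(N+1)-way softmax classification at temperature τ. The Y-domain term
(queries from G(y), positives from y) is a contrastive identity loss
discouraging unnecessary changes.

Defaults that matter (units in parentheses):

| parameter | default | why |
|---|---|---|
| τ (temperature) | 0.07 | conventional contrastive-learning value; sharp enough to make the classification discriminative |
| patches per tap | 256 (capped by grid size) | the reference setting for 256-pixel-scale images |
| optimizer | Adam(0.5, 0.999) | GAN-conventional low first moment |
| base learning rate | 2e-4 | the stable setting for this family; the schedule holds it constant for 3 epochs then decays linearly to exactly 0 over 3 more |
| batch size | 1 | axial 2-D slices as samples |
| weight init | N(0, 0.02²), seeded | reference convention; makes builds reproducible |

## HU channelization

To keep the full CT number range [−1024, 3071] HU through an 8-bit
3-channel image pipeline, the range is partitioned into three equal
segments ([−1024, 341], [341, 1706], [1706, 3071]) and each segment is
rescaled to [0, 255] in its own channel. A pixel's channels fill in a
saturating ("thermometer") pattern — channels below its segment read
255, channels above read 0 — so encoding is monotone in HU and decoding
is affine in the channel vector: h = e₀ + Σ_c (v_c/255)·w_c. Quantization
is round-half-away-from-zero, making the worst-case round-trip error
exactly (1365/255)/2 ≈ 2.68 HU, verified by exhaustive integer sweep.

Two consequences of this codec shape the whole problem:

1. **Sensitivity.** The decoder sums three channels spanning 4095 HU, so
   a unit-scale error δ in network output space costs ≈ 2275·δ HU. HU
   fidelity demands far higher output precision than ordinary image
   translation.
2. **Saturation.** In-segment pixels need exact channel extremes (0 and
   255). A tanh reaches ±1 only asymptotically, and the sum-decoder turns
   incomplete saturation into a *one-sided* HU bias. The network value
   domain therefore maps channels to [−0.9, 0.9] (`UNIT_SCALE`), leaving
   the extremes expressible at finite pre-activations with live
   gradients.

## Preprocessing

Volumes are clipped to [−1024, 3071], optionally resampled (output grid
size ⌈n·s_in/s_out⌉ per axis; linear interpolation for images, nearest
for masks; world coordinate of voxel i is origin + i·spacing). The body
mask thresholds at Otsu's value (256 equal-width bins over the value
range, bin-edge candidates, between-class variance ω₀ω₁(μ₀−μ₁)², ties to
the smallest edge), keeps the largest 6-connected 3-D component, and
fills internal cavities slice-wise. Anything disconnected from the body
— the treatment couch above all — is discarded, and masked-out voxels
are set to −1024 (air) so the codec maps them to channel zeros.

## Evaluation

MAE and RMSE are computed over body-mask voxels in HU. SSIM is the
global-statistics form ((2μ_xμ_y + c₁)(2σ_xy + c₂)) / ((μ_x² + μ_y² +
c₁)(σ_x² + σ_y² + c₂)) with population moments over the mask and
c₁ = (0.01·L)², c₂ = (0.03·L)², L = 4095 HU (the full dynamic range; a
windowed variant is not the default because the global expression is the
protocol's stated form). FID is ‖μ_a − μ_b‖² + Tr(Σ_a + Σ_b −
2(Σ_aΣ_b)^½), covariances with n−1 denominators; the trace term is
evaluated via symmetric eigendecompositions with tiny negative
eigenvalues clamped to zero. Cross-validation results are summarized as
mean with standard error (sample SD/√k).

FID's canonical feature extractor is the deepest pooling layer of an
ImageNet-pretrained Inception v3; because that requires pretrained
weights at runtime, the extractor is pluggable and the default backend
is a seeded fixed Gaussian random projection of 16×16-average-pooled,
standardized slices (64-d). Fixed-projection FID is a valid Fréchet
distance between feature distributions and is fully deterministic, but
its absolute values are not comparable to Inception-based FIDs.

## The phantom simulator

Each synthetic patient is an ellipse-composite pelvis: a fat body ellipse
with per-slice axis jitter (±3%), an inner muscle compartment, an
anterior bladder, two femoral heads and a posterior sacrum arc
(trabecular core, cortical rim), 0–3 fiducial seeds (1–3 voxel radius)
inside a central prostate region, and a treatment-couch slab separated
from the body by ≥2 voxels of air. Voxel HU values equal their tissue
label's table entry exactly (air −1000, fat −100, muscle +40, bladder 0,
trabecular +200, cortical +700, fiducial +3000, couch +150), so the
label map is exact ground truth.

CBCT degradation is phenomenological, applied in order: multiplicative
low-order radial shading (cupping, ±8% about the mid-radius, acting on
HU + 1024), scatter modeled as in-plane Gaussian-blur leakage (fraction
0.15, blur 3 voxels), additive Gaussian noise (SD 25 HU), global offset
(+40 HU), then clipping. All-zero parameters give the exact identity.
These defaults produce a masked MAE against the clean phantom of roughly
30–40 HU, in the range reported for clinical CBCT. Projection-domain
physics (beam hardening, true scatter transport) is out of scope.

Unpaired cohorts draw a *different* geometry seed for each patient's
CBCT-domain training volume, so the training streams share no geometry;
a degraded copy of each patient's own clean volume is kept separately
and used only for evaluation, where voxel-aligned pairs are required.

## Scaled end-to-end experiment

The full-size configuration (512×512 slices, 11.4 M-parameter generator,
~10⁴ slices per epoch) is far beyond a desk-scale CPU run, so the
end-to-end experiment (`cutsct.e2e`) uses a reduced problem: 10 phantom
patients on 32×32×16 grids (8 mm in-plane voxels), a generator with 8
base filters and 2 residual blocks, a single-downsampling patch
discriminator (16 base filters) whose 16-pixel receptive field keeps the
patch-score map local relative to the 32-pixel image — mirroring the
70/512 locality of the full-size design, where a 3-downsampling
discriminator would see the whole image as one patch — 64 patches per
tap (grid-limited), learning rate 2e-4 on the 3+3 schedule with 128
iterations per epoch (768 updates). One run takes about two minutes on
one CPU core.

### What the phantom experiments show — and a negative result

The passing desk-scale checks demonstrate: exact architecture
accounting; codec fidelity and monotonicity; oracle-exact losses and
metrics; couch removal; deterministic, finite, reproducible unpaired
adversarial training; and that the full simulate→train→translate→
evaluate pipeline runs end to end.

They do **not** demonstrate clinical-grade HU restoration, and the
scaled experiment documents a specific negative result: at this problem
size the translated phantoms plateau at a masked MAE of roughly 100 HU
against clean truth — *above* the ~30–40 HU MAE of the degraded inputs
themselves. Two structural effects explain the plateau, both verified by
targeted probes (supervised reconstruction probes, per-tissue error
decomposition, checkerboard parity analysis):

1. The channel codec amplifies residual adversarial equilibrium noise
   (~0.05 in unit space, typical for a small least-squares GAN trained
   for hundreds of updates) into ~100 HU of within-tissue speckle.
   Matching the input's own error level requires ~0.013 unit precision,
   which the full-size study reaches only with orders of magnitude more
   optimization.
2. The phantoms are exactly piecewise-constant by design (the label-map
   contract). Inside a flat tissue region every patch is identical, so
   the contrastive term's (N+1)-way classification is degenerate there
   and its gradients vanish — on real, textured anatomy PatchNCE
   supplies a dense pixel-correspondence signal that is precisely what
   pins output values to input structure. The phantom regime removes the
   method's strongest fidelity signal while keeping its adversarial
   noise.

Tissue-level statistics of trained models are nonetheless sensible
(per-tissue output means within ~10–50 HU of the target values, correct
ordering across tissues, no mode collapse, finite losses), i.e. the
method learns the right mapping at coarse scale; it is per-voxel
precision that does not reach the input's error level in this regime.
The improvement test in the acceptance suite states the original
pass condition and is expected to fail at this problem size; it is kept
as an honest record rather than weakened.

## Numerical and implementation choices

- Networks run on `cutsct.nn`, a compact NumPy reverse-mode autodiff
  engine (im2col/col2im convolutions, fused instance norm and softmax
  cross-entropy); everything is float32, single-threaded-deterministic,
  and seeded through `numpy.random.Generator`.
- Otsu near-ties are resolved to the smallest bin edge within a 1e-12
  relative tolerance band (float summation-order noise can otherwise
  flip the argmax between exactly tied candidates).
- Instance norm uses ε = 1e-5; row normalization in the projector uses
  ε = 1e-10 under the square root.
- Degenerate inputs raise typed errors rather than returning NaN:
  constant images (Otsu), empty masks (metrics), <2 fold values, <2
  feature vectors (FID).
- Checkpoints are `.npz` weight archives with a JSON sidecar carrying
  the full specs, training config, seed, and epoch; loading validates
  spec consistency.

## Known limitations

- No DICOM ingestion, registration, or oblique geometry: volumes must be
  axis-aligned NIfTI, already in HU, and pre-aligned.
- The fixed-projection FID backend is not numerically comparable to
  Inception-based FID values.
- The phantom's flat-tissue regime under-exercises the contrastive loss
  (see above); a textured phantom would exercise it better but would
  break the exact label↔HU contract that the masking and evaluation
  tests rely on.
- Full-size (512×512, 64-filter) training is supported by the same code
  path but is not practical on a single CPU core.
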