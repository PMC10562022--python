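"""Adversarial, patch-contrastive (PatchNCE), and identity losses; total objective.

The translation objective combines a least-squares adversarial term with
patch-wise noise-contrastive estimation: each output ("query") patch must
pick out the input patch at the same location ("positive") from among the
other patches of the same image ("negatives") — an (N+1)-way softmax
classification in a shared embedding space. The same contrastive term
applied to target-domain images (queries from G(y), positives from y)
discourages unnecessary changes. The total is

    L = L_GAN + lambda_X * L_NCE(X) + lambda_Y * L_NCE(Y)

with both weights defaulting to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cutsct.networks import Generator, PatchProjector, extract_features, sample_patches
from cutsct.nn.autograd import Tensor, cross_entropy_logits, mse_to_constant


@dataclass(frozen=True)
class NCEConfig:
    """Contrastive-loss knobs: softmax temperature and patches per tap."""

    temperature: float = 0.07
    n_patches: int = 256

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")


@dataclass(frozen=True)
class ObjectiveWeights:
    lambda_x: float = 1.0
    lambda_y: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_x < 0 or self.lambda_y < 0:
            raise ValueError("objective weights must be non-negative")


def adversarial_loss(patch_scores: Tensor | np.ndarray, target_is_real: bool) -> Tensor:
    """Least-squares GAN loss: mean squared deviation from the target label."""
    scores = patch_scores if isinstance(patch_scores, Tensor) else Tensor(patch_scores)
    if not np.isfinite(scores.data).all():
        raise FloatingPointError("non-finite discriminator scores")
    return mse_to_constant(scores, 1.0 if target_is_real else 0.0)


def patch_nce_loss(
    query: np.ndarray,
    positive: np.ndarray,
    negatives: np.ndarray,
    temperature: float = 0.07,
) -> float:
    """Single-query PatchNCE: softmax cross-entropy of picking the positive.

    ``-log[ exp(q.p/tau) / (exp(q.p/tau) + sum_n exp(q.v_n/tau)) ]`` for
    unit vectors q, p and negatives v_n.
    """
    q = np.asarray(query, dtype=np.float64)
    p = np.asarray(positive, dtype=np.float64)
    vs = np.atleast_2d(np.asarray(negatives, dtype=np.float64))
    if q.ndim != 1 or p.shape != q.shape or vs.shape[1] != q.size:
        raise ValueError("query/positive/negatives dimensions disagree")
    norms = [np.linalg.norm(q), np.linalg.norm(p), *np.linalg.norm(vs, axis=1)]
    if min(norms) < 1e-12:
        raise FloatingPointError("zero-length vector in contrastive loss")
    logits = np.concatenate([[q @ p], vs @ q]) / temperature
    logits -= logits.max()
    return float(-logits[0] + np.log(np.exp(logits).sum()))


def patch_nce_batch(queries: Tensor, positives: Tensor, temperature: float) -> Tensor:
    """Batched PatchNCE over P locations of one image.

    Builds the (P, P) similarity matrix between queries and positives; the
    diagonal entries are the positives and each row's off-diagonal entries
    are that query's in-image negatives.
    """
    from cutsct.nn.autograd import linear  # similarity via the linear op

    P = queries.shape[0]
    zero_bias = Tensor(np.zeros(P, dtype=np.float32))
    # logits[i, j] = q_i . p_j / tau
    logits = linear(queries, _transpose(positives), zero_bias) * (1.0 / temperature)
    return cross_entropy_logits(logits, np.arange(P))


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, t.requires_grad, (t,))
    if out.requires_grad:
        out._backward = lambda g, a=t: a._accum(g.T)
    return out


def multilayer_nce_loss(
    gen: Generator,
    projector: PatchProjector,
    source: Tensor,
    output: Tensor,
    config: NCEConfig,
    rng: np.random.Generator,
    taps: tuple[int, ...] | None = None,
    feats_src: dict[int, Tensor] | None = None,
) -> Tensor:
    """PatchNCE averaged over encoder taps, queries from `output`, positives from `source`.

    Locations are drawn once per tap from the output's feature grids and
    reused on the source so query/positive pairs sit at identical positions.
    ``feats_src`` may carry the source's encoder features when they are
    already available from the pass that produced ``output``.
    """
    taps = taps if taps is not None else projector.spec.tap_layer_ids
    feats_out = extract_features(gen, output, taps)
    if feats_src is None:
        feats_src = extract_features(gen, source, taps)
    n_patch = {
        t: min(config.n_patches, f.shape[2] * f.shape[3]) for t, f in feats_out.items()
    }
    total: Tensor | None = None
    for t in taps:
        q_raw, locs = sample_patches({t: feats_out[t]}, n_patch[t], seed=rng)
        p_raw, _ = sample_patches({t: feats_src[t]}, n_patch[t], locations=locs)
        q = projector(t, q_raw[t])
        p = projector(t, p_raw[t])
        term = patch_nce_batch(q, p, config.temperature)
        total = term if total is None else total + term
    return total * (1.0 / len(taps))


def identity_nce_loss(
    gen: Generator,
    projector: PatchProjector,
    y_image: Tensor,
    config: NCEConfig,
    rng: np.random.Generator,
) -> Tensor:
    """Contrastive identity term: PatchNCE between G(y) queries and y positives."""
    idt = gen(y_image)
    return multilayer_nce_loss(gen, projector, y_image, idt, config, rng)


def total_objective(
    l_gan: Tensor | float,
    l_nce_x: Tensor | float,
    l_nce_y: Tensor | float,
    weights: ObjectiveWeights = ObjectiveWeights(),
) -> Tensor | float:
    """l_gan + lambda_X * l_nce_x + lambda_Y * l_nce_y."""
    return l_gan + weights.lambda_x * l_nce_x + weights.lambda_y * l_nce_y
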