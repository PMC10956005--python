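"""Hierarchical consistency losses for the dual-domain framework.

Three levels of constraint tie the four generative functions together, all
expressed as empirical mean-absolute errors:

* intra-domain (stage 1): each generator is supervised against its own
  domain's target, independently;
* inter-domain (stage 2): the image-domain prediction must agree with the
  acquisition-domain prediction carried across the transform, and vice
  versa (weights lambda1..lambda4);
* cycle (stage 3): source -> target -> source compositions, in the image
  domain and through the acquisition domain, must return the input
  (weights xi1..xi4).

Every composite loss is an autodiff scalar, so a single ``backward`` call
propagates through the generators and through F / F^-1.  For the
accelerated-MRI configuration only the source-to-target generators are
trainable and the weights lambda3, lambda4, xi1, xi3 are flagged inactive —
requesting a loss that needs them raises instead of silently zeroing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from . import autodiff as ad
from .generators import GeneratorSet
from .operators import TransformSpec, apply_mask_op, fbp_op, fft2c_op, ifft2c_op, radon_op

__all__ = [
    "LossWeights",
    "InactiveWeightError",
    "image_tensor",
    "transform_forward",
    "transform_inverse",
    "loss_stage1",
    "loss_stage2_t",
    "loss_stage2_s",
    "loss_stage3_t",
    "loss_stage3_s",
]


class InactiveWeightError(ValueError):
    """A loss requested a weight that is not applicable to this task."""


_WEIGHT_NAMES = [f"lambda{i}" for i in (1, 2, 3, 4)] + [f"xi{i}" for i in (1, 2, 3, 4)]


@dataclass
class LossWeights:
    """Inter-domain (lambda) and cycle (xi) weights plus per-domain L1 scales."""

    lambda1: float = 0.5
    lambda2: float = 0.5
    lambda3: float = 0.5
    lambda4: float = 0.5
    xi1: float = 0.5
    xi2: float = 0.5
    xi3: float = 0.5
    xi4: float = 0.5
    image_scale: float = 1.0
    acq_scale: float = 1.0
    inactive: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for f in fields(self):
            if f.name == "inactive":
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        self.inactive = frozenset(self.inactive)
        unknown = self.inactive - set(_WEIGHT_NAMES)
        if unknown:
            raise ValueError(f"unknown inactive weights {sorted(unknown)}")

    def weight(self, name: str) -> float:
        if name in self.inactive:
            raise InactiveWeightError(
                f"weight {name} is flagged inactive for this task"
            )
        return float(getattr(self, name))

    def weight_or_none(self, name: str):
        """The weight value, or None when the term is flagged inactive.

        Composite losses use this to drop inapplicable terms (e.g. the
        image-domain cycle for accelerated MRI) rather than zeroing them.
        """
        return None if name in self.inactive else float(getattr(self, name))

    @classmethod
    def for_task(cls, task: str) -> "LossWeights":
        if task in ("lowdose", "synthesis"):
            return cls()  # all lambdas and xis 0.5
        if task == "mar":
            kw = {n: 0.2 for n in _WEIGHT_NAMES[:4]}
            kw.update({n: 0.1 for n in _WEIGHT_NAMES[4:]})
            return cls(image_scale=10.0, acq_scale=0.1, **kw)
        if task == "mri":
            return cls(inactive=frozenset({"lambda3", "lambda4", "xi1", "xi3"}))
        raise ValueError(f"unknown task {task!r}")


# -- domain plumbing -------------------------------------------------------


def image_tensor(x: np.ndarray, spec: TransformSpec) -> ad.Tensor:
    """Wrap an image as the channel layout its transform expects.

    Radon tasks use a single real channel; Fourier tasks carry (re, im) as
    two real channels so complex data flows through real-valued generators.
    """
    x = np.asarray(x)
    if spec.kind == "radon":
        return ad.const(np.real(x)[None])
    return ad.const(np.stack([np.real(x), np.imag(x) if np.iscomplexobj(x) else np.zeros_like(np.real(x))]))


def transform_forward(t: ad.Tensor, spec: TransformSpec) -> ad.Tensor:
    """F as an autodiff node, in acquisition-normalized units.

    The raw transform output is divided by ``spec.acq_norm`` so the grids fed
    to acquisition-domain generators are of order one; :func:`transform_inverse`
    multiplies it back, so F^-1(F(x)) is unchanged.  For masked Fourier specs
    the mask is part of F.
    """
    if spec.kind == "radon":
        return ad.scale(radon_op(t, spec), 1.0 / spec.acq_norm)
    k = ad.scale(fft2c_op(t), 1.0 / spec.acq_norm)
    if spec.mask is not None:
        k = apply_mask_op(k, spec.mask)
    return k


def transform_inverse(t: ad.Tensor, spec: TransformSpec) -> ad.Tensor:
    """F^-1 as an autodiff node (FBP, or zero-filled inverse DFT)."""
    if spec.kind == "radon":
        return fbp_op(ad.scale(t, spec.acq_norm), spec)
    return ifft2c_op(ad.scale(t, spec.acq_norm))


def _l1(t: ad.Tensor, scale: float) -> ad.Tensor:
    return ad.l1_mean(t, weight=scale)


def _pair_tensors(pair, spec):
    return image_tensor(pair.x_s, spec), image_tensor(pair.x_t, spec)


# -- stage 1: intra-domain -------------------------------------------------


def loss_stage1(
    gs: GeneratorSet,
    pair,
    spec: TransformSpec,
    w: LossWeights | None = None,
    roles=None,
):
    """Supervised L1 per role: the four independent intra-domain terms.

    Returns a dict {role: scalar Tensor}; ``roles`` restricts which terms
    are built (default: the set's active roles).  Requesting a role that is
    not built raises an error naming it.
    """
    w = w or LossWeights()
    xs, xt = _pair_tensors(pair, spec)
    out = {}
    for role in roles if roles is not None else gs.active_roles():
        g = gs.require(role)
        if role == "G_t_I":
            out[role] = _l1(ad.sub(g(xs), xt), w.image_scale)
        elif role == "G_s_I":
            out[role] = _l1(ad.sub(g(xt), xs), w.image_scale)
        elif role == "G_t_A":
            out[role] = _l1(
                ad.sub(g(transform_forward(xs, spec)), transform_forward(xt, spec)),
                w.acq_scale,
            )
        elif role == "G_s_A":
            out[role] = _l1(
                ad.sub(g(transform_forward(xt, spec)), transform_forward(xs, spec)),
                w.acq_scale,
            )
    return out


# -- stage 2: inter-domain -------------------------------------------------


def loss_stage2_t(gs: GeneratorSet, pair, spec: TransformSpec, w: LossWeights):
    """Source-to-target inter-domain pair of composite losses.

    The first couples the image prediction to the acquisition prediction
    carried back by F^-1 (weight lambda1); the second couples the
    acquisition prediction to the image prediction carried over by F
    (weight lambda2).  The caller freezes whichever partner is not being
    updated.
    """
    xs, xt = _pair_tensors(pair, spec)
    g_i, g_a = gs.require("G_t_I"), gs.require("G_t_A")
    pred_i = g_i(xs)
    pred_a = g_a(transform_forward(xs, spec))
    sup_i = _l1(ad.sub(pred_i, xt), w.image_scale)
    cross_i = _l1(ad.sub(pred_i, transform_inverse(pred_a, spec)), w.image_scale)
    l_img = ad.weighted_sum([sup_i, cross_i], [1.0, w.weight("lambda1")])
    sup_a = _l1(ad.sub(pred_a, transform_forward(xt, spec)), w.acq_scale)
    cross_a = _l1(ad.sub(pred_a, transform_forward(pred_i, spec)), w.acq_scale)
    l_acq = ad.weighted_sum([sup_a, cross_a], [1.0, w.weight("lambda2")])
    return l_img, l_acq


def loss_stage2_s(gs: GeneratorSet, pair, spec: TransformSpec, w: LossWeights):
    """Target-to-source mirror of :func:`loss_stage2_t` (lambda3, lambda4)."""
    xs, xt = _pair_tensors(pair, spec)
    g_i, g_a = gs.require("G_s_I"), gs.require("G_s_A")
    pred_i = g_i(xt)
    pred_a = g_a(transform_forward(xt, spec))
    sup_i = _l1(ad.sub(pred_i, xs), w.image_scale)
    cross_i = _l1(ad.sub(pred_i, transform_inverse(pred_a, spec)), w.image_scale)
    l_img = ad.weighted_sum([sup_i, cross_i], [1.0, w.weight("lambda3")])
    sup_a = _l1(ad.sub(pred_a, transform_forward(xs, spec)), w.acq_scale)
    cross_a = _l1(ad.sub(pred_a, transform_forward(pred_i, spec)), w.acq_scale)
    l_acq = ad.weighted_sum([sup_a, cross_a], [1.0, w.weight("lambda4")])
    return l_img, l_acq


# -- stage 3: cycle --------------------------------------------------------


def loss_stage3_t(gs: GeneratorSet, pair, spec: TransformSpec, w: LossWeights) -> ad.Tensor:
    """Anti-clockwise (source-to-source) cycle loss fine-tuning G_t_I.

    Supervised term + image-domain cycle (xi1) + cross-domain cycle through
    F, the frozen acquisition map and F^-1 (xi2).
    """
    xs, xt = _pair_tensors(pair, spec)
    g_t_i = gs.require("G_t_I")
    pred = g_t_i(xs)
    terms = [_l1(ad.sub(pred, xt), w.image_scale)]
    coeffs = [1.0]
    xi1 = w.weight_or_none("xi1")
    if xi1 is not None:
        terms.append(_l1(ad.sub(gs.require("G_s_I")(pred), xs), w.image_scale))
        coeffs.append(xi1)
    xi2 = w.weight_or_none("xi2")
    if xi2 is not None:
        carried = transform_inverse(
            gs.require("G_s_A")(transform_forward(pred, spec)), spec
        )
        terms.append(_l1(ad.sub(carried, xs), w.image_scale))
        coeffs.append(xi2)
    return ad.weighted_sum(terms, coeffs)


def loss_stage3_s(gs: GeneratorSet, pair, spec: TransformSpec, w: LossWeights) -> ad.Tensor:
    """Clockwise (target-to-target) cycle loss fine-tuning G_s_I (xi3, xi4)."""
    xs, xt = _pair_tensors(pair, spec)
    g_s_i = gs.require("G_s_I")
    pred = g_s_i(xt)
    terms = [_l1(ad.sub(pred, xs), w.image_scale)]
    coeffs = [1.0]
    xi3 = w.weight_or_none("xi3")
    if xi3 is not None:
        terms.append(_l1(ad.sub(gs.require("G_t_I")(pred), xt), w.image_scale))
        coeffs.append(xi3)
    xi4 = w.weight_or_none("xi4")
    if xi4 is not None:
        carried = transform_inverse(
            gs.require("G_t_A")(transform_forward(pred, spec)), spec
        )
        terms.append(_l1(ad.sub(carried, xt), w.image_scale))
        coeffs.append(xi4)
    return ad.weighted_sum(terms, coeffs)
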