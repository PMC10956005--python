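"""Trainable generative functions for both domains.

Four roles make up the framework: source-to-target and target-to-source maps
in the image domain (G_t_I, G_s_I) and in the acquisition domain
(G_t_A, G_s_A).  Image-domain backbones are small encoder-decoder networks
(UNet, or the residual RUNet variant whose zero-initialised head makes it an
identity map at initialisation); acquisition-domain backbones are fully
connected maps applied along the detector / phase-encoding axis, shared
across angles or rows to keep the parameter count proportional to the grid
width.  For accelerated MRI the source-direction roles are the non-trainable
data-consistency maps: sampled k-space locations are forced back to the
measured values.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import autodiff as ad
from .operators import KSpace, SamplingMask

__all__ = [
    "Module",
    "ImageUNet",
    "AcquisitionFCN",
    "DataConsistencyGenerator",
    "GeneratorSet",
    "build_image_generator",
    "build_acquisition_generator",
    "data_consistency_map",
    "ROLES",
]

ROLES = ("G_s_I", "G_t_I", "G_s_A", "G_t_A")


class Module:
    """Base class: a named parameter list plus a checksum for freeze audits."""

    def __init__(self):
        self._params: Dict[str, ad.Tensor] = {}
        self.frozen = False

    def add_param(self, name: str, data: np.ndarray) -> ad.Tensor:
        t = ad.param(data)
        self._params[name] = t
        return t

    def parameters(self):
        return list(self._params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self._params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self._params[name].data).tobytes())
        return h.hexdigest()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self._params[k].data = np.array(v, dtype=np.float64)

    def __call__(self, x: ad.Tensor) -> ad.Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _he(rng, shape, fan_in):
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class ImageUNet(Module):
    """Small encoder-decoder with skip connections on (C,H,W) tensors.

    ``residual=True`` (the RUNet variant) adds the input to a zero-initialised
    1x1 output head, so the untrained network is exactly the identity —
    a stable starting point when source and target images are already close.
    """

    def __init__(
        self,
        in_channels: int = 1,
        out_channels: int = 1,
        base_filters: int = 8,
        depth: int = 2,
        residual: bool = True,
        alpha: float = 0.1,
        norm: str = "instance",
        seed: int = 0,
    ):
        super().__init__()
        if base_filters < 1 or depth < 1:
            raise ValueError("base_filters and depth must be positive")
        if norm not in ("instance", "none"):
            raise ValueError("norm must be 'instance' or 'none'")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.depth = depth
        self.residual = residual
        self.alpha = alpha
        self.norm = norm
        rng = np.random.default_rng(seed)

        def conv_param(name, cin, cout):
            w = self.add_param(name + "_w", _he(rng, (cout, cin, 3, 3), cin * 9))
            b = self.add_param(name + "_b", np.zeros(cout))
            if norm == "instance":
                gamma = self.add_param(name + "_g", np.ones(cout))
                beta = self.add_param(name + "_be", np.zeros(cout))
                return w, b, gamma, beta
            return w, b

        self.enc = []
        cin = in_channels
        f = base_filters
        for d in range(depth):
            self.enc.append((conv_param(f"enc{d}a", cin, f), conv_param(f"enc{d}b", f, f)))
            cin = f
            f *= 2
        self.bott = (conv_param("bott_a", cin, f), conv_param("bott_b", f, f))
        self.dec = []
        for d in reversed(range(depth)):
            skip = base_filters * (2**d)
            self.dec.append(
                (conv_param(f"dec{d}a", f + skip, skip), conv_param(f"dec{d}b", skip, skip))
            )
            f = skip
        if residual and in_channels != out_channels:
            raise ValueError("residual variant requires matching in/out channels")
        head_w = self.add_param("head_w", np.zeros((out_channels, f, 1, 1)))
        if not residual:
            # non-residual head gets a proper random init
            head_w.data = _he(rng, (out_channels, f, 1, 1), f)
        self.add_param("head_b", np.zeros(out_channels))

    def _conv_act(self, x, p):
        if self.norm == "instance":
            w, b, gamma, beta = p
            h = ad.instance_norm(ad.conv2d(x, w, b), gamma, beta)
        else:
            w, b = p
            h = ad.conv2d(x, w, b)
        return ad.leaky_relu(h, self.alpha)

    def _block(self, x, pair):
        return self._conv_act(self._conv_act(x, pair[0]), pair[1])

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        skips = []
        h = x
        for pair in self.enc:
            h = self._block(h, pair)
            skips.append(h)
            h = ad.avg_pool2(h)
        h = self._block(h, self.bott)
        for pair, skip in zip(self.dec, reversed(skips)):
            h = ad.upsample2(h)
            h = ad.concat_channels(h, skip)
            h = self._block(h, pair)
        out = ad.conv2d(h, self._params["head_w"], self._params["head_b"])
        if self.residual:
            out = ad.add(out, x)
        return out


class AcquisitionFCN(Module):
    """Fully connected map along the last (detector / line) axis.

    One weight matrix is shared across angles, rows and channels; with
    ``hidden=0`` it is a single affine layer initialised at the identity, so
    the untrained map passes measurements through unchanged.
    """

    def __init__(self, grid_shape, hidden: int = 0, alpha: float = 0.1, seed: int = 0):
        super().__init__()
        self.grid_shape = tuple(grid_shape)
        self.alpha = alpha
        d = self.grid_shape[-1]
        rng = np.random.default_rng(seed)
        if hidden:
            self.w1 = self.add_param("w1", _he(rng, (d, hidden), d))
            self.b1 = self.add_param("b1", np.zeros(hidden))
            self.w2 = self.add_param("w2", np.zeros((hidden, d)))
            self.b2 = self.add_param("b2", np.zeros(d))
            self.skip = True
        else:
            self.w1 = self.add_param("w1", np.eye(d))
            self.b1 = self.add_param("b1", np.zeros(d))
            self.skip = False
        self.hidden = hidden

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        if self.hidden:
            h = ad.leaky_relu(ad.linear(x, self.w1, self.b1), self.alpha)
            out = ad.linear(h, self.w2, self.b2)
            return ad.add(out, x)  # residual around the bottleneck
        return ad.linear(x, self.w1, self.b1)


class DataConsistencyGenerator(Module):
    """Non-trainable k-space map replacing sampled locations by measurements.

    Acts on 2-channel (re, im) k-space tensors; the measured lines are pinned
    to the acquisition and the unsampled ones pass through.  The measurements
    differ per sample, so the trainer (or caller) binds the current sample's
    mask and measured k-space before evaluating.
    """

    def __init__(self, mask: Optional[SamplingMask] = None, measured_k=None):
        super().__init__()
        self._grid = None
        self._measured = None
        if mask is not None and measured_k is not None:
            self.bind(mask, measured_k)

    def bind(self, mask: SamplingMask, measured_k: np.ndarray) -> None:
        measured_k = np.asarray(measured_k)
        grid = mask.as_grid(measured_k.shape)
        self._grid = np.stack([grid, grid])
        self._measured = np.stack([measured_k.real, measured_k.imag])

    def __call__(self, k: ad.Tensor) -> ad.Tensor:
        if self._grid is None:
            raise ValueError("data-consistency generator is not bound to a sample")
        kept = ad.mul_const(k, 1.0 - self._grid)
        return ad.add(kept, ad.const(self._measured * self._grid))


def data_consistency_map(
    predicted_k: KSpace, measured_k: KSpace, mask: SamplingMask
) -> KSpace:
    """Array-level data consistency: measured values win at sampled lines."""
    if predicted_k.values.shape != measured_k.values.shape:
        raise ValueError("k-space shapes disagree")
    grid = mask.as_grid(predicted_k.values.shape)
    out = predicted_k.values * (1.0 - grid) + measured_k.values * grid
    return KSpace(out, mask_applied=measured_k.mask_applied)


@dataclass
class GeneratorSet:
    """The four generative-function roles plus freeze states.

    ``weight_sharing`` may tie two roles to one underlying module (the MRI
    configuration shares the image-domain backbone with the acquisition
    role); tied roles then report identical checksums by construction.
    """

    G_s_I: Optional[Module] = None
    G_t_I: Optional[Module] = None
    G_s_A: Optional[Module] = None
    G_t_A: Optional[Module] = None
    weight_sharing: dict = field(default_factory=dict)

    def role(self, name: str) -> Optional[Module]:
        if name not in ROLES:
            raise KeyError(name)
        return getattr(self, name)

    def require(self, name: str) -> Module:
        g = self.role(name)
        if g is None:
            raise ValueError(f"generator role {name} is not built")
        return g

    def active_roles(self):
        return [r for r in ROLES if self.role(r) is not None]

    def checksums(self) -> Dict[str, str]:
        return {r: self.role(r).checksum() for r in self.active_roles()}

    def set_frozen(self, frozen_roles) -> None:
        for r in self.active_roles():
            self.role(r).frozen = r in frozen_roles

    def trainable_parameters(self):
        params, seen = [], set()
        for r in self.active_roles():
            g = self.role(r)
            if g.frozen:
                continue
            for p in g.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params


def build_image_generator(
    arch: str = "runet",
    base_filters: int = 8,
    in_out_channels=(1, 1),
    depth: int = 2,
    seed: int = 0,
) -> ImageUNet:
    """Image-domain backbone; ``runet`` is the residual variant."""
    if arch not in ("unet", "runet"):
        raise ValueError(f"unsupported image architecture {arch!r}")
    cin, cout = in_out_channels
    return ImageUNet(
        in_channels=cin,
        out_channels=cout,
        base_filters=base_filters,
        depth=depth,
        residual=(arch == "runet"),
        seed=seed,
    )


def build_acquisition_generator(
    kind: str = "fcn", grid_shape=(64, 91), hidden: int = 0, seed: int = 0
) -> Module:
    """Acquisition-domain backbone mapping grids to same-shape grids."""
    if kind == "fcn":
        return AcquisitionFCN(grid_shape, hidden=hidden, seed=seed)
    if kind == "unet":
        return ImageUNet(
            in_channels=1, out_channels=1, base_filters=8, depth=1, residual=True, seed=seed
        )
    raise ValueError(f"unsupported acquisition architecture {kind!r}")
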