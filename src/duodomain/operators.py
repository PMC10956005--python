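"""Acquisition-domain transforms F / F^-1 and sampling masks.

Two transform families link the image domain to the acquisition domain:

* parallel-beam Radon projection (sinogram domain, CT/PET), realised as an
  explicit sparse pixel-driven projection matrix so that the forward operator
  and its adjoint (the interpolating backprojector) form an exact pair, and
* the centered 2-D discrete Fourier transform (k-space domain, MRI),
  optionally composed with a Cartesian line-sampling mask.

Both transforms are linear, so their vector-Jacobian products are their
adjoints; the ``*_op`` functions wrap them as autodiff nodes for use inside
the consistency losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse

from . import autodiff as ad

__all__ = [
    "TransformSpec",
    "Sinogram",
    "KSpace",
    "SamplingMask",
    "radon_forward",
    "radon_inverse",
    "fourier_forward",
    "fourier_inverse",
    "make_cartesian_gaussian_mask",
    "n_detectors_for",
    "radon_op",
    "fbp_op",
    "fft2c_op",
    "ifft2c_op",
    "apply_mask_op",
    "save_acquisition",
    "load_acquisition",
]

_FILTERS = ("ramp", "hann")


def n_detectors_for(image_shape) -> int:
    """Detector count: the image diagonal in pixels, rounded up to odd."""
    diag = int(np.ceil(np.hypot(*image_shape)))
    return diag + 1 if diag % 2 == 0 else diag


@dataclass
class SamplingMask:
    """Cartesian phase-encoding line mask for k-space undersampling."""

    columns_sampled: np.ndarray  # boolean over lines
    acceleration: float
    n_center: int

    def __post_init__(self):
        self.columns_sampled = np.asarray(self.columns_sampled, dtype=bool)
        n = self.columns_sampled.size
        start = (n - self.n_center) // 2
        if not self.columns_sampled[start : start + self.n_center].all():
            raise ValueError("all center lines must be sampled")

    @property
    def n_lines(self) -> int:
        return self.columns_sampled.size

    def as_grid(self, image_shape) -> np.ndarray:
        """Broadcast the line mask to a full 2-D 0/1 grid (lines = columns)."""
        rows, cols = image_shape
        if cols != self.n_lines:
            raise ValueError("mask line count does not match image columns")
        return np.broadcast_to(self.columns_sampled[None, :], (rows, cols)).astype(
            np.float64
        )

    def save_txt(self, path) -> None:
        np.savetxt(path, self.columns_sampled.astype(int), fmt="%d")


@dataclass
class TransformSpec:
    """Geometry of the invertible acquisition operator F / F^-1."""

    kind: str  # "radon" | "fourier"
    image_shape: tuple
    n_angles: Optional[int] = None
    angles: Optional[np.ndarray] = None
    filter_name: str = "ramp"
    mask: Optional[SamplingMask] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.image_shape = tuple(int(s) for s in self.image_shape)
        if self.kind not in ("radon", "fourier"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "radon":
            if self.angles is None:
                if self.n_angles is None:
                    raise ValueError("radon spec needs n_angles or angles")
                self.angles = np.linspace(0.0, 180.0, self.n_angles, endpoint=False)
            self.angles = np.asarray(self.angles, dtype=np.float64)
            self.n_angles = self.angles.size
            if np.any(np.diff(self.angles) <= 0):
                raise ValueError("angles must be strictly increasing")
            if self.angles[0] < 0 or self.angles[-1] >= 180.0:
                raise ValueError("angles must lie in [0, 180)")
            if self.filter_name not in _FILTERS:
                raise ValueError(f"unknown FBP filter {self.filter_name!r}")

    # -- radon machinery ---------------------------------------------------

    @property
    def n_detectors(self) -> int:
        return n_detectors_for(self.image_shape)

    @property
    def acq_norm(self) -> float:
        """Normalization constant for acquisition-domain network inputs.

        Radon line integrals of a unit image average n_pixels / n_detectors
        per bin, and the unnormalized DFT grows with sqrt(n_pixels); dividing
        by these keeps acquisition-domain activations of order one so the
        published learning rates behave the same in both domains.
        """
        if self.kind == "radon":
            return self.image_shape[0] * self.image_shape[1] / self.n_detectors
        return float(np.sqrt(self.image_shape[0] * self.image_shape[1]))

    def projection_matrix(self) -> sparse.csr_matrix:
        """Sparse pixel-driven projector A: image (H*W) -> sinogram (n_angles*n_det).

        Each pixel center is projected onto the detector axis at
        t = x cos(theta) + y sin(theta) and its value split linearly between
        the two nearest bins, so per-angle detector sums conserve the image
        sum exactly and A^T is the matching interpolating backprojector.
        """
        if "A" in self._cache:
            return self._cache["A"]
        H, W = self.image_shape
        nd = self.n_detectors
        jj, ii = np.meshgrid(np.arange(W), np.arange(H))
        x = (jj - (W - 1) / 2.0).ravel()
        y = ((H - 1) / 2.0 - ii).ravel()
        npix = H * W
        rows, cols, vals = [], [], []
        half = (nd - 1) / 2.0
        for a, theta in enumerate(np.deg2rad(self.angles)):
            t = x * np.cos(theta) + y * np.sin(theta) + half
            i0 = np.floor(t).astype(int)
            w1 = t - i0
            for off, wgt in ((0, 1.0 - w1), (1, w1)):
                idx = i0 + off
                ok = (idx >= 0) & (idx < nd) & (wgt > 0)
                rows.append(a * nd + idx[ok])
                cols.append(np.arange(npix)[ok])
                vals.append(wgt[ok])
        A = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_angles * nd, npix),
        )
        self._cache["A"] = A
        self._cache["AT"] = A.T.tocsr()
        return A

    def _fourier_ramp(self):
        if "filt" in self._cache:
            return self._cache["filt"]
        nd = self.n_detectors
        size = max(64, int(2 ** np.ceil(np.log2(2 * nd))))
        # Band-limited ramp built from its real-space kernel (Kak & Slaney):
        # h[0] = 1/4, h[n] = -1/(pi n)^2 for odd n, 0 for even n.  Unlike a
        # plain |f| frequency ramp this keeps the correct DC response and
        # avoids a cupping bias in the reconstruction.
        n = np.concatenate(
            [np.arange(1, size // 2 + 1, 2), np.arange(size // 2 - 1, 0, -2)]
        )
        h = np.zeros(size)
        h[0] = 0.25
        h[1::2] = -1.0 / (np.pi * n) ** 2
        filt = 2.0 * np.real(np.fft.fft(h))
        freq = np.fft.fftfreq(size)
        if self.filter_name == "hann":
            filt = filt * (1.0 + np.cos(2.0 * np.pi * freq)) / 2.0
        filt = filt / 2.0  # continuous-ramp normalization |f| at band edge 1/2
        # The pixel-driven projector splats each pixel with a unit triangle
        # kernel, whose frequency response sinc^2(f) blurs every projection;
        # dividing the ramp by it deconvolves that known interpolation blur.
        filt = filt / np.maximum(np.sinc(freq) ** 2, 1e-3)
        self._cache["filt"] = (filt, size)
        return filt, size

    def filter_sinogram(self, sino_values: np.ndarray) -> np.ndarray:
        """Ramp-family filtering of each projection along the detector axis."""
        filt, size = self._fourier_ramp()
        nd = sino_values.shape[-1]
        padded = np.zeros(sino_values.shape[:-1] + (size,))
        padded[..., :nd] = sino_values
        out = np.real(np.fft.ifft(np.fft.fft(padded, axis=-1) * filt, axis=-1))
        return out[..., :nd]


@dataclass
class Sinogram:
    """Line-integral projections, one row per angle."""

    values: np.ndarray  # (n_angles, n_detectors)
    geometry: TransformSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )


@dataclass
class KSpace:
    """Centered 2-D spatial-frequency data (DC at the grid center)."""

    values: np.ndarray  # complex, same shape as the image
    mask_applied: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)


# -- forward / inverse transforms -----------------------------------------


def radon_forward(image: np.ndarray, spec: TransformSpec) -> Sinogram:
    """Parallel-beam line integrals of ``image`` at the spec's angles."""
    if spec.kind != "radon":
        raise ValueError("radon_forward requires a radon TransformSpec")
    image = np.asarray(image, dtype=np.float64)
    if image.shape != spec.image_shape:
        raise ValueError(
            f"image shape {image.shape} does not match geometry {spec.image_shape}"
        )
    A = spec.projection_matrix()
    vals = (A @ image.ravel()).reshape(spec.n_angles, spec.n_detectors)
    return Sinogram(vals, spec)


def radon_inverse(sino: Sinogram, spec: TransformSpec) -> np.ndarray:
    """Filtered back projection with the spec's ramp-family filter."""
    if spec.kind != "radon":
        raise ValueError("radon_inverse requires a radon TransformSpec")
    if sino.values.shape != (spec.n_angles, spec.n_detectors):
        raise ValueError("sinogram does not match the reconstruction geometry")
    filtered = spec.filter_sinogram(sino.values)
    AT = spec.projection_matrix().T
    recon = (AT @ filtered.ravel()).reshape(spec.image_shape)
    return recon * (np.pi / spec.n_angles)


def fourier_forward(image: np.ndarray, spec: TransformSpec) -> KSpace:
    """Centered (fftshifted) unnormalized 2-D DFT; applies the spec's mask."""
    if spec.kind != "fourier":
        raise ValueError("fourier_forward requires a fourier TransformSpec")
    image = np.asarray(image)
    if image.shape != spec.image_shape:
        raise ValueError("image shape does not match the fourier geometry")
    k = np.fft.fftshift(np.fft.fft2(image))
    if spec.mask is not None:
        k = k * spec.mask.as_grid(spec.image_shape)
        return KSpace(k, mask_applied=True)
    return KSpace(k, mask_applied=False)


def fourier_inverse(k: KSpace, spec: TransformSpec) -> np.ndarray:
    """Centered inverse DFT; zero-filled reconstruction when mask_applied."""
    if spec.kind != "fourier":
        raise ValueError("fourier_inverse requires a fourier TransformSpec")
    if k.values.shape != spec.image_shape:
        raise ValueError("k-space shape does not match the fourier geometry")
    return np.fft.ifft2(np.fft.ifftshift(k.values))


def make_cartesian_gaussian_mask(
    n_lines: int, accel: float, n_center: int, seed: int
) -> SamplingMask:
    """Gaussian-density Cartesian line mask with always-sampled center lines.

    ``round(n_lines / accel)`` lines are kept: a contiguous block of
    ``n_center`` central lines plus lines drawn without replacement with
    probability proportional to a Gaussian (sigma = n_lines / 6) centered on
    the middle line.  Deterministic for a fixed seed.
    """
    n_keep = int(round(n_lines / accel))
    if n_keep < n_center:
        raise ValueError(
            f"budget round({n_lines}/{accel})={n_keep} cannot cover {n_center} center lines"
        )
    cols = np.zeros(n_lines, dtype=bool)
    start = (n_lines - n_center) // 2
    cols[start : start + n_center] = True
    remaining = n_keep - n_center
    if remaining > 0:
        rng = np.random.default_rng(seed)
        candidates = np.flatnonzero(~cols)
        center = (n_lines - 1) / 2.0
        sigma = n_lines / 6.0
        w = np.exp(-0.5 * ((candidates - center) / sigma) ** 2)
        chosen = rng.choice(candidates, size=remaining, replace=False, p=w / w.sum())
        cols[chosen] = True
    return SamplingMask(cols, acceleration=float(accel), n_center=int(n_center))


# -- autodiff wrappers -----------------------------------------------------


def radon_op(x: "ad.Tensor", spec: TransformSpec) -> "ad.Tensor":
    """Differentiable Radon projection: (1,H,W) image -> (1,n_angles,n_det)."""
    A = spec.projection_matrix()
    AT = spec._cache["AT"]
    H, W = spec.image_shape
    na, nd = spec.n_angles, spec.n_detectors

    def fwd(v):
        return (A @ v.reshape(-1)).reshape(1, na, nd)

    def adj(g):
        return (AT @ g.reshape(-1)).reshape(1, H, W)

    return ad.linop(x, fwd, adj)


def fbp_op(s: "ad.Tensor", spec: TransformSpec) -> "ad.Tensor":
    """Differentiable FBP: (1,n_angles,n_det) sinogram -> (1,H,W) image.

    FBP = c * A^T * Phi with Phi the (symmetric) ramp filter, so the adjoint
    is c * Phi * A.
    """
    A = spec.projection_matrix()
    AT = spec._cache["AT"]
    H, W = spec.image_shape
    na, nd = spec.n_angles, spec.n_detectors
    c = np.pi / na

    def fwd(v):
        filtered = spec.filter_sinogram(v.reshape(na, nd))
        return c * (AT @ filtered.ravel()).reshape(1, H, W)

    def adj(g):
        proj = (A @ g.reshape(-1)).reshape(na, nd)
        return c * spec.filter_sinogram(proj).reshape(1, na, nd)

    return ad.linop(s, fwd, adj)


def _split(z):
    return np.stack([z.real, z.imag])


def fft2c_op(x: "ad.Tensor") -> "ad.Tensor":
    """Differentiable centered DFT on a 2-channel (re, im) image tensor."""

    def fwd(v):
        return _split(np.fft.fftshift(np.fft.fft2(v[0] + 1j * v[1])))

    def adj(g):
        n = g[0].size
        return _split(n * np.fft.ifft2(np.fft.ifftshift(g[0] + 1j * g[1])))

    return ad.linop(x, fwd, adj)


def ifft2c_op(k: "ad.Tensor") -> "ad.Tensor":
    """Differentiable centered inverse DFT on a 2-channel k-space tensor."""

    def fwd(v):
        return _split(np.fft.ifft2(np.fft.ifftshift(v[0] + 1j * v[1])))

    def adj(g):
        n = g[0].size
        return _split(np.fft.fftshift(np.fft.fft2(g[0] + 1j * g[1])) / n)

    return ad.linop(k, fwd, adj)


def apply_mask_op(k: "ad.Tensor", mask: SamplingMask) -> "ad.Tensor":
    grid = mask.as_grid(k.data.shape[-2:])
    return ad.mul_const(k, grid[None])


# -- persistence -----------------------------------------------------------


def save_acquisition(path, obj, meta: Optional[dict] = None) -> None:
    """Save a Sinogram or KSpace as NPZ with keys {values, angles|mask, meta}."""
    meta_arr = np.array(repr(meta or {}))
    if isinstance(obj, Sinogram):
        np.savez(path, values=obj.values, angles=obj.geometry.angles, meta=meta_arr)
    elif isinstance(obj, KSpace):
        np.savez(
            path,
            values=obj.values,
            mask=np.array(obj.mask_applied),
            meta=meta_arr,
        )
    else:
        raise TypeError("save_acquisition expects a Sinogram or KSpace")


def load_acquisition(path):
    """Load an NPZ written by :func:`save_acquisition`; returns values + extras."""
    with np.load(path, allow_pickle=False) as f:
        data = {k: f[k] for k in f.files}
    return data
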