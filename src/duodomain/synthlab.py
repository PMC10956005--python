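"""Seeded synthetic paired datasets for the four generative tasks.

Real paired acquisitions (standard/low-dose PET-CT, metal-free/metal-affected
CT, fully-sampled/undersampled k-space, co-registered PET-CT) come from
scanners; this module reproduces the *degradation mechanisms* on random
ellipse phantoms so that every training stage and metric can be exercised
from a seed alone:

* low dose      — sinogram count thinning (Poisson) + EM-style reconstruction,
* metal         — extra attenuation and photon starvation on rays through metal,
* MRI           — Cartesian Gaussian line masking of k-space + zero filling,
* synthesis     — two monotone tissue-to-intensity transfer functions.

Every sample records its full provenance (parameters + seeds) and can be
regenerated bit-identically from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .operators import (
    KSpace,
    Sinogram,
    TransformSpec,
    fourier_forward,
    fourier_inverse,
    make_cartesian_gaussian_mask,
    radon_forward,
    radon_inverse,
)

__all__ = [
    "Phantom",
    "PairedSample",
    "make_phantom",
    "phantom_from_params",
    "simulate_low_dose",
    "simulate_metal",
    "simulate_undersampled_mri",
    "make_modality_pair",
    "make_dataset",
    "write_dataset",
    "regenerate_from_manifest",
]

LABEL_BACKGROUND, LABEL_SOFT, LABEL_BONE, LABEL_LESION = 0, 1, 2, 3

# Tissue label -> nominal intensity in the [0, 1] phantom scale.
_LABEL_INTENSITY = {LABEL_SOFT: 0.35, LABEL_BONE: 0.8, LABEL_LESION: 0.6}

# Hounsfield-style window used by the metal-artifact task: phantom values are
# mapped linearly onto [-1000, 2000] HU and converted to attenuation via the
# water coefficient mu_w = 0.192.
HU_MIN, HU_MAX, MU_WATER = -1000.0, 2000.0, 0.192


@dataclass
class Phantom:
    """Random ellipse composite with tissue labels; image values in [0, 1]."""

    image: np.ndarray
    ellipse_params: list  # (center_rc, axes_rc, angle_deg, intensity, label)
    tissue_labels: np.ndarray

    @property
    def shape(self):
        return self.image.shape


@dataclass
class PairedSample:
    """One (source, target) training/evaluation pair with its provenance."""

    x_s: np.ndarray
    x_t: np.ndarray
    task: str
    transform: TransformSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.asarray(self.x_s).shape != np.asarray(self.x_t).shape:
            raise ValueError("x_s and x_t must share the same grid shape")


def _ellipse_mask(shape, center, axes, angle_deg):
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    th = np.deg2rad(angle_deg)
    u = dr * np.cos(th) + dc * np.sin(th)
    v = -dr * np.sin(th) + dc * np.cos(th)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def phantom_from_params(ellipse_params, shape) -> Phantom:
    """Deterministically paint a phantom from its ellipse parameter list."""
    image = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    for center, axes, angle, intensity, label in ellipse_params:
        m = _ellipse_mask(shape, center, axes, angle)
        image[m] = intensity
        labels[m] = label
    return Phantom(np.clip(image, 0.0, 1.0), list(ellipse_params), labels)


def make_phantom(shape, n_ellipses: int = 5, seed: int = 0) -> Phantom:
    """Shepp-Logan-style random phantom: one body ellipse, internal soft/bone
    structures, and 1-3 high-contrast lesions, all inside the body so the
    support is a single connected component."""
    if n_ellipses < 1:
        raise ValueError("n_ellipses must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    body_axes = (rows * 0.42, cols * 0.38)
    params = [
        ((cr, cc), body_axes, rng.uniform(-15, 15), _LABEL_INTENSITY[LABEL_SOFT], LABEL_SOFT)
    ]

    def interior_point(margin):
        # rejection-sample a point comfortably inside the body ellipse
        while True:
            dr = rng.uniform(-0.6, 0.6) * body_axes[0]
            dc = rng.uniform(-0.6, 0.6) * body_axes[1]
            if (dr / body_axes[0]) ** 2 + (dc / body_axes[1]) ** 2 < (1 - margin) ** 2:
                return cr + dr, cc + dc

    for _ in range(n_ellipses - 1):
        label = LABEL_BONE if rng.random() < 0.4 else LABEL_SOFT
        base = _LABEL_INTENSITY[label]
        intensity = np.clip(base + rng.uniform(-0.08, 0.08), 0.0, 1.0)
        params.append(
            (
                interior_point(0.35),
                (rng.uniform(0.06, 0.2) * rows, rng.uniform(0.06, 0.2) * cols),
                rng.uniform(0, 180),
                intensity,
                label,
            )
        )
    for _ in range(int(rng.integers(1, 4))):
        params.append(
            (
                interior_point(0.45),
                (rng.uniform(0.03, 0.07) * rows, rng.uniform(0.03, 0.07) * cols),
                rng.uniform(0, 180),
                np.clip(_LABEL_INTENSITY[LABEL_LESION] + rng.uniform(0, 0.25), 0, 1),
                LABEL_LESION,
            )
        )
    return phantom_from_params(params, shape)


# -- low-dose reconstruction ----------------------------------------------


def _em_reconstruct(sino_values, spec: TransformSpec, n_iter: int) -> np.ndarray:
    """Plain (subset-free) EM reconstruction from non-negative projections."""
    A = spec.projection_matrix()
    sens = np.asarray(A.sum(axis=0)).ravel()
    sens[sens == 0] = 1.0
    x = np.full(spec.image_shape[0] * spec.image_shape[1], max(sino_values.mean(), 1e-8))
    y = sino_values.ravel()
    for _ in range(n_iter):
        proj = A @ x
        ratio = np.divide(y, proj, out=np.zeros_like(y), where=proj > 1e-12)
        x = x / sens * (A.T @ ratio)
    return x.reshape(spec.image_shape)


def simulate_low_dose(
    standard: Phantom,
    dose_fraction: float,
    spec: TransformSpec,
    counts_full: float = 500.0,
    seed: int = 0,
    poisson: bool = True,
    recon: str = "em",
    em_iters: int = 4,
) -> PairedSample:
    """Low-dose pair by Poisson thinning of the standard-dose sinogram.

    The standard image is forward projected; expected counts per bin are
    ``counts_full`` at the sinogram maximum, scaled by ``dose_fraction``;
    Poisson counts are drawn and reconstructed (EM by default, FBP
    optionally).  The target is the same reconstruction of the noiseless
    full-dose sinogram, so at dose 1 with the noise disabled x_s == x_t.
    """
    if not 0.0 < dose_fraction <= 1.0:
        raise ValueError("dose_fraction must lie in (0, 1]")
    if spec.kind != "radon":
        raise ValueError("low-dose simulation requires a radon TransformSpec")
    sino = radon_forward(standard.image, spec).values
    scale = counts_full / max(sino.max(), 1e-12)
    lam_full = sino * scale
    lam_low = lam_full * dose_fraction
    rng = np.random.default_rng(seed)
    if poisson:
        counts_low = rng.poisson(lam_low).astype(np.float64)
        sino_low = counts_low / (scale * dose_fraction)
    else:
        # noise-free thinning rescales back to the original sinogram exactly
        counts_low = lam_low
        sino_low = sino.copy()

    if recon == "em":
        x_t = _em_reconstruct(sino, spec, em_iters)
        x_s = _em_reconstruct(sino_low, spec, em_iters)
    elif recon == "fbp":
        x_t = radon_inverse(Sinogram(sino, spec), spec)
        x_s = radon_inverse(Sinogram(sino_low, spec), spec)
    else:
        raise ValueError(f"unknown recon {recon!r}")
    return PairedSample(
        x_s,
        x_t,
        task="lowdose",
        transform=spec,
        provenance={
            "dose_fraction": dose_fraction,
            "counts_full": counts_full,
            "seed": seed,
            "poisson": poisson,
            "recon": recon,
            "em_iters": em_iters,
            "counts_low_total": float(counts_low.sum()),
            "counts_full_total": float(lam_full.sum()),
        },
    )


# -- metal artifacts -------------------------------------------------------


def _to_mu(image01: np.ndarray) -> np.ndarray:
    hu = np.clip(HU_MIN + (HU_MAX - HU_MIN) * image01, HU_MIN, HU_MAX)
    return MU_WATER * (1.0 + hu / 1000.0)


def _from_mu(mu: np.ndarray) -> np.ndarray:
    hu = 1000.0 * (mu / MU_WATER - 1.0)
    return (hu - HU_MIN) / (HU_MAX - HU_MIN)


def simulate_metal(
    clean: Phantom,
    n_metals: int,
    metal_intensity: float,
    spec: TransformSpec,
    seed: int = 0,
    beta: float = 0.02,
    floor_counts: float = 5.0,
    i0: float = 1e5,
) -> PairedSample:
    """Metal-corrupted / metal-free CT pair.

    ``n_metals`` small high-intensity ellipses are inserted; rays whose
    metal-excess line integral is large lose counts as exp(-beta * excess)
    and are floored (photon starvation), producing streaks in the FBP of the
    corrupted sinogram.  Both images pass through the same HU window /
    attenuation mapping and FBP so that zero metal contrast gives x_s == x_t.
    """
    if not 1 <= n_metals <= 4:
        raise ValueError("n_metals must be in 1..4")
    if spec.kind != "radon":
        raise ValueError("metal simulation requires a radon TransformSpec")
    rng = np.random.default_rng(seed)
    rows, cols = clean.shape
    metal_img = clean.image.copy()
    metal_mask = np.zeros(clean.shape, dtype=bool)
    body = clean.tissue_labels > 0
    cand_r, cand_c = np.nonzero(ndimage.binary_erosion(body, iterations=3))
    for _ in range(n_metals):
        i = rng.integers(len(cand_r))
        m = _ellipse_mask(
            clean.shape,
            (cand_r[i], cand_c[i]),
            (rng.uniform(1.5, 3.0), rng.uniform(1.5, 3.0)),
            rng.uniform(0, 180),
        )
        metal_img[m] = metal_intensity
        metal_mask |= m

    p_clean = radon_forward(_to_mu(clean.image), spec).values
    p_metal = radon_forward(_to_mu(metal_img), spec).values
    excess = radon_forward(
        np.clip(_to_mu(metal_img) - _to_mu(clean.image), 0, None), spec
    ).values
    counts = i0 * np.exp(-beta * p_metal)
    counts *= np.exp(-beta * excess)  # beam-hardening-style extra loss
    counts = np.maximum(counts, floor_counts)  # photon starvation floor
    p_corrupt = -np.log(counts / i0) / beta

    x_t = _from_mu(radon_inverse(Sinogram(p_clean, spec), spec))
    x_s = _from_mu(radon_inverse(Sinogram(p_corrupt, spec), spec))
    return PairedSample(
        x_s,
        x_t,
        task="mar",
        transform=spec,
        provenance={
            "n_metals": n_metals,
            "metal_intensity": metal_intensity,
            "seed": seed,
            "beta": beta,
            "floor_counts": floor_counts,
            "i0": i0,
            "metal_mask": metal_mask,
            "n_metal_components": int(ndimage.label(metal_mask)[1]),
        },
    )


# -- undersampled MRI ------------------------------------------------------


def simulate_undersampled_mri(
    fullysampled: Phantom, accel: float, n_center: int = 6, seed: int = 0
) -> PairedSample:
    """Zero-filled / fully-sampled pair from Cartesian Gaussian masking."""
    rows, cols = fullysampled.shape
    mask = make_cartesian_gaussian_mask(cols, accel, n_center, seed)
    spec = TransformSpec("fourier", fullysampled.shape, mask=mask)
    k_full = fourier_forward(fullysampled.image, TransformSpec("fourier", fullysampled.shape))
    k_meas = KSpace(k_full.values * mask.as_grid(fullysampled.shape), mask_applied=True)
    zf = fourier_inverse(k_meas, spec)
    return PairedSample(
        np.abs(zf),
        fullysampled.image.copy(),
        task="mri",
        transform=spec,
        provenance={
            "accel": accel,
            "n_center": n_center,
            "seed": seed,
            "k_measured": k_meas.values,
            "mask": mask.columns_sampled.copy(),
        },
    )


# -- modality synthesis ----------------------------------------------------


def make_modality_pair(anatomy: Phantom, seed: int = 0) -> PairedSample:
    """Co-registered PET-like (source) / CT-like (target) pair.

    The shared tissue labels pass through two distinct monotone transfer
    functions: CT-like is sharp with bright bone; PET-like is smoothed with
    hot lesions and low bone uptake.  Mild Gaussian noise models detector
    variability.
    """
    rng = np.random.default_rng(seed)
    labels = anatomy.tissue_labels
    ct_lut = {LABEL_BACKGROUND: 0.0, LABEL_SOFT: 0.3, LABEL_BONE: 0.95, LABEL_LESION: 0.45}
    pet_lut = {LABEL_BACKGROUND: 0.0, LABEL_SOFT: 0.4, LABEL_BONE: 0.15, LABEL_LESION: 1.0}
    ct = np.zeros(anatomy.shape)
    pet = np.zeros(anatomy.shape)
    for lab, v in ct_lut.items():
        ct[labels == lab] = v
    for lab, v in pet_lut.items():
        pet[labels == lab] = v
    pet = ndimage.gaussian_filter(pet, sigma=1.5)
    ct = np.clip(ct + 0.01 * rng.standard_normal(ct.shape), 0, 1)
    pet = np.clip(pet + 0.02 * rng.standard_normal(pet.shape), 0, 1)
    spec = TransformSpec("radon", anatomy.shape, n_angles=_default_angles(anatomy.shape))
    return PairedSample(
        pet,
        ct,
        task="synthesis",
        transform=spec,
        provenance={"seed": seed, "tissue_labels": labels.copy()},
    )


# -- dataset assembly ------------------------------------------------------


def _default_angles(shape) -> int:
    # about 1.4 angles per image row keeps FBP quality without inflating cost
    return max(24, int(round(1.4 * shape[0])))


def _make_sample(task, shape, sample_seed, **kw):
    ss = np.random.SeedSequence([int(sample_seed)])
    phantom_seed, degrade_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    phantom = make_phantom(shape, n_ellipses=kw.get("n_ellipses", 5), seed=phantom_seed)
    if task == "lowdose":
        spec = TransformSpec("radon", shape, n_angles=kw.get("n_angles", _default_angles(shape)))
        return simulate_low_dose(
            phantom,
            kw.get("dose_fraction", 0.25),
            spec,
            counts_full=kw.get("counts_full", 500.0),
            seed=degrade_seed,
            recon=kw.get("recon", "em"),
            em_iters=kw.get("em_iters", 4),
        )
    if task == "mar":
        spec = TransformSpec("radon", shape, n_angles=kw.get("n_angles", _default_angles(shape)))
        return simulate_metal(
            phantom,
            n_metals=kw.get("n_metals", 2),
            metal_intensity=kw.get("metal_intensity", 4.0),
            spec=spec,
            seed=degrade_seed,
        )
    if task == "mri":
        return simulate_undersampled_mri(
            phantom,
            accel=kw.get("accel", 4),
            n_center=kw.get("n_center", 6),
            seed=degrade_seed,
        )
    if task == "synthesis":
        return make_modality_pair(phantom, seed=degrade_seed)
    raise ValueError(f"unknown task {task!r}")


def make_dataset(
    task: str,
    n_train: int,
    n_val: int,
    n_test: int,
    seed: int = 0,
    shape=(64, 64),
    **task_kwargs,
) -> dict:
    """Seeded disjoint train/val/test splits of PairedSamples plus a manifest."""
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("split sizes must be >= 1")
    total = n_train + n_val + n_test
    sample_seeds = np.random.SeedSequence(int(seed)).generate_state(total) % (2**31)
    samples = [
        _make_sample(task, tuple(shape), s, **task_kwargs) for s in sample_seeds
    ]
    manifest = {
        "task": task,
        "seed": int(seed),
        "shape": list(shape),
        "splits": {"train": n_train, "val": n_val, "test": n_test},
        "sample_seeds": [int(s) for s in sample_seeds],
        "task_kwargs": {k: v for k, v in task_kwargs.items()},
    }
    return {
        "train": samples[:n_train],
        "val": samples[n_train : n_train + n_val],
        "test": samples[n_train + n_val :],
        "manifest": manifest,
    }


def regenerate_from_manifest(manifest: dict) -> dict:
    """Rebuild a dataset bit-identically from its manifest."""
    return make_dataset(
        manifest["task"],
        manifest["splits"]["train"],
        manifest["splits"]["val"],
        manifest["splits"]["test"],
        seed=manifest["seed"],
        shape=tuple(manifest["shape"]),
        **manifest.get("task_kwargs", {}),
    )


def write_dataset(dataset: dict, out_dir) -> Path:
    """NPZ per sample + JSON manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for split in ("train", "val", "test"):
        d = out / split
        d.mkdir(exist_ok=True)
        for i, s in enumerate(dataset[split]):
            np.savez(d / f"sample_{i:04d}.npz", x_s=s.x_s, x_t=s.x_t, task=s.task)
    with open(out / "manifest.json", "w") as f:
        json.dump(dataset["manifest"], f, indent=2)
    return out
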