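"""Image-quality evaluation: SSIM, PSNR, radial noise power spectrum, SUV bias.

SSIM and PSNR follow their canonical definitions (Gaussian-weighted 11x11
window, sigma 1.5, K1=0.01, K2=0.03 for SSIM; 10*log10(range^2/MSE) for
PSNR).  The noise power spectrum treats the difference between a
reconstruction and its reference as the noise image, ensemble-averages
squared DFT magnitudes of detrended overlapping ROIs, and bins the 2-D
spectrum radially.  SUV bias is the signed percent error of the mean / max
uptake inside an explicit region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "psnr",
    "ssim",
    "nps2d",
    "nps_radial",
    "suv_bias",
    "nrmse",
    "MetricsReport",
    "evaluate_pairs",
]


def psnr(a: np.ndarray, b: np.ndarray, data_range: Optional[float] = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("psnr requires same-shape images")
    if data_range is None:
        data_range = float(b.max() - b.min())
    mse = np.mean((a - b) ** 2)
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: Optional[float] = None,
    sigma: float = 1.5,
    truncate: float = 3.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity with a Gaussian window.

    Local means, variances and covariance are Gaussian-filtered moments
    (sigma 1.5 truncated at 3.5 sigma, i.e. an 11x11 window), variances use
    the sample-covariance correction, and ``data_range`` defaults to the
    range of the reference image ``b``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("ssim requires same-shape images")
    if data_range is None:
        data_range = float(b.max() - b.min())
    r = int(truncate * sigma + 0.5)
    npix = (2 * r + 1) ** 2
    cov_norm = npix / (npix - 1)

    def filt(x):
        return ndimage.gaussian_filter(x, sigma=sigma, truncate=truncate)

    ua, ub = filt(a), filt(b)
    uaa, ubb, uab = filt(a * a), filt(b * b), filt(a * b)
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    vab = cov_norm * (uab - ua * ub)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * ua * ub + c1) * (2 * vab + c2)
    den = (ua**2 + ub**2 + c1) * (va + vb + c2)
    s = num / den
    pad = r  # ignore the filter's edge region, as the windowed mean does
    return float(s[pad:-pad, pad:-pad].mean()) if min(s.shape) > 2 * pad else float(s.mean())


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error normalised by the reference Euclidean norm."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


def _detrend_first_order(roi: np.ndarray) -> np.ndarray:
    """Subtract the least-squares plane a + b*x + c*y from a ROI."""
    h, w = roi.shape
    yy, xx = np.mgrid[0:h, 0:w]
    basis = np.stack([np.ones(h * w), xx.ravel(), yy.ravel()], axis=1)
    coef, *_ = np.linalg.lstsq(basis, roi.ravel(), rcond=None)
    return roi - (basis @ coef).reshape(h, w)


def nps2d(
    recon: np.ndarray,
    reference: np.ndarray,
    roi_size: int = 32,
    n_rois: Optional[int] = None,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Ensemble 2-D noise power spectrum of recon - reference.

    Overlapping ROIs (50% step) are first-order detrended; the NPS is
    pixel_area / N * the ensemble mean of |DFT|^2, so that the integral of
    the 2-D NPS over frequency equals the noise variance (Parseval).
    """
    recon = np.asarray(recon, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if recon.shape != reference.shape:
        raise ValueError("recon and reference must share a shape")
    if roi_size > min(recon.shape):
        raise ValueError("roi_size exceeds the image size")
    noise = recon - reference
    step = max(roi_size // 2, 1)
    rois = []
    for r0 in range(0, noise.shape[0] - roi_size + 1, step):
        for c0 in range(0, noise.shape[1] - roi_size + 1, step):
            rois.append(_detrend_first_order(noise[r0 : r0 + roi_size, c0 : c0 + roi_size]))
    if n_rois is not None:
        rois = rois[:n_rois]
    if len(rois) < 1:
        raise ValueError("too few ROIs for an NPS estimate")
    spectra = [np.abs(np.fft.fft2(r)) ** 2 for r in rois]
    return (pixel_size**2 / (roi_size * roi_size)) * np.mean(spectra, axis=0)


def nps_radial(
    recon: np.ndarray,
    reference: np.ndarray,
    roi_size: int = 32,
    n_rois: Optional[int] = None,
    pixel_size: float = 1.0,
):
    """Radially averaged 1-D NPS curve: (spatial frequency, power) arrays."""
    s2 = nps2d(recon, reference, roi_size, n_rois, pixel_size)
    f = np.fft.fftfreq(roi_size, d=pixel_size)
    fu, fv = np.meshgrid(f, f, indexing="ij")
    radius = np.hypot(fu, fv)
    df = 1.0 / (roi_size * pixel_size)
    bins = np.arange(0.0, radius.max() + df, df)
    idx = np.digitize(radius.ravel(), bins) - 1
    power = np.zeros(len(bins) - 1)
    for i in range(len(power)):
        sel = idx == i
        power[i] = s2.ravel()[sel].mean() if sel.any() else 0.0
    centers = 0.5 * (bins[:-1] + bins[1:])
    return centers, power


def suv_bias(pred_uptake: np.ndarray, gt_uptake: np.ndarray, roi_mask: np.ndarray):
    """Signed percent bias of (mean, max) uptake inside the ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("roi_mask is empty")
    pred = np.asarray(pred_uptake, dtype=np.float64)[roi_mask]
    gt = np.asarray(gt_uptake, dtype=np.float64)[roi_mask]
    out = []
    for stat in (np.mean, np.max):
        g = stat(gt)
        if g == 0:
            raise ValueError("ground-truth ROI statistic is zero")
        out.append(float(100.0 * (stat(pred) - g) / g))
    return tuple(out)


@dataclass
class MetricsReport:
    """Per-sample fidelity metrics plus recomputable aggregates."""

    per_sample: list = field(default_factory=list)  # dicts: ssim, psnr_dB, ...
    nps_curve: Optional[tuple] = None  # (freq, power)

    def add(self, **metrics) -> None:
        self.per_sample.append(metrics)

    def aggregates(self) -> dict:
        keys = sorted({k for rec in self.per_sample for k in rec if rec[k] is not None})
        out = {}
        for k in keys:
            vals = np.array([rec[k] for rec in self.per_sample if rec.get(k) is not None])
            finite = vals[np.isfinite(vals)]
            if finite.size:
                out[k] = {"mean": float(finite.mean()), "sd": float(finite.std(ddof=0))}
        return out

    def to_dict(self) -> dict:
        d = {"per_sample": self.per_sample, "aggregates": self.aggregates()}
        if self.nps_curve is not None:
            d["nps_curve"] = {
                "frequency": list(map(float, self.nps_curve[0])),
                "power": list(map(float, self.nps_curve[1])),
            }
        return d


def evaluate_pairs(pred_gt_pairs, data_range: float = 1.0, roi_masks=None) -> MetricsReport:
    """SSIM/PSNR (and SUV bias where a ROI is given) over (pred, gt) pairs."""
    report = MetricsReport()
    for i, (pred, gt) in enumerate(pred_gt_pairs):
        rec = {
            "ssim": ssim(pred, gt, data_range=data_range),
            "psnr_dB": psnr(pred, gt, data_range=data_range),
        }
        if roi_masks is not None and roi_masks[i] is not None:
            mb, xb = suv_bias(pred, gt, roi_masks[i])
            rec["suv_mean_bias_pct"] = mb
            rec["suv_max_bias_pct"] = xb
        report.add(**rec)
    return report
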