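"""Reconstruction quality metrics: PSNR, SNR and the high-frequency error norm.

All three compare magnitude images (reference phantoms are real and
nonnegative; reconstructions may carry residual phase).  HFEN filters the
difference image with a rotationally symmetric Laplacian-of-Gaussian
kernel, so it isolates errors in edges and fine features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

__all__ = ["MetricsReport", "psnr", "snr", "hfen", "log_kernel"]


@dataclass
class MetricsReport:
    """Quality metrics of one reconstruction (or one iteration of it)."""

    psnr_db: float
    snr_db: float
    hfen: float
    iteration: int = 0
    undersampling_factor: float = 1.0

# LoG filter parameters (kernel taps and Gaussian width)
HFEN_KERNEL_SIZE = 15
HFEN_SIGMA = 1.5


def _magnitudes(reference, recon) -> tuple[np.ndarray, np.ndarray]:
    ref = np.abs(np.asarray(reference)).astype(np.float64)
    rec = np.abs(np.asarray(recon)).astype(np.float64)
    if ref.shape != rec.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {rec.shape}")
    return ref, rec


def psnr(reference, recon) -> float:
    """Peak-signal-to-noise ratio in dB.

    20*log10(peak of the reference / RMS magnitude error); identical
    images return +inf.
    """
    ref, rec = _magnitudes(reference, recon)
    peak = ref.max()
    if peak == 0:
        raise ValueError("reference image is all-zero")
    err = np.sqrt(np.mean((rec - ref) ** 2))
    if err == 0:
        return np.inf
    return float(20.0 * np.log10(peak / err))


def snr(reference, recon) -> float:
    """Global signal-to-error ratio in dB: 20*log10(||ref|| / ||error||)."""
    ref, rec = _magnitudes(reference, recon)
    sig = np.linalg.norm(ref)
    if sig == 0:
        raise ValueError("reference image is all-zero")
    err = np.linalg.norm(rec - ref)
    if err == 0:
        return np.inf
    return float(20.0 * np.log10(sig / err))


def log_kernel(size: int = HFEN_KERNEL_SIZE, sigma: float = HFEN_SIGMA) -> np.ndarray:
    """Rotationally symmetric LoG kernel, mean-subtracted.

    Sampled Gaussian normalized to unit sum, multiplied by the Laplacian
    factor, then shifted to exact zero sum so a constant image filters to
    exactly zero.
    """
    half = (size - 1) / 2.0
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = x * x + y * y
    g = np.exp(-r2 / (2.0 * sigma**2))
    g /= g.sum()
    h = g * (r2 - 2.0 * sigma**2) / sigma**4
    return h - h.mean()


def hfen(reference, recon) -> float:
    """High-frequency error norm: ||LoG(|recon| - |ref|)||_F.

    The LoG filter is applied with symmetric boundary padding.
    """
    ref, rec = _magnitudes(reference, recon)
    diff = rec - ref
    filtered = correlate(diff, log_kernel(), mode="reflect")
    return float(np.linalg.norm(filtered))
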