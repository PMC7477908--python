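"""Fourier sampling operators, undersampling masks and the k-space update.

All transforms are centered (DC at the grid center) and unitary, so
Parseval's identity holds exactly and the data-consistency weight is
independent of grid size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceGrid",
    "fft2c",
    "ifft2c",
    "make_sampling_mask",
    "undersample",
    "zero_filled_recon",
    "kspace_data_update",
]

MASK_KINDS = ("variable_density_2d", "cartesian_lines", "uniform_random", "full")

# Exponent of the radial density (1 - r)^p used by the variable-density
# generator; higher p concentrates samples more tightly around DC.
VD_DENSITY_EXPONENT = 6.0


@dataclass
class SamplingMask:
    """Boolean k-space sampling pattern Omega on an H x W grid."""

    grid: np.ndarray  # boolean (H, W), True = sampled
    undersampling_factor: float
    kind: str
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def sampled_fraction(self) -> float:
        return float(self.grid.mean())


@dataclass
class KSpaceGrid:
    """Complex k-space data with its sampling mask.

    When ``is_measurement`` is true the array follows the zero-filled
    convention: entries outside Omega are stored as 0.
    """

    values: np.ndarray  # complex (H, W)
    mask: SamplingMask
    is_measurement: bool = True


def _check_2d(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got ndim={x.ndim}")
    return x


def fft2c(image: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT (image domain -> k-space)."""
    image = _check_2d(image, "image")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))


def ifft2c(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (k-space -> image domain)."""
    spectrum = _check_2d(spectrum, "spectrum")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spectrum), norm="ortho"))


def _dc_index(H: int, W: int) -> tuple[int, int]:
    # fftshift puts the DC bin at (H//2, W//2)
    return H // 2, W // 2


def _radius_map(H: int, W: int) -> np.ndarray:
    ci, cj = _dc_index(H, W)
    ii = (np.arange(H) - ci)[:, None] / max(ci, 1)
    jj = (np.arange(W) - cj)[None, :] / max(cj, 1)
    return np.minimum(np.hypot(ii, jj), 1.0)


def make_sampling_mask(
    H: int, W: int, factor: float, kind: str = "variable_density_2d", seed: int = 0
) -> SamplingMask:
    """Generate a k-space sampling mask keeping ~1/factor of the grid.

    ``variable_density_2d`` draws samples with radial density
    (1 - r)^p about DC, ``cartesian_lines`` keeps whole phase-encode rows,
    ``uniform_random`` samples uniformly.  The DC location is always
    included so the zero-filled initialization keeps the image intensity
    scale.
    """
    if factor < 1:
        raise ValueError(f"undersampling factor must be >= 1, got {factor}")
    if kind not in MASK_KINDS:
        raise ValueError(f"unknown mask kind {kind!r}; choose from {MASK_KINDS}")
    rng = np.random.default_rng(seed)
    grid = np.zeros((H, W), dtype=bool)
    dc = _dc_index(H, W)

    if kind == "full" or factor == 1:
        grid[:] = True
        return SamplingMask(grid=grid, undersampling_factor=factor, kind=kind, seed=seed)

    if kind == "cartesian_lines":
        n_lines = max(int(round(H / factor)), 1)
        rows = rng.choice(H, size=n_lines, replace=False)
        if dc[0] not in rows:
            rows[0] = dc[0]
        grid[rows, :] = True
        return SamplingMask(grid=grid, undersampling_factor=factor, kind=kind, seed=seed)

    n_samples = max(int(round(H * W / factor)), 1)
    if kind == "uniform_random":
        pdf = np.ones(H * W)
    else:  # variable_density_2d
        pdf = _variable_density_pdf(H, W, 1.0 / factor).ravel()
    # exact-count weighted selection: keep the n_samples bins where a
    # uniform draw falls furthest below its inclusion probability
    u = rng.uniform(size=H * W)
    order = np.argsort(u / np.maximum(pdf, 1e-12))
    grid.ravel()[order[:n_samples]] = True
    grid[dc] = True
    return SamplingMask(grid=grid, undersampling_factor=factor, kind=kind, seed=seed)


def _variable_density_pdf(H: int, W: int, target: float) -> np.ndarray:
    """Radial inclusion-probability map with mean ``target``.

    Polynomial falloff (1 - r)^p about DC, clipped to [0, 1] after an
    additive offset (or multiplicative scale when the bare polynomial
    already oversamples) solved by bisection so the expected sampled
    fraction matches the target.  The offset spreads a uniform floor of
    samples across high frequencies, which keeps the aliasing incoherent.
    """
    base = (1.0 - _radius_map(H, W)) ** VD_DENSITY_EXPONENT

    def mean_with(c: float) -> float:
        return float(np.clip(base + c, 0.0, 1.0).mean())

    def mean_scaled(a: float) -> float:
        return float(np.clip(a * base, 0.0, 1.0).mean())

    if mean_with(0.0) <= target:
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mean_with(mid) < target:
                lo = mid
            else:
                hi = mid
        return np.clip(base + hi, 0.0, 1.0)
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_scaled(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.clip(hi * base, 0.0, 1.0)


def undersample(image: np.ndarray, mask: SamplingMask) -> KSpaceGrid:
    """Simulate measurement: transform to k-space and zero out unsampled bins."""
    image = _check_2d(image, "image")
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} does not match mask shape {mask.shape}"
        )
    values = fft2c(image) * mask.grid
    return KSpaceGrid(values=values, mask=mask, is_measurement=True)


def zero_filled_recon(y: KSpaceGrid) -> np.ndarray:
    """Inverse transform of the zero-filled spectrum (the naive baseline)."""
    if not y.is_measurement:
        raise ValueError("zero_filled_recon expects measurement data")
    return ifft2c(y.values)


def kspace_data_update(
    M: np.ndarray, M0: np.ndarray, mask: SamplingMask, v: float
) -> np.ndarray:
    """Closed-form data-consistency update of the k-space estimate.

    Outside Omega the current estimate ``M`` is kept; on Omega the output
    is the convex combination ``(M + v*M0) / (1 + v)`` with the measured
    zero-filled spectrum ``M0``.  Large ``v`` enforces the measurements
    nearly exactly; ``v = 0`` ignores them.
    """
    M = _check_2d(M, "M")
    M0 = _check_2d(M0, "M0")
    if M.shape != M0.shape or M.shape != mask.shape:
        raise ValueError("M, M0 and mask must share the same shape")
    if v < 0:
        raise ValueError(f"v must be non-negative, got {v}")
    out = M.astype(np.complex128, copy=True)
    omega = mask.grid
    out[omega] = (M[omega] + v * M0[omega]) / (1.0 + v)
    return out
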