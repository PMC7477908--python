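"""Synthetic inputs: analytic head phantoms and sparse-coding test problems.

Everything here is generated programmatically and reproducibly from a seed,
so the rest of the package can be exercised without any measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "SHEPP_LOGAN_ELLIPSES",
    "generate_phantom",
    "add_complex_gaussian_noise",
    "SyntheticDLProblem",
    "make_synthetic_dl_problem",
    "make_incoherent_dictionary",
]

# Classical 10-ellipse Shepp-Logan head phantom with the widely used
# contrast-modified intensities (Toft variant).  Each entry is
# (x0, y0, a, b, phi_deg, intensity) in the [-1, 1]^2 plane, x to the
# right and y upward.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (0.0, 0.0, 0.69, 0.92, 0.0, 1.0),
    (0.0, -0.0184, 0.6624, 0.874, 0.0, -0.8),
    (0.22, 0.0, 0.11, 0.31, -18.0, -0.2),
    (-0.22, 0.0, 0.16, 0.41, 18.0, -0.2),
    (0.0, 0.35, 0.21, 0.25, 0.0, 0.1),
    (0.0, 0.1, 0.046, 0.046, 0.0, 0.1),
    (0.0, -0.1, 0.046, 0.046, 0.0, 0.1),
    (-0.08, -0.605, 0.046, 0.023, 0.0, 0.1),
    (0.0, -0.605, 0.023, 0.023, 0.0, 0.1),
    (0.06, -0.605, 0.023, 0.046, 0.0, 0.1),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of an additive-ellipse phantom.

    Ellipses are given as ``(x0, y0, a, b, phi_deg, intensity)`` tuples in
    the normalized plane [-1, 1]^2 (x rightward, y upward); the rendered
    value at a pixel is the sum of intensities of all ellipses containing
    its center, clipped to ``intensity_range``.
    """

    grid_size: int = 128
    ellipses: tuple[tuple[float, float, float, float, float, float], ...] = field(
        default=SHEPP_LOGAN_ELLIPSES
    )
    intensity_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError(f"grid_size must be >= 8, got {self.grid_size}")
        if not self.ellipses:
            raise ValueError("ellipses list must be non-empty")


def _pixel_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of pixel centers mapped to [-1, 1]^2, row index downward."""
    c = (2.0 * np.arange(n) + 1.0) / n - 1.0
    x = c[np.newaxis, :]
    y = -c[:, np.newaxis]  # row 0 is the top of the image -> y = +1 side
    return x, y


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a phantom image on a ``grid_size``-square grid.

    Deterministic for a given spec; the default spec produces the
    Shepp-Logan head phantom used throughout the reconstruction
    experiments.
    """
    n = spec.grid_size
    x, y = _pixel_grid(n)
    img = np.zeros((n, n), dtype=np.float64)
    for x0, y0, a, b, phi_deg, amp in spec.ellipses:
        phi = np.deg2rad(phi_deg)
        c, s = np.cos(phi), np.sin(phi)
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        img += amp * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    lo, hi = spec.intensity_range
    return np.clip(img, lo, hi)


def point_in_ellipse_value(spec: PhantomSpec, x: float, y: float) -> float:
    """Signed sum of intensities of all spec ellipses containing (x, y).

    Direct membership evaluation at a single point; useful as an
    independent check of the rasterizer.
    """
    total = 0.0
    for x0, y0, a, b, phi_deg, amp in spec.ellipses:
        phi = np.deg2rad(phi_deg)
        c, s = np.cos(phi), np.sin(phi)
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        if (xr / a) ** 2 + (yr / b) ** 2 <= 1.0:
            total += amp
    lo, hi = spec.intensity_range
    return float(np.clip(total, lo, hi))


def add_complex_gaussian_noise(
    image: np.ndarray, sigma: float, seed: int
) -> np.ndarray:
    """Add i.i.d. circular complex Gaussian noise, std ``sigma`` per component.

    Models thermal receiver noise, which in MRI enters each quadrature
    channel independently.  ``sigma = 0`` returns the input unchanged
    (cast to complex).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    image = np.asarray(image)
    out = image.astype(np.complex128, copy=True)
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, image.shape) + 1j * rng.normal(
        0.0, sigma, image.shape
    )
    return out + noise


@dataclass
class SyntheticDLProblem:
    """An exactly-sparse dictionary-learning problem with known ground truth.

    ``signals = true_dictionary @ true_codes`` plus optional complex
    Gaussian noise; every code column has exactly ``s`` nonzeros.
    """

    true_dictionary: np.ndarray  # (m, n_true), unit-norm columns
    true_codes: np.ndarray  # (n_true, N), exactly s nonzeros per column
    signals: np.ndarray  # (m, N)
    s: int
    noise_sigma: float
    seed: int


def make_synthetic_dl_problem(
    m: int,
    n_true: int,
    N: int,
    s: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticDLProblem:
    """Draw a random ground-truth dictionary and exactly-s-sparse codes.

    The dictionary has i.i.d. Gaussian entries normalized to unit columns;
    code supports are uniform without replacement and coefficients are
    standard Gaussian.
    """
    if s > m:
        raise ValueError(f"sparsity s={s} exceeds signal dimension m={m}")
    if m > n_true:
        raise ValueError(f"need m <= n_true, got m={m}, n_true={n_true}")
    if N < n_true:
        raise ValueError(f"need N >= n_true, got N={N}, n_true={n_true}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((m, n_true))
    D /= np.linalg.norm(D, axis=0, keepdims=True)
    X = np.zeros((n_true, N))
    for k in range(N):
        support = rng.choice(n_true, size=s, replace=False)
        X[support, k] = rng.standard_normal(s)
    Y = D @ X
    if noise_sigma > 0:
        Y = Y + rng.normal(0.0, noise_sigma, Y.shape)
    return SyntheticDLProblem(
        true_dictionary=D,
        true_codes=X,
        signals=Y,
        s=s,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_incoherent_dictionary(
    m: int,
    n: int,
    max_coherence: float,
    seed: int = 0,
    max_iter: int = 500,
) -> np.ndarray:
    """Construct a unit-norm dictionary with pairwise coherence below a bound.

    Alternating projection on the Gram matrix: clip off-diagonal magnitudes
    to ``max_coherence``, project back to rank m, renormalize.  Raises if
    the bound is not reached (e.g. below the Welch bound for (m, n)).
    """
    if n < m:
        raise ValueError("need n >= m")
    welch = np.sqrt((n - m) / (m * (n - 1.0))) if n > 1 else 0.0
    if max_coherence < welch:
        raise ValueError(
            f"max_coherence {max_coherence} is below the Welch bound {welch:.4f}"
        )
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((m, n))
    D /= np.linalg.norm(D, axis=0, keepdims=True)
    target = 0.95 * max_coherence  # shrink slightly so the final check clears
    for _ in range(max_iter):
        G = D.T @ D
        off = G - np.diag(np.diag(G))
        mu = np.max(np.abs(off))
        if mu < max_coherence:
            return D
        clipped = np.clip(off, -target, target)
        G = clipped + np.eye(n)
        w, V = np.linalg.eigh(G)
        keep = w[-m:]
        D = (V[:, -m:] * np.sqrt(np.maximum(keep, 0.0))).T
        D /= np.linalg.norm(D, axis=0, keepdims=True)
    G = D.T @ D
    mu = np.max(np.abs(G - np.diag(np.diag(G))))
    if mu >= max_coherence:
        raise RuntimeError(
            f"could not reach coherence {max_coherence} (achieved {mu:.4f})"
        )
    return D
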