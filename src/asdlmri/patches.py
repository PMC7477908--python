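"""Overlapping patch extraction and averaging re-assembly.

Patches are vectorized column-major within the patch; origins are
enumerated row-major over the image.  With periodic (wraparound)
extraction at stride 1 every pixel is covered by exactly m = patch_side^2
patches, which is what makes the k-space reconstruction update an exact
least-squares solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["PatchMatrix", "extract_patches", "aggregate_patches"]


@dataclass
class PatchMatrix:
    """m x N matrix of vectorized overlapping patches with their geometry."""

    data: np.ndarray  # (m, N)
    patch_side: int
    stride: int
    origins: np.ndarray  # (N, 2) top-left (row, col) coordinates
    image_shape: tuple[int, int]
    wraparound: bool

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n_patches(self) -> int:
        return self.data.shape[1]


def _origin_grid(
    H: int, W: int, p: int, stride: int, wraparound: bool
) -> tuple[np.ndarray, np.ndarray]:
    if wraparound:
        rows = np.arange(0, H, stride)
        cols = np.arange(0, W, stride)
    else:
        rows = np.arange(0, H - p + 1, stride)
        cols = np.arange(0, W - p + 1, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return rr.ravel(), cc.ravel()


def extract_patches(
    image: np.ndarray, patch_side: int, stride: int = 1, wraparound: bool = True
) -> PatchMatrix:
    """Extract all overlapping ``patch_side``-square patches of an image."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    H, W = image.shape
    p = patch_side
    if p > min(H, W):
        raise ValueError(f"patch_side {p} exceeds image size {image.shape}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    src = np.pad(image, ((0, p - 1), (0, p - 1)), mode="wrap") if wraparound else image
    windows = sliding_window_view(src, (p, p))[::stride, ::stride]
    # transpose each window before raveling -> column-major vectorization
    data = windows.reshape(-1, p, p).transpose(0, 2, 1).reshape(-1, p * p).T
    rows, cols = _origin_grid(H, W, p, stride, wraparound)
    return PatchMatrix(
        data=np.ascontiguousarray(data),
        patch_side=p,
        stride=stride,
        origins=np.column_stack([rows, cols]),
        image_shape=(H, W),
        wraparound=wraparound,
    )


def _pixel_indices(patches: PatchMatrix) -> np.ndarray:
    """Flat image index of every (within-patch offset, patch) entry."""
    p = patches.patch_side
    H, W = patches.image_shape
    r = np.arange(p * p)
    a = r % p  # row offset within patch (column-major vectorization)
    b = r // p  # col offset within patch
    rows = patches.origins[:, 0][None, :] + a[:, None]
    cols = patches.origins[:, 1][None, :] + b[:, None]
    if patches.wraparound:
        rows %= H
        cols %= W
    elif (rows >= H).any() or (cols >= W).any():
        raise ValueError("patch origins extend beyond the image without wraparound")
    return rows * W + cols


def aggregate_patches(patches: PatchMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Scatter patch columns back onto the image grid.

    Returns ``(numerator, counts)`` where ``numerator[p]`` sums the values
    of all patches covering pixel p and ``counts[p]`` is how many do;
    the patch-averaged image is ``numerator / counts``.  Raises if any
    pixel is left uncovered.
    """
    H, W = patches.image_shape
    idx = _pixel_indices(patches).ravel()
    counts = np.bincount(idx, minlength=H * W).astype(np.float64)
    if (counts == 0).any():
        bad = np.flatnonzero(counts == 0)
        coords = [(int(b) // W, int(b) % W) for b in bad[:5]]
        raise ValueError(
            f"{bad.size} pixels not covered by any patch, e.g. {coords}; "
            "use wraparound or a smaller stride"
        )
    vals = patches.data.ravel()
    if np.iscomplexobj(vals):
        numerator = (
            np.bincount(idx, weights=vals.real, minlength=H * W)
            + 1j * np.bincount(idx, weights=vals.imag, minlength=H * W)
        )
    else:
        numerator = np.bincount(idx, weights=vals, minlength=H * W)
    return numerator.reshape(H, W), counts.reshape(H, W)
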