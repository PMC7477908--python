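"""File I/O: magnitude images (16-bit PNG, NIfTI) and k-space bundles (.npz)."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .datasets import SyntheticDLProblem
from .dictlearn import Dictionary
from .kspace import KSpaceGrid, SamplingMask

__all__ = [
    "save_image",
    "load_image",
    "save_kspace_bundle",
    "load_kspace_bundle",
    "save_dictionary",
    "load_dictionary",
    "save_dl_problem",
    "load_dl_problem",
]

_PNG_MAX = np.iinfo(np.uint16).max


def save_image(path, image: np.ndarray) -> None:
    """Write a magnitude image; format chosen by extension (.png or .nii/.nii.gz).

    PNG output is 16-bit, scaled so the image maximum maps to full range
    (the scale is not stored; PNG is for display).  NIfTI stores the raw
    float magnitudes.
    """
    path = Path(path)
    mag = np.abs(np.asarray(image)).astype(np.float64)
    if path.suffix == ".png":
        peak = mag.max()
        scaled = mag / peak if peak > 0 else mag
        iio.imwrite(path, (scaled * _PNG_MAX + 0.5).astype(np.uint16))
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(mag, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def load_image(path) -> np.ndarray:
    """Read a magnitude image; PNG values are rescaled to [0, 1]."""
    path = Path(path)
    if path.suffix == ".png":
        arr = iio.imread(path).astype(np.float64)
        if arr.ndim == 3:  # collapse any color channels
            arr = arr.mean(axis=-1)
        return arr / _PNG_MAX if arr.max() > 1 else arr
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    raise ValueError(f"unsupported image format: {path.name}")


def save_kspace_bundle(path, y: KSpaceGrid) -> None:
    """Write k-space values + mask + acquisition metadata to one .npz file."""
    meta = {
        "undersampling_factor": float(y.mask.undersampling_factor),
        "kind": y.mask.kind,
        "seed": int(y.mask.seed),
        "is_measurement": bool(y.is_measurement),
        "shape": list(y.values.shape),
    }
    np.savez(
        path,
        values=y.values.astype(np.complex128),
        mask=y.mask.grid.astype(bool),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_kspace_bundle(path) -> KSpaceGrid:
    """Read a k-space bundle written by :func:`save_kspace_bundle`."""
    with np.load(path) as npz:
        values = npz["values"]
        grid = npz["mask"].astype(bool)
        meta = json.loads(npz["meta"].tobytes().decode())
    mask = SamplingMask(
        grid=grid,
        undersampling_factor=meta["undersampling_factor"],
        kind=meta["kind"],
        seed=meta["seed"],
    )
    return KSpaceGrid(values=values, mask=mask, is_measurement=meta["is_measurement"])


def save_dictionary(path, D: Dictionary) -> None:
    """Write dictionary atoms + metadata (m, n, power order) to .npz."""
    meta = {"m": D.m, "n": D.n, "sorted_by_power": bool(D.sorted_by_power)}
    np.savez(
        path,
        atoms=D.atoms,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_dictionary(path) -> Dictionary:
    with np.load(path) as npz:
        atoms = npz["atoms"]
        meta = json.loads(npz["meta"].tobytes().decode())
    return Dictionary(atoms=atoms, sorted_by_power=meta["sorted_by_power"])


def save_dl_problem(path, prob: SyntheticDLProblem) -> None:
    """Write a synthetic sparse-coding problem + metadata to .npz."""
    meta = {"s": prob.s, "noise_sigma": prob.noise_sigma, "seed": prob.seed}
    np.savez(
        path,
        true_dictionary=prob.true_dictionary,
        true_codes=prob.true_codes,
        signals=prob.signals,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_dl_problem(path) -> SyntheticDLProblem:
    with np.load(path) as npz:
        meta = json.loads(npz["meta"].tobytes().decode())
        return SyntheticDLProblem(
            true_dictionary=npz["true_dictionary"],
            true_codes=npz["true_codes"],
            signals=npz["signals"],
            s=meta["s"],
            noise_sigma=meta["noise_sigma"],
            seed=meta["seed"],
        )
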