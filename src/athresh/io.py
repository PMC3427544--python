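"""NIfTI input/output and small test fixtures.

NIfTI is the only imaging dialect supported.  Statistic maps are 3D,
residual series 4D (time last, as conventional for NIfTI); internally the
package works time-first, so :func:`read_residuals` rolls the axis.
Trailing singleton spatial axes are squeezed so that planar (2D) maps
stored as ``(nx, ny, 1)`` volumes analyze as true 2D fields.
"""

from __future__ import annotations

import os

import numpy as np
import nibabel as nib

from .exceptions import InputError
from .simulation import SimulationSpec, fit_glm, simulate_dataset

__all__ = ["read_statmap", "read_residuals", "write_mask", "write_statmap",
           "make_fixture"]


def _load(path):
    try:
        img = nib.load(os.fspath(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise InputError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    return data, img.affine


def _squeeze_spatial(data):
    """Drop trailing singleton spatial axes (3D plane -> 2D field)."""
    while data.ndim > 2 and data.shape[-1] == 1:
        data = data[..., 0]
    return data


def read_statmap(path, *, squeeze: bool = True):
    """Read a 3D statistic map; returns ``(data, affine)``."""
    data, affine = _load(path)
    if data.ndim != 3:
        raise InputError(
            f"{path!r}: expected a 3D statistic map, got {data.ndim}D")
    if squeeze:
        data = _squeeze_spatial(data)
    return data, affine


def read_residuals(path, *, squeeze: bool = True):
    """Read 4D residuals; returns ``(frames, affine)`` with time first."""
    data, affine = _load(path)
    if data.ndim != 4:
        raise InputError(
            f"{path!r}: expected a 4D residual series, got {data.ndim}D")
    frames = np.moveaxis(data, -1, 0)
    if squeeze:
        frames = _squeeze_spatial(frames)
    return frames, affine


def read_mask(path, *, squeeze: bool = True):
    data, affine = _load(path)
    if data.ndim != 3:
        raise InputError(f"{path!r}: expected a 3D mask, got {data.ndim}D")
    if squeeze:
        data = _squeeze_spatial(data)
    return data > 0, affine


def write_statmap(data, affine, path) -> None:
    arr = np.asarray(data, dtype=np.float32)
    while arr.ndim < 3:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, affine), os.fspath(path))


def write_mask(mask, affine, path) -> None:
    """Write a binary activation mask as uint8 NIfTI (values 0/1 only)."""
    arr = np.asarray(mask, dtype=bool).astype(np.uint8)
    while arr.ndim < 3:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr, affine), os.fspath(path))


def make_fixture(seed: int, out_dir, *, signal_height: float = 0.6):
    """Write a small planar analogue of the simulation for fast tests.

    A 32x32 grid, 40 frames (20 rest / 20 task), two squares, FWHM-4
    smoothing.  Saves ``tmap.nii.gz`` (32x32x1) and ``residuals.nii.gz``
    (32x32x1x40); returns their paths and the ground-truth mask.
    """
    spec = SimulationSpec(grid=(32, 32), n_frames=40, rest_frames=20,
                          square_sizes=(4, 6), signal_height=signal_height,
                          smooth_fwhm=4.0, margin=4, gap=4, seed=int(seed))
    dataset = simulate_dataset(spec)
    glm = fit_glm(dataset)
    os.makedirs(out_dir, exist_ok=True)
    affine = np.eye(4)
    tmap_path = os.path.join(os.fspath(out_dir), "tmap.nii.gz")
    res_path = os.path.join(os.fspath(out_dir), "residuals.nii.gz")
    write_statmap(glm.tmap[..., None], affine, tmap_path)
    res4d = np.moveaxis(glm.residuals, 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(res4d.astype(np.float32), affine), res_path)
    return {"tmap": tmap_path, "residuals": res_path, "df": glm.df,
            "truth_mask": dataset.truth_mask, "spec": spec}
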