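"""NIfTI and tabular I/O."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import ImageSeries
from .scheme import read_scheme, write_scheme

__all__ = ["read_image", "write_image", "read_series", "write_series"]


def _affine(voxel_size) -> np.ndarray:
    """RAS-oriented diagonal affine from a voxel-size triplet (mm)."""
    return np.diag(list(voxel_size) + [1.0])


def write_image(path: str | Path, data: np.ndarray,
                voxel_size=(2.0, 2.0, 5.0),
                affine: np.ndarray | None = None) -> None:
    """Write a 3D map or 4D series as float32 NIfTI-1."""
    if affine is None:
        affine = _affine(voxel_size)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_image(path: str | Path, ndim: int | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if ndim is not None and data.ndim != ndim:
        raise ValueError(f"{path}: expected {ndim}D image, got {data.ndim}D")
    return data, img.affine


def write_series(stem: str | Path, series: ImageSeries) -> None:
    """Write a series as <stem>.nii.gz plus bval/bvec/cval/json sidecars
    and a <stem>_mask.nii.gz."""
    stem = Path(stem)
    write_image(stem.with_suffix(".nii.gz"), series.data, series.voxel_size)
    write_image(Path(str(stem) + "_mask.nii.gz"),
                series.mask.astype(np.float32), series.voxel_size)
    write_scheme(series.scheme, stem.with_suffix(".bval"),
                 stem.with_suffix(".bvec"), stem.with_suffix(".cval"),
                 stem.with_suffix(".json"))


def read_series(stem: str | Path) -> ImageSeries:
    """Read a series written by :func:`write_series`."""
    stem = Path(stem)
    data, affine = read_image(stem.with_suffix(".nii.gz"))
    if data.ndim != 4:
        raise ValueError(f"{stem}: series data must be 4D, got {data.ndim}D")
    mask, _ = read_image(Path(str(stem) + "_mask.nii.gz"), ndim=3)
    scheme = read_scheme(stem.with_suffix(".bval"), stem.with_suffix(".bvec"),
                         stem.with_suffix(".cval"), stem.with_suffix(".json"))
    voxel_size = tuple(float(abs(affine[i, i])) for i in range(3))
    return ImageSeries(data, scheme, mask > 0.5, voxel_size)
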