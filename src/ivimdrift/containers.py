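"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import AcquisitionScheme

__all__ = ["ImageSeries", "IVIMMaps", "Phantom", "ROI_NAMES"]

#: ROI label values: prefrontal white matter, centrum semiovale, cerebellum.
ROI_NAMES = {1: "PFWM", 2: "CS", 3: "CB"}


@dataclass
class ImageSeries:
    """4D dMRI series S(x, y, z, n) with its acquisition scheme.

    ``data`` is stored spatial-first (nibabel convention); the 4th axis
    indexes acquisitions and must match the scheme length.
    """

    data: np.ndarray
    scheme: AcquisitionScheme
    mask: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 5.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("ImageSeries data must be 4D")
        if self.data.shape[-1] != len(self.scheme):
            raise ValueError(
                f"series has {self.data.shape[-1]} volumes but scheme has "
                f"{len(self.scheme)} acquisitions"
            )
        if np.any(self.data < 0):
            raise ValueError("ImageSeries data must be nonnegative")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def copy_with(self, data: np.ndarray, scheme: AcquisitionScheme | None = None
                  ) -> "ImageSeries":
        return ImageSeries(data, scheme or self.scheme, self.mask.copy(),
                           self.voxel_size)


@dataclass
class IVIMMaps:
    """Per-voxel IVIM parameter maps.

    D and Dstar in µm²/ms, f dimensionless (0–1), v_d in mm/s, S0 and the
    intermediate intercept A in signal units.  Maps not applicable to a
    regime are None; invalid voxels are NaN.
    """

    D: np.ndarray | None = None
    f: np.ndarray | None = None
    Dstar: np.ndarray | None = None
    v_d: np.ndarray | None = None
    S0: np.ndarray | None = None
    A: np.ndarray | None = None

    def present(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in vars(self).items() if v is not None}

    @property
    def shape(self) -> tuple[int, ...]:
        for v in vars(self).values():
            if v is not None:
                return v.shape
        raise ValueError("empty IVIMMaps")


@dataclass
class Phantom:
    """Synthetic brain-like object: parameter maps, mask and ROI labels."""

    maps: IVIMMaps
    mask: np.ndarray
    roi_labels: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 5.0)

    def __post_init__(self) -> None:
        if np.any(self.roi_labels[~self.mask] != 0):
            raise ValueError("ROI labels outside the mask")

    def roi_mask(self, roi: int | str) -> np.ndarray:
        if isinstance(roi, str):
            inv = {v: k for k, v in ROI_NAMES.items()}
            roi = inv[roi]
        return self.roi_labels == roi

    @property
    def roi_masks(self) -> dict[str, np.ndarray]:
        return {name: self.roi_labels == lab for lab, name in ROI_NAMES.items()}
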