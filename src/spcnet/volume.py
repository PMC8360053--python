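"""Voxel-grid container and NIfTI I/O.

All volumes in this package use axis order (slice, row, col), 0-based, with
isotropic in-plane spacing and a (usually coarser) through-plane spacing.
Physical volume of a voxel set is ``count * in_plane_mm**2 * slice_mm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "read_volume", "write_volume", "VolumeError"]


class VolumeError(ValueError):
    """Raised for invalid volume construction or mismatched grids."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing.

    Parameters
    ----------
    data
        Array of shape ``(n_slices, n_rows, n_cols)``. Masks are stored as
        ``uint8`` with values in {0, 1}.
    in_plane_spacing_mm
        Row/column pixel size in millimetres (isotropic in plane).
    slice_spacing_mm
        Distance between consecutive slices in millimetres.
    is_mask
        Whether the volume is a binary mask (affects interpolation and I/O
        round-trip guarantees).
    """

    data: np.ndarray
    in_plane_spacing_mm: float
    slice_spacing_mm: float
    is_mask: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D data, got shape {self.data.shape}")
        if self.in_plane_spacing_mm <= 0 or self.slice_spacing_mm <= 0:
            raise VolumeError("spacings must be strictly positive")
        if self.is_mask:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise VolumeError("mask volumes may contain only {0, 1}")
            self.data = self.data.astype(np.uint8)
        else:
            self.data = self.data.astype(np.float64, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_spacing_mm**2 * self.slice_spacing_mm

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.in_plane_spacing_mm - other.in_plane_spacing_mm) <= tol
            and abs(self.slice_spacing_mm - other.slice_spacing_mm) <= tol
        )

    def require_same_grid(self, other: "ImageVolume", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise VolumeError(
                f"grid mismatch with {what}: {self.shape}@"
                f"({self.in_plane_spacing_mm},{self.slice_spacing_mm}) vs "
                f"{other.shape}@({other.in_plane_spacing_mm},{other.slice_spacing_mm})"
            )

    def with_data(self, data: np.ndarray, is_mask: bool | None = None) -> "ImageVolume":
        """New volume on the same grid carrying different voxel values."""
        return replace(
            self, data=data, is_mask=self.is_mask if is_mask is None else is_mask
        )


def _affine(in_plane_mm: float, slice_mm: float) -> np.ndarray:
    # axis order (slice, row, col) -> NIfTI (i, j, k) with spacings on the diagonal
    return np.diag([slice_mm, in_plane_mm, in_plane_mm, 1.0])


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz); spacing goes into the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data.astype(np.uint8) if vol.is_mask else vol.data.astype(np.float64)
    img = nib.Nifti1Image(data, _affine(vol.in_plane_spacing_mm, vol.slice_spacing_mm))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, is_mask: bool = False) -> ImageVolume:
    """Read a NIfTI volume; spacings are recovered from the affine.

    In-plane anisotropy beyond 1% triggers a warning and the mean spacing is
    used; this package assumes isotropic in-plane grids throughout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for bad files
        raise VolumeError(f"not a readable NIfTI file: {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    slice_mm, row_mm, col_mm = float(zooms[0]), float(zooms[1]), float(zooms[2])
    if row_mm > 0 and abs(row_mm - col_mm) / row_mm > 0.01:
        warnings.warn(
            f"anisotropic in-plane spacing ({row_mm:.4f}, {col_mm:.4f}) in {path.name}; "
            "using the mean",
            stacklevel=2,
        )
    in_plane = 0.5 * (row_mm + col_mm)
    return ImageVolume(data, in_plane, slice_mm, is_mask=is_mask)
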