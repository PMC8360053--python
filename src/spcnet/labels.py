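"""Fusing per-voxel Gleason-pattern maps and pathologist cancer masks into
3-class soft labels.

The label classes are (normal, indolent, aggressive). Gleason pattern 3 is
indolent; patterns 4 and 5 are aggressive and are not distinguished further.
Voxels the pathologist marked as cancer but for which no Gleason pattern is
available ("ungraded") are labelled indolent/aggressive with equal probability
0.5 and tracked in a separate boolean channel so that evaluation can exclude
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume, VolumeError

__all__ = [
    "GP_NONE",
    "GP3",
    "GP4",
    "GP5",
    "CLASS_NORMAL",
    "CLASS_INDOLENT",
    "CLASS_AGGRESSIVE",
    "GradeMap",
    "SoftLabelVolume",
    "fuse_labels",
]

# Gleason-pattern codes in a GradeMap
GP_NONE, GP3, GP4, GP5 = 0, 3, 4, 5
_VALID_GP = (GP_NONE, GP3, GP4, GP5)

# class channel indices in soft labels and model outputs
CLASS_NORMAL, CLASS_INDOLENT, CLASS_AGGRESSIVE = 0, 1, 2


@dataclass
class GradeMap:
    """Per-voxel Gleason pattern codes on an image grid.

    ``data`` holds values in {0 (none), 3, 4, 5}.
    """

    data: np.ndarray
    in_plane_spacing_mm: float
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D grade map, got shape {self.data.shape}")
        if not np.isin(self.data, _VALID_GP).all():
            bad = sorted(set(np.unique(self.data)) - set(_VALID_GP))
            raise VolumeError(f"grade map contains invalid codes {bad}")
        self.data = self.data.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def cancer_mask(self) -> np.ndarray:
        return self.data != GP_NONE

    def aggressive_mask(self) -> np.ndarray:
        return (self.data == GP4) | (self.data == GP5)


@dataclass
class SoftLabelVolume:
    """Per-voxel (normal, indolent, aggressive) probabilities plus an
    ``ungraded`` flag channel.

    ``probs`` has shape (3, slices, rows, cols) and sums to 1 over axis 0.
    ``ungraded`` marks pathologist-cancer-without-grade voxels, which carry
    (0, 0.5, 0.5).
    """

    probs: np.ndarray
    ungraded: np.ndarray
    in_plane_spacing_mm: float
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.ungraded = np.asarray(self.ungraded, dtype=bool)
        if self.probs.ndim != 4 or self.probs.shape[0] != 3:
            raise VolumeError(f"probs must be (3, S, R, C), got {self.probs.shape}")
        if self.ungraded.shape != self.probs.shape[1:]:
            raise VolumeError("ungraded channel shape mismatch")
        s = self.probs.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-6):
            raise VolumeError("per-voxel probabilities must sum to 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_spacing_mm**2 * self.slice_spacing_mm

    def hard_labels(self) -> np.ndarray:
        """Argmax class per voxel (ties break to the lower class index, so an
        ungraded 0.5/0.5 voxel reads as indolent — track ``ungraded`` to
        separate it)."""
        return np.argmax(self.probs, axis=0)

    def cancer_mask(self) -> np.ndarray:
        """Voxels carrying any cancer probability mass (incl. ungraded)."""
        return (self.hard_labels() != CLASS_NORMAL) | self.ungraded

    def aggressive_mask(self) -> np.ndarray:
        """Voxels whose argmax label is aggressive; excludes ungraded."""
        return (self.hard_labels() == CLASS_AGGRESSIVE) & ~self.ungraded

    def as_channels(self) -> np.ndarray:
        """4-channel array (3 probabilities + ungraded flag) for serialization."""
        return np.concatenate(
            [self.probs, self.ungraded[None].astype(np.float64)], axis=0
        )

    @classmethod
    def from_channels(
        cls, arr: np.ndarray, in_plane_mm: float, slice_mm: float
    ) -> "SoftLabelVolume":
        if arr.ndim != 4 or arr.shape[0] != 4:
            raise VolumeError(f"expected 4-channel array, got {arr.shape}")
        return cls(arr[:3], arr[3] > 0.5, in_plane_mm, slice_mm)


def fuse_labels(
    grade_map: GradeMap,
    pathologist_mask: ImageVolume,
    prostate_mask: ImageVolume,
) -> SoftLabelVolume:
    """Fuse grade information and the pathologist cancer outline into soft labels.

    Rules, applied per voxel:

    * Gleason pattern 4 or 5  -> (0, 0, 1) aggressive; pattern 3 -> (0, 1, 0)
      indolent. Grade information overrides the pathologist outline.
    * Pathologist cancer with no grade -> (0, 0.5, 0.5), flagged ``ungraded``.
    * Everything else -> (1, 0, 0) normal tissue.

    Voxels outside the prostate mask are forced to normal; cancer labels
    outside the gland (a registration artifact in real data) trigger a warning,
    not an error.
    """
    pathologist_mask.require_same_grid(prostate_mask, "prostate mask")
    if grade_map.shape != prostate_mask.shape:
        raise VolumeError(
            f"grade map shape {grade_map.shape} != mask shape {prostate_mask.shape}"
        )
    gland = prostate_mask.data.astype(bool)
    gp = grade_map.data
    path = pathologist_mask.data.astype(bool)

    aggressive = ((gp == GP4) | (gp == GP5)) & gland
    indolent = (gp == GP3) & gland
    ungraded = path & (gp == GP_NONE) & gland

    n_outside = int((((gp != GP_NONE) | path) & ~gland).sum())
    if n_outside:
        warnings.warn(
            f"{n_outside} cancer-labeled voxels outside the prostate mask; "
            "forced to normal (registration artifact)",
            stacklevel=2,
        )

    shape = prostate_mask.shape
    probs = np.zeros((3,) + shape, dtype=np.float64)
    probs[CLASS_AGGRESSIVE][aggressive] = 1.0
    probs[CLASS_INDOLENT][indolent] = 1.0
    probs[CLASS_INDOLENT][ungraded] = 0.5
    probs[CLASS_AGGRESSIVE][ungraded] = 0.5
    probs[CLASS_NORMAL] = 1.0 - probs[CLASS_INDOLENT] - probs[CLASS_AGGRESSIVE]
    return SoftLabelVolume(
        probs,
        ungraded,
        prostate_mask.in_plane_spacing_mm,
        prostate_mask.slice_spacing_mm,
    )
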