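"""Lesion objects from voxel labels: 3D morphological closing, 26-connected
component extraction with a minimum-volume filter, clinical-significance
flags, and the sextant partition of the gland used for negative sampling.

The closing step merges small, nearby label fragments (a by-product of
histopathology-to-MRI label mapping) into coherent 3D lesions. Components
below 250 mm^3 are discarded for lesion- and patient-level evaluation only —
never for training labels. A lesion is clinically significant when at least
1% (or 5%) of its cancer voxels are aggressive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .labels import CLASS_NORMAL, SoftLabelVolume
from .model import ProbabilityVolume
from .volume import ImageVolume, VolumeError

__all__ = [
    "Lesion",
    "SextantPartition",
    "close_labels_3d",
    "extract_lesions",
    "build_sextants",
    "benign_sextants",
    "extract_predicted_lesions",
    "DEFAULT_CLOSING_RADII_MM",
    "MIN_LESION_VOLUME_MM3",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)

# structuring-element physical radii (in-plane mm, through-plane mm)
DEFAULT_CLOSING_RADII_MM = (3.0, 1.0)
MIN_LESION_VOLUME_MM3 = 250.0


@dataclass
class Lesion:
    """A 26-connected lesion with volume and aggressive-fraction metadata."""

    lesion_id: int
    voxels: np.ndarray  # (n, 3) int coordinates (slice, row, col)
    volume_mm3: float
    aggressive_fraction: float
    significant_at_1pct: bool
    significant_at_5pct: bool

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[tuple(self.voxels.T)] = True
        return out


@dataclass
class SextantPartition:
    """Sextant ids 1..6 per in-gland voxel, 0 outside the gland.

    Id = 1 + side * 3 + tertile, side 0 = left (lower column indices),
    tertile 0/1/2 = base-to-apex slice groups."""

    labels: np.ndarray

    def ids(self) -> list[int]:
        return sorted(int(i) for i in np.unique(self.labels) if i > 0)

    def mask(self, sextant_id: int) -> np.ndarray:
        return self.labels == sextant_id


def _structuring_element(
    radii_mm: tuple[float, float], in_plane_mm: float, slice_mm: float
) -> np.ndarray:
    r_ip_mm, r_tp_mm = radii_mm
    if r_ip_mm < 0 or r_tp_mm < 0:
        raise ValueError("closing radii must be non-negative")
    r_ip = max(1, round(r_ip_mm / in_plane_mm)) if r_ip_mm > 0 else 0
    r_tp = round(r_tp_mm / slice_mm)  # 0 allowed through-plane
    zz, yy, xx = np.meshgrid(
        np.arange(-r_tp, r_tp + 1),
        np.arange(-r_ip, r_ip + 1),
        np.arange(-r_ip, r_ip + 1),
        indexing="ij",
    )
    ez = (zz / r_tp) ** 2 if r_tp else np.zeros_like(zz, dtype=float)
    eip = (
        (yy / r_ip) ** 2 + (xx / r_ip) ** 2
        if r_ip
        else np.zeros_like(yy, dtype=float)
    )
    return (ez + eip) <= 1.0


def close_labels_3d(
    cancer_mask: ImageVolume,
    closing_radii_mm: tuple[float, float] = DEFAULT_CLOSING_RADII_MM,
) -> ImageVolume:
    """3D morphological closing with an ellipsoidal element of the given
    physical radii. The input is padded before closing so the result always
    contains the input (no border clipping)."""
    if closing_radii_mm[0] < 0 or closing_radii_mm[1] < 0:
        raise ValueError("closing radii must be non-negative")
    data = cancer_mask.data.astype(bool)
    if closing_radii_mm == (0.0, 0.0):
        return cancer_mask.with_data(data.astype(np.uint8), is_mask=True)
    struct = _structuring_element(
        closing_radii_mm, cancer_mask.in_plane_spacing_mm, cancer_mask.slice_spacing_mm
    )
    pad = [(s // 2,) * 2 for s in struct.shape]
    padded = np.pad(data, pad)
    closed = ndimage.binary_closing(padded, structure=struct)
    sl = tuple(slice(p[0], padded.shape[i] - p[1]) for i, p in enumerate(pad))
    out = closed[sl] | data
    return cancer_mask.with_data(out.astype(np.uint8), is_mask=True)


def extract_lesions(
    closed_mask: ImageVolume,
    soft_labels: SoftLabelVolume | None = None,
    min_volume_mm3: float = MIN_LESION_VOLUME_MM3,
) -> list[Lesion]:
    """26-connected components of a closed cancer mask as Lesion objects.

    The aggressive fraction of a lesion counts aggressive-argmax voxels of
    the original labels in the numerator (ungraded voxels excluded) over all
    cancer voxels of the component in the denominator (ungraded voxels
    included). Components below ``min_volume_mm3`` are dropped. With no
    ``soft_labels`` (e.g. thresholded model predictions) the fraction is NaN
    and significance flags are False.
    """
    data = closed_mask.data.astype(bool)
    vox = closed_mask.voxel_volume_mm3
    if soft_labels is not None:
        if soft_labels.shape != closed_mask.shape:
            raise VolumeError("soft labels not aligned with the closed mask")
        agg = soft_labels.aggressive_mask()
        cancer = soft_labels.cancer_mask()
    lab, n = ndimage.label(data, structure=_CONN26)
    lesions: list[Lesion] = []
    next_id = 1
    for i in range(1, n + 1):
        comp = lab == i
        volume = float(comp.sum() * vox)
        if volume < min_volume_mm3:
            continue
        if soft_labels is not None:
            n_cancer = int((comp & cancer).sum())
            n_agg = int((comp & agg).sum())
            frac = n_agg / n_cancer if n_cancer else 0.0
        else:
            frac = float("nan")
        sig1 = soft_labels is not None and frac >= 0.01
        sig5 = soft_labels is not None and frac >= 0.05
        lesions.append(
            Lesion(
                lesion_id=next_id,
                voxels=np.argwhere(comp),
                volume_mm3=volume,
                aggressive_fraction=frac,
                significant_at_1pct=sig1,
                significant_at_5pct=sig5,
            )
        )
        next_id += 1
    return lesions


def build_sextants(prostate_mask: ImageVolume) -> SextantPartition:
    """Partition the gland into sextants: a left/right split at the gland
    bounding-box midline (ties to the left half) crossed with three
    contiguous, near-equal slice tertiles (largest-remainder sizes) along
    the longitudinal axis."""
    gland = prostate_mask.data.astype(bool)
    if not gland.any():
        raise VolumeError("prostate mask is empty")
    slices_present = np.flatnonzero(gland.any(axis=(1, 2)))
    if slices_present.size < 3:
        raise VolumeError("gland spans fewer than 3 slices")
    cols_present = np.flatnonzero(gland.any(axis=(0, 1)))
    cmin, cmax = cols_present[0], cols_present[-1]
    span = cmax - cmin + 1
    # left half takes the extra column when the span is odd
    mid = cmin + (span + 1) // 2
    col_idx = np.arange(gland.shape[2])
    side = (col_idx >= mid).astype(int)  # 0 left, 1 right

    tertile_of_slice = np.full(gland.shape[0], -1, dtype=int)
    for t, group in enumerate(np.array_split(slices_present, 3)):
        tertile_of_slice[group] = t

    labels = np.zeros(gland.shape, dtype=np.int8)
    vox = np.argwhere(gland)
    labels[tuple(vox.T)] = (
        1 + side[vox[:, 2]] * 3 + tertile_of_slice[vox[:, 0]]
    )
    return SextantPartition(labels)


def benign_sextants(
    partition: SextantPartition,
    soft_labels: SoftLabelVolume,
    benign_threshold: float = 0.95,
) -> list[int]:
    """Sextants whose fraction of normal-argmax voxels (over the sextant's
    in-gland voxels) is >= the threshold; these serve as negatives in the
    lesion-level ROC."""
    if soft_labels.shape != partition.labels.shape:
        raise VolumeError("soft labels not aligned with the sextant partition")
    normal = soft_labels.hard_labels() == CLASS_NORMAL
    out = []
    for sid in partition.ids():
        m = partition.mask(sid)
        if normal[m].mean() >= benign_threshold:
            out.append(sid)
    return out


def extract_predicted_lesions(
    prob: ProbabilityVolume,
    class_channels: int | tuple[int, ...],
    threshold: float,
    closing_radii_mm: tuple[float, float] = DEFAULT_CLOSING_RADII_MM,
    min_volume_mm3: float = MIN_LESION_VOLUME_MM3,
    strict: bool = True,
) -> list[Lesion]:
    """Predicted lesions: threshold the (summed) class channel(s), then apply
    the same closing and minimum-volume rule used for ground-truth lesion
    outlines."""
    if isinstance(class_channels, int):
        class_channels = (class_channels,)
    score = sum(prob.probs[c] for c in class_channels)
    binary = score > threshold if strict else score >= threshold
    mask = ImageVolume(
        binary.astype(np.uint8),
        prob.in_plane_spacing_mm,
        prob.slice_spacing_mm,
        is_mask=True,
    )
    closed = close_labels_3d(mask, closing_radii_mm)
    return extract_lesions(closed, None, min_volume_mm3)
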