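"""MRI preprocessing: in-plane resampling, prostate-centred cropping,
histogram-landmark intensity standardization, and in-gland z-scoring.

Intensity standardization follows the classic histogram-landmark approach:
a set of percentile landmarks is learned once from the training volumes of
each sequence (T2w and ADC independently), and every volume is then mapped
onto those landmarks by a monotone piecewise-linear transform of its in-gland
intensities. Landmarks learned on the training split are frozen and applied
unchanged to test cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .volume import ImageVolume, VolumeError

__all__ = [
    "HistogramLandmarks",
    "resample_to_grid",
    "crop_around_prostate",
    "learn_landmarks",
    "apply_standardization",
    "zscore_in_gland",
    "preprocess_case",
]

DEFAULT_PERCENTILES = tuple(float(p) for p in range(10, 100, 10))
DEFAULT_CLIP = (1.0, 99.0)
# common intensity range volumes are anchored to before landmark averaging
_STANDARD_RANGE = (0.0, 100.0)


@dataclass
class HistogramLandmarks:
    """Learned mean percentile landmarks for one MRI sequence."""

    sequence_tag: str  # {"t2w", "adc"}
    percentiles: tuple[float, ...]
    mean_landmark_intensities: tuple[float, ...]
    clip_percentiles: tuple[float, float] = DEFAULT_CLIP

    def __post_init__(self) -> None:
        if len(self.percentiles) != len(self.mean_landmark_intensities):
            raise VolumeError("percentiles and landmark intensities differ in length")
        vals = np.asarray(self.mean_landmark_intensities, dtype=float)
        if not (np.diff(vals) > 0).all():
            raise VolumeError("mean landmark intensities must be strictly increasing")
        pcts = np.asarray(self.percentiles, dtype=float)
        if not ((pcts > 0).all() and (pcts < 100).all() and (np.diff(pcts) > 0).all()):
            raise VolumeError("percentiles must be strictly increasing in (0, 100)")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "sequence_tag": self.sequence_tag,
            "percentiles": list(self.percentiles),
            "mean_landmark_intensities": [
                float(v) for v in self.mean_landmark_intensities
            ],
            "clip_percentiles": list(self.clip_percentiles),
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HistogramLandmarks":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            sequence_tag=payload["sequence_tag"],
            percentiles=tuple(payload["percentiles"]),
            mean_landmark_intensities=tuple(payload["mean_landmark_intensities"]),
            clip_percentiles=tuple(payload["clip_percentiles"]),
        )


def resample_to_grid(vol: ImageVolume, target_in_plane_mm: float) -> ImageVolume:
    """Resample in-plane to ``target_in_plane_mm``; slice spacing is never
    changed. Intensity volumes use bilinear interpolation, masks nearest
    neighbour (so mask outputs stay binary)."""
    if target_in_plane_mm <= 0:
        raise ValueError("target spacing must be positive")
    factor = vol.in_plane_spacing_mm / target_in_plane_mm
    if abs(factor - 1.0) < 1e-9:
        return vol.with_data(vol.data.copy())
    order = 0 if vol.is_mask else 1
    data = ndimage.zoom(
        vol.data.astype(np.float64),
        (1.0, factor, factor),
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    if vol.is_mask:
        data = (data > 0.5).astype(np.uint8)
    return ImageVolume(
        data, target_in_plane_mm, vol.slice_spacing_mm, is_mask=vol.is_mask
    )


def _centroid_index(mask: np.ndarray) -> tuple[int, int]:
    """Rounded in-plane centroid (row, col); .5 ties round toward the smaller
    index."""
    idx = np.argwhere(mask)
    cr, cc = idx[:, 1].mean(), idx[:, 2].mean()
    return int(np.ceil(cr - 0.5)), int(np.ceil(cc - 0.5))


def crop_around_prostate(
    vol: ImageVolume, prostate_mask: ImageVolume, size_px: int
) -> ImageVolume:
    """An in-plane ``size_px`` x ``size_px`` window centred at the rounded
    prostate centroid, all slices retained; zero-padded where the window
    exceeds the grid."""
    vol.require_same_grid(prostate_mask, "prostate mask")
    if prostate_mask.data.sum() == 0:
        raise VolumeError("prostate mask is empty")
    cr, cc = _centroid_index(prostate_mask.data.astype(bool))
    ns, nr, nc = vol.shape
    half = size_px // 2
    r0, c0 = cr - half, cc - half
    out = np.zeros((ns, size_px, size_px), dtype=vol.data.dtype)
    rs, re = max(r0, 0), min(r0 + size_px, nr)
    cs, ce = max(c0, 0), min(c0 + size_px, nc)
    if rs < re and cs < ce:
        out[:, rs - r0 : re - r0, cs - c0 : ce - c0] = vol.data[:, rs:re, cs:ce]
    return ImageVolume(
        out, vol.in_plane_spacing_mm, vol.slice_spacing_mm, is_mask=vol.is_mask
    )


def _anchored_rescale(
    values: np.ndarray, clip: tuple[float, float]
) -> np.ndarray:
    """Linearly map the volume's [clip_low, clip_high] percentile range onto
    the common standard range, so landmark averaging compares like with like."""
    lo, hi = np.percentile(values, clip)
    if hi <= lo:
        raise VolumeError("degenerate in-gland histogram (clip percentiles equal)")
    s0, s1 = _STANDARD_RANGE
    return s0 + (values - lo) * (s1 - s0) / (hi - lo)


def learn_landmarks(
    training_volumes: list[tuple[ImageVolume, ImageVolume]],
    sequence_tag: str,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    clip_percentiles: tuple[float, float] = DEFAULT_CLIP,
) -> HistogramLandmarks:
    """Learn mean percentile landmarks over the in-gland voxels of the
    training volumes of one sequence."""
    if not training_volumes:
        raise VolumeError("need at least one training volume")
    per_volume = []
    for vol, mask in training_volumes:
        vol.require_same_grid(mask, "prostate mask")
        in_gland = vol.data[mask.data.astype(bool)]
        if in_gland.size < 10:
            raise VolumeError("volume has fewer than 10 prostate voxels")
        rescaled = _anchored_rescale(in_gland, clip_percentiles)
        per_volume.append(np.percentile(rescaled, percentiles))
    means = np.mean(per_volume, axis=0)
    return HistogramLandmarks(
        sequence_tag=sequence_tag,
        percentiles=tuple(percentiles),
        mean_landmark_intensities=tuple(float(v) for v in means),
        clip_percentiles=tuple(clip_percentiles),
    )


def _piecewise_map(
    values: np.ndarray, src: np.ndarray, dst: np.ndarray
) -> np.ndarray:
    """Monotone piecewise-linear map src->dst with end-segment slope
    extrapolation beyond the outermost knots."""
    out = np.interp(values, src, dst)
    lo_slope = (dst[1] - dst[0]) / (src[1] - src[0])
    hi_slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
    below = values < src[0]
    above = values > src[-1]
    out[below] = dst[0] + (values[below] - src[0]) * lo_slope
    out[above] = dst[-1] + (values[above] - src[-1]) * hi_slope
    return out


def apply_standardization(
    vol: ImageVolume, prostate_mask: ImageVolume, landmarks: HistogramLandmarks
) -> ImageVolume:
    """Map the volume's own in-gland percentiles onto the learned landmarks.

    Only prostate voxels are transformed; the rest of the frame is passed
    through unchanged (it is discarded by the in-gland z-scoring and
    evaluation anyway)."""
    vol.require_same_grid(prostate_mask, "prostate mask")
    gland = prostate_mask.data.astype(bool)
    in_gland = vol.data[gland]
    if in_gland.size < 10:
        raise VolumeError("volume has fewer than 10 prostate voxels")
    src = np.percentile(in_gland, landmarks.percentiles)
    if not (np.diff(src) > 0).all():
        raise VolumeError(
            "degenerate in-gland histogram: percentiles are not strictly increasing"
        )
    dst = np.asarray(landmarks.mean_landmark_intensities)
    data = vol.data.astype(np.float64).copy()
    data[gland] = _piecewise_map(in_gland, src, dst)
    return vol.with_data(data)


def zscore_in_gland(vol: ImageVolume, prostate_mask: ImageVolume) -> ImageVolume:
    """Affine transform making in-gland intensities zero-mean, unit-SD; the
    same affine is applied to the whole frame."""
    vol.require_same_grid(prostate_mask, "prostate mask")
    gland = prostate_mask.data.astype(bool)
    in_gland = vol.data[gland]
    if in_gland.size < 2:
        raise VolumeError("need at least 2 prostate voxels")
    mu, sd = float(in_gland.mean()), float(in_gland.std())
    if sd == 0:
        raise VolumeError("zero in-gland standard deviation")
    return vol.with_data((vol.data - mu) / sd)


def preprocess_case(
    t2w: ImageVolume,
    adc: ImageVolume,
    prostate_mask: ImageVolume,
    landmarks: dict[str, HistogramLandmarks],
    target_in_plane_mm: float = 0.29,
    crop_px: int = 224,
    extra_masks: dict[str, ImageVolume] | None = None,
) -> dict[str, ImageVolume]:
    """Full chain for one case: resample -> crop -> standardize -> z-score.

    ``extra_masks`` (e.g. label or outline volumes) ride along through the
    geometric steps with nearest-neighbour interpolation. Returns a dict with
    keys "t2w", "adc", "prostate_mask" and any extra mask names.
    """
    t2w.require_same_grid(adc, "ADC")
    t2w.require_same_grid(prostate_mask, "prostate mask")
    mask_r = resample_to_grid(prostate_mask, target_in_plane_mm)
    out: dict[str, ImageVolume] = {}
    for name, vol in (("t2w", t2w), ("adc", adc)):
        v = resample_to_grid(vol, target_in_plane_mm)
        v = crop_around_prostate(v, mask_r, crop_px)
        out[name] = v
    mask_c = crop_around_prostate(mask_r, mask_r, crop_px)
    out["prostate_mask"] = mask_c
    for name in ("t2w", "adc"):
        v = apply_standardization(out[name], mask_c, landmarks[name])
        out[name] = zscore_in_gland(v, mask_c)
    if extra_masks:
        for name, vol in extra_masks.items():
            v = resample_to_grid(vol, target_in_plane_mm)
            out[name] = crop_around_prostate(v, mask_r, crop_px)
    return out
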