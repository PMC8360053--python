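"""Synthetic bi-parametric prostate MRI phantoms with ground-truth labels.

Each generated case carries a T2w volume, an ADC volume, a prostate mask, a
per-voxel Gleason-pattern map, a pathologist cancer mask (the grade map plus
an optional ungraded rim), and an imperfect radiologist outline that misses
some lesions entirely and underestimates the extent of the rest — the failure
modes that motivate histopathology-derived labels in the first place.

The generator emulates clinical acquisition geometry (sub-millimetre in-plane
spacing, 3–4.5 mm slice spacing) and a lognormal lesion-volume distribution
with mean ≈ 1,800 mm³ and SD ≈ 2,200 mm³, matching radical-prostatectomy
cohorts. Lesions are hypointense on ADC and mildly hypointense on T2w, with
aggressive (Gleason ≥ 4) subregions darkest on ADC. Mixed lesions embed an
aggressive core strictly inside an indolent lesion so that aggressive and
indolent cancer coexist within one connected lesion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import GP3, GP4, GP5, GP_NONE, GradeMap
from .volume import ImageVolume, VolumeError, write_volume

__all__ = [
    "PhantomParams",
    "StudyCase",
    "generate_prostate_mask",
    "place_lesions",
    "render_case",
    "generate_cohort",
]

# nominal gland extent (mm): left-right (cols), ant-post (rows), sup-inf (slices)
_GLAND_LR_MM = 40.0
_GLAND_AP_MM = 30.0
_GLAND_SI_MM = 38.0
_MARGIN_MM = 6.0

# realized lesion volumes are rejected outside this band (mm^3)
_LESION_VOL_MIN, _LESION_VOL_MAX = 50.0, 20000.0


@dataclass(frozen=True)
class PhantomParams:
    """Configuration for the phantom cohort generator.

    ``class_mix`` gives the proportions of (normal, indolent-only,
    mixed-lesion) cases. ``contrast`` maps each sequence to additive mean
    intensity offsets for (tissue, indolent, aggressive) voxels, in native
    intensity units. ``noise_sd`` is the Gaussian noise SD as a fraction of
    the in-gland base intensity. ``radiologist_shrink_factor`` is the
    fraction of in-plane lesion area the radiologist outline retains
    (1.0 = perfect outline); ``radiologist_miss_prob`` is the per-lesion
    probability that the radiologist misses the lesion entirely.
    """

    seed: int = 0
    n_cases: int = 10
    class_mix: tuple[float, float, float] = (0.2, 0.3, 0.5)
    in_plane_spacing_mm: float = 0.29
    slice_spacing_mm: float = 3.0
    grid: tuple[int, int, int] = (20, 180, 180)
    lesion_volume_lognormal: tuple[float, float] = (7.04, 0.96)
    n_lesions_range: tuple[int, int] = (1, 2)
    contrast: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "t2w": (0.0, -60.0, -100.0),
            "adc": (0.0, -350.0, -650.0),
        }
    )
    noise_sd: float = 0.05
    radiologist_miss_prob: float = 0.2
    radiologist_shrink_factor: float = 0.7
    ungraded_rim_prob: float = 0.3

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.class_mix), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix must sum to 1")
        if not (0 < self.radiologist_shrink_factor <= 1.0):
            raise ValueError("radiologist_shrink_factor must be in (0, 1]")
        if self.in_plane_spacing_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("spacings must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_spacing_mm**2 * self.slice_spacing_mm

    def lesion_volume_mean_mm3(self) -> float:
        mu, sigma = self.lesion_volume_lognormal
        return math.exp(mu + sigma**2 / 2)

    @classmethod
    def high_contrast(cls, **overrides) -> "PhantomParams":
        """Preset with strong lesion contrast and low noise, for small-scale
        training experiments where the signal must dominate a short schedule."""
        defaults = dict(
            contrast={"t2w": (0.0, -120.0, -180.0), "adc": (0.0, -550.0, -850.0)},
            noise_sd=0.03,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class StudyCase:
    """One synthetic patient: paired volumes plus ground-truth annotations."""

    case_id: str
    t2w: ImageVolume
    adc: ImageVolume
    prostate_mask: ImageVolume
    grade_map: GradeMap
    pathologist_mask: ImageVolume
    radiologist_outline: ImageVolume
    cohort_tag: str  # {"prostatectomy-like", "normal", "biopsy-like"}

    def __post_init__(self) -> None:
        for name in ("adc", "prostate_mask", "pathologist_mask", "radiologist_outline"):
            self.t2w.require_same_grid(getattr(self, name), name)
        if self.grade_map.shape != self.t2w.shape:
            raise VolumeError("grade map grid mismatch")
        if self.prostate_mask.data.sum() == 0:
            raise VolumeError("prostate mask is empty")
        gland = self.prostate_mask.data.astype(bool)
        if (self.grade_map.cancer_mask() & ~gland).any():
            raise VolumeError("cancer voxels outside the prostate mask")


def _grid_extent_mm(params: PhantomParams) -> tuple[float, float, float]:
    ns, nr, nc = params.grid
    return (
        ns * params.slice_spacing_mm,
        nr * params.in_plane_spacing_mm,
        nc * params.in_plane_spacing_mm,
    )


def _smooth_noise(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_prostate_mask(
    params: PhantomParams, rng: np.random.Generator
) -> ImageVolume:
    """A smoothed, slightly perturbed ellipsoidal gland mask centred in the grid.

    The nominal gland is ~40 (LR) x 30 (AP) x 38 (SI) mm; its boundary is
    perturbed by a smooth random field so no two cases are identical. The grid
    must fit the ellipsoid plus a margin and the gland must span at least 5
    slices.
    """
    si, ap, lr = _grid_extent_mm(params)
    if (
        si < _GLAND_SI_MM + 2 * params.slice_spacing_mm
        or ap < _GLAND_AP_MM + _MARGIN_MM
        or lr < _GLAND_LR_MM + _MARGIN_MM
        or params.grid[0] < 7
    ):
        raise ValueError(
            f"grid {params.grid} at ({params.in_plane_spacing_mm}, "
            f"{params.slice_spacing_mm}) mm cannot contain a "
            f"{_GLAND_LR_MM:g}x{_GLAND_AP_MM:g}x{_GLAND_SI_MM:g} mm gland with margin"
        )
    ns, nr, nc = params.grid
    z, y, x = np.meshgrid(
        (np.arange(ns) - (ns - 1) / 2) * params.slice_spacing_mm,
        (np.arange(nr) - (nr - 1) / 2) * params.in_plane_spacing_mm,
        (np.arange(nc) - (nc - 1) / 2) * params.in_plane_spacing_mm,
        indexing="ij",
    )
    d = np.sqrt(
        (z / (_GLAND_SI_MM / 2)) ** 2
        + (y / (_GLAND_AP_MM / 2)) ** 2
        + (x / (_GLAND_LR_MM / 2)) ** 2
    )
    sig_ip = max(1.0, 6.0 / params.in_plane_spacing_mm)
    perturb = _smooth_noise(rng, params.grid, (1.0, sig_ip, sig_ip))
    mask = (d + 0.08 * perturb) < 1.0
    # light smoothing of the binary boundary
    mask = ndimage.gaussian_filter(mask.astype(np.float64), (0.5, 1.5, 1.5)) > 0.5
    # keep the largest connected component
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("gland generation produced an empty mask")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    if np.unique(np.nonzero(mask)[0]).size < 5:
        raise ValueError("gland spans fewer than 5 slices")
    return ImageVolume(
        mask.astype(np.uint8),
        params.in_plane_spacing_mm,
        params.slice_spacing_mm,
        is_mask=True,
    )


def _anisotropic_distance_mm(shape, center, params: PhantomParams) -> np.ndarray:
    ns, nr, nc = shape
    z = (np.arange(ns) - center[0]) * params.slice_spacing_mm
    y = (np.arange(nr) - center[1]) * params.in_plane_spacing_mm
    x = (np.arange(nc) - center[2]) * params.in_plane_spacing_mm
    return np.sqrt(
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    )


def _grow_blob(
    available: np.ndarray,
    target_mm3: float,
    params: PhantomParams,
    rng: np.random.Generator,
    max_attempts: int = 25,
) -> np.ndarray | None:
    """One connected, irregular blob of approximately ``target_mm3`` inside
    ``available``; None if no acceptable blob is found.

    The blob is the sublevel set of (distance from a random in-gland seed +
    smooth noise), thresholded at the order statistic that realises the target
    voxel count; candidates whose untrimmed extent leaves the gland by more
    than 25% or whose realised volume misses the target by more than 20% are
    rejected and resampled.
    """
    vox = params.voxel_volume_mm3
    k_target = max(1, int(round(target_mm3 / vox)))
    cand = np.argwhere(available)
    if cand.shape[0] < k_target:
        return None
    sig_ip = max(1.0, 4.0 / params.in_plane_spacing_mm)
    r_eq = (3 * target_mm3 / (4 * math.pi)) ** (1 / 3)
    for _ in range(max_attempts):
        center = cand[rng.integers(cand.shape[0])]
        dist = _anisotropic_distance_mm(available.shape, center, params)
        noise = _smooth_noise(rng, available.shape, (0.8, sig_ip, sig_ip))
        f = dist + 0.35 * r_eq * noise
        f_in = f[available]
        thr = np.partition(f_in, k_target - 1)[k_target - 1]
        untrimmed = f <= thr
        if untrimmed.sum() > 0 and (untrimmed & ~available).sum() > 0.25 * untrimmed.sum():
            continue  # leaves the gland too much; resample
        blob = untrimmed & available
        lab, n = ndimage.label(blob, structure=np.ones((3, 3, 3), dtype=int))
        if n == 0:
            continue
        blob = lab == lab[tuple(center)]
        if not blob.any():
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
            blob = lab == (1 + int(np.argmax(sizes)))
        realized = blob.sum() * vox
        if abs(realized - target_mm3) <= 0.2 * target_mm3:
            return blob
    return None


def _sample_lesion_volume(params: PhantomParams, rng: np.random.Generator) -> float:
    mu, sigma = params.lesion_volume_lognormal
    for _ in range(200):
        v = float(rng.lognormal(mu, sigma))
        if _LESION_VOL_MIN <= v <= _LESION_VOL_MAX:
            return v
    return float(np.clip(math.exp(mu), _LESION_VOL_MIN, _LESION_VOL_MAX))


def place_lesions(
    mask: ImageVolume,
    params: PhantomParams,
    rng: np.random.Generator,
    case_kind: str = "mixed",
    n_lesions: int | None = None,
) -> GradeMap:
    """Place 0..n lesions inside the gland and return a Gleason-pattern map.

    ``case_kind`` is "normal" (no lesions), "indolent" (pure Gleason pattern 3
    lesions), or "mixed" (at least one lesion with an embedded aggressive
    core, a strict subset of the lesion). Lesions are kept 26-disconnected
    from each other by excluding a dilated neighbourhood of already-placed
    lesions.
    """
    if mask.data.sum() == 0:
        raise VolumeError("prostate mask is empty")
    gp = np.zeros(mask.shape, dtype=np.int8)
    if case_kind == "normal":
        return GradeMap(gp, mask.in_plane_spacing_mm, mask.slice_spacing_mm)
    if case_kind not in ("indolent", "mixed"):
        raise ValueError(f"unknown case kind {case_kind!r}")

    if n_lesions is None:
        lo, hi = params.n_lesions_range
        n_lesions = int(rng.integers(lo, hi + 1))
    available = mask.data.astype(bool)
    gland_vol = available.sum() * params.voxel_volume_mm3
    placed = 0
    for j in range(n_lesions):
        target = min(_sample_lesion_volume(params, rng), 0.4 * gland_vol)
        blob = _grow_blob(available, target, params, rng)
        if blob is None:
            continue
        wants_core = case_kind == "mixed" and (placed == 0 or rng.random() < 0.5)
        gp[blob] = GP3
        if wants_core:
            core = _embed_core(blob, params, rng)
            gp[core] = GP5 if rng.random() < 0.15 else GP4
        placed += 1
        # forbid 26-adjacency between lesions: exclude a 2-voxel halo
        halo = ndimage.binary_dilation(
            blob, structure=np.ones((3, 3, 3), dtype=bool), iterations=2
        )
        available &= ~halo
    return GradeMap(gp, mask.in_plane_spacing_mm, mask.slice_spacing_mm)


def _embed_core(
    blob: np.ndarray, params: PhantomParams, rng: np.random.Generator
) -> np.ndarray:
    """An aggressive core strictly inside ``blob``: the given fraction of the
    lesion's voxels nearest to an interior seed, with the outermost shell of
    the lesion always excluded so 0 < aggressive fraction < 1."""
    interior = ndimage.binary_erosion(blob, structure=np.ones((1, 3, 3), dtype=bool))
    if not interior.any():
        interior = blob
    shell_excluded = interior
    frac = rng.uniform(0.2, 0.7)
    k = max(1, int(frac * blob.sum()))
    k = min(k, int(shell_excluded.sum()))
    seeds = np.argwhere(shell_excluded)
    center = seeds[rng.integers(seeds.shape[0])]
    dist = _anisotropic_distance_mm(blob.shape, center, params)
    dist_in = np.where(shell_excluded, dist, np.inf)
    thr = np.partition(dist_in[shell_excluded], k - 1)[k - 1]
    core = (dist_in <= thr) & shell_excluded
    if core.sum() >= blob.sum():  # degenerate tiny lesion; keep one voxel indolent
        core[tuple(center)] = False
    return core


def _lesion_components(gp: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(gp != GP_NONE, structure=np.ones((3, 3, 3), dtype=int))


def _erode_to_fraction(
    lesion: np.ndarray, fraction: float
) -> np.ndarray:
    """In-plane erosion of a 3D lesion until its voxel count drops to
    ``fraction`` of the original (never below 1 voxel)."""
    if fraction >= 1.0:
        return lesion.copy()
    target = max(1, int(round(fraction * lesion.sum())))
    out = lesion.copy()
    struct = np.zeros((1, 3, 3), dtype=bool)
    struct[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    while out.sum() > target:
        nxt = ndimage.binary_erosion(out, structure=struct)
        if nxt.sum() == 0:
            break
        out = nxt
    return out


def render_case(
    mask: ImageVolume,
    grade_map: GradeMap,
    params: PhantomParams,
    rng: np.random.Generator,
    case_id: str = "case",
    cohort_tag: str | None = None,
) -> StudyCase:
    """Render intensities and annotations for one case.

    T2w/ADC = base tissue intensity + per-class contrast offsets + a smooth
    multiplicative bias field + Gaussian noise. The pathologist mask is the
    cancer extent of the grade map, optionally with a 1-voxel in-plane
    ungraded rim per lesion (cancer per the pathologist, no grade available).
    The radiologist outline drops each lesion with ``radiologist_miss_prob``
    and erodes survivors in-plane to ``radiologist_shrink_factor`` of their
    area.
    """
    gland = mask.data.astype(bool)
    gp = grade_map.data
    indolent = gp == GP3
    aggressive = (gp == GP4) | (gp == GP5)

    bases = {"t2w": (400.0, 250.0), "adc": (1300.0, 900.0)}
    images: dict[str, ImageVolume] = {}
    for seq in ("t2w", "adc"):
        base_in, base_out = bases[seq]
        off_tissue, off_ind, off_agg = params.contrast[seq]
        img = np.where(gland, base_in + off_tissue, base_out).astype(np.float64)
        img[indolent] = base_in + off_ind
        img[aggressive] = base_in + off_agg
        # smooth lesion borders slightly so contrast is not a hard step
        img = ndimage.gaussian_filter(img, (0.0, 1.0, 1.0))
        sig = max(2.0, 20.0 / params.in_plane_spacing_mm)
        bias = 1.0 + 0.03 * _smooth_noise(rng, mask.shape, (2.0, sig, sig))
        img = img * bias + rng.normal(0.0, params.noise_sd * base_in, mask.shape)
        images[seq] = ImageVolume(
            img, params.in_plane_spacing_mm, params.slice_spacing_mm
        )

    lab, n_lesions = _lesion_components(gp)
    pathologist = gp != GP_NONE
    radiologist = np.zeros(mask.shape, dtype=bool)
    for i in range(1, n_lesions + 1):
        lesion = lab == i
        if rng.random() < params.ungraded_rim_prob:
            rim = (
                ndimage.binary_dilation(
                    lesion, structure=np.ones((1, 3, 3), dtype=bool)
                )
                & ~(gp != GP_NONE)
                & gland
            )
            pathologist |= rim
        if rng.random() >= params.radiologist_miss_prob:
            radiologist |= _erode_to_fraction(lesion, params.radiologist_shrink_factor)

    if cohort_tag is None:
        cohort_tag = "normal" if n_lesions == 0 else "prostatectomy-like"
    as_mask = lambda arr: ImageVolume(  # noqa: E731
        arr.astype(np.uint8),
        params.in_plane_spacing_mm,
        params.slice_spacing_mm,
        is_mask=True,
    )
    return StudyCase(
        case_id=case_id,
        t2w=images["t2w"],
        adc=images["adc"],
        prostate_mask=mask,
        grade_map=grade_map,
        pathologist_mask=as_mask(pathologist),
        radiologist_outline=as_mask(radiologist),
        cohort_tag=cohort_tag,
    )


def _largest_remainder_counts(n: int, mix: tuple[float, ...]) -> list[int]:
    raw = [n * p for p in mix]
    counts = [int(math.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def lesion_records(case: StudyCase) -> list[dict]:
    """Ground-truth per-lesion records (26-connected components of the grade
    map): volume and aggressive voxel fraction."""
    lab, n = _lesion_components(case.grade_map.data)
    vox = case.grade_map.in_plane_spacing_mm**2 * case.grade_map.slice_spacing_mm
    agg = case.grade_map.aggressive_mask()
    out = []
    for i in range(1, n + 1):
        comp = lab == i
        size = int(comp.sum())
        out.append(
            {
                "case_id": case.case_id,
                "cohort_tag": case.cohort_tag,
                "lesion_id": i,
                "volume_mm3": size * vox,
                "aggressive_fraction": float((comp & agg).sum() / size),
            }
        )
    return out


def generate_cohort(
    params: PhantomParams, out_dir: str | Path | None = None
) -> tuple[list[StudyCase], pd.DataFrame]:
    """Generate a seeded cohort honouring ``class_mix`` exactly
    (largest-remainder rounding), optionally writing NIfTI volumes and a
    manifest CSV.

    Returns the cases and the per-lesion manifest (one row per lesion;
    normal cases appear with lesion_id 0 and zero volume).
    """
    if params.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    counts = _largest_remainder_counts(params.n_cases, params.class_mix)
    kinds = (
        ["normal"] * counts[0] + ["indolent"] * counts[1] + ["mixed"] * counts[2]
    )
    cases: list[StudyCase] = []
    records: list[dict] = []
    for idx, kind in enumerate(kinds):
        rng = np.random.default_rng([params.seed, idx])
        case_id = f"phantom-{params.seed:05d}-{idx:03d}"
        mask = generate_prostate_mask(params, rng)
        gp = place_lesions(mask, params, rng, case_kind=kind)
        case = render_case(mask, gp, params, rng, case_id=case_id)
        cases.append(case)
        recs = lesion_records(case)
        if not recs:
            recs = [
                {
                    "case_id": case_id,
                    "cohort_tag": case.cohort_tag,
                    "lesion_id": 0,
                    "volume_mm3": 0.0,
                    "aggressive_fraction": 0.0,
                }
            ]
        records.extend(recs)
    manifest = pd.DataFrame.from_records(
        records,
        columns=["case_id", "cohort_tag", "lesion_id", "volume_mm3", "aggressive_fraction"],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            for case in cases:
                d = out_dir / case.case_id
                write_volume(case.t2w, d / "t2w.nii.gz")
                write_volume(case.adc, d / "adc.nii.gz")
                write_volume(case.prostate_mask, d / "prostate_mask.nii.gz")
                write_volume(
                    ImageVolume(
                        case.grade_map.data.astype(np.float64),
                        params.in_plane_spacing_mm,
                        params.slice_spacing_mm,
                    ),
                    d / "grade_map.nii.gz",
                )
                write_volume(case.pathologist_mask, d / "pathologist_mask.nii.gz")
                write_volume(case.radiologist_outline, d / "radiologist_outline.nii.gz")
            manifest.to_csv(out_dir / "manifest.csv", index=False)
        except OSError as exc:
            raise OSError(f"cannot write cohort to {out_dir}: {exc}") from exc
    return cases, manifest
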