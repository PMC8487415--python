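"""Synthetic ⁶⁸Ga-DOTATATE-like liver phantom generation.

Real somatostatin-receptor PET of the liver shows a high, fairly uniform
normal background with substantial image noise; metastatic neuroendocrine
lesions appear as focal regions of increased uptake spanning a handful of
consecutive trans-axial slices.  This module renders studies with that
statistical structure — an elliptical liver filled with a uniform mean
activity, optional spherical lesions at a configurable uptake contrast, a
Gaussian point-spread blur, and additive Gaussian noise — together with the
aligned liver mask and gold-standard lesion label map that the detection
pipeline consumes.

Lesion counts per abnormal study follow a normal distribution with mean 4.0
and SD 2.75, rounded and clamped to [1, 9]; studies span 23–71 slices and
each lesion covers 4–5 consecutive slices, mirroring the clinical cohort the
pipeline is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
from scipy import ndimage


class PlacementError(RuntimeError):
    """Raised when lesions or background spheres cannot be placed."""


@dataclass(frozen=True)
class LiverShape:
    """Per-study liver ellipse: semi-axes as grid fractions, center jitter."""

    semi_axis_row_frac: float = 0.32
    semi_axis_col_frac: float = 0.38
    center_jitter_frac: float = 0.04


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic liver study generator.

    Activity is in arbitrary uptake units; all geometry is in millimetres
    converted through ``pixel_spacing_mm``.  Slice thickness is
    ``pixel_spacing_mm * slice_anisotropy``.
    """

    grid_shape: tuple[int, int] = (64, 64)
    pixel_spacing_mm: float = 4.0
    n_slices_range: tuple[int, int] = (23, 71)
    liver_shape_params: LiverShape = field(default_factory=LiverShape)
    background_mean: float = 100.0
    noise_sigma: float = 10.0
    lesion_count_mean: float = 4.0
    lesion_count_sd: float = 2.75
    lesion_count_max: int = 9
    lesion_slice_span_range: tuple[int, int] = (4, 5)
    lesion_radius_range_mm: tuple[float, float] = (6.0, 14.0)
    lesion_contrast_range: tuple[float, float] = (2.0, 3.5)
    blur_fwhm_mm: float = 6.0
    slice_anisotropy: float = 1.0
    enforce_detectable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_count_max > 9:
            raise ValueError("lesion_count_max must be <= 9 (well-defined, "
                             "non-confluent studies have fewer than 10 lesions)")
        if self.lesion_count_max < 1:
            raise ValueError("lesion_count_max must be >= 1")
        for name in ("pixel_spacing_mm", "slice_anisotropy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if min(self.grid_shape) <= 0 or min(self.n_slices_range) <= 0:
            raise ValueError("grid and slice counts must be strictly positive")
        if self.lesion_radius_range_mm[0] <= 0:
            raise ValueError("lesion radii must be strictly positive")
        if self.lesion_contrast_range[0] <= 1.0:
            raise ValueError("lesion contrast must exceed 1 (uptake above background)")
        if self.blur_fwhm_mm < 0 or self.noise_sigma < 0:
            raise ValueError("blur and noise must be non-negative")
        if self.enforce_detectable and self.background_mean > 0:
            # Lesion peak must clear the modified PERCIST level
            # 1.5*mean + 2*SD by construction.
            floor = (1.5 * self.background_mean + 2.0 * self.noise_sigma)
            peak = self.lesion_contrast_range[0] * self.background_mean
            if peak <= floor:
                raise ValueError(
                    "lesion_contrast_range lower bound "
                    f"{self.lesion_contrast_range[0]} yields peak {peak} <= "
                    f"detection floor {floor}; raise the contrast or set "
                    "enforce_detectable=False")

    @property
    def slice_thickness_mm(self) -> float:
        return self.pixel_spacing_mm * self.slice_anisotropy

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if isinstance(d.get("liver_shape_params"), dict):
            d["liver_shape_params"] = LiverShape(**d["liver_shape_params"])
        for key in ("grid_shape", "n_slices_range", "lesion_slice_span_range",
                    "lesion_radius_range_mm", "lesion_contrast_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SliceStack:
    """A study's activity volume, shape (slices, rows, cols)."""

    voxels: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float | None = None
    slice_index_origin: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("SliceStack expects a 3D (slice, row, col) array")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("activity values must be finite and non-negative")
        if self.slice_thickness_mm is None:
            self.slice_thickness_mm = self.pixel_spacing_mm

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class OrganMask:
    """Binary liver mask aligned with a :class:`SliceStack`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("OrganMask expects a 3D array")
        if not self.mask.any():
            raise ValueError("OrganMask must contain at least one foreground pixel")


@dataclass
class LesionLabelMap:
    """Gold-standard lesion pixels; distinct lesions carry distinct ids."""

    labels: np.ndarray  # int array, 0 = background

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("LesionLabelMap expects a 3D array")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def lesion_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class Study:
    """One synthetic study with its masks and metadata."""

    study_id: str
    stack: SliceStack
    liver: OrganMask
    lesions: LesionLabelMap
    abnormal: bool


def sample_lesion_count(spec: PhantomSpec, rng: np.random.Generator) -> int:
    """Draw a lesion count: round(N(mean, sd)) clamped to [1, lesion_count_max]."""
    raw = rng.normal(spec.lesion_count_mean, spec.lesion_count_sd)
    return int(np.clip(round(raw), 1, spec.lesion_count_max))


def _render_liver(spec: PhantomSpec, n_slices: int,
                  rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid_shape
    p = spec.liver_shape_params
    jr = rng.uniform(-p.center_jitter_frac, p.center_jitter_frac) * rows
    jc = rng.uniform(-p.center_jitter_frac, p.center_jitter_frac) * cols
    cr, cc = (rows - 1) / 2.0 + jr, (cols - 1) / 2.0 + jc
    ar, ac = p.semi_axis_row_frac * rows, p.semi_axis_col_frac * cols
    rr, cg = np.mgrid[0:rows, 0:cols]
    ellipse = ((rr - cr) / ar) ** 2 + ((cg - cc) / ac) ** 2 <= 1.0
    return np.broadcast_to(ellipse, (n_slices, rows, cols)).copy()


def _lesion_mask(spec: PhantomSpec, n_slices: int, center: tuple[float, float, float],
                 radius_mm: float, span: int) -> np.ndarray:
    """Rasterize one lesion: an ellipsoid whose axial extent covers exactly
    ``span`` consecutive slices and whose in-plane semi-axis is ``radius_mm``."""
    rows, cols = spec.grid_shape
    t = spec.slice_thickness_mm
    cz, cr, cc = center
    axial_semi = 0.5 * span * t * 0.98  # covers span slice centers, not span+1
    zz, rr, cg = np.mgrid[0:n_slices, 0:rows, 0:cols]
    dz = (zz - cz) * t
    dr = (rr - cr) * spec.pixel_spacing_mm
    dc = (cg - cc) * spec.pixel_spacing_mm
    return (dz / axial_semi) ** 2 + (dr ** 2 + dc ** 2) / radius_mm ** 2 <= 1.0


_STRUCT_3D = np.ones((3, 3, 3), bool)  # confluence test: 8-connected + adjacent slices


def generate_study(spec: PhantomSpec, abnormal: bool, seed: int,
                   max_retries: int = 200) -> tuple[SliceStack, OrganMask, LesionLabelMap]:
    """Generate one study: activity stack, liver mask, gold lesion labels.

    The pre-blur structure image is background_mean inside the liver and 0
    outside; lesions (abnormal studies only) are rendered at
    contrast × background_mean.  The structure is then blurred with the
    point-spread Gaussian, i.i.d. Gaussian noise of SD noise_sigma is added,
    and negative values are clipped to 0.  The label map records the pre-blur
    lesion extents.  Identical (spec, abnormal, seed) give identical output.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.n_slices_range
    n_slices = int(rng.integers(lo, hi + 1))
    liver = _render_liver(spec, n_slices, rng)

    rows, cols = spec.grid_shape
    labels = np.zeros((n_slices, rows, cols), np.int32)
    structure = liver.astype(np.float64) * spec.background_mean

    if abnormal:
        n_lesions = sample_lesion_count(spec, rng)
        occupied = np.zeros_like(liver)
        for lesion_id in range(1, n_lesions + 1):
            placed = False
            for _ in range(max_retries):
                span = int(rng.integers(spec.lesion_slice_span_range[0],
                                        spec.lesion_slice_span_range[1] + 1))
                radius = rng.uniform(*spec.lesion_radius_range_mm)
                contrast = rng.uniform(*spec.lesion_contrast_range)
                half = 0.5 * (span - 1)
                cz = rng.uniform(half, n_slices - 1 - half)
                cr = rng.uniform(0, rows - 1)
                cc = rng.uniform(0, cols - 1)
                lesion = _lesion_mask(spec, n_slices, (cz, cr, cc), radius, span)
                if not lesion.any():
                    continue
                if not liver[lesion].all():
                    continue
                spans = np.unique(np.nonzero(lesion)[0])
                if not (spec.lesion_slice_span_range[0] <= len(spans)
                        <= spec.lesion_slice_span_range[1]):
                    continue
                # non-confluence: no 26-neighborhood contact with other lesions
                if (ndimage.binary_dilation(lesion, _STRUCT_3D) & occupied).any():
                    continue
                labels[lesion] = lesion_id
                occupied |= lesion
                structure[lesion] = contrast * spec.background_mean
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place lesion {lesion_id}/{n_lesions} inside the "
                    f"liver without confluence after {max_retries} retries; "
                    "the liver is too small for the requested lesions")

    if spec.blur_fwhm_mm > 0:
        sigma_px = spec.blur_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma = (sigma_px / spec.slice_thickness_mm,
                 sigma_px / spec.pixel_spacing_mm,
                 sigma_px / spec.pixel_spacing_mm)
        structure = ndimage.gaussian_filter(structure, sigma=sigma)

    if spec.noise_sigma > 0:
        structure = structure + rng.normal(0.0, spec.noise_sigma, structure.shape)
    voxels = np.clip(structure, 0.0, None)

    return (SliceStack(voxels, spec.pixel_spacing_mm, spec.slice_thickness_mm),
            OrganMask(liver), LesionLabelMap(labels))


def generate_dataset(spec: PhantomSpec, n_abnormal: int, n_normal: int,
                     seed: int) -> list[Study]:
    """Generate a dataset of studies with unique sequential 5-digit IDs.

    Abnormal studies come first, then normal; per-study seeds are derived
    deterministically from ``seed`` so the collection is reproducible.
    """
    if n_abnormal < 0 or n_normal < 0:
        raise ValueError("study counts must be non-negative")
    studies: list[Study] = []
    flags = [True] * n_abnormal + [False] * n_normal
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   seed_seq.spawn(len(flags))]
    for idx, (abnormal, study_seed) in enumerate(zip(flags, child_seeds), start=1):
        stack, liver, lesions = generate_study(spec, abnormal, study_seed)
        studies.append(Study(f"{idx:05d}", stack, liver, lesions, abnormal))
    return studies


def iter_slices(study: Study) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (activity, liver, lesion-mask) 2D triples for each slice."""
    for z in range(study.stack.n_slices):
        yield (study.stack.voxels[z], study.liver.mask[z],
               study.lesions.mask[z])
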