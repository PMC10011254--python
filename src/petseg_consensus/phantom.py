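"""Synthetic lung-lesion PET phantoms with kinetic-model uptake.

The generator emulates a lesion-in-lung digital phantom: an irregular
blob-shaped lesion partitioned into three concentric activity levels whose
70-minute values come from the two-tissue compartment model, embedded in a
uniform lung background normalized to 1.  Respiratory motion is modeled as
a rigid sinusoidal translation averaged over breathing bins, and scanner
degradation as PSF blur -> Poisson counting noise -> post-reconstruction
Gaussian smoothing (an image-domain stand-in for projection-space
simulation and iterative reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .kinetics import TISSUE_PARAMS, FengInput, KineticParams, compute_uptake_ratios
from .volume import VoxelVolume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "build_phantom",
    "apply_motion",
    "degrade",
    "gen_masks",
    "cohort_specs",
    "simulate_case",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Everything needed to build one phantom case reproducibly.

    Lengths are cm, times minutes.  ``noise_scale`` is the expected count
    per unit activity per voxel (larger = less noise); ``psf_fwhm_mm``
    stands in for scanner resolution plus reconstruction blur and is
    calibrated so that post-degradation lesion-to-background contrast lands
    in the 3-4.5 range typical of reconstructed FDG images of such lesions.
    """

    shape: tuple[int, int, int] = (48, 200, 200)
    spacing: tuple[float, float, float] = (0.50, 0.41, 0.41)
    lesion_center: tuple[float, float, float] | None = None  # voxel coords (z, y, x)
    lesion_volume_cm3: float = 14.0
    boundary_amplitude: float = 0.35  # radius perturbation, fraction of base radius
    boundary_smoothness_cm: float = 0.8  # correlation length of the perturbation
    level_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    tissues: dict[str, KineticParams] = field(
        default_factory=lambda: dict(TISSUE_PARAMS))
    uptake_time_min: float = 70.0
    motion_bins: int = 10
    diaphragm_cm: float = 1.5
    ap_cm: float = 0.5
    cycle_s: float = 5.0
    static_bin: int = 3
    noise_scale: float = 30.0
    psf_fwhm_mm: float = 12.0
    post_filter_fwhm_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.level_fractions) - 1.0) > 1e-9:
            raise ValueError("level fractions must sum to 1")
        if any(f < 0 for f in self.level_fractions):
            raise ValueError("level fractions must be non-negative")
        if self.motion_bins < 1:
            raise ValueError("motion_bins must be >= 1")
        if self.diaphragm_cm < 0 or self.ap_cm < 0:
            raise ValueError("motion amplitudes must be non-negative")
        if not 0 <= self.static_bin < self.motion_bins:
            raise ValueError("static_bin must index a motion bin")


@dataclass
class PhantomCase:
    """One simulated case: ground-truth activity plus derived volumes."""

    activity: VoxelVolume  # noise-free 70-min activity, lung == 1
    gt_static: np.ndarray  # lesion mask at the static (reference) bin
    gt_motion: np.ndarray  # union of the lesion mask over motion bins
    level_masks: tuple[np.ndarray, np.ndarray, np.ndarray]
    labels: np.ndarray  # 0 = lung background, 1..3 = lesion levels
    pet_image: VoxelVolume | None = None  # degraded image, filled by `degrade`
    case_id: str = "case"

    def __post_init__(self) -> None:
        for m in (self.gt_static, self.gt_motion, *self.level_masks):
            if m.shape != self.activity.shape:
                raise ValueError("masks must share the activity grid")


def _smooth_unit_noise(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """Gaussian-correlated field, normalized to zero mean / unit std."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded irregular blob with volume calibrated to the spec target."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    if spec.lesion_center is None:
        center = (nz / 2.0, ny / 2.0, nx / 2.0)
    else:
        center = spec.lesion_center
    r0 = (3.0 * spec.lesion_volume_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)  # cm

    # work on a crop around the lesion for speed
    half = [int(np.ceil(2.5 * r0 / s)) + 4 for s in spec.spacing]
    lo = [max(0, int(round(c)) - h) for c, h in zip(center, half)]
    hi = [min(n, int(round(c)) + h + 1) for c, n, h in zip(center, spec.shape, half)]
    sub = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) - center[0]) * dz,
        (np.arange(lo[1], hi[1]) - center[1]) * dy,
        (np.arange(lo[2], hi[2]) - center[2]) * dx,
        indexing="ij",
    )
    rho = np.sqrt(zz**2 + yy**2 + xx**2) / r0
    sigma_vox = [spec.boundary_smoothness_cm / s for s in spec.spacing]
    bump = spec.boundary_amplitude * _smooth_unit_noise(rng, rho.shape, sigma_vox)
    level = rho + bump

    # calibrate the iso-level so the blob volume matches the target
    voxel_cm3 = dz * dy * dx
    target_vox = spec.lesion_volume_cm3 / voxel_cm3
    lo_t, hi_t = 0.2, 2.5
    for _ in range(60):
        mid = 0.5 * (lo_t + hi_t)
        if np.count_nonzero(level < mid) < target_vox:
            lo_t = mid
        else:
            hi_t = mid
    blob = level < 0.5 * (lo_t + hi_t)
    blob = ndimage.binary_fill_holes(blob)
    lab, n = ndimage.label(blob)
    if n == 0:
        raise ValueError("lesion specification produced an empty mask")
    if n > 1:
        blob = lab == (np.argmax(np.bincount(lab.ravel())[1:]) + 1)

    mask = np.zeros(spec.shape, dtype=bool)
    mask[sub] = blob
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any() \
            or mask[:, :, 0].any() or mask[:, :, -1].any():
        raise ValueError("lesion does not fit inside the grid")
    return mask


def _partition_levels(mask: np.ndarray, spacing, fractions) -> np.ndarray:
    """Concentric partition: deepest voxels are Level 1 (core), rim Level 3.

    Ranks voxels by depth (Euclidean distance to the lesion surface) and
    cuts at the cumulative fractions, so level counts match the requested
    fractions exactly up to rounding.
    """
    depth = ndimage.distance_transform_edt(mask, sampling=spacing)
    idx = np.flatnonzero(mask.ravel())
    order = np.argsort(-depth.ravel()[idx], kind="stable")  # deepest first
    n = idx.size
    n1 = int(round(fractions[0] * n))
    n2 = int(round((fractions[0] + fractions[1]) * n))
    labels = np.zeros(mask.shape, dtype=np.uint8).ravel()
    labels[idx[order[:n1]]] = 1
    labels[idx[order[n1:n2]]] = 2
    labels[idx[order[n2:]]] = 3
    return labels.reshape(mask.shape)


def build_phantom(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Build the noise-free phantom: lesion geometry + kinetic activity.

    Lesion voxels carry the Level I/II/III lesion-to-lung activity ratios at
    the uptake time; the lung background is 1 everywhere else.  Fully
    reproducible from ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    mask = _lesion_mask(spec, rng)
    labels = _partition_levels(mask, spec.spacing, spec.level_fractions)

    lesion = [spec.tissues[f"lesion_level_{i}"] for i in (1, 2, 3)]
    ratios = compute_uptake_ratios(lesion, spec.tissues["lung"], FengInput(),
                                   t=spec.uptake_time_min)
    activity = np.ones(spec.shape, dtype=np.float64)
    for lvl, ratio in zip((1, 2, 3), ratios):
        activity[labels == lvl] = ratio

    level_masks = tuple(labels == lvl for lvl in (1, 2, 3))
    return PhantomCase(
        activity=VoxelVolume(activity, spec.spacing),
        gt_static=mask,
        gt_motion=mask.copy(),
        level_masks=level_masks,
        labels=labels,
        case_id=case_id,
    )


def _bin_shifts_vox(spec: PhantomSpec) -> np.ndarray:
    """Per-bin (z, y, x) voxel displacements relative to the static bin.

    The trajectory is sinusoidal over the breathing cycle: displacement
    ``amp * (1 - cos(phi)) / 2`` with bin phases at bin centers.  The
    diaphragm amplitude acts along z, the anterior-posterior amplitude
    along y.
    """
    phases = 2.0 * np.pi * (np.arange(spec.motion_bins) + 0.5) / spec.motion_bins
    excursion = (1.0 - np.cos(phases)) / 2.0  # in [0, 1]
    rel = excursion - excursion[spec.static_bin]
    shifts = np.zeros((spec.motion_bins, 3))
    shifts[:, 0] = rel * spec.diaphragm_cm / spec.spacing[0]
    shifts[:, 1] = rel * spec.ap_cm / spec.spacing[1]
    return shifts


def apply_motion(case: PhantomCase, spec: PhantomSpec) -> PhantomCase:
    """Average the activity over respiratory bins; union the ground truth.

    The static input is taken as the reference (intermediate) bin, so its
    displacement is zero and ``gt_static`` is always contained in the
    motion-union mask.  Activity is shifted with linear interpolation,
    which conserves total activity for interior lesions.
    """
    shifts = _bin_shifts_vox(spec)
    if np.allclose(shifts, 0.0):
        return replace(case, gt_motion=case.gt_static.copy())
    acc = np.zeros_like(case.activity.data)
    union = np.zeros(case.gt_static.shape, dtype=bool)
    gt_float = case.gt_static.astype(np.float64)
    for s in shifts:
        acc += ndimage.shift(case.activity.data, s, order=1, mode="nearest")
        union |= ndimage.shift(gt_float, s, order=1, mode="constant") > 0.5
    acc /= spec.motion_bins
    union |= case.gt_static
    return replace(case, activity=case.activity.like(acc), gt_motion=union)


def degrade(activity: VoxelVolume, spec: PhantomSpec,
            seed: int | np.random.Generator | None = None) -> VoxelVolume:
    """PET-like degradation: PSF blur -> Poisson noise -> post-filter.

    The blurred activity is scaled to expected counts (``noise_scale``
    counts per unit activity per voxel), Poisson-sampled, scaled back, and
    smoothed with the post-reconstruction filter.
    """
    if spec.noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    if np.any(activity.data < 0):
        raise ValueError("activity must be non-negative")
    rng = np.random.default_rng(seed)
    sigma_psf = [spec.psf_fwhm_mm / 10.0 * _FWHM_TO_SIGMA / s for s in activity.spacing]
    blurred = ndimage.gaussian_filter(activity.data, sigma_psf)
    counts = rng.poisson(np.clip(blurred, 0.0, None) * spec.noise_scale)
    noisy = counts / spec.noise_scale
    sigma_post = [spec.post_filter_fwhm_mm / 10.0 * _FWHM_TO_SIGMA / s
                  for s in activity.spacing]
    return activity.like(ndimage.gaussian_filter(noisy, sigma_post))


def gen_masks(gt: np.ndarray, seed: int | np.random.Generator | None = None,
              margin: int = 3, dilate_min: float = 1.0, dilate_max: float = 4.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """The two user-defined initial masks around a lesion.

    Returns ``(rectangle, irregular)``: the axis-aligned bounding box of
    ``gt`` expanded by ``margin`` voxels per axis (deterministic), and
    ``gt`` dilated by a seeded, spatially varying radius in
    ``[dilate_min, dilate_max]`` voxels, hole-filled.  Both contain ``gt``.
    """
    gt = np.asarray(gt, dtype=bool)
    if not gt.any():
        raise ValueError("ground-truth mask is empty")
    rng = np.random.default_rng(seed)

    rect = np.zeros_like(gt)
    slices = ndimage.find_objects(gt.astype(np.uint8))[0]
    grown = tuple(
        slice(max(0, s.start - margin), min(n, s.stop + margin))
        for s, n in zip(slices, gt.shape)
    )
    rect[grown] = True

    dist = ndimage.distance_transform_edt(~gt)
    radius_field = _smooth_unit_noise(rng, gt.shape, sigma_vox=3.0)
    lo, hi = radius_field.min(), radius_field.max()
    radius = dilate_min + (dilate_max - dilate_min) * (radius_field - lo) / max(hi - lo, 1e-12)
    irregular = ndimage.binary_fill_holes(dist <= radius) | gt
    return rect, irregular


def cohort_specs(n_cases: int = 13, base_seed: int = 0,
                 volume_range_cm3: tuple[float, float] = (3.5, 55.0),
                 **overrides) -> list[PhantomSpec]:
    """Specs for a cohort of lesions with volumes log-spaced over the range.

    Case seeds derive deterministically from ``base_seed``; extra keyword
    arguments override ``PhantomSpec`` fields for every case.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_cases)
    vols = np.geomspace(*volume_range_cm3, n_cases) if n_cases > 1 \
        else np.array([np.sqrt(volume_range_cm3[0] * volume_range_cm3[1])])
    return [
        PhantomSpec(lesion_volume_cm3=float(v), seed=int(s % (2**31)), **overrides)
        for v, s in zip(vols, seeds)
    ]


def simulate_case(spec: PhantomSpec, motion: bool, case_id: str = "case",
                  noise_seed: int | None = None) -> PhantomCase:
    """Build, optionally move, and degrade one case in a single call."""
    case = build_phantom(spec, case_id=case_id)
    if motion:
        case = apply_motion(case, spec)
    seed = spec.seed + 1 if noise_seed is None else noise_seed
    case.pet_image = degrade(case.activity, spec, seed=seed)
    return case
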