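"""Synthetic pelvic phantoms: CT-like textures, dose-like fields, ROI masks.

The generator emulates the acquisition geometry of a radiotherapy planning
CT (anisotropic ~1 x 1 x 5 mm voxels) and provides a controllable sweep of
in-ROI heterogeneity, from near-homogeneous soft tissue (bladder-like) to
multi-compartment, high-contrast tissue (femoral-bone-like).  A CT phantom
is a piecewise tissue base (``n_tissue_levels`` intensity plateaus laid out
by a smooth random partition) plus a Gaussian-correlated noise texture with
correlation length ``texture_scale`` (mm) and standard deviation
``contrast`` (HU).  A dose phantom is a smooth field at ``dose_peak`` Gy
inside a target, decaying as ``exp(-d / dose_falloff)`` with distance d (mm)
from the target surface — the sharp fall-off adjacent to a target that
pelvic organs at risk experience.

Cohorts add a subject-level intensity offset (the between-subject variance
component the ICC analysis must recover) and give every subject an
independent noise realization.  All randomness fans out from one master
seed through ``numpy`` ``SeedSequence`` spawn keys, so any subject is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .volumes import ImageVolume, ROIMask

#: the five pelvic structures delineated in cervical-cancer planning
ROI_LABELS = ("CTV", "Bladder", "Rectum", "LFemoral", "RFemoral")

# ellipsoid stand-ins: fractional (cx, cy, cz) center and fractional
# (rx, ry, rz) semi-axes, distinct sizes, pairwise disjoint by placement
_ROI_GEOMETRY = {
    "CTV": ((0.50, 0.32, 0.50), (0.150, 0.150, 0.42)),
    "Bladder": ((0.50, 0.62, 0.50), (0.130, 0.120, 0.36)),
    "Rectum": ((0.50, 0.86, 0.50), (0.095, 0.085, 0.44)),
    "LFemoral": ((0.15, 0.62, 0.50), (0.105, 0.105, 0.46)),
    "RFemoral": ((0.85, 0.62, 0.50), (0.105, 0.100, 0.46)),
}


@dataclass
class PhantomConfig:
    """Generation parameters for one synthetic subject.

    Defaults mirror a pelvic planning-CT setting: 0.98 x 0.98 mm pixels,
    5 mm slices, moderate soft-tissue texture, ~50 Gy prescription with a
    ~10 mm penumbra.
    """

    shape: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = (0.98, 0.98, 5.0)
    texture_scale: float = 3.0          # mm, correlation length of CT texture
    contrast: float = 30.0              # HU, SD of the noise texture
    n_tissue_levels: int = 3            # piecewise tissue plateaus
    #: HU span of the plateaus; None derives adjacent-plateau separation as
    #: 3x the noise SD, so compartments stay distinct modes and each added
    #: compartment widens the histogram (entropy grows with n_tissue_levels)
    tissue_range: tuple[float, float] | None = None
    dose_peak: float = 50.0             # Gy inside the target
    dose_falloff: float = 10.0          # mm, exponential fall-off length
    dose_noise: float = 0.0             # Gy, SD of optional smooth dose noise
    #: fraction of voxels receiving a large artifact offset (partial-volume /
    #: streak speckle); part of the noise model, so contrast = 0 disables it.
    #: Speckle stretches the in-ROI range, which is what concentrates the
    #: fixed-bin-number histogram of homogeneous tissue into few bins
    speckle_fraction: float = 0.002
    speckle_hu: tuple[float, float] = (300.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if nx < 16 or ny < 16:
            raise ParameterError(f"in-plane shape must be >= 16, got {self.shape}")
        if nz < 4:
            raise ParameterError(f"need >= 4 slices, got {nz}")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        if self.contrast < 0:
            raise ParameterError("contrast must be >= 0")
        if self.dose_peak <= 0:
            raise ParameterError("dose_peak must be > 0")
        if self.n_tissue_levels < 1:
            raise ParameterError("n_tissue_levels must be >= 1")

    @property
    def effective_tissue_range(self) -> tuple[float, float]:
        """Plateau intensity bounds (HU), centered on soft tissue (~100 HU)."""
        if self.tissue_range is not None:
            return self.tissue_range
        half = 1.5 * self.contrast * (self.n_tissue_levels - 1)
        return (100.0 - half, 100.0 + half)


def _subseed(master: int, *key: int) -> int:
    """Deterministic counter-scheme sub-seed (below 2**31)."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _correlated_noise(shape, spacing, scale_mm, rng) -> np.ndarray:
    """Unit-SD Gaussian-correlated noise with correlation length scale_mm."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(scale_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth / sd


def make_ct_phantom(config: PhantomConfig, *, plateau_seed: int | None = None,
                    noise_seed: int | None = None, offset: float = 0.0) -> ImageVolume:
    """Generate a CT-like volume: tissue plateaus + correlated noise texture.

    ``plateau_seed`` and ``noise_seed`` let a cohort share anatomy (plateau
    layout) while varying texture realizations; both default to
    ``config.seed``.
    """
    if plateau_seed is None:
        plateau_seed = config.seed
    if noise_seed is None:
        noise_seed = config.seed

    lo, hi = config.effective_tissue_range
    if config.n_tissue_levels == 1:
        base = np.full(config.shape, 0.5 * (lo + hi))
    else:
        rng_b = np.random.default_rng(plateau_seed)
        # a smooth random field quantiled into n plateaus: blobby tissue
        # compartments at roughly 4x the noise texture scale
        layout = _correlated_noise(config.shape, config.spacing,
                                   4.0 * config.texture_scale, rng_b)
        qs = np.quantile(layout, np.linspace(0, 1, config.n_tissue_levels + 1)[1:-1])
        labels = np.searchsorted(qs, layout)
        intensities = np.linspace(lo, hi, config.n_tissue_levels)
        base = intensities[labels]

    vox = base.astype(np.float64)
    if config.contrast > 0:
        rng_n = np.random.default_rng(noise_seed)
        vox = vox + config.contrast * _correlated_noise(
            config.shape, config.spacing, config.texture_scale, rng_n)
        if config.speckle_fraction > 0:
            n_speck = max(1, int(round(config.speckle_fraction * vox.size)))
            idx = rng_n.choice(vox.size, size=n_speck, replace=False)
            lo_s, hi_s = config.speckle_hu
            amp = (rng_n.uniform(lo_s, hi_s, size=n_speck)
                   * rng_n.choice((-1.0, 1.0), size=n_speck))
            vox.flat[idx] += amp
    vox = vox + offset
    return ImageVolume(voxels=vox, spacing=config.spacing, modality="CT")


def make_dose_phantom(config: PhantomConfig, target_mask: ROIMask,
                      *, peak: float | None = None,
                      noise_seed: int | None = None) -> ImageVolume:
    """Generate a dose-like field: flat at the peak inside the target,
    exponential fall-off with physical distance outside."""
    if tuple(target_mask.shape) != tuple(config.shape):
        raise GeometryError(
            f"target mask shape {target_mask.shape} != config shape {config.shape}")
    if peak is None:
        peak = config.dose_peak
    inside = target_mask.as_bool()
    # physical distance (mm) from the target surface, 0 inside
    dist = ndimage.distance_transform_edt(~inside, sampling=config.spacing)
    vox = peak * np.exp(-dist / config.dose_falloff)
    if config.dose_noise > 0:
        rng = np.random.default_rng(
            noise_seed if noise_seed is not None else config.seed)
        vox = vox + config.dose_noise * _correlated_noise(
            config.shape, config.spacing, 2.0 * config.texture_scale, rng)
    return ImageVolume(voxels=vox, spacing=config.spacing, modality="DOSE")


def make_roi_masks(config: PhantomConfig, labels=ROI_LABELS) -> list[ROIMask]:
    """Ellipsoidal/tubular stand-ins for the five delineated pelvic ROIs.

    Masks are pairwise disjoint with distinct sizes; each must contain at
    least 200 voxels (raise if the grid is too small to support that).
    """
    nx, ny, nz = config.shape
    xx, yy, zz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    masks = []
    for name in labels:
        (cx, cy, cz), (rx, ry, rz) = _ROI_GEOMETRY[name]
        center = (cx * (nx - 1), cy * (ny - 1), cz * (nz - 1))
        semi = (max(rx * nx, 1.0), max(ry * ny, 1.0), max(rz * nz, 1.0))
        ell = (((xx - center[0]) / semi[0]) ** 2
               + ((yy - center[1]) / semi[1]) ** 2
               + ((zz - center[2]) / semi[2]) ** 2) <= 1.0
        if ell.sum() < 200:
            raise GeometryError(
                f"grid {config.shape} too small: ROI {name} has {int(ell.sum())}"
                " voxels (< 200); enlarge the phantom")
        masks.append(ROIMask(voxels=ell.astype(np.uint8), spacing=config.spacing,
                             roi_name=name))
    # placement guarantees disjointness; assert the contract anyway
    total = sum(m.voxels.astype(int) for m in masks)
    if total.max() > 1:
        raise GeometryError("ROI masks overlap; adjust phantom geometry")
    return masks


@dataclass
class Subject:
    """One synthetic subject: CT, dose and its ROI masks."""

    subject_id: str
    ct: ImageVolume
    dose: ImageVolume
    masks: list[ROIMask]
    seed: int = 0


def make_cohort(n_subjects: int, config: PhantomConfig,
                between_subject_sd: float = 20.0,
                labels=ROI_LABELS) -> list[Subject]:
    """Generate a cohort sharing anatomy but with independent textures.

    Each subject receives (a) an independent noise-texture realization and
    (b) an intensity offset drawn ``Normal(0, between_subject_sd)`` applied
    to the CT and, scaled relative to the tissue span, to the dose peak.
    The offset is the between-subject variance component that the ICC
    analysis is expected to recover.
    """
    if n_subjects < 3:
        raise ParameterError("need n_subjects >= 3 for a repeatability cohort")
    rng = np.random.default_rng(_subseed(config.seed, 0))
    offsets = rng.normal(0.0, between_subject_sd, size=n_subjects)
    masks = make_roi_masks(config, labels=labels)
    target = masks[0]  # first label is the target (CTV under defaults)
    tr = config.effective_tissue_range
    span = tr[1] - tr[0]
    span = span if span > 0 else 300.0
    subjects = []
    for i in range(n_subjects):
        noise_seed = _subseed(config.seed, 1, i)
        ct = make_ct_phantom(config, plateau_seed=config.seed,
                             noise_seed=noise_seed, offset=offsets[i])
        # dose peak varies with the same subject offset, scaled to ~Gy
        peak = config.dose_peak * (1.0 + offsets[i] / span)
        dose = make_dose_phantom(config, target, peak=peak,
                                 noise_seed=_subseed(config.seed, 2, i))
        subjects.append(Subject(subject_id=f"S{i:03d}", ct=ct, dose=dose,
                                masks=masks, seed=noise_seed))
    return subjects
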