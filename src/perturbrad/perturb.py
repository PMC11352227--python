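"""Image perturbation: random rigid transforms and contour randomization.

Two mechanisms are composed, mimicking test-retest positioning differences
and inter-observer delineation variability:

* **Rigid perturbation** — an in-plane translation of 0, 0.4 or 0.8 pixel
  per axis combined with an axial rotation of -20, 0 or +20 degrees about
  the volume center, each drawn uniformly and independently per
  perturbation.  Images are resampled with linear interpolation; masks are
  linearly resampled and re-thresholded at 0.5.  Out-of-field voxels are
  filled with the modality background (-1000 HU for CT, 0 Gy for dose).
  There is no z translation: with 5 mm slices a sub-pixel z shift is
  meaningless.

* **Contour randomization** — the segmentation mask is warped through a
  smoothed random displacement field.  Per voxel, x/y components are drawn
  Uniform(-1, 1) and the z component is identically zero (contours are
  drawn slice by slice in clinical practice); the field is normalized by
  the root-mean-square vector magnitude and then smoothed with a Gaussian
  of width ``sigma_smooth`` voxels (default 5).  At warp time the field is
  rescaled so its RMS displacement equals ``amplitude`` voxels — the knob
  that sets how far randomized contours stray from the original.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import ndimage

from .errors import EmptyROIError, ParameterError
from .phantoms import _subseed
from .volumes import ImageVolume, ROIMask, check_same_geometry

TRANSLATIONS_PX = (0.0, 0.4, 0.8)
ROTATIONS_DEG = (-20.0, 0.0, 20.0)
DEFAULT_SIGMA_SMOOTH = 5.0
DEFAULT_AMPLITUDE = 3.0


@dataclass(frozen=True)
class RigidPerturbation:
    """One sampled rigid move: in-plane pixel shifts and an axial rotation."""

    tx: float = 0.0       # pixels, x
    ty: float = 0.0       # pixels, y
    theta: float = 0.0    # degrees about the z axis through the volume center

    def __post_init__(self) -> None:
        if self.tx not in TRANSLATIONS_PX or self.ty not in TRANSLATIONS_PX:
            raise ParameterError(
                f"translations must come from {TRANSLATIONS_PX}, got "
                f"({self.tx}, {self.ty})")
        if self.theta not in ROTATIONS_DEG:
            raise ParameterError(
                f"rotation must come from {ROTATIONS_DEG}, got {self.theta}")

    @property
    def is_identity(self) -> bool:
        return self.tx == 0.0 and self.ty == 0.0 and self.theta == 0.0


@dataclass
class DisplacementField:
    """A smoothed random displacement field (voxel units), dz == 0."""

    dx: np.ndarray
    dy: np.ndarray
    sigma_smooth: float
    seed: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dx.shape

    @property
    def dz(self) -> np.ndarray:
        """The z component is identically zero (slice-wise contouring)."""
        return np.zeros_like(self.dx)

    @property
    def rms_magnitude(self) -> float:
        return float(np.sqrt(np.mean(self.dx ** 2 + self.dy ** 2)))


@dataclass
class PerturbationSet:
    """The ordered perturbations applied to one subject (CT and dose alike)."""

    subject_id: str
    specs: list[tuple[RigidPerturbation, int]]  # (rigid move, field seed)

    @property
    def k(self) -> int:
        return len(self.specs)


def sample_perturbation_set(subject_seed: int, k: int = 40,
                            subject_id: str = "") -> PerturbationSet:
    """Draw ``k`` independent perturbations for one subject.

    tx, ty are each uniform over {0, 0.4, 0.8} pixels and theta uniform over
    {-20, 0, 20} degrees; every perturbation also receives a fresh
    displacement-field seed.  Deterministic given ``subject_seed``.
    """
    if k < 2:
        raise ParameterError("k must be >= 2 (ICC is undefined for fewer)")
    rng = np.random.default_rng(int(subject_seed))
    specs = []
    for _ in range(k):
        p = RigidPerturbation(
            tx=float(rng.choice(TRANSLATIONS_PX)),
            ty=float(rng.choice(TRANSLATIONS_PX)),
            theta=float(rng.choice(ROTATIONS_DEG)),
        )
        specs.append((p, int(rng.integers(2 ** 31))))
    return PerturbationSet(subject_id=subject_id, specs=specs)


def _rigid_backward_map(shape, p: RigidPerturbation):
    """(matrix, offset) mapping output voxel coords to input coords."""
    theta = np.deg2rad(p.theta)
    c, s = np.cos(theta), np.sin(theta)
    # forward: out = R (in - center) + center + t  =>  in = R^-1 (out - center - t) + center
    rot_inv = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    t = np.array([p.tx, p.ty, 0.0])
    offset = center - rot_inv @ (center + t)
    return rot_inv, offset


def apply_rigid(volume: ImageVolume, mask: ROIMask,
                p: RigidPerturbation) -> tuple[ImageVolume, ROIMask]:
    """Rotate + translate image and mask identically (linear resampling)."""
    check_same_geometry(volume, mask)
    if p.is_identity:
        return (volume.with_voxels(volume.voxels.copy()),
                mask.with_voxels(mask.voxels.copy()))
    matrix, offset = _rigid_backward_map(volume.shape, p)
    img = ndimage.affine_transform(volume.voxels, matrix, offset=offset,
                                   order=1, mode="constant",
                                   cval=volume.background)
    msk = ndimage.affine_transform(mask.voxels.astype(np.float64), matrix,
                                   offset=offset, order=1, mode="constant",
                                   cval=0.0)
    return volume.with_voxels(img), mask.with_voxels((msk >= 0.5).astype(np.uint8))


def apply_rigid_volume(volume: ImageVolume, p: RigidPerturbation) -> ImageVolume:
    """Rigid transform of a volume alone (used for per-modality streaming)."""
    if p.is_identity:
        return volume.with_voxels(volume.voxels.copy())
    matrix, offset = _rigid_backward_map(volume.shape, p)
    img = ndimage.affine_transform(volume.voxels, matrix, offset=offset,
                                   order=1, mode="constant",
                                   cval=volume.background)
    return volume.with_voxels(img)


def apply_rigid_mask(mask: ROIMask, p: RigidPerturbation) -> ROIMask:
    if p.is_identity:
        return mask.with_voxels(mask.voxels.copy())
    matrix, offset = _rigid_backward_map(mask.shape, p)
    msk = ndimage.affine_transform(mask.voxels.astype(np.float64), matrix,
                                   offset=offset, order=1, mode="constant",
                                   cval=0.0)
    return mask.with_voxels((msk >= 0.5).astype(np.uint8))


def make_displacement_field(shape, seed: int,
                            sigma_smooth: float = DEFAULT_SIGMA_SMOOTH
                            ) -> DisplacementField:
    """Draw, normalize and smooth a random in-plane displacement field.

    Pipeline: (1) dx, dy ~ Uniform(-1, 1) i.i.d. per voxel, dz = 0;
    (2) divide both components by the RMS of the vector magnitude over the
    whole field (RMS magnitude is exactly 1 afterwards); (3) smooth each
    component with a 3D Gaussian of width ``sigma_smooth`` voxels
    (``sigma_smooth = 0`` skips smoothing, exposing the normalized field).
    """
    shape = tuple(int(n) for n in shape)
    rng = np.random.default_rng(int(seed))
    dx = rng.uniform(-1.0, 1.0, size=shape)
    dy = rng.uniform(-1.0, 1.0, size=shape)
    rms = np.sqrt(np.mean(dx ** 2 + dy ** 2))
    dx /= rms
    dy /= rms
    if sigma_smooth > 0:
        dx = ndimage.gaussian_filter(dx, sigma=sigma_smooth, mode="reflect")
        dy = ndimage.gaussian_filter(dy, sigma=sigma_smooth, mode="reflect")
    return DisplacementField(dx=dx, dy=dy, sigma_smooth=float(sigma_smooth),
                             seed=int(seed))


def randomize_contour(mask: ROIMask, field: DisplacementField,
                      amplitude: float = DEFAULT_AMPLITUDE) -> ROIMask:
    """Warp a mask through the field scaled to RMS displacement ``amplitude``.

    Backward warping with linear interpolation, re-thresholded at 0.5.  With
    dz == 0 every output slice depends only on its own input slice.
    """
    if mask.shape != field.shape:
        raise ParameterError(
            f"field shape {field.shape} != mask shape {mask.shape}")
    if amplitude == 0:
        return mask.with_voxels(mask.voxels.copy())
    rms = field.rms_magnitude
    if rms == 0:
        raise ParameterError("displacement field is identically zero")
    scale = amplitude / rms
    idx = np.indices(mask.shape, dtype=np.float64)
    coords = np.array([idx[0] + scale * field.dx,
                       idx[1] + scale * field.dy,
                       idx[2]])
    warped = ndimage.map_coordinates(mask.voxels.astype(np.float64), coords,
                                     order=1, mode="constant", cval=0.0)
    out = (warped >= 0.5).astype(np.uint8)
    if out.sum() == 0:
        raise EmptyROIError(
            f"contour randomization emptied ROI {mask.roi_name!r}")
    return mask.with_voxels(out)


def perturb_subject(ct: ImageVolume, dose: ImageVolume, masks,
                    pset: PerturbationSet,
                    amplitude: float = DEFAULT_AMPLITUDE,
                    sigma_smooth: float = DEFAULT_SIGMA_SMOOTH,
                    ) -> Iterator[tuple[int, str, str, ImageVolume, ROIMask]]:
    """Stream perturbed (image, mask) pairs for both modalities.

    For each perturbation: the rigid move is applied identically to CT,
    dose and every mask; one displacement field (per perturbation) then
    randomizes each rigidly-moved contour.  CT and dose for a given
    (perturbation, ROI) share the identical final mask.

    Yields ``(perturbation_index, modality, roi_name, volume, mask)``.
    """
    for m in masks:
        check_same_geometry(ct, m)
        check_same_geometry(dose, m)
    for idx, (p, field_seed) in enumerate(pset.specs):
        ct_p = apply_rigid_volume(ct, p)
        dose_p = apply_rigid_volume(dose, p)
        field = make_displacement_field(ct.shape, field_seed,
                                        sigma_smooth=sigma_smooth)
        for m in masks:
            m_rigid = apply_rigid_mask(m, p)
            m_final = randomize_contour(m_rigid, field, amplitude=amplitude)
            yield idx, "CT", m.roi_name, ct_p, m_final
            yield idx, "DOSE", m.roi_name, dose_p, m_final


def sample_perturbations_for_cohort(master_seed: int, n_subjects: int,
                                    k: int = 40) -> list[PerturbationSet]:
    """Per-subject perturbation sets derived from one master seed."""
    return [
        sample_perturbation_set(_subseed(master_seed, 3, i), k=k,
                                subject_id=f"S{i:03d}")
        for i in range(n_subjects)
    ]


def dice(a: ROIMask | np.ndarray, b: ROIMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    av = a.as_bool() if isinstance(a, ROIMask) else np.asarray(a, dtype=bool)
    bv = b.as_bool() if isinstance(b, ROIMask) else np.asarray(b, dtype=bool)
    denom = av.sum() + bv.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(av, bv).sum() / denom)
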