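"""Volume and mask containers plus medical-image I/O.

Arrays are stored in ``(x, y, z)`` axis order with ``z`` the slice axis,
0-based voxel indices, and physical geometry (mm spacing, mm origin) taken
from the file headers.  CT volumes carry Hounsfield units, dose volumes Gy.

Supported formats: NIfTI (``.nii``/``.nii.gz``), NRRD (``.nrrd``), and DICOM
series directories (CT or RTDOSE pixel data).  Masks are consumed as label
volumes in the same formats and binarized on load; RTSTRUCT contour polygons
are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk

from .errors import EmptyROIError, FormatError, GeometryError

#: tolerance (mm) for comparing spacing/origin between a mask and its image
GEOMETRY_TOL_MM = 1e-3

MODALITIES = ("CT", "DOSE")

#: background fill value used when resampling moves voxels out of the field
BACKGROUND = {"CT": -1000.0, "DOSE": 0.0}


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    voxels
        ``(nx, ny, nz)`` float array; HU for CT, Gy for dose.
    spacing
        Per-axis voxel size ``(sx, sy, sz)`` in mm, strictly positive.
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm.
    modality
        Either ``"CT"`` or ``"DOSE"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.98, 0.98, 5.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise GeometryError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite voxels (NaN/Inf)")
        if self.modality not in MODALITIES:
            raise FormatError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def background(self) -> float:
        return BACKGROUND[self.modality]

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """Same geometry/modality, new voxel data."""
        return replace(self, voxels=voxels)

    def same_geometry(self, other, tol: float = GEOMETRY_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class ROIMask:
    """A binary region-of-interest mask sharing an :class:`ImageVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.98, 0.98, 5.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    roi_name: str = "ROI"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        uniq = np.unique(vox)
        if not np.isin(uniq, (0, 1)).all():
            raise FormatError(f"mask values must be 0/1, found {uniq[:8]}")
        self.voxels = vox.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.sum() == 0:
            raise EmptyROIError(f"ROI {self.roi_name!r} has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def with_voxels(self, voxels: np.ndarray) -> "ROIMask":
        return replace(self, voxels=voxels)

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)


def check_same_geometry(volume: ImageVolume, mask: ROIMask,
                        tol: float = GEOMETRY_TOL_MM) -> None:
    """Raise :class:`GeometryError` unless mask and volume share a grid."""
    if volume.shape != mask.shape:
        raise GeometryError(
            f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    if not np.allclose(volume.spacing, mask.spacing, atol=tol):
        raise GeometryError(
            f"spacing mismatch: {volume.spacing} vs {mask.spacing}")
    if not np.allclose(volume.origin, mask.origin, atol=tol):
        raise GeometryError(
            f"origin mismatch: {volume.origin} vs {mask.origin}")


# ---------------------------------------------------------------------------
# I/O (SimpleITK-backed)
# ---------------------------------------------------------------------------

def _read_sitk(path: str) -> sitk.Image:
    path = str(path)
    if os.path.isdir(path):
        return _read_dicom_series(path)
    try:
        return sitk.ReadImage(path)
    except RuntimeError as exc:  # SimpleITK wraps unreadable files in RuntimeError
        raise FormatError(f"cannot read {path!r}: {exc}") from exc


def _read_dicom_series(directory: str) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(directory)
    if not names:
        raise FormatError(f"no DICOM series found in {directory!r}")
    reader.SetFileNames(names)
    try:
        img = reader.Execute()
    except RuntimeError as exc:
        raise FormatError(f"cannot read DICOM series in {directory!r}: {exc}") from exc
    _check_uniform_slice_spacing(names)
    return img


def _check_uniform_slice_spacing(names, tol: float = GEOMETRY_TOL_MM) -> None:
    import pydicom

    zs = []
    for name in names:
        ds = pydicom.dcmread(name, stop_before_pixels=True)
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            zs.append(float(ipp[2]))
    if len(zs) >= 3:
        gaps = np.diff(sorted(zs))
        if np.ptp(gaps) > tol:
            raise GeometryError(
                f"inconsistent DICOM slice spacing: gaps range "
                f"{gaps.min():.4f}-{gaps.max():.4f} mm")


def load_volume(path, modality: str = "CT") -> ImageVolume:
    """Load a scalar volume from NIfTI, NRRD or a DICOM series directory.

    SimpleITK returns arrays in ``(z, y, x)`` order; they are transposed to
    the package's ``(x, y, z)`` convention.  Non-finite voxels raise
    :class:`FormatError` (the headers alone cannot guarantee finiteness).
    """
    img = _read_sitk(path)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4 and arr.shape[0] == 1:  # some RTDOSE files carry a frame axis
        arr = arr[0]
    if arr.ndim != 3:
        raise FormatError(f"{path!r} is not a 3D volume (ndim={arr.ndim})")
    vox = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    return ImageVolume(
        voxels=vox,
        spacing=tuple(img.GetSpacing())[:3],
        origin=tuple(img.GetOrigin())[:3],
        modality=modality,
    )


def load_mask(path, reference: ImageVolume, roi_name: str | None = None) -> ROIMask:
    """Load a label volume, binarize (any nonzero label -> 1) and check geometry."""
    vol = load_volume(path, modality=reference.modality)
    if vol.shape != reference.shape:
        raise GeometryError(
            f"mask shape {vol.shape} does not match reference {reference.shape}")
    if not np.allclose(vol.spacing, reference.spacing, atol=GEOMETRY_TOL_MM):
        raise GeometryError(
            f"mask spacing {vol.spacing} does not match reference {reference.spacing}")
    if not np.allclose(vol.origin, reference.origin, atol=GEOMETRY_TOL_MM):
        raise GeometryError(
            f"mask origin {vol.origin} does not match reference {reference.origin}")
    binary = (vol.voxels != 0).astype(np.uint8)
    if roi_name is None:
        roi_name = os.path.basename(str(path)).split(".")[0]
    return ROIMask(voxels=binary, spacing=vol.spacing, origin=vol.origin,
                   roi_name=roi_name)


def save_volume(obj, path) -> None:
    """Write an :class:`ImageVolume` or :class:`ROIMask` to NIfTI or NRRD."""
    arr = np.asarray(obj.voxels)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(obj.spacing))
    img.SetOrigin(tuple(obj.origin))
    sitk.WriteImage(img, str(path))
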