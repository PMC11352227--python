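"""Preprocessing filter bank and gray-level discretization.

The bank holds 14 image types per input volume: the original image, five
Laplacian-of-Gaussian responses (sigma = 1..5 mm, computed in physical
units on the anisotropic grid) and the eight sub-bands of a single-level
undecimated separable coif1 wavelet decomposition (low/high pass per axis,
LLL..HHH).  No isotropic resampling and no intensity normalization are
applied.  Filtered images are then discretized over the ROI with a fixed
bin number (default 32), so gray levels run 0..31.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from .errors import EmptyROIError, ParameterError
from .volumes import ImageVolume, ROIMask, check_same_geometry

LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)
WAVELET_NAME = "coif1"
WAVELET_SUBBANDS = tuple("".join(c) for c in product("LH", repeat=3))  # LLL..HHH
DEFAULT_N_BINS = 32


@dataclass(frozen=True)
class FilterSpec:
    """One member of the preprocessing bank."""

    kind: str                     # "original" | "log" | "wavelet"
    sigma_mm: float | None = None  # LoG only
    subband: str | None = None     # wavelet only, e.g. "LLH"

    def __post_init__(self) -> None:
        if self.kind == "log":
            if self.sigma_mm is None or self.sigma_mm <= 0:
                raise ParameterError("LoG filter needs sigma_mm > 0")
        elif self.kind == "wavelet":
            if self.subband not in WAVELET_SUBBANDS:
                raise ParameterError(
                    f"subband must be one of {WAVELET_SUBBANDS}, got {self.subband!r}")
        elif self.kind != "original":
            raise ParameterError(f"unknown filter kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "original":
            return "original"
        if self.kind == "log":
            sig = self.sigma_mm
            stxt = f"{sig:g}"
            return f"log-sigma-{stxt}-mm"
        return f"wavelet-{self.subband}"


def default_filter_bank() -> list[FilterSpec]:
    """The 14 default image types: 1 original + 5 LoG + 8 wavelet."""
    bank = [FilterSpec("original")]
    bank += [FilterSpec("log", sigma_mm=s) for s in LOG_SIGMAS_MM]
    bank += [FilterSpec("wavelet", subband=b) for b in WAVELET_SUBBANDS]
    return bank


def filter_bank_from_names(names) -> list[FilterSpec]:
    """Resolve filter names (as produced by :attr:`FilterSpec.name`)."""
    by_name = {spec.name: spec for spec in default_filter_bank()}
    out = []
    for n in names:
        if n not in by_name:
            raise ParameterError(f"unknown filter name {n!r}; known: {sorted(by_name)}")
        out.append(by_name[n])
    return out


# ---------------------------------------------------------------------------
# Laplacian of Gaussian
# ---------------------------------------------------------------------------

def _gauss_kernel_1d(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian (order 0, unit sum) or its analytic second
    derivative (order 2, corrected to zero sum so constants are
    annihilated exactly even at sub-voxel sigma)."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    k = (x ** 2 / sigma ** 4 - 1.0 / sigma ** 2) * phi
    return k - k.sum() / k.size


def apply_log(volume: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Physical-unit LoG response on the anisotropic grid.

    The response is sum_axis d2/daxis2 of the Gaussian-smoothed image with
    per-axis Gaussian width ``sigma_mm / spacing`` voxels; each second
    derivative is divided by spacing**2 so the Laplacian is per mm^2.
    Separable sampled-kernel filtering with reflect boundary handling; the
    second-derivative kernels are DC-corrected, so a constant volume maps
    to an identically zero response.
    """
    if sigma_mm <= 0:
        raise ParameterError("sigma_mm must be > 0")
    if sigma_mm < min(volume.spacing):
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below the smallest voxel dimension "
            f"{min(volume.spacing)} mm; the response is noise-dominated",
            stacklevel=2)
    sigma_vox = [sigma_mm / s for s in volume.spacing]
    out = np.zeros_like(volume.voxels)
    for deriv_axis in range(3):
        term = volume.voxels
        for ax in range(3):
            k1 = _gauss_kernel_1d(sigma_vox[ax], 2 if ax == deriv_axis else 0)
            term = ndimage.correlate1d(term, k1, axis=ax, mode="reflect")
        out += term / volume.spacing[deriv_axis] ** 2
    return volume.with_voxels(out)


# ---------------------------------------------------------------------------
# Stationary (undecimated) separable coif1 wavelet
# ---------------------------------------------------------------------------

def _wavelet_kernels(name: str = WAVELET_NAME) -> dict[str, np.ndarray]:
    wav = pywt.Wavelet(name)
    return {"L": np.asarray(wav.dec_lo, dtype=np.float64),
            "H": np.asarray(wav.dec_hi, dtype=np.float64)}


def apply_wavelet(volume: ImageVolume, subband: str,
                  wavelet: str = WAVELET_NAME) -> ImageVolume:
    """One sub-band of a single-level undecimated separable decomposition.

    Each axis is filtered with the wavelet's low- or high-pass decomposition
    filter (per the sub-band code, axis order x/y/z), without downsampling,
    with reflect boundary handling, so the output stays on the input grid
    and masks transfer without resampling.
    """
    if subband not in WAVELET_SUBBANDS:
        raise ParameterError(f"invalid sub-band {subband!r}")
    kernels = _wavelet_kernels(wavelet)
    out = volume.voxels
    for ax, code in enumerate(subband):
        out = ndimage.convolve1d(out, kernels[code], axis=ax, mode="reflect")
    return volume.with_voxels(out)


def apply_filter(volume: ImageVolume, spec: FilterSpec) -> ImageVolume:
    if spec.kind == "original":
        return volume.with_voxels(volume.voxels.copy())
    if spec.kind == "log":
        return apply_log(volume, spec.sigma_mm)
    return apply_wavelet(volume, spec.subband)


def apply_filter_bank(volume: ImageVolume, specs=None) -> dict[str, ImageVolume]:
    """Apply the bank; returns ``{filter name: filtered volume}``."""
    if specs is None:
        specs = default_filter_bank()
    return {spec.name: apply_filter(volume, spec) for spec in specs}


# ---------------------------------------------------------------------------
# Fixed-bin-number discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedROI:
    """In-ROI gray levels after fixed-bin-number discretization.

    ``levels`` is a full-grid int array with -1 outside the ROI and values
    0..n_bins-1 inside; ``roi_min``/``roi_max`` are the in-ROI intensity
    bounds the binning used.
    """

    levels: np.ndarray
    mask: np.ndarray            # bool
    n_bins: int
    roi_min: float
    roi_max: float

    @property
    def in_roi(self) -> np.ndarray:
        """1D array of in-ROI gray levels."""
        return self.levels[self.mask]


def discretize(volume: ImageVolume, mask: ROIMask,
               n_bins: int = DEFAULT_N_BINS) -> DiscretizedROI:
    """Fixed-bin-number discretization over the in-ROI intensity range.

    Bin width is ``(roi_max - roi_min) / n_bins``; a voxel maps to
    ``floor((v - roi_min) / width)`` with ``v == roi_max`` assigned the top
    bin.  A constant ROI maps entirely to level 0.
    """
    check_same_geometry(volume, mask)
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    m = mask.as_bool()
    if not m.any():
        raise EmptyROIError("cannot discretize an empty ROI")
    vals = volume.voxels[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.full(volume.shape, -1, dtype=np.int32)
    if hi == lo:
        levels[m] = 0
    else:
        width = (hi - lo) / n_bins
        lev = np.floor((vals - lo) / width).astype(np.int32)
        np.clip(lev, 0, n_bins - 1, out=lev)
        levels[m] = lev
    return DiscretizedROI(levels=levels, mask=m, n_bins=int(n_bins),
                          roi_min=lo, roi_max=hi)
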