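"""First-order statistics and full feature-vector extraction.

The feature vector of one (volume, ROI) pair contains 93 features per image
type — 18 first-order, 24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM and 5 NGTDM —
across the 14-member filter bank, i.e. 1302 values under the default
configuration.  Feature ids follow ``<filter>_<class>_<name>``, e.g.
``log-sigma-3-mm_glcm_Contrast`` or ``wavelet-LLH_firstorder_Entropy``.

Histogram-based first-order features (entropy, uniformity) are computed on
the fixed-bin-number discretized in-ROI levels; all other first-order
statistics act on the raw (filtered) in-ROI intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyROIError, ParameterError
from .filters import (DEFAULT_N_BINS, DiscretizedROI, FilterSpec,
                      apply_filter, default_filter_bank, discretize)
from .texture import CLASS_NAMES, all_texture_features
from .volumes import ImageVolume, ROIMask, check_same_geometry

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

#: per-class feature counts under the default roster
CLASS_COUNTS = {"firstorder": 18, "glcm": 24, "gldm": 14, "glrlm": 16,
                "glszm": 16, "ngtdm": 5}
FEATURES_PER_FILTER = sum(CLASS_COUNTS.values())  # 93


@dataclass
class FeatureVector:
    """Ordered feature-id -> value map with provenance and quality flags."""

    values: dict[str, float]
    subject: str = ""
    modality: str = ""
    roi: str = ""
    perturbation: int = -1
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def first_order(disc: DiscretizedROI, raw_in_mask: np.ndarray,
                voxel_volume_mm3: float = 1.0) -> dict[str, float]:
    """The 18 first-order statistics of one discretized ROI.

    ``entropy`` and ``uniformity`` come from the discretized histogram
    (:math:`-\\sum p \\log_2 p` and :math:`\\sum p^2`); everything else uses
    the raw in-ROI intensities.  Population (biased) moments are used for
    variance, skewness and kurtosis; kurtosis is *not* excess-corrected.
    Skewness/kurtosis on a zero-variance ROI return 0 (degenerate limit).
    """
    v = np.asarray(raw_in_mask, dtype=np.float64)
    if v.size == 0:
        raise EmptyROIError("first-order statistics need at least one voxel")
    counts = np.bincount(disc.in_roi, minlength=disc.n_bins).astype(np.float64)
    p = counts / counts.sum()
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    uniformity = float((p ** 2).sum())

    mean = float(v.mean())
    m2 = float(((v - mean) ** 2).mean())
    if m2 > 0 and v.size >= 2:
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        skewness = m3 / m2 ** 1.5
        kurtosis = m4 / m2 ** 2
    else:
        skewness = 0.0
        kurtosis = 0.0
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    energy = float((v ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume_mm3) * energy,
        "Entropy": entropy,
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(np.median(v)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((v ** 2).mean())),
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "Variance": m2,
        "Uniformity": uniformity,
    }


def extract_filtered(filtered: ImageVolume, mask: ROIMask,
                     n_bins: int = DEFAULT_N_BINS) -> dict[str, float]:
    """93 features (first-order + 5 texture classes) of one filtered image."""
    disc = discretize(filtered, mask, n_bins=n_bins)
    raw = filtered.voxels[mask.as_bool()]
    out = {}
    for name, val in first_order(disc, raw, filtered.voxel_volume_mm3).items():
        out[f"firstorder_{name}"] = val
    out.update(all_texture_features(disc))
    return out


def extract_all(volume: ImageVolume, mask: ROIMask,
                filter_specs: list[FilterSpec] | None = None,
                n_bins: int = DEFAULT_N_BINS,
                subject: str = "", perturbation: int = -1,
                roi: str | None = None) -> FeatureVector:
    """Extract the full feature vector of one (volume, ROI) pair.

    Applies the filter bank (default: all 14 image types), discretizes each
    filtered image over the mask and computes all six feature classes.
    Deterministic; every value is finite.
    """
    check_same_geometry(volume, mask)
    if mask.n_voxels == 0:
        raise EmptyROIError("cannot extract features from an empty ROI")
    if filter_specs is None:
        filter_specs = default_filter_bank()
    values: dict[str, float] = {}
    flags: list[str] = []
    for spec in filter_specs:
        filt = apply_filter(volume, spec)
        feats = extract_filtered(filt, mask, n_bins=n_bins)
        for key, val in feats.items():
            if not np.isfinite(val):  # documented-limit policy: never NaN
                flags.append(f"{spec.name}_{key}")
                val = 0.0
            values[f"{spec.name}_{key}"] = float(val)
    return FeatureVector(values=values, subject=subject,
                         modality=volume.modality,
                         roi=roi if roi is not None else mask.roi_name,
                         perturbation=perturbation, flags=flags)


def expected_feature_count(n_filters: int = 14) -> int:
    """Feature-count contract: 93 per image type."""
    return n_filters * FEATURES_PER_FILTER


def feature_class_of(feature_id: str) -> str:
    """Parse the class (firstorder/glcm/...) out of a feature id."""
    parts = feature_id.split("_")
    if len(parts) < 3:
        raise ParameterError(f"malformed feature id {feature_id!r}")
    return parts[1]


def feature_filter_of(feature_id: str) -> str:
    """Parse the filter name out of a feature id."""
    return feature_id.split("_", 1)[0]
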