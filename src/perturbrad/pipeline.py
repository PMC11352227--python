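"""End-to-end orchestration: phantoms -> perturb -> extract -> ICC -> report.

The inter-stage contract is a long-format CSV (subject, modality, roi,
perturbation, feature_id, value); perturbation index -1 denotes the
unperturbed baseline used for the image-characteristics analysis.  Every
random draw derives from the run's master seed, so re-running a config
reproduces every CSV byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characteristics import correlation_table, image_characteristics
from .errors import ParameterError
from .features import extract_all
from .filters import default_filter_bank, filter_bank_from_names
from .perturb import (DEFAULT_AMPLITUDE, DEFAULT_SIGMA_SMOOTH, perturb_subject,
                      sample_perturbation_set)
from .phantoms import ROI_LABELS, PhantomConfig, make_cohort, _subseed
from .repeatability import (agreement_counts, compare_modalities, icc_table,
                            summarize_by_group)

log = logging.getLogger("perturbrad")

LONG_COLUMNS = ("subject", "modality", "roi", "perturbation", "feature_id", "value")


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    n_subjects: int = 5
    k: int = 5
    seed: int = 0
    amplitude: float = DEFAULT_AMPLITUDE
    sigma_smooth: float = DEFAULT_SIGMA_SMOOTH
    shape: tuple[int, int, int] = (48, 48, 8)
    spacing: tuple[float, float, float] = (0.98, 0.98, 5.0)
    texture_scale: float = 3.0
    contrast: float = 30.0
    n_tissue_levels: int = 3
    between_subject_sd: float = 20.0
    dose_peak: float = 50.0
    dose_falloff: float = 10.0
    dose_noise: float = 0.0
    speckle_fraction: float = 0.002
    rois: tuple[str, ...] = ROI_LABELS
    filters: tuple[str, ...] | None = None  # None -> full 14-filter bank
    n_bins: int = 32
    icc_threshold: float = 0.9
    icc_denominator: str = "k_minus_1"
    output_dir: str = "run"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError("k must be >= 2 (ICC undefined otherwise)")
        if self.n_subjects < 3:
            raise ParameterError("need >= 3 subjects")
        unknown = set(self.rois) - set(ROI_LABELS)
        if unknown:
            raise ParameterError(f"unknown ROI labels {sorted(unknown)}")

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(shape=tuple(self.shape), spacing=tuple(self.spacing),
                             texture_scale=self.texture_scale,
                             contrast=self.contrast,
                             n_tissue_levels=self.n_tissue_levels,
                             dose_peak=self.dose_peak,
                             dose_falloff=self.dose_falloff,
                             dose_noise=self.dose_noise,
                             speckle_fraction=self.speckle_fraction,
                             seed=self.seed)

    def filter_specs(self):
        if self.filters is None:
            return default_filter_bank()
        return filter_bank_from_names(self.filters)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("shape", "spacing", "rois"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("filters") is not None:
            d["filters"] = tuple(d["filters"])
        return cls(**d)


def extract_cohort_features(config: RunConfig) -> pd.DataFrame:
    """Generate the cohort, perturb it, and extract all feature vectors.

    Returns the long-format feature table, including the unperturbed
    baseline rows (perturbation == -1).
    """
    specs = config.filter_specs()
    cohort = make_cohort(config.n_subjects, config.phantom_config(),
                         between_subject_sd=config.between_subject_sd,
                         labels=config.rois)
    rows = []

    def emit(fv):
        for fid, val in fv.values.items():
            rows.append((fv.subject, fv.modality, fv.roi, fv.perturbation,
                         fid, val))

    for i, subj in enumerate(cohort):
        t0 = time.time()
        for mask in subj.masks:
            for volume in (subj.ct, subj.dose):
                emit(extract_all(volume, mask, filter_specs=specs,
                                 n_bins=config.n_bins, subject=subj.subject_id,
                                 perturbation=-1))
        pset = sample_perturbation_set(_subseed(config.seed, 3, i),
                                       k=config.k, subject_id=subj.subject_id)
        for idx, modality, roi, volume, mask in perturb_subject(
                subj.ct, subj.dose, subj.masks, pset,
                amplitude=config.amplitude, sigma_smooth=config.sigma_smooth):
            emit(extract_all(volume, mask, filter_specs=specs,
                             n_bins=config.n_bins, subject=subj.subject_id,
                             perturbation=idx, roi=roi))
        log.info("subject %s extracted in %.1fs", subj.subject_id,
                 time.time() - t0)
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute every stage and write all outputs under ``config.output_dir``.

    Returns a manifest mapping artifact names to file paths.  Stage
    failures abort with the failing stage named; partial outputs remain.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict[str, str] = {}

    def write_csv(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(out, name)
        df.to_csv(path, index=False, float_format="%.12g")
        manifest[name] = path

    stage = "extract"
    try:
        features = extract_cohort_features(config)
        write_csv(features, "features_long.csv")

        stage = "icc"
        perturbed = features[features["perturbation"] >= 0]
        icc = icc_table(perturbed, threshold=config.icc_threshold,
                        denominator=config.icc_denominator)
        for modality in sorted(icc["modality"].unique()):
            for roi in sorted(icc.loc[icc["modality"] == modality, "roi"].unique()):
                sub = icc[(icc["modality"] == modality) & (icc["roi"] == roi)]
                write_csv(sub, f"icc_{modality}_{roi}.csv")
        write_csv(icc, "icc_all.csv")
        for grouping in ("filter", "class"):
            write_csv(summarize_by_group(icc, grouping),
                      f"icc_summary_by_{grouping}.csv")

        stage = "agreement"
        ct_icc = icc[icc["modality"] == "CT"]
        dose_icc = icc[icc["modality"] == "DOSE"]
        if len(ct_icc) and len(dose_icc):
            agreement = compare_modalities(ct_icc, dose_icc)
            write_csv(agreement, "agreement.csv")
            write_csv(agreement_counts(agreement, "filter"),
                      "agreement_counts_by_filter.csv")
            write_csv(agreement_counts(agreement, "feature_class"),
                      "agreement_counts_by_class.csv")

        stage = "characteristics"
        baseline = features[features["perturbation"] == -1]
        records = image_characteristics(baseline, icc)
        write_csv(records, "characteristics.csv")
        write_csv(correlation_table(records), "correlations.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump({"config": json.loads(config.to_json()),
                   "artifacts": sorted(manifest)}, fh, indent=2, sort_keys=True)
    manifest["manifest.json"] = os.path.join(out, "manifest.json")
    return manifest


def report(run_dir: str) -> str:
    """Summarize a completed run as a markdown document.

    Covers mean ICC by image filter and feature class, the CT-vs-dose
    agreement counts, and the characteristic-repeatability correlations.
    Missing artifacts are listed; available stages are still reported.
    """
    expected = ["icc_summary_by_filter.csv", "icc_summary_by_class.csv",
                "agreement_counts_by_filter.csv", "correlations.csv"]
    present = {name: os.path.join(run_dir, name) for name in expected
               if os.path.exists(os.path.join(run_dir, name))}
    missing = [n for n in expected if n not in present]
    if not present:
        raise FileNotFoundError(
            f"no run artifacts found in {run_dir!r}; missing: {missing}")

    lines = ["# Perturbation repeatability report", ""]
    if missing:
        lines += ["Missing artifacts: " + ", ".join(missing), ""]
    for title, name in [("Mean ICC by image filter", "icc_summary_by_filter.csv"),
                        ("Mean ICC by feature class", "icc_summary_by_class.csv")]:
        if name in present:
            df = pd.read_csv(present[name])
            lines += [f"## {title}", "", df.to_markdown(index=False), ""]
    if "agreement_counts_by_filter.csv" in present:
        df = pd.read_csv(present["agreement_counts_by_filter.csv"])
        lines += ["## CT vs dose agreement (by filter)", "",
                  df.to_markdown(index=False), ""]
    if "correlations.csv" in present:
        df = pd.read_csv(present["correlations.csv"])
        lines += ["## Image characteristics vs mean ICC", "",
                  df.to_markdown(index=False), ""]
    text = "\n".join(lines)
    with open(os.path.join(run_dir, "report.md"), "w") as fh:
        fh.write(text)
    return text
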