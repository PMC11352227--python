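"""Per-feature repeatability: one-way random-effects ICC and binarization.

For one feature in one (modality, ROI) stratum, the data form an
``n_subjects x k`` matrix of values across perturbations.  Repeatability is
the one-way, random, absolute, single-measurement intraclass correlation

    ICC = (MSR - MSW) / (MSR + (k - 1) * MSW)

where MSR is the between-subject mean square and MSW the within-subject
(across-perturbation) mean square from a one-way ANOVA.  A feature is
classed high-repeatable when ICC >= 0.9.  ICC is invariant under affine
transforms of the feature and lies in (-1/(k-1), 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .features import feature_class_of, feature_filter_of

DEFAULT_ICC_THRESHOLD = 0.9

AGREEMENT_CATEGORIES = ("both_high", "both_low", "ct_only", "dose_only")


@dataclass
class ICCResult:
    """ICC with its ANOVA components for one feature in one stratum."""

    icc: float
    msr: float
    msw: float
    n: int
    k: float
    high_repeatable: bool
    flag: str = ""


def icc_oneway(matrix: np.ndarray,
               threshold: float = DEFAULT_ICC_THRESHOLD,
               denominator: str = "k_minus_1") -> ICCResult:
    """One-way random-effects absolute-agreement single-measurement ICC.

    Parameters
    ----------
    matrix
        ``(n_subjects, k)`` feature values; NaN entries are excluded
        (rows then contribute their available perturbations, unbalanced
        ANOVA formulas are used and ``k`` reported as the mean count).
    threshold
        Binarization cut for ``high_repeatable`` (>= comparison).
    denominator
        ``"k_minus_1"`` (standard ICC(1,1)) or ``"k_plus_1"``, an audit
        variant using MSR + (k+1)*MSW in the denominator.

    An all-equal matrix (MSR = MSW = 0) is defined as ICC = 1, flagged
    ``"degenerate"``.
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ParameterError("ICC needs a 2D (subjects x perturbations) matrix")
    valid = np.isfinite(x)
    counts = valid.sum(axis=1)
    keep = counts >= 2
    x = x[keep]
    valid = valid[keep]
    counts = counts[keep]
    n = x.shape[0]
    if n < 3:
        raise ParameterError(f"ICC needs >= 3 subjects with >= 2 values, got {n}")
    if x.shape[1] < 2:
        raise ParameterError("ICC needs k >= 2 perturbations")

    row_sums = np.where(valid, x, 0.0).sum(axis=1)
    row_means = row_sums / counts
    grand = row_sums.sum() / counts.sum()

    ss_between = float((counts * (row_means - grand) ** 2).sum())
    resid = np.where(valid, x - row_means[:, None], 0.0)
    ss_within = float((resid ** 2).sum())

    msr = ss_between / (n - 1)
    msw = ss_within / (counts.sum() - n)
    k = float(counts.mean())

    flag = ""
    if msr == 0.0 and msw == 0.0:
        icc = 1.0
        flag = "degenerate"
    else:
        if denominator == "k_minus_1":
            denom = msr + (k - 1.0) * msw
        elif denominator == "k_plus_1":
            denom = msr + (k + 1.0) * msw
        else:
            raise ParameterError(f"unknown denominator rule {denominator!r}")
        icc = (msr - msw) / denom
    return ICCResult(icc=float(icc), msr=float(msr), msw=float(msw), n=int(n),
                     k=k, high_repeatable=bool(icc >= threshold), flag=flag)


def icc_table(features: pd.DataFrame,
              threshold: float = DEFAULT_ICC_THRESHOLD,
              denominator: str = "k_minus_1") -> pd.DataFrame:
    """Per-feature ICC for every (modality, roi) stratum of a long table.

    ``features`` columns: subject, modality, roi, perturbation, feature_id,
    value.  Returns one row per (modality, roi, feature_id) with the ICC,
    ANOVA components, counts and the binarized class.  Strata with fewer
    than 3 subjects or 2 perturbations are skipped with a warning.
    """
    import warnings

    required = {"subject", "modality", "roi", "perturbation", "feature_id", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ParameterError(f"feature table lacks columns {sorted(missing)}")
    rows = []
    for (modality, roi), stratum in features.groupby(["modality", "roi"], sort=True):
        wide_all = stratum.pivot_table(index=["feature_id", "subject"],
                                       columns="perturbation", values="value")
        n_subj = stratum["subject"].nunique()
        n_pert = stratum["perturbation"].nunique()
        if n_subj < 3 or n_pert < 2:
            warnings.warn(
                f"stratum ({modality}, {roi}) has n={n_subj}, k={n_pert}; skipped",
                stacklevel=2)
            continue
        for fid, block in wide_all.groupby(level="feature_id", sort=True):
            res = icc_oneway(block.to_numpy(), threshold=threshold,
                             denominator=denominator)
            rows.append({
                "modality": modality, "roi": roi, "feature_id": fid,
                "icc": res.icc, "msr": res.msr, "msw": res.msw,
                "n": res.n, "k": res.k,
                "high_repeatable": res.high_repeatable, "flag": res.flag,
            })
    return pd.DataFrame(rows)


def summarize_by_group(icc_df: pd.DataFrame, grouping: str = "filter") -> pd.DataFrame:
    """Mean and SD of ICC per image filter or per feature class.

    ``grouping`` is ``"filter"`` (the 14 image types) or ``"class"``
    (the 6 feature classes); summaries are reported per (modality, roi).
    """
    if grouping == "filter":
        key = icc_df["feature_id"].map(feature_filter_of)
    elif grouping == "class":
        key = icc_df["feature_id"].map(feature_class_of)
    else:
        raise ParameterError("grouping must be 'filter' or 'class'")
    df = icc_df.assign(group=key)
    out = (df.groupby(["modality", "roi", "group"], sort=True)["icc"]
             .agg(mean_icc="mean", sd_icc="std", n_features="count")
             .reset_index())
    out["sd_icc"] = out["sd_icc"].fillna(0.0)
    out["grouping"] = grouping
    return out


def compare_modalities(ct_table: pd.DataFrame, dose_table: pd.DataFrame
                       ) -> pd.DataFrame:
    """Binarized CT-vs-dose agreement per feature.

    Each matched (roi, feature_id) is classed ``both_high`` / ``both_low`` /
    ``ct_only`` / ``dose_only`` from the two ``high_repeatable`` booleans.
    Unmatched feature ids raise, listing the offenders.
    """
    ct = ct_table.rename(columns={"icc": "icc_ct",
                                  "high_repeatable": "high_ct"})
    dose = dose_table.rename(columns={"icc": "icc_dose",
                                      "high_repeatable": "high_dose"})
    keys = ["roi", "feature_id"]
    merged = ct[keys + ["icc_ct", "high_ct"]].merge(
        dose[keys + ["icc_dose", "high_dose"]], on=keys, how="outer",
        indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        raise ParameterError(
            "unmatched feature ids between CT and dose tables: "
            f"{sorted(bad['feature_id'].unique())[:10]} ...")
    merged = merged.drop(columns="_merge")

    def categorize(row):
        if row["high_ct"] and row["high_dose"]:
            return "both_high"
        if not row["high_ct"] and not row["high_dose"]:
            return "both_low"
        return "ct_only" if row["high_ct"] else "dose_only"

    merged["category"] = merged.apply(categorize, axis=1)
    merged["filter"] = merged["feature_id"].map(feature_filter_of)
    merged["feature_class"] = merged["feature_id"].map(feature_class_of)
    return merged


def agreement_counts(agreement: pd.DataFrame, by: str = "filter") -> pd.DataFrame:
    """Category counts (and ratios) per filter or feature class and ROI."""
    if by not in ("filter", "feature_class"):
        raise ParameterError("by must be 'filter' or 'feature_class'")
    counts = (agreement.groupby(["roi", by, "category"], sort=True)
              .size().unstack("category", fill_value=0))
    for cat in AGREEMENT_CATEGORIES:
        if cat not in counts.columns:
            counts[cat] = 0
    counts = counts[list(AGREEMENT_CATEGORIES)]
    total = counts.sum(axis=1)
    ratios = counts.div(total, axis=0).add_prefix("ratio_")
    out = pd.concat([counts, ratios], axis=1)
    out["total"] = total
    return out.reset_index()
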