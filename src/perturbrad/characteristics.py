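"""Image characteristics vs. feature repeatability.

For every (image filter, ROI, modality) the cohort-mean entropy, uniformity
and variance of the *unperturbed* preprocessed images — taken directly from
the first-order features — are paired with the mean ICC of all features
from that filter and ROI.  Pearson correlation across the (filter, ROI)
points then quantifies how image complexity, homogeneity and contrast
relate to repeatability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

#: first-order features used as image characteristics
CHARACTERISTICS = ("entropy", "uniformity", "variance")

_FO_KEYS = {"entropy": "Entropy", "uniformity": "Uniformity",
            "variance": "Variance"}


def image_characteristics(baseline_features: pd.DataFrame,
                          icc_df: pd.DataFrame) -> pd.DataFrame:
    """Join mean image characteristics with mean ICC per (filter, roi, modality).

    ``baseline_features`` is a long table (subject, modality, roi,
    feature_id, value) of features extracted from the *unperturbed* images;
    ``icc_df`` is the per-feature ICC table.  Returns one record per
    (modality, roi, filter) with mean_entropy, mean_uniformity,
    mean_variance and mean_icc.
    """
    fo = baseline_features[
        baseline_features["feature_id"].str.contains("_firstorder_")].copy()
    parts = fo["feature_id"].str.split("_", n=2, expand=True)
    fo["filter"] = parts[0]
    fo["name"] = parts[2]
    records = []
    for (modality, roi, filt), grp in fo.groupby(["modality", "roi", "filter"],
                                                 sort=True):
        rec = {"modality": modality, "roi": roi, "filter": filt}
        ok = True
        for char, key in _FO_KEYS.items():
            vals = grp.loc[grp["name"] == key, "value"]
            if vals.empty:
                ok = False
                break
            rec[f"mean_{char}"] = float(vals.mean())
        if not ok:
            continue
        records.append(rec)
    chars = pd.DataFrame(records)
    if chars.empty:
        raise ParameterError(
            "no first-order entropy/uniformity/variance features found")

    icc = icc_df.copy()
    icc["filter"] = icc["feature_id"].str.split("_", n=1).str[0]
    mean_icc = (icc.groupby(["modality", "roi", "filter"], sort=True)["icc"]
                .mean().rename("mean_icc").reset_index())
    out = chars.merge(mean_icc, on=["modality", "roi", "filter"], how="inner")
    dropped = len(chars) - len(out)
    if dropped:
        import warnings
        warnings.warn(f"{dropped} characteristic strata had no matching ICC "
                      "entries and were dropped", stacklevel=2)
    return out


def correlate(records: pd.DataFrame, characteristic: str,
              modality: str | None = None) -> dict:
    """Pearson correlation of one mean characteristic with mean ICC.

    Points are (filter, ROI) combinations, pooled per modality when
    ``modality`` is given.  Returns r, the two-sided p-value and the number
    of points.
    """
    if characteristic not in CHARACTERISTICS:
        raise ParameterError(
            f"characteristic must be one of {CHARACTERISTICS}")
    df = records
    if modality is not None:
        df = df[df["modality"] == modality]
    x = df[f"mean_{characteristic}"].to_numpy(dtype=float)
    y = df["mean_icc"].to_numpy(dtype=float)
    if x.size < 3:
        raise ParameterError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError(
            f"undefined correlation: zero variance in "
            f"{'characteristic' if np.ptp(x) == 0 else 'mean ICC'}")
    r, p = stats.pearsonr(x, y)
    return {"characteristic": characteristic,
            "modality": modality if modality is not None else "all",
            "r": float(r), "p": float(p), "n": int(x.size)}


def correlation_table(records: pd.DataFrame) -> pd.DataFrame:
    """All characteristic x modality Pearson correlations as one table."""
    rows = []
    for modality in sorted(records["modality"].unique()):
        for char in CHARACTERISTICS:
            rows.append(correlate(records, char, modality=modality))
    return pd.DataFrame(rows)
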