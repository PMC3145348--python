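"""Derived features and per-image aggregation.

Per-object tables are pandas DataFrames with a ``(set_id, label)``
MultiIndex and full feature names as columns.  Derived features — per-cell
ratios of two features, and the per-image fraction of cells above a
threshold ("classified" features) — enter the same namespace and are
screened exactly like raw features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ratio_feature", "classify_fraction", "aggregate_per_image"]


def ratio_feature(perobj: pd.DataFrame, numerator: str, denominator: str) -> pd.Series:
    """Per-object numerator/denominator, named
    ``Derived_Ratio_<num>_over_<den>``.

    A zero or missing denominator yields a missing value, never infinity.
    The two features are joined per object through the shared row index, so
    compartments derived from the same nucleus line up by construction.
    """
    for name in (numerator, denominator):
        if name not in perobj.columns:
            raise KeyError(f"unknown feature {name!r}")
    num = perobj[numerator]
    den = perobj[denominator]
    out = num / den.where(den != 0)
    out.name = f"Derived_Ratio_{numerator}_over_{denominator}"
    return out


def classify_fraction(perobj: pd.DataFrame, feature: str, threshold: float) -> pd.Series:
    """Per-image fraction of objects whose value is strictly above threshold.

    The denominator counts objects with a non-missing value; an image with
    none is missing.  Named ``Derived_Classified_<feature>_gt_<threshold>``.
    Strictly ``>``: ties at the threshold fall below.
    """
    if feature not in perobj.columns:
        raise KeyError(f"unknown feature {feature!r}")
    vals = perobj[feature]
    set_ids = perobj.index.get_level_values(0)
    valid = vals.notna().groupby(set_ids).sum()
    above = (vals > threshold).groupby(set_ids).sum()
    out = above / valid.where(valid > 0)
    out.name = f"Derived_Classified_{feature}_gt_{threshold:g}"
    return out


def aggregate_per_image(perobj: pd.DataFrame) -> pd.DataFrame:
    """Per-image mean and median of every per-object feature.

    Returns a DataFrame indexed by set_id with ``Mean_<feature>`` and
    ``Median_<feature>`` columns (over non-missing objects) plus an
    ``ObjectCount`` column.  Images whose objects are all missing for a
    feature get a missing aggregate.
    """
    set_ids = perobj.index.get_level_values(0)
    grouped = perobj.groupby(set_ids)
    mean = grouped.mean().add_prefix("Mean_")
    median = grouped.median().add_prefix("Median_")
    count = grouped.size().rename("ObjectCount").astype(float)
    return pd.concat([mean, median, count], axis=1)
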