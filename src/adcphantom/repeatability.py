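"""Accuracy against nominal references and intra-session repeatability.

Accuracy is the signed percent deviation of the repeat-averaged VOI median ADC
from the nominal value; repeatability is the intra-session coefficient of
variation of the repeat medians plus the extreme percent deviations of later
repeats from the first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "percent_deviation",
    "coefficient_of_variation",
    "max_percent_deviation",
    "aggregate_sessions",
]


def percent_deviation(measured: float, nominal: float) -> float:
    """100 * (measured - nominal) / nominal."""
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    return 100.0 * (measured - nominal) / nominal


def coefficient_of_variation(values) -> float:
    """100 * sd(n-1) / mean over repeat medians, in percent."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two repeats")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * v.std(ddof=1) / mean)


def max_percent_deviation(values) -> tuple[float, float]:
    """Extreme percent deviations of repeats 2..n from repeat 1.

    Returns ``(min_i d_i, max_i d_i)`` with ``d_i = 100 (v_i - v_1) / v_1``;
    both extrema can share a sign when every later repeat moved one way.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two repeats")
    if v[0] <= 0:
        raise ValueError("first repeat must be positive")
    d = 100.0 * (v[1:] - v[0]) / v[0]
    return float(d.min()), float(d.max())


def aggregate_sessions(
    accuracy_repeats: pd.DataFrame,
    repeatability: pd.DataFrame,
    wasserstein: pd.DataFrame,
    percent_diff: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Pool per-session tables across the two sessions.

    * CV and Wasserstein distance: arithmetic mean over sessions per cell.
    * Maximum deviations: signed extrema over both sessions.
    * Accuracy: per-repeat deviations from both sessions concatenated, then
      summarised as median and IQR per vial x level.
    * Feature percent differences: per-vial mean over all (session, repeat)
      values, then mean +/- sd across vials per feature x level pair.

    Raises if fewer than two sessions are present in any input.
    """
    for name, df in (
        ("accuracy_repeats", accuracy_repeats),
        ("repeatability", repeatability),
        ("wasserstein", wasserstein),
        ("percent_diff", percent_diff),
    ):
        if df["session"].nunique() < 2:
            raise ValueError(f"{name}: need both sessions to aggregate")

    acc = (
        accuracy_repeats.groupby(["sequence", "vial", "level"], sort=True)["deviation_percent"]
        .agg(
            median_deviation_percent="median",
            iqr_deviation_percent=lambda s: float(
                np.percentile(s, 75) - np.percentile(s, 25)
            ),
        )
        .reset_index()
    )

    cv = (
        repeatability.groupby(["sequence", "vial", "level"], sort=True)
        .agg(
            cv_percent=("cv_percent", "mean"),
            max_dev_percent_neg=("max_dev_percent_neg", "min"),
            max_dev_percent_pos=("max_dev_percent_pos", "max"),
        )
        .reset_index()
    )

    wd = (
        wasserstein.groupby(["sequence", "vial", "level"], sort=True)["wasserstein"]
        .mean()
        .reset_index()
    )

    per_vial = (
        percent_diff.groupby(["sequence", "feature", "level", "vial"], sort=True)[
            "percent_difference"
        ]
        .mean()
        .reset_index()
    )
    pdiff = (
        per_vial.groupby(["sequence", "feature", "level"], sort=True)["percent_difference"]
        .agg(mean="mean", sd=lambda s: float(np.std(s, ddof=1)) if len(s) >= 2 else np.nan)
        .reset_index()
    )

    return {
        "accuracy_pooled": acc,
        "repeatability_pooled": cv,
        "wasserstein_pooled": wd,
        "percent_diff_pooled": pdiff,
    }
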