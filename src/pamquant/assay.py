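"""Reporter-assay arithmetic.

Four readout calculations used by the reporter assays, plus Tukey-style
notched boxplot summaries:

* ``gfxfp_activity`` — background-subtracted GFP% within the mCherry+
  gate, using crRNA-less/inactive-nuclease wells as negative controls.
* ``gfp_disruption_ratio`` — 1 - sample / control-mean (a fraction).
* ``gfp_disruption_subtractive`` — control-mean - sample (percentage
  points; not clamped by default).
* ``hdr_activity`` — control-subtracted day-14 GFP% rescaled by day-2 GFP%
  to correct for transfection-efficiency variation.

Input tables follow the AssayTable schema: columns ``condition``,
``replicate``, ``gfp_pct``, ``mcherry_pct``, ``role``
(sample/negative_control), ``day``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ASSAY_COLUMNS = ["condition", "replicate", "gfp_pct", "mcherry_pct", "role", "day"]
ROLES = {"sample", "negative_control"}


def validate_assay_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")
    bad_roles = set(table["role"]) - ROLES
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    for col in ("gfp_pct", "mcherry_pct"):
        vals = table[col].to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValueError(f"{col} outside [0, 100]")
    dup = table.duplicated(subset=["condition", "replicate", "role", "day"])
    if dup.any():
        raise ValueError("duplicate replicate index within condition")
    return table


def gfxfp_activity(table: pd.DataFrame, clamp_at_zero: bool = False) -> pd.DataFrame:
    """Per-condition background-subtracted GFP% with replicate mean and sd.

    Background = mean GFP% of the negative-control wells; negative
    activities are kept unless ``clamp_at_zero`` is set.
    """
    validate_assay_table(table)
    controls = table[table["role"] == "negative_control"]
    if controls.empty:
        raise ValueError("no negative controls in assay table")
    background = controls["gfp_pct"].mean()

    samples = table[table["role"] == "sample"].copy()
    samples["activity"] = samples["gfp_pct"] - background
    if clamp_at_zero:
        samples["activity"] = samples["activity"].clip(lower=0.0)
    out = (samples.groupby("condition", sort=True)["activity"]
           .agg(n="size", mean="mean", sd="std")
           .reset_index())
    out["background"] = background
    return out


def gfp_disruption_ratio(sample_gfp: float, control_mean: float) -> float:
    """Disruption as 1 - sample / control-mean (dimensionless fraction)."""
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    return 1.0 - sample_gfp / control_mean


def gfp_disruption_subtractive(sample_gfp: float, control_mean: float) -> float:
    """Disruption as control-mean - sample, in percentage points."""
    return control_mean - sample_gfp


def hdr_activity(day14_table: pd.DataFrame, day2_table: pd.DataFrame,
                 controls: pd.DataFrame) -> pd.DataFrame:
    """Normalized knock-in GFP% per condition.

    HDR = (day-14 sample GFP% - matched day-14 control GFP%)
          * (plate-wide day-2 mean GFP% / condition day-2 GFP%).
    """
    d14 = day14_table.groupby("condition")["gfp_pct"].mean()
    d2 = day2_table.groupby("condition")["gfp_pct"].mean()
    ctrl = controls.groupby("condition")["gfp_pct"].mean()
    if (d2 <= 0).any():
        raise ValueError("day-2 GFP% must be > 0 for normalization")
    plate_mean_d2 = day2_table["gfp_pct"].mean()

    rows = []
    for condition, sample_gfp in d14.items():
        if condition not in ctrl.index:
            raise ValueError(f"no matched control for condition {condition!r}")
        if condition not in d2.index:
            raise ValueError(f"no day-2 row for condition {condition!r}")
        factor = plate_mean_d2 / d2[condition]
        rows.append((condition, (sample_gfp - ctrl[condition]) * factor, factor))
    return pd.DataFrame(rows, columns=["condition", "hdr_pct", "day2_factor"])


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    notch_lo: float
    notch_hi: float


def boxplot_stats(values) -> SummaryStats:
    """Notched-boxplot summary.

    Quartiles are medians of the lower/upper halves, excluding the overall
    median when n is odd; whiskers reach the most extreme data within
    1.5 IQR of the quartiles; notch = median +/- 1.58 IQR / sqrt(n).
    """
    data = np.sort(np.asarray(list(values), dtype=float))
    n = data.size
    if n == 0:
        raise ValueError("boxplot_stats requires at least one value")
    median = float(np.median(data))
    lower = data[: n // 2]
    upper = data[(n + 1) // 2 :]
    q1 = float(np.median(lower)) if lower.size else median
    q3 = float(np.median(upper)) if upper.size else median
    iqr = q3 - q1
    in_lo = data[data >= q1 - 1.5 * iqr]
    in_hi = data[data <= q3 + 1.5 * iqr]
    half_notch = 1.58 * iqr / math.sqrt(n)
    return SummaryStats(
        n=n,
        mean=float(data.mean()),
        sd=float(data.std(ddof=1)) if n > 1 else float("nan"),
        median=median,
        q1=q1,
        q3=q3,
        whisker_lo=float(in_lo.min()),
        whisker_hi=float(in_hi.max()),
        notch_lo=median - half_notch,
        notch_hi=median + half_notch,
    )
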