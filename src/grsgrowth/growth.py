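"""Per-individual longitudinal growth parameters.

Two periods:

* 0-2 years: the slope of the internal z-score on age from a per-child
  ordinary least-squares fit, kept only when the child has at least five
  measurements under age 2, at least one in each of the first and second
  years of life, and the slope standard error is below 0.4 z/year.

* 2-20 years: the change in internal z-score between the measurement nearest
  age 2 (strictly within 1.5-2.5 years) and the first adult measurement
  (strictly over 20 years).

Filters are evaluated independently and every violated filter is reported,
so exclusion reasons are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthFit",
    "infant_growth_slope",
    "infant_growth_table",
    "select_anchor_measurements",
    "childhood_change",
    "childhood_change_table",
]


@dataclass
class GrowthFit:
    """Per-child infant growth slope with filter diagnostics."""

    n: int
    slope: float
    se: float
    included: bool
    reasons: tuple


def infant_growth_slope(ages, z, *, min_records=5, max_se=0.4, max_age=2.0,
                        year1=(0.0, 1.0), year2=(1.0, 2.0)):
    """OLS slope of z on age for one child over the 0-2 year window.

    ``year1`` is the half-open interval [0, 1) and ``year2`` the closed
    interval [1, 2] by default.  Returns a :class:`GrowthFit`; a child
    failing any filter is excluded with all violated filters listed.
    """
    ages = np.asarray(ages, dtype=float)
    z = np.asarray(z, dtype=float)
    keep = (ages >= 0) & (ages <= max_age) & np.isfinite(z) & np.isfinite(ages)
    ages, z = ages[keep], z[keep]
    n = len(ages)
    reasons = []
    if n < min_records:
        reasons.append("too_few_measurements")
    if not ((ages >= year1[0]) & (ages < year1[1])).any():
        reasons.append("no_year1_record")
    if not ((ages >= year2[0]) & (ages <= year2[1])).any():
        reasons.append("no_year2_record")
    slope = np.nan
    se = np.nan
    if n >= 2:
        sxx = float(np.sum((ages - ages.mean()) ** 2))
        if sxx <= 0:
            reasons.append("constant_age")
        else:
            sxy = float(np.sum((ages - ages.mean()) * (z - z.mean())))
            slope = sxy / sxx
            resid = z - z.mean() - slope * (ages - ages.mean())
            if n > 2:
                se = float(np.sqrt(np.sum(resid ** 2) / (n - 2) / sxx))
            else:
                se = np.inf
            if not se < max_se:
                reasons.append("slope_se_too_large")
    return GrowthFit(n=n, slope=slope, se=se,
                     included=not reasons, reasons=tuple(reasons))


def infant_growth_table(df, *, id_col="individual_id", age_col="age",
                        z_col="z", **kwargs):
    """Apply :func:`infant_growth_slope` per child; one row per child."""
    rows = []
    for iid, sub in df.groupby(id_col, sort=True):
        fit = infant_growth_slope(sub[age_col], sub[z_col], **kwargs)
        rows.append({
            id_col: iid, "n": fit.n, "slope": fit.slope, "se": fit.se,
            "included": fit.included, "reasons": ";".join(fit.reasons),
        })
    return pd.DataFrame(rows)


def select_anchor_measurements(df, *, id_col="individual_id", age_col="age",
                               target=2.0, window=(1.5, 2.5), adult_min=20.0):
    """Per individual: the record nearest age 2 (strictly inside the window)
    and the first adult record (age strictly above ``adult_min``).

    Ties in distance to the target take the later measurement.  Returns a
    frame indexed by individual with the positional row indices (into ``df``)
    of each anchor, NaN when absent.
    """
    rows = []
    ages_all = np.asarray(df[age_col], dtype=float)
    indices = df.groupby(id_col, sort=True).indices
    for iid in sorted(indices):
        pos = np.asarray(indices[iid])
        ages = ages_all[pos]
        in_win = (ages > window[0]) & (ages < window[1])
        two_idx = np.nan
        two_age = np.nan
        if in_win.any():
            cand_ages = ages[in_win]
            cand_pos = pos[in_win]
            dist = np.abs(cand_ages - target)
            best = dist == dist.min()
            # tie-break: take the later measurement
            pick = np.argmax(np.where(best, cand_ages, -np.inf))
            two_idx = int(cand_pos[pick])
            two_age = float(cand_ages[pick])
        adult = ages > adult_min
        adult_idx = np.nan
        adult_age = np.nan
        if adult.any():
            pick = int(np.argmin(np.where(adult, ages, np.inf)))
            adult_idx = int(pos[pick])
            adult_age = float(ages[pick])
        rows.append({id_col: iid, "idx_2y": two_idx, "age_2y": two_age,
                     "idx_adult": adult_idx, "age_adult": adult_age})
    return pd.DataFrame(rows).set_index(id_col)


def childhood_change(z_2y, z_adult):
    """2-20 year growth parameter: z(first adult) - z(~2 years)."""
    return np.asarray(z_adult, dtype=float) - np.asarray(z_2y, dtype=float)


def childhood_change_table(anchors, z_2y, z_adult, *, measure="weight"):
    """Per-individual 2-20 y change table with exclusion reasons.

    ``z_2y`` and ``z_adult`` are Series indexed like ``anchors`` (NaN where
    the anchor is missing).
    """
    rows = []
    for iid in anchors.index:
        has2 = np.isfinite(anchors.loc[iid, "idx_2y"]) and np.isfinite(z_2y.loc[iid])
        hasa = (np.isfinite(anchors.loc[iid, "idx_adult"])
                and np.isfinite(z_adult.loc[iid]))
        reasons = []
        if not has2:
            reasons.append("no_2y_anchor")
        if not hasa:
            reasons.append("no_adult_anchor")
        delta = (float(z_adult.loc[iid]) - float(z_2y.loc[iid])
                 if not reasons else np.nan)
        rows.append({"individual_id": iid, "measure": measure, "delta_z": delta,
                     "included": not reasons, "reasons": ";".join(reasons)})
    return pd.DataFrame(rows).set_index("individual_id")
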