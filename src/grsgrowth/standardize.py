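"""Internally calibrated anthropometric z-scores.

Two standardization routes, both strictly internal to the study sample (no
external growth references):

* :func:`group_zscore` — the classic (x - mean)/SD within an age-sex group,
  with an optional log transform first (used for weight and height, which are
  right-skewed; not for birthweight or adult BMI).

* :class:`WfhCalibrationModel` — continuous sex-specific calibration used for
  weight-for-height at all ages: a two-stage regression fitting log(weight)
  to polynomials of age plus terms in (log) height, and the squared stage-1
  residuals to a polynomial of age, giving smooth mean and SD functions so
  that z = (log W - mean(age, height)) / SD(age).  The same machinery with
  the height terms dropped (or with log-height as the response) yields
  continuous weight-for-age and height-for-age calibrations used by the
  infant growth-slope analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "group_zscore",
    "SexCalibration",
    "WfhCalibration",
    "WfhCalibrationModel",
]

_KINDS = ("weight_for_height", "weight_for_age", "height_for_age")


def group_zscore(values, groups, log_first=False):
    """Standardize within groups: z = (x - mean) / sample SD per group.

    Parameters
    ----------
    values : array-like
        Measurements.
    groups : array-like
        Group label per measurement (e.g. sex, or sex x age band).
    log_first : bool
        Log-transform before standardizing (reduces right skew of weight
        and height).

    Every group must contain at least two members with nonzero spread.
    """
    values = pd.Series(np.asarray(values, dtype=float)).reset_index(drop=True)
    groups = pd.Series(np.asarray(groups)).reset_index(drop=True)
    if len(values) != len(groups):
        raise InputError("values and groups have different lengths")
    if log_first:
        if (values <= 0).any():
            raise InputError("log transform requested but values are not all positive")
        values = np.log(values)
    gb = values.groupby(groups)
    counts = gb.transform("count")
    if (counts < 2).any():
        bad = groups[counts < 2].iloc[0]
        raise InputError(f"group {bad!r} has fewer than 2 members")
    mean = gb.transform("mean")
    sd = gb.transform(lambda s: s.std(ddof=1))
    if (sd <= 0).any():
        bad = groups[sd <= 0].iloc[0]
        raise InputError(f"group {bad!r} has zero standard deviation")
    return ((values - mean) / sd).to_numpy()


def _age_design(age_scaled, degree):
    cols = [np.ones_like(age_scaled)]
    for d in range(1, degree + 1):
        cols.append(age_scaled ** d)
    return np.column_stack(cols)


@dataclass
class SexCalibration:
    """Fitted mean/variance functions for one sex."""

    sex: str
    n: int
    age_scale: float
    age_degree: int
    height_degree: int
    var_degree: int
    mean_coef: list
    height_center: float
    var_coef: list
    var_floor: float
    age_min: float
    age_max: float

    def _mean(self, age, height_term=None):
        a = np.asarray(age, dtype=float) / self.age_scale
        X = _age_design(a, self.age_degree)
        if self.height_degree > 0:
            h = np.asarray(height_term, dtype=float) - self.height_center
            for d in range(1, self.height_degree + 1):
                X = np.column_stack([X, h ** d])
        return X @ np.asarray(self.mean_coef)

    def predict_sd(self, age):
        a = np.asarray(age, dtype=float) / self.age_scale
        var = _age_design(a, self.var_degree) @ np.asarray(self.var_coef)
        return np.sqrt(np.maximum(var, self.var_floor))


@dataclass
class WfhCalibration:
    """Sex-specific continuous z-score calibration (fitted results object)."""

    kind: str
    log_height: bool
    calibrations: dict  # sex -> SexCalibration

    def zscore(self, df, age_col="age", weight_col="weight_kg",
               height_col="height_m", sex_col="sex"):
        """Apply the calibration; returns a frame with z and flags.

        Records with a missing response or covariate are skipped (z = NaN,
        ``skipped`` set); ages beyond the fitted range are standardized but
        flagged ``extrapolated``.
        """
        n = len(df)
        z = np.full(n, np.nan)
        extrap = np.zeros(n, dtype=bool)
        skipped = np.zeros(n, dtype=bool)
        age = np.asarray(df[age_col], dtype=float)
        sex = np.asarray(df[sex_col]).astype(str)
        weight = np.asarray(df[weight_col], dtype=float) if weight_col in df else None
        height = np.asarray(df[height_col], dtype=float) if height_col in df else None

        if self.kind == "height_for_age":
            resp = height
            needs_height_cov = False
        else:
            resp = weight
            needs_height_cov = self.kind == "weight_for_height"
        if resp is None:
            raise InputError(f"calibration kind {self.kind} needs its response column")

        for s, cal in self.calibrations.items():
            m = sex == s
            if not m.any():
                continue
            ok = m & np.isfinite(resp) & (resp > 0) & np.isfinite(age)
            if needs_height_cov:
                ok &= np.isfinite(height) & (height > 0)
            skipped |= m & ~ok
            if not ok.any():
                continue
            if needs_height_cov:
                hterm = np.log(height[ok]) if self.log_height else height[ok]
            else:
                hterm = None
            mu = cal._mean(age[ok], hterm)
            sd = cal.predict_sd(age[ok])
            z[ok] = (np.log(resp[ok]) - mu) / sd
            extrap[ok] = (age[ok] < cal.age_min) | (age[ok] > cal.age_max)
        unknown = ~np.isin(sex, list(self.calibrations))
        if unknown.any():
            skipped |= unknown
        return pd.DataFrame({"z": z, "extrapolated": extrap, "skipped": skipped},
                            index=df.index)

    def to_dict(self):
        return {
            "kind": self.kind,
            "log_height": self.log_height,
            "calibrations": {s: asdict(c) for s, c in self.calibrations.items()},
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d):
        return cls(
            kind=d["kind"],
            log_height=d["log_height"],
            calibrations={s: SexCalibration(**c)
                          for s, c in d["calibrations"].items()},
        )

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class WfhCalibrationModel:
    """Two-stage internal calibration model, fitted per sex.

    Stage 1: least squares of the logged response on a polynomial in age (of
    ``age_degree``) plus, for weight-for-height, a polynomial in centred log
    height (``height_degree``).  Stage 2: least squares of the squared
    stage-1 residuals on a polynomial in age (``var_degree``); the fitted
    variance is floored at the ``var_floor_quantile`` quantile of its positive
    fitted values so the implied SD is strictly positive.

    Parameters
    ----------
    data : DataFrame
        Needs age, sex and (depending on ``kind``) weight/height columns.
    kind : {"weight_for_height", "weight_for_age", "height_for_age"}
    """

    def __init__(self, data, kind="weight_for_height", *, age_degree=5,
                 height_degree=2, var_degree=3, log_height=True,
                 var_floor_quantile=0.01, min_obs=30,
                 age_col="age", weight_col="weight_kg", height_col="height_m",
                 sex_col="sex"):
        if kind not in _KINDS:
            raise InputError(f"kind must be one of {_KINDS}")
        if kind != "weight_for_height":
            height_degree = 0
        self.data = data
        self.kind = kind
        self.age_degree = age_degree
        self.height_degree = height_degree
        self.var_degree = var_degree
        self.log_height = log_height
        self.var_floor_quantile = var_floor_quantile
        self.min_obs = min_obs
        self.cols = dict(age=age_col, weight=weight_col, height=height_col,
                         sex=sex_col)

    def _fit_one_sex(self, sub, sex):
        age = np.asarray(sub[self.cols["age"]], dtype=float)
        if self.kind == "height_for_age":
            resp = np.log(np.asarray(sub[self.cols["height"]], dtype=float))
        else:
            resp = np.log(np.asarray(sub[self.cols["weight"]], dtype=float))
        n = len(resp)
        if n < self.min_obs:
            raise InputError(
                f"sex {sex!r}: {n} observations is below the minimum {self.min_obs}"
            )
        age_scale = max(float(np.abs(age).max()), 1.0)
        a = age / age_scale
        X = _age_design(a, self.age_degree)
        height_center = 0.0
        if self.height_degree > 0:
            h = np.asarray(sub[self.cols["height"]], dtype=float)
            hterm = np.log(h) if self.log_height else h
            height_center = float(hterm.mean())
            hc = hterm - height_center
            for d in range(1, self.height_degree + 1):
                X = np.column_stack([X, hc ** d])
        coef, _, rank, _ = np.linalg.lstsq(X, resp, rcond=None)
        if rank < X.shape[1]:
            raise InputError(
                f"sex {sex!r}: rank-deficient mean design "
                f"(rank {rank} < {X.shape[1]}); try a lower polynomial degree"
            )
        resid = resp - X @ coef
        Xv = _age_design(a, self.var_degree)
        vcoef, _, vrank, _ = np.linalg.lstsq(Xv, resid ** 2, rcond=None)
        if vrank < Xv.shape[1]:
            raise InputError(
                f"sex {sex!r}: rank-deficient variance design; "
                "try a lower variance polynomial degree"
            )
        fitted_var = Xv @ vcoef
        pos = fitted_var[fitted_var > 0]
        if pos.size:
            floor = float(np.quantile(pos, self.var_floor_quantile))
        else:  # degenerate (e.g. noise-free data): fall back to a tiny floor
            floor = max(float(np.mean(resid ** 2)), 1e-12)
        floor = max(floor, 1e-12)
        return SexCalibration(
            sex=str(sex), n=n, age_scale=age_scale,
            age_degree=self.age_degree, height_degree=self.height_degree,
            var_degree=self.var_degree, mean_coef=list(map(float, coef)),
            height_center=height_center, var_coef=list(map(float, vcoef)),
            var_floor=floor, age_min=float(age.min()), age_max=float(age.max()),
        )

    def fit(self):
        data = self.data
        need = [self.cols["age"], self.cols["sex"]]
        if self.kind == "height_for_age":
            need.append(self.cols["height"])
        else:
            need.append(self.cols["weight"])
            if self.kind == "weight_for_height":
                need.append(self.cols["height"])
        mask = np.ones(len(data), dtype=bool)
        for c in need:
            col = data[c]
            if col.dtype.kind in "fiu":
                vals = np.asarray(col, dtype=float)
                mask &= np.isfinite(vals)
                if c not in (self.cols["sex"], self.cols["age"]):
                    mask &= vals > 0
            else:
                mask &= col.notna().to_numpy()
        data = data.loc[mask]
        cals = {}
        for sex, sub in data.groupby(self.cols["sex"]):
            cals[str(sex)] = self._fit_one_sex(sub, sex)
        if not cals:
            raise InputError("no usable observations to calibrate")
        return WfhCalibration(kind=self.kind, log_height=self.log_height,
                              calibrations=cals)
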