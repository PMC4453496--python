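"""Association models: clustered GLS, three-level mixed model, gene-by-age interaction.

The scientific core of the package.  A combined risk-allele score is related
to internally standardized anthropometric z-scores, cross-sectionally with a
mother-cluster random-intercept GLS and longitudinally with a three-level
mixed model (family / individual-within-family / observation).  The change of
the genetic effect with age is modelled by interacting the score with an
orthogonal cubic polynomial basis in age, and the fitted interaction is
re-expressed as a raw-age linear slope in z-units per allele per year.

All models are maximum likelihood; Wald intervals use the conventional 1.96
multiplier throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from ._nested import fit_nested_ml
from .exceptions import InputError

__all__ = [
    "AssociationResult",
    "ClusteredGLS",
    "ThreeLevelModel",
    "AgeInteractionModel",
    "OrthoAgeBasis",
    "build_design",
    "score_distribution_summary",
]

Z95 = 1.96


@dataclass
class AssociationResult:
    """One row of the summary association table: an effect of the allele score."""

    outcome: str
    n: int
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    covariates: tuple = ()
    term: str = "score"

    def as_dict(self):
        return {
            "outcome": self.outcome,
            "n": self.n,
            "coefficient": self.coefficient,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
        }


def build_design(df, score="score", village=None, birth_year=None, extra=None):
    """Build a design matrix: intercept, score, village dummies, centred birth year.

    Village enters as a categorical with the alphabetically first level as
    reference; year of birth enters centred and linear.  Returns (X, names).
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append(np.asarray(df[score], dtype=float))
    names.append(score)
    if village is not None:
        levels = sorted(pd.unique(df[village].astype(str)))
        for lev in levels[1:]:
            cols.append((df[village].astype(str) == lev).to_numpy(float))
            names.append(f"{village}[{lev}]")
    if birth_year is not None:
        by = np.asarray(df[birth_year], dtype=float)
        cols.append(by - by.mean())
        names.append(f"{birth_year}_c")
    if extra is not None:
        for c in extra.columns:
            cols.append(np.asarray(extra[c], dtype=float))
            names.append(str(c))
    return np.column_stack(cols), names


class _MLResults:
    """Shared results surface: params / bse / pvalues / conf_int / summary."""

    def __init__(self, model, raw):
        self.model = model
        self._raw = raw
        self.params = pd.Series(raw.params, index=model.exog_names, name="coef")
        self.cov_params_ = pd.DataFrame(
            raw.cov_params, index=model.exog_names, columns=model.exog_names
        )
        self.bse = pd.Series(np.sqrt(np.diag(raw.cov_params)),
                             index=model.exog_names, name="se")
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=model.exog_names
        )
        self.llf = raw.llf
        self.nobs = raw.nobs
        self.converged = raw.converged

    def cov_params(self):
        return self.cov_params_

    def conf_int(self):
        return pd.DataFrame(
            {"low": self.params - Z95 * self.bse,
             "high": self.params + Z95 * self.bse}
        )

    @property
    def variance_components(self):
        vc = {"family": self._raw.sigma2_fam, "observation": self._raw.sigma2_obs}
        if self._raw.sigma2_ind is not None:
            vc["individual"] = self._raw.sigma2_ind
        return vc

    def association_result(self, term="score", outcome="", n=None):
        est = float(self.params[term])
        se = float(self.bse[term])
        return AssociationResult(
            outcome=outcome or term,
            n=int(n if n is not None else self.nobs),
            coefficient=est,
            se=se,
            ci_low=est - Z95 * se,
            ci_high=est + Z95 * se,
            pvalue=float(self.pvalues[term]),
            covariates=tuple(self.model.exog_names),
            term=term,
        )

    def summary(self):
        ci = self.conf_int()
        lines = [
            f"{type(self.model).__name__} (maximum likelihood)",
            f"No. observations: {self.nobs}    log-likelihood: {self.llf:.4f}",
            "Variance components: "
            + ", ".join(f"{k}={v:.6g}" for k, v in self.variance_components.items()),
            "",
            f"{'term':<24}{'coef':>12}{'se':>12}{'z':>9}{'p':>10}"
            f"{'[0.025':>12}{'0.975]':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<24}{self.params[name]:>12.6f}{self.bse[name]:>12.6f}"
                f"{self.zvalues[name]:>9.3f}{self.pvalues[name]:>10.4g}"
                f"{ci.loc[name, 'low']:>12.6f}{ci.loc[name, 'high']:>12.6f}"
            )
        return "\n".join(lines)


class ClusteredGLS:
    """Random-intercept (cluster + residual) regression fitted by ML.

    One row per individual; clusters are sibships defined by the mother.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        self.groups = np.asarray(groups)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]

    @classmethod
    def from_dataframe(cls, df, outcome, score="score", cluster="mother_id",
                       village=None, birth_year=None, extra=None):
        X, names = build_design(df, score=score, village=village,
                                birth_year=birth_year, extra=extra)
        return cls(df[outcome], X, df[cluster], exog_names=names)

    def fit(self, **opts):
        score_like = [n for n in self.exog_names if n != "intercept"]
        for name in score_like[:1]:
            col = self.exog[:, self.exog_names.index(name)]
            if np.ptp(col) == 0:
                raise InputError(f"regressor '{name}' is constant")
        groups = self.groups
        if len(np.unique(groups)) == 1:
            warnings.warn(
                "only one cluster present; falling back to OLS",
                stacklevel=2,
            )
            groups = np.arange(len(self.endog))
        raw = fit_nested_ml(self.endog, self.exog, groups, **opts)
        return ClusteredGLSResults(self, raw)


class ClusteredGLSResults(_MLResults):
    pass


class ThreeLevelModel:
    """Three-level mixed model: family, individual-within-family, observation.

    Random intercepts at the family and individual levels plus an
    observation-level residual, all estimated by maximum likelihood.
    """

    def __init__(self, endog, exog, family, individual, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        self.family = np.asarray(family)
        self.individual = np.asarray(individual)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]

    @classmethod
    def from_dataframe(cls, df, outcome, score="score", family="mother_id",
                       individual="individual_id", village=None,
                       birth_year=None, extra=None):
        X, names = build_design(df, score=score, village=village,
                                birth_year=birth_year, extra=extra)
        return cls(df[outcome], X, df[family], df[individual], exog_names=names)

    def fit(self, **opts):
        raw = fit_nested_ml(self.endog, self.exog, self.family,
                            self.individual, **opts)
        return ThreeLevelResults(self, raw)


class ThreeLevelResults(_MLResults):
    @property
    def n_individuals(self):
        return self._raw.n_ind

    @property
    def n_families(self):
        return self._raw.n_fam


@dataclass
class OrthoAgeBasis:
    """Orthogonal polynomial basis in age, built on the analysis sample.

    ``coef`` maps raw monomials [1, t, t^2, ..., t^degree] to the basis
    columns, i.e. basis_k(t) = sum_j coef[j, k] * t**j.  The columns are
    mutually orthogonal and orthogonal to the constant on the construction
    sample (QR factorization of the Vandermonde matrix with the intercept in
    the first column), so the score main effect stays interpretable as the
    effect at the basis-mean age.
    """

    degree: int
    coef: np.ndarray
    n: int
    age_min: float
    age_max: float

    @classmethod
    def build(cls, ages, degree=3):
        ages = np.asarray(ages, dtype=float).ravel()
        if len(np.unique(ages)) < degree + 1:
            raise InputError(
                f"need at least {degree + 1} distinct ages for a degree-{degree} basis"
            )
        A = np.vander(ages, degree + 1, increasing=True)
        Q, R = np.linalg.qr(A)
        signs = np.sign(np.diag(R))
        signs[signs == 0] = 1.0
        R = signs[:, None] * R
        Rinv = solve_triangular(R, np.eye(degree + 1))
        return cls(degree=degree, coef=Rinv[:, 1:], n=len(ages),
                   age_min=float(ages.min()), age_max=float(ages.max()))

    def transform(self, ages):
        ages = np.asarray(ages, dtype=float).ravel()
        return np.vander(ages, self.degree + 1, increasing=True) @ self.coef

    def raw_coefficients(self, gamma):
        """Map basis-scale coefficients to raw-age monomial coefficients.

        Returns the coefficients on (t, t^2, ..., t^degree); the constant
        shift is absorbed by the score main effect.
        """
        gamma = np.asarray(gamma, dtype=float)
        return self.coef[1:, :] @ gamma

    def linear_weights(self):
        """Weights w with raw linear coefficient = w . gamma."""
        return self.coef[1, :].copy()

    def validate_sample(self, ages, rtol=1e-6):
        """Check the basis was built on exactly this observation-age sample."""
        ages = np.asarray(ages, dtype=float).ravel()
        if len(ages) != self.n:
            raise InputError("orthogonal basis was built on a different sample "
                             "(size mismatch)")
        B = self.transform(ages)
        gram = B.T @ B
        col_sums = B.sum(axis=0)
        scale = max(np.abs(np.diag(gram)).max(), 1.0)
        if (np.abs(col_sums).max() > rtol * np.sqrt(self.n * scale)
                or np.abs(gram - np.diag(np.diag(gram))).max() > rtol * scale):
            raise InputError("orthogonal basis was built on a different sample "
                             "(orthogonality fails on the model ages)")


class AgeInteractionModel(ThreeLevelModel):
    """Three-level model with score x orthogonal-age-polynomial interactions.

    The design contains the intercept, the score, optional covariates, the
    age-basis main effects (hierarchy principle; can be switched off) and the
    score x basis interaction columns.  The fitted linear interaction is
    re-expressed on the raw-age scale in z-units/allele/year.
    """

    def __init__(self, endog, score, age, family, individual, *,
                 exog_extra=None, extra_names=None, degree=3,
                 include_age_main=True, basis=None):
        score = np.asarray(score, dtype=float).ravel()
        age = np.asarray(age, dtype=float).ravel()
        if basis is None:
            basis = OrthoAgeBasis.build(age, degree=degree)
        else:
            basis.validate_sample(age)
        B = basis.transform(age)
        n = len(score)
        cols = [np.ones(n), score]
        names = ["intercept", "score"]
        if exog_extra is not None:
            exog_extra = np.asarray(exog_extra, dtype=float)
            if exog_extra.ndim == 1:
                exog_extra = exog_extra[:, None]
            for j in range(exog_extra.shape[1]):
                cols.append(exog_extra[:, j])
                names.append(extra_names[j] if extra_names else f"cov{j}")
        if include_age_main:
            for k in range(B.shape[1]):
                cols.append(B[:, k])
                names.append(f"age{k + 1}")
        for k in range(B.shape[1]):
            cols.append(score * B[:, k])
            names.append(f"score:age{k + 1}")
        X = np.column_stack(cols)
        super().__init__(endog, X, family, individual, exog_names=names)
        self.basis = basis
        self.age = age

    @classmethod
    def from_dataframe(cls, df, outcome="z", score="score", age="age",
                       family="mother_id", individual="individual_id",
                       village=None, birth_year=None, **kw):
        extra_cols = []
        extra_names = []
        if village is not None:
            levels = sorted(pd.unique(df[village].astype(str)))
            for lev in levels[1:]:
                extra_cols.append((df[village].astype(str) == lev).to_numpy(float))
                extra_names.append(f"{village}[{lev}]")
        if birth_year is not None:
            by = np.asarray(df[birth_year], dtype=float)
            extra_cols.append(by - by.mean())
            extra_names.append(f"{birth_year}_c")
        extra = np.column_stack(extra_cols) if extra_cols else None
        return cls(df[outcome], df[score], df[age], df[family], df[individual],
                   exog_extra=extra, extra_names=extra_names or None, **kw)

    def fit(self, **opts):
        raw = fit_nested_ml(self.endog, self.exog, self.family,
                            self.individual, **opts)
        return AgeInteractionResults(self, raw)


class AgeInteractionResults(ThreeLevelResults):
    @property
    def interaction_names(self):
        return [n for n in self.params.index if n.startswith("score:age")]

    def _interaction_block(self):
        names = self.interaction_names
        gamma = self.params[names].to_numpy()
        cov = self.cov_params_.loc[names, names].to_numpy()
        return names, gamma, cov

    def linear_slope_raw(self, outcome="zWT-HT by age"):
        """Linear age-interaction re-expressed in z-units/allele/year."""
        _, gamma, cov = self._interaction_block()
        w = self.model.basis.linear_weights()
        est = float(w @ gamma)
        se = float(np.sqrt(w @ cov @ w))
        z = est / se if se > 0 else np.inf
        return AssociationResult(
            outcome=outcome,
            n=int(self.nobs),
            coefficient=est,
            se=se,
            ci_low=est - Z95 * se,
            ci_high=est + Z95 * se,
            pvalue=float(2.0 * stats.norm.sf(abs(z))),
            covariates=tuple(self.model.exog_names),
            term="score x age (linear, raw scale)",
        )

    def raw_interaction_coefficients(self):
        """Raw-age-scale interaction polynomial coefficients (t, t^2, t^3)."""
        _, gamma, _ = self._interaction_block()
        return self.model.basis.raw_coefficients(gamma)

    def wald_higher_order(self):
        """Joint Wald test that the quadratic and cubic interactions are zero."""
        names, gamma, cov = self._interaction_block()
        if len(names) < 2:
            raise InputError("no higher-order interaction terms in the model")
        g = gamma[1:]
        c = cov[1:, 1:]
        stat = float(g @ np.linalg.solve(c, g))
        df = len(g)
        return {"statistic": stat, "df": df,
                "pvalue": float(stats.chi2.sf(stat, df))}

    def predict_effect_by_age(self, ages):
        """Per-allele effect on the outcome as a function of age, with 95% CI.

        At the basis-mean age the effect equals the score main effect; the
        pointwise band comes from the fixed-effect covariance (delta method,
        exact here since the effect is linear in the coefficients).
        """
        ages = np.asarray(ages, dtype=float).ravel()
        names = ["score"] + self.interaction_names
        theta = self.params[names].to_numpy()
        cov = self.cov_params_.loc[names, names].to_numpy()
        B = self.model.basis.transform(ages)
        G = np.column_stack([np.ones(len(ages)), B])
        eff = G @ theta
        var = np.einsum("ij,jk,ik->i", G, cov, G)
        se = np.sqrt(np.maximum(var, 0.0))
        return pd.DataFrame({
            "age": ages,
            "effect": eff,
            "ci_low": eff - Z95 * se,
            "ci_high": eff + Z95 * se,
            "extrapolated": (ages < self.model.basis.age_min)
                            | (ages > self.model.basis.age_max),
        })


def score_distribution_summary(scores, z):
    """Histogram of the allele score with unadjusted mean (+/- SE) outcome per bin.

    Scores are binned to the nearest integer (fractional scores arise from
    mean imputation).  Bins with a single observation report a missing SE.
    """
    scores = np.asarray(scores, dtype=float)
    z = np.asarray(z, dtype=float)
    bins = np.round(scores).astype(int)
    out = []
    for b in np.unique(bins):
        zi = z[bins == b]
        n = len(zi)
        out.append({
            "score_bin": int(b),
            "n": n,
            "mean_z": float(zi.mean()),
            "se_z": float(zi.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        })
    return pd.DataFrame(out)
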