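"""Genotype QC and construction of the combined BMI risk-allele score.

Genotypes are held as a pandas DataFrame of BMI-increasing-allele counts
(rows = individuals, columns = SNPs, values 0/1/2 or NaN; fractional after
mean imputation).  The QC chain mirrors standard allele-score practice:
call-rate filtering, exclusion of monomorphic markers, recoding of a
tri-allelic variant to risk-allele counts, a Hardy-Weinberg goodness-of-fit
test on one randomly chosen representative per sibship (so family structure
does not distort the test), mean-allele imputation of sporadic missingness,
exclusion of individuals missing too many markers, and finally the combined
score as the row sum of risk-allele counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

__all__ = [
    "SnpDef",
    "recode_triallelic",
    "encode_genotypes",
    "call_rates",
    "qc_call_rate",
    "monomorphic_snps",
    "allele_frequencies",
    "hwe_chisq",
    "hwe_exact",
    "hwe_test_sibships",
    "impute_missing",
    "compute_score",
    "GenotypeQCResult",
    "run_genotype_qc",
    "read_vcf_genotypes",
]


@dataclass
class SnpDef:
    """Per-SNP metadata: identity, risk allele and QC flags."""

    snp_id: str
    risk_allele: str = "A"
    alleles: tuple = ()
    risk_allele_frequency: float = np.nan
    call_rate: float = np.nan
    monomorphic: bool = False
    triallelic: bool = False
    failed_hwe: bool = False


def recode_triallelic(calls, risk_allele, alleles=None, sep="/"):
    """Recode allele-pair strings to counts of the BMI-increasing allele.

    A tri-allelic variant collapses to bi-allelic: the count of risk alleles,
    whatever the non-risk alleles are.  Missing calls (NaN/empty) stay NaN.

    Parameters
    ----------
    calls : Series of strings like ``"A/C"``.
    risk_allele : the BMI-increasing allele code.
    alleles : optional collection of valid allele codes; any other code
        raises :class:`InputError`.
    """
    calls = pd.Series(calls)
    out = np.full(len(calls), np.nan)
    valid = set(alleles) if alleles is not None else None
    for i, c in enumerate(calls):
        if c is None or (isinstance(c, float) and np.isnan(c)) or c == "":
            continue
        parts = str(c).split(sep)
        if len(parts) != 2:
            raise InputError(f"malformed genotype call {c!r}")
        if valid is not None:
            for a in parts:
                if a not in valid:
                    raise InputError(f"unknown allele code {a!r} in call {c!r}")
        out[i] = sum(a == risk_allele for a in parts)
    return pd.Series(out, index=calls.index)


def encode_genotypes(raw, panel=None):
    """Coerce a raw genotype table to numeric risk-allele counts.

    Numeric columns pass through; string (allele-pair) columns are recoded
    with :func:`recode_triallelic` using the ``risk_allele`` (and optional
    comma-separated ``alleles``) from the matching ``panel`` row.
    """
    out = {}
    for snp in raw.columns:
        col = raw[snp]
        if col.dtype.kind in "fiu":
            out[snp] = col.astype(float)
            continue
        numeric = pd.to_numeric(col, errors="coerce")
        strings = col[numeric.isna() & col.notna()]
        if len(strings) == 0:
            out[snp] = numeric.astype(float)
            continue
        if panel is None or snp not in set(panel["snp_id"]):
            raise InputError(
                f"SNP {snp!r} has allele-pair calls but no panel entry"
            )
        row = panel.loc[panel["snp_id"] == snp].iloc[0]
        alleles = None
        if "alleles" in panel.columns and isinstance(row["alleles"], str):
            alleles = tuple(row["alleles"].split(","))
        out[snp] = recode_triallelic(col, row["risk_allele"], alleles=alleles)
    df = pd.DataFrame(out, index=raw.index)
    bad = df.stack(future_stack=True).dropna()
    if ((bad < 0) | (bad > 2)).any():
        raise InputError("genotype counts outside [0, 2]")
    return df


def call_rates(gt):
    """Per-SNP proportion of non-missing calls."""
    if gt.shape[0] == 0 or gt.shape[1] == 0:
        raise InputError("empty genotype matrix")
    return gt.notna().mean(axis=0)


def qc_call_rate(gt, threshold=0.95):
    """Pass/fail per SNP: call rate at or above the threshold passes."""
    if not 0 < threshold <= 1:
        raise InputError("call-rate threshold must be in (0, 1]")
    return call_rates(gt) >= threshold


def allele_frequencies(gt):
    """Risk-allele frequency per SNP from non-missing calls (mean count / 2)."""
    return gt.mean(axis=0, skipna=True) / 2.0


def monomorphic_snps(gt):
    """SNPs with a single observed allele among non-missing calls.

    All-zero (only the non-risk allele seen) or all-two (only the risk
    allele); heterozygote-containing columns are polymorphic by definition.
    """
    freq = allele_frequencies(gt)
    return list(freq.index[(freq == 0.0) | (freq == 1.0)])


def hwe_chisq(n0, n1, n2):
    """1-df chi-square goodness of fit against Hardy-Weinberg proportions.

    Counts are genotype classes with 0, 1 and 2 risk alleles; the expected
    counts use the sample allele frequency; no continuity correction.
    """
    n = n0 + n1 + n2
    if n == 0:
        return np.nan, np.nan
    p = (n1 + 2 * n2) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    obs = np.array([n0, n1, n2], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return stat, float(stats.chi2.sf(stat, 1))


def hwe_exact(n0, n1, n2):
    """Exact Hardy-Weinberg test (conditional on allele counts).

    Enumerates the heterozygote distribution given the rare-allele count; the
    p-value sums probabilities of outcomes no more probable than the observed
    one.  Preferable for low-MAF SNPs where the chi-square is unreliable.
    """
    n = n0 + n1 + n2
    n_rare = min(n1 + 2 * n2, n1 + 2 * n0)
    if n == 0:
        return np.nan
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    def log_prob(h):
        homr = (n_rare - h) // 2
        homc = n - h - homr
        return (gammaln(n + 1) - gammaln(h + 1) - gammaln(homr + 1)
                - gammaln(homc + 1) + h * np.log(2)
                + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1)
                - gammaln(2 * n + 1))
    for i, h in enumerate(hets):
        logp[i] = log_prob(h)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n1][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_test_sibships(gt, mothers, seed, *, min_samples=30, method="chisq",
                      alpha=0.05):
    """Per-SNP HWE test on one randomly selected representative per sibship.

    Sibships are defined by a shared mother; individuals without a mother id
    are their own (singleton) sibships.  The Bonferroni failure threshold is
    ``alpha / n_snps_tested``.

    Parameters
    ----------
    gt : DataFrame of risk-allele counts (pre-imputation).
    mothers : Series of mother ids aligned to ``gt``'s index.
    seed : int seed for the representative sampling (logged in the output).
    """
    mothers = pd.Series(mothers).reindex(gt.index)
    sib = mothers.astype(object).where(mothers.notna(), other=None)
    labels = np.where(
        sib.isna() | (sib == ""), "self:" + gt.index.astype(str),
        "mother:" + sib.astype(str),
    )
    rng = np.random.default_rng(seed)
    reps = []
    groups = pd.Series(np.arange(len(gt)), index=gt.index).groupby(labels)
    for _, pos in groups:
        reps.append(pos.iloc[rng.integers(len(pos))])
    sample = gt.iloc[sorted(reps)]

    if len(sample) < min_samples:
        warnings.warn(
            f"only {len(sample)} sibship representatives (< {min_samples}); "
            "HWE test skipped", stacklevel=2,
        )
        return pd.DataFrame(
            {"snp_id": gt.columns, "n": len(sample), "freq": np.nan,
             "statistic": np.nan, "pvalue": np.nan, "failed_hwe": False,
             "skipped": True, "seed": seed}
        ).set_index("snp_id")

    rows = []
    for snp in gt.columns:
        col = sample[snp].dropna()
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        if n0 + n1 + n2 != len(col):  # fractional values: not raw calls
            raise InputError(f"SNP {snp!r} has non-integer genotypes; "
                             "run the HWE test before imputation")
        if method == "chisq":
            stat, p = hwe_chisq(n0, n1, n2)
        elif method == "exact":
            stat, p = np.nan, hwe_exact(n0, n1, n2)
        else:
            raise InputError("method must be 'chisq' or 'exact'")
        freq = (n1 + 2 * n2) / (2 * len(col)) if len(col) else np.nan
        rows.append({"snp_id": snp, "n": len(col), "freq": freq,
                     "statistic": stat, "pvalue": p})
    out = pd.DataFrame(rows).set_index("snp_id")
    threshold = alpha / len(out)
    out["failed_hwe"] = out["pvalue"] < threshold
    out["skipped"] = False
    out["seed"] = seed
    out.attrs["bonferroni_threshold"] = threshold
    return out


def impute_missing(gt, max_missing=5):
    """Mean-allele imputation with an individual-level exclusion rule.

    Individuals missing more than ``max_missing`` SNPs (default: 6 or more
    missing of a 28-SNP panel) are excluded outright; for the rest each
    missing genotype is replaced by twice the risk-allele frequency computed
    from the retained sample's non-missing calls.

    Returns ``(imputed, excluded_ids, n_imputed)``.
    """
    n_missing = gt.isna().sum(axis=1)
    excluded = n_missing > max_missing
    kept = gt.loc[~excluded]
    if kept.shape[0] == 0:
        raise InputError("all individuals excluded by the missingness rule")
    zero_calls = kept.notna().sum(axis=0) == 0
    if zero_calls.any():
        bad = list(kept.columns[zero_calls])
        raise InputError(f"cannot impute SNPs with no non-missing calls: {bad}")
    fill = 2.0 * allele_frequencies(kept)
    imputed = kept.fillna(fill)
    n_imputed = kept.isna().sum(axis=1)
    return imputed, gt.index[excluded], n_imputed


def compute_score(gt):
    """Combined score: cumulative risk-allele count across the scored SNPs.

    Requires a complete (post-imputation) matrix; any remaining missing value
    is a contract violation and raises.
    """
    if gt.isna().any().any():
        raise InputError("genotype matrix still contains missing values; "
                         "impute before scoring")
    score = gt.sum(axis=1)
    return pd.DataFrame({"score": score})


@dataclass
class GenotypeQCResult:
    """Outputs of the full QC + scoring chain."""

    scores: pd.DataFrame
    snp_report: pd.DataFrame
    excluded_individuals: list
    scored_snps: list
    hwe_seed: int


def run_genotype_qc(raw, panel=None, mothers=None, *, call_rate_threshold=0.95,
                    max_missing=5, hwe_seed=0, drop_hwe_failures=True,
                    hwe_method="chisq", hwe_alpha=0.05):
    """Full genotype QC chain: encode, call-rate, monomorphic, HWE, impute, score."""
    gt = encode_genotypes(raw, panel)
    cr = call_rates(gt)
    pass_cr = qc_call_rate(gt, call_rate_threshold)
    mono = set(monomorphic_snps(gt))
    report = pd.DataFrame({
        "call_rate": cr,
        "pass_call_rate": pass_cr,
        "monomorphic": [c in mono for c in gt.columns],
        "risk_allele_frequency": allele_frequencies(gt),
    })
    usable = [c for c in gt.columns if pass_cr[c] and c not in mono]
    gtu = gt[usable]
    if mothers is not None:
        hwe = hwe_test_sibships(gtu, mothers, hwe_seed, method=hwe_method,
                                alpha=hwe_alpha)
        report = report.join(hwe[["pvalue", "failed_hwe"]]
                             .rename(columns={"pvalue": "hwe_pvalue"}))
        if drop_hwe_failures:
            usable = [c for c in usable if not hwe.loc[c, "failed_hwe"]]
            gtu = gt[usable]
    imputed, excluded, n_imputed = impute_missing(gtu, max_missing=max_missing)
    scores = compute_score(imputed)
    scores["n_imputed"] = n_imputed
    report["scored"] = [c in set(usable) for c in report.index]
    return GenotypeQCResult(
        scores=scores,
        snp_report=report,
        excluded_individuals=list(excluded),
        scored_snps=usable,
        hwe_seed=hwe_seed,
    )


def read_vcf_genotypes(path, panel):
    """Read a VCF into risk-allele counts using a SnpDef panel (needs cyvcf2).

    The panel frame needs columns snp_id and risk_allele; sites are matched
    by ID.  Only the GT field is used.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = dict(zip(panel["snp_id"], panel["risk_allele"]))
    data = {}
    for var in vcf:
        if var.ID not in wanted:
            continue
        risk = wanted[var.ID]
        alleles = [var.REF] + list(var.ALT)
        counts = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            a = [x for x in g[:2]]
            if any(x < 0 for x in a):
                continue
            counts[i] = sum(alleles[x] == risk for x in a)
        data[var.ID] = counts
    return pd.DataFrame(data, index=samples)
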