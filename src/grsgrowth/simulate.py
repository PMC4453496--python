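"""Synthetic cohort generator.

Emulates the structure the analysis assumes: mother-defined sibships in a
handful of villages, founder genotypes in Hardy-Weinberg proportions with
Mendelian transmission to offspring, a dense infant / sparse later
measurement schedule, and a weight-for-height signal in which the per-allele
effect of the combined risk score grows linearly with age on the z scale:

    log W(t) = m_sex(t) + c * (log H - log Hbar_sex(t)) + s_ref * eta
    eta      = (score - E[score]) * (delta0 + delta1 * t)
               + u_family + v_individual + e_observation

with u, v, e drawn from the three configured variance components (z-units
squared) and ``s_ref`` a constant reference SD converting z-units to
log-weight units.  ``eta`` is exactly the outcome model of the association
module, so parameter-recovery tests are well-posed; it is returned alongside
the raw measurements as ``z_true``.

The mean curves are piecewise-smooth double-exponential approaches to adult
size (rapid infant gain, slower childhood growth, plateau in adulthood) with
realistic anthropometry: birthweight ~2.94 kg, adult weight ~58.7/54.6 kg and
adult height ~1.70/1.59 m for males/females.  No seasonality, secular trend,
mortality or informative dropout is simulated; genotype missingness is MCAR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "SnpSpec",
    "OffspringSpec",
    "ScheduleSpec",
    "SimulationConfig",
    "TruthRecord",
    "Cohort",
    "default_snp_panel",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_measurements",
    "simulate_cohort",
    "write_cohort",
    "write_vcf",
]

_TRIALLELIC_CODES = ("A", "C", "G")


@dataclass(frozen=True)
class SnpSpec:
    """One SNP of the simulated panel."""

    snp_id: str
    freq: float  # risk-allele frequency among founders
    triallelic: bool = False
    monomorphic: bool = False

    def __post_init__(self):
        if not 0.0 <= self.freq <= 1.0:
            raise ConfigurationError(
                f"{self.snp_id}: risk-allele frequency {self.freq} outside [0, 1]"
            )
        if self.monomorphic and self.freq not in (0.0, 1.0):
            raise ConfigurationError(
                f"{self.snp_id}: monomorphic SNPs need frequency 0 or 1"
            )


@dataclass(frozen=True)
class OffspringSpec:
    """Truncated-Poisson sibship size: Poisson(mean) conditioned on [min, max]."""

    mean: float = 4.0
    min: int = 1
    max: int = 8

    def __post_init__(self):
        if not (self.min >= 1 and self.max >= self.min and self.mean > 0):
            raise ConfigurationError("invalid offspring distribution spec")

    def pmf(self):
        """Support and probabilities of the truncated distribution."""
        from scipy.stats import poisson

        k = np.arange(self.min, self.max + 1)
        p = poisson.pmf(k, self.mean)
        return k, p / p.sum()


@dataclass(frozen=True)
class ScheduleSpec:
    """Measurement ages: birth, dense to 2 y, sparse to an adult cap."""

    dense_n: int = 12
    dense_max_age: float = 2.0
    sparse_interval: float = 3.0
    max_age: float = 50.0
    min_followup: float = 0.5

    def __post_init__(self):
        if not (self.dense_n >= 1 and 0 < self.dense_max_age < self.max_age
                and self.sparse_interval > 0
                and 0 < self.min_followup < self.max_age):
            raise ConfigurationError("invalid measurement schedule spec")


def default_snp_panel():
    """30-SNP panel: 27 biallelic + 1 tri-allelic scored markers spanning a
    range of risk-allele frequencies, plus 2 monomorphic distractors."""
    freqs = np.linspace(0.10, 0.90, 28)
    panel = []
    for i, f in enumerate(freqs, start=1):
        panel.append(SnpSpec(snp_id=f"snp{i:02d}", freq=round(float(f), 4),
                             triallelic=(i == 6)))
    panel.append(SnpSpec(snp_id="snp29", freq=0.0, monomorphic=True))
    panel.append(SnpSpec(snp_id="snp30", freq=1.0, monomorphic=True))
    return tuple(panel)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the analysis's default problem size (~400 sibships,
    ~1,600 offspring, ~20 measurements each) with a per-allele
    weight-for-height effect growing linearly with age at
    ``effect_slope`` z-units/allele/year and three variance components
    (family, individual, observation) in z-units squared summing to 1.
    The variance-component magnitudes are free parameters of the generator:
    no empirical decomposition is available to pin them down.
    """

    n_families: int = 400
    offspring: OffspringSpec = field(default_factory=OffspringSpec)
    snp_panel: tuple = field(default_factory=default_snp_panel)
    missing_rate: float = 0.015
    effect_intercept: float = 0.0  # delta0, z-units/allele at birth
    effect_slope: float = 0.008    # delta1, z-units/allele/year
    var_family: float = 0.2
    var_individual: float = 0.3
    var_observation: float = 0.5
    n_villages: int = 3
    birth_year_range: tuple = (1950, 2005)
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    twin_rate: float = 0.004
    sd_log_weight: float = 0.12    # reference SD: log-weight units per z-unit
    height_coupling: float = 2.0   # d log W / d log H at fixed age
    height_individual_sd: float = 0.04
    height_noise_sd: float = 0.01
    prop_majority_ethnicity: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        for name in ("var_family", "var_individual", "var_observation"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.twin_rate < 1.0:
            raise ConfigurationError("twin_rate must be in [0, 1)")
        if self.sd_log_weight <= 0:
            raise ConfigurationError("sd_log_weight must be positive")
        if self.n_villages < 1:
            raise ConfigurationError("n_villages must be >= 1")
        y0, y1 = self.birth_year_range
        if not y1 >= y0:
            raise ConfigurationError("birth_year_range must be increasing")
        a = np.linspace(0, self.schedule.max_age, 101)
        traj = self.effect_intercept + self.effect_slope * a
        if not np.isfinite(traj).all():
            raise ConfigurationError("effect trajectory not finite over the age range")

    @property
    def scored_snps(self):
        return [s for s in self.snp_panel if not s.monomorphic]

    @property
    def expected_score(self):
        return 2.0 * sum(s.freq for s in self.scored_snps)


@dataclass
class TruthRecord:
    """Ground truth stored with every simulated cohort for recovery scoring."""

    effect_intercept: float
    effect_slope: float
    var_family: float
    var_individual: float
    var_observation: float
    expected_score: float
    scored_snps: list
    realized_allele_freqs: dict
    true_score: pd.Series

    def to_json(self, path):
        d = {
            "effect_intercept": self.effect_intercept,
            "effect_slope": self.effect_slope,
            "var_family": self.var_family,
            "var_individual": self.var_individual,
            "var_observation": self.var_observation,
            "expected_score": self.expected_score,
            "scored_snps": list(self.scored_snps),
            "realized_allele_freqs": {k: float(v) for k, v
                                      in self.realized_allele_freqs.items()},
            "true_score": {str(k): float(v) for k, v in self.true_score.items()},
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class Cohort:
    """A simulated cohort: pedigree + genotypes + longitudinal anthropometry."""

    pedigree: pd.DataFrame
    genotypes: pd.DataFrame
    anthro: pd.DataFrame
    truth: TruthRecord
    config: SimulationConfig


# --------------------------------------------------------------------------
# pedigree

def simulate_pedigree(config, rng=None):
    """Mother-defined sibships with villages, birth dates, sexes and twins.

    One implicit father per sibship (fathers are not emitted as rows); every
    child carries a mother id.  A fraction ``twin_rate`` of births are twin
    pairs sharing an exact birth date.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    k, p = config.offspring.pmf()
    sizes = rng.choice(k, size=config.n_families, p=p)
    villages = rng.integers(config.n_villages, size=config.n_families)
    y0, y1 = config.birth_year_range
    rows = []
    counter = 0
    for fam in range(config.n_families):
        mother = f"M{fam + 1:05d}"
        vil = f"village_{villages[fam] + 1}"
        for _ in range(int(sizes[fam])):
            birth = float(rng.uniform(y0, y1))
            is_twin = rng.random() < config.twin_rate
            n_births = 2 if is_twin else 1
            twin_id = f"T{fam + 1:05d}.{counter}" if is_twin else ""
            for _ in range(n_births):
                counter += 1
                rows.append({
                    "individual_id": f"I{counter:06d}",
                    "mother_id": mother,
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "birth_date": birth,
                    "village": vil,
                    "twin_id": twin_id,
                    "ethnicity": ("majority"
                                  if rng.random() < config.prop_majority_ethnicity
                                  else "other"),
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# genotypes

def _transmit_biallelic(n_fam, children_fam, freq, rng):
    """Founder haplotypes at HWE + Mendelian transmission; returns counts."""
    mother = rng.random((n_fam, 2)) < freq
    father = rng.random((n_fam, 2)) < freq
    n_children = len(children_fam)
    from_mother = mother[children_fam, rng.integers(2, size=n_children)]
    from_father = father[children_fam, rng.integers(2, size=n_children)]
    return (from_mother.astype(int) + from_father.astype(int))


def _transmit_triallelic(n_fam, children_fam, freq, rng):
    """As above but with three allele codes; code 0 is the risk allele."""
    probs = np.array([freq, (1 - freq) / 2.0, (1 - freq) / 2.0])
    mother = rng.choice(3, size=(n_fam, 2), p=probs)
    father = rng.choice(3, size=(n_fam, 2), p=probs)
    n_children = len(children_fam)
    a1 = mother[children_fam, rng.integers(2, size=n_children)]
    a2 = father[children_fam, rng.integers(2, size=n_children)]
    return a1, a2


def simulate_genotypes(pedigree, config, rng=None):
    """Genotype matrix with Mendelian family structure and MCAR missingness.

    Returns ``(raw, true_counts)``: ``raw`` is the write-ready table (integer
    risk-allele counts; allele-pair strings like ``"A/C"`` for the
    tri-allelic SNP; missing as NaN/empty), ``true_counts`` the complete
    risk-allele count matrix before missingness was applied.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    fams = pd.unique(pedigree["mother_id"])
    fam_index = pd.Series(np.arange(len(fams)), index=fams)
    children_fam = fam_index[pedigree["mother_id"]].to_numpy()
    n_fam = len(fams)
    n = len(pedigree)
    raw = {}
    true = {}
    for spec in config.snp_panel:
        if spec.triallelic:
            a1, a2 = _transmit_triallelic(n_fam, children_fam, spec.freq, rng)
            counts = (a1 == 0).astype(int) + (a2 == 0).astype(int)
            lo = np.minimum(a1, a2)
            hi = np.maximum(a1, a2)
            codes = np.array(_TRIALLELIC_CODES)
            calls = pd.Series(
                [f"{codes[i]}/{codes[j]}" for i, j in zip(lo, hi)],
                index=pedigree["individual_id"], dtype=object,
            )
            miss = rng.random(n) < config.missing_rate
            calls[miss] = np.nan
            raw[spec.snp_id] = calls
        else:
            counts = _transmit_biallelic(n_fam, children_fam, spec.freq, rng)
            vals = counts.astype(float)
            miss = rng.random(n) < config.missing_rate
            vals[miss] = np.nan
            raw[spec.snp_id] = pd.Series(vals, index=pedigree["individual_id"])
        true[spec.snp_id] = pd.Series(counts.astype(float),
                                      index=pedigree["individual_id"])
    raw = pd.DataFrame(raw)
    true = pd.DataFrame(true)
    return raw, true


# --------------------------------------------------------------------------
# measurements

_GROWTH = {
    # adult height (m), adult weight (kg), shared birth size
    "M": {"adult_height": 1.70, "adult_weight": 58.7},
    "F": {"adult_height": 1.59, "adult_weight": 54.6},
}
_BIRTH_HEIGHT = 0.50
_BIRTH_WEIGHT = 2.94
_HEIGHT_PLATEAU_AGE = 18.0
_WEIGHT_PLATEAU_AGE = 20.0


def _rescaled_decay(age, plateau, raw):
    """Map a decaying 'gap fraction' so it is 1 at birth and exactly 0 at the
    plateau age (size then sits at its adult value)."""
    t = np.minimum(np.asarray(age, dtype=float), plateau)
    tail = raw(plateau)
    return (raw(t) - tail) / (1.0 - tail)


def mean_height(age, sex):
    """Sex-specific mean height curve (m): exponential approach to adult
    height, plateauing exactly at age 18 (~0.88 m at age 2)."""
    frac = _rescaled_decay(age, _HEIGHT_PLATEAU_AGE,
                           lambda t: np.exp(-0.18 * t))
    ha = _GROWTH[sex]["adult_height"]
    return ha - (ha - _BIRTH_HEIGHT) * frac


def mean_log_weight(age, sex):
    """Sex-specific mean log-weight curve at the mean height for that age:
    rapid infant gain (~12.5 kg at 2 y), slower childhood growth, adult
    weight reached at age 20."""
    frac = _rescaled_decay(
        age, _WEIGHT_PLATEAU_AGE,
        lambda t: 0.30 * np.exp(-1.4 * t) + 0.70 * np.exp(-0.075 * t),
    )
    lwa = np.log(_GROWTH[sex]["adult_weight"])
    return lwa - (lwa - np.log(_BIRTH_WEIGHT)) * frac


def _measurement_ages(followup, schedule, rng):
    ages = [0.0]
    dense = (np.arange(1, schedule.dense_n + 1)
             * schedule.dense_max_age / schedule.dense_n)
    dense = dense + rng.uniform(-0.04, 0.04, size=len(dense))
    dense = np.clip(dense, 0.02, schedule.dense_max_age)
    ages.extend(dense[dense <= followup])
    start = schedule.dense_max_age + schedule.sparse_interval
    sparse = np.arange(start, schedule.max_age + schedule.sparse_interval,
                       schedule.sparse_interval)
    sparse = sparse + rng.uniform(-0.4, 0.4, size=len(sparse))
    sparse = sparse[(sparse > schedule.dense_max_age + 0.1)
                    & (sparse <= followup)]
    ages.extend(sparse)
    return np.sort(np.asarray(ages))


def simulate_measurements(pedigree, true_score, config, rng=None):
    """Longitudinal weight/height records with the configured signal.

    Returns a frame with one row per measurement: individual_id, age (exact
    decimal years), sex, weight_kg, height_m and the generating z-scale
    signal ``z_true`` (score effect + family + individual + observation
    noise), which downstream standardization is meant to reconstruct.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    fams = pd.unique(pedigree["mother_id"])
    fam_u = pd.Series(rng.normal(0.0, np.sqrt(config.var_family), len(fams)),
                      index=fams)
    sched = config.schedule
    sd_e = np.sqrt(config.var_observation)
    sd_v = np.sqrt(config.var_individual)
    mean_s = config.expected_score
    out = []
    for row in pedigree.itertuples(index=False):
        iid = row.individual_id
        sex = row.sex
        s_c = float(true_score[iid]) - mean_s
        u = float(fam_u[row.mother_id])
        v = float(rng.normal(0.0, sd_v))
        h_scale = float(rng.normal(0.0, config.height_individual_sd))
        followup = float(rng.uniform(sched.min_followup, sched.max_age))
        ages = _measurement_ages(followup, sched, rng)
        m = len(ages)
        log_h = (np.log(mean_height(ages, sex)) + h_scale
                 + rng.normal(0.0, config.height_noise_sd, m))
        eta = (s_c * (config.effect_intercept + config.effect_slope * ages)
               + u + v + rng.normal(0.0, sd_e, m))
        log_w = (mean_log_weight(ages, sex)
                 + config.height_coupling * (log_h - np.log(mean_height(ages, sex)))
                 + config.sd_log_weight * eta)
        out.append(pd.DataFrame({
            "individual_id": iid,
            "age": ages,
            "sex": sex,
            "weight_kg": np.exp(log_w),
            "height_m": np.exp(log_h),
            "z_true": eta,
        }))
    return pd.concat(out, ignore_index=True)


def simulate_cohort(config):
    """End-to-end simulation; deterministic given ``config`` (incl. its seed)."""
    ss = np.random.SeedSequence(config.seed)
    rng_ped, rng_gen, rng_meas = (np.random.default_rng(s) for s in ss.spawn(3))
    pedigree = simulate_pedigree(config, rng_ped)
    raw_gt, true_counts = simulate_genotypes(pedigree, config, rng_gen)
    scored = [s.snp_id for s in config.scored_snps]
    true_score = true_counts[scored].sum(axis=1)
    anthro = simulate_measurements(pedigree, true_score, config, rng_meas)
    truth = TruthRecord(
        effect_intercept=config.effect_intercept,
        effect_slope=config.effect_slope,
        var_family=config.var_family,
        var_individual=config.var_individual,
        var_observation=config.var_observation,
        expected_score=config.expected_score,
        scored_snps=scored,
        realized_allele_freqs=(true_counts.mean(axis=0) / 2.0).to_dict(),
        true_score=true_score,
    )
    return Cohort(pedigree=pedigree, genotypes=raw_gt, anthro=anthro,
                  truth=truth, config=config)


# --------------------------------------------------------------------------
# writers

def snp_panel_table(config):
    """Panel metadata table consumed by the genotype reader."""
    rows = []
    for spec in config.snp_panel:
        rows.append({
            "snp_id": spec.snp_id,
            "risk_allele": _TRIALLELIC_CODES[0],
            "alleles": ",".join(_TRIALLELIC_CODES) if spec.triallelic
                       else ",".join(_TRIALLELIC_CODES[:2]),
            "triallelic": spec.triallelic,
            "monomorphic": spec.monomorphic,
            "configured_freq": spec.freq,
        })
    return pd.DataFrame(rows)


def write_cohort(cohort, outdir):
    """Write the standard pipeline inputs: pedigree.tsv, genotypes.tsv,
    anthro.tsv, snp_panel.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.pedigree.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
    gt = cohort.genotypes.copy()
    gt.index.name = "individual_id"
    gt.to_csv(outdir / "genotypes.tsv", sep="\t")
    cohort.anthro.drop(columns=["z_true"]).to_csv(
        outdir / "anthro.tsv", sep="\t", index=False
    )
    snp_panel_table(cohort.config).to_csv(outdir / "snp_panel.tsv", sep="\t",
                                          index=False)
    cohort.truth.to_json(outdir / "truth.json")
    return outdir


def write_vcf(cohort, path):
    """Minimal VCF export (GT only) of the biallelic SNPs."""
    gt = cohort.genotypes
    samples = list(gt.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    pos = 1000
    for spec in cohort.config.snp_panel:
        if spec.triallelic:
            continue
        col = gt[spec.snp_id]
        calls = []
        for v in col:
            if pd.isna(v):
                calls.append("./.")
            else:
                v = int(v)
                calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[v])
        # ALT is the risk allele so GT allele-1 dosage == risk count
        lines.append("\t".join(
            ["1", str(pos), spec.snp_id, "C", "A", ".", "PASS", ".", "GT"]
            + calls
        ))
        pos += 1000
    Path(path).write_text("\n".join(lines) + "\n")
    return path
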