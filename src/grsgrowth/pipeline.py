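"""End-to-end analysis pipeline.

Orchestrates simulate/load -> preprocess (twin exclusion) -> genotype QC and
scoring -> internal standardization -> growth parameters -> association
models, producing a summary association table, an effect-by-age curve and a run
manifest whose per-stage counts reconcile exactly (stage input = stage output
+ exclusions).

A single master seed fans out to per-stage child seeds (simulation, twin
exclusion, sibship-representative sampling for HWE) so each stage is
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetics, growth, io, simulate
from .association import (AgeInteractionModel, ClusteredGLS, ThreeLevelModel,
                          score_distribution_summary)
from .exceptions import ConfigurationError, InputError
from .standardize import WfhCalibrationModel, group_zscore

logger = logging.getLogger("grsgrowth")

__all__ = ["PipelineConfig", "InputPaths", "RunManifest", "PipelineResult",
           "preprocess_cohort", "run_pipeline"]

BIRTH_AGE_MAX = 0.02  # years (~1 week): a measurement this early is "at birth"
ADULT_MIN_AGE = 20.0


@dataclass
class InputPaths:
    pedigree: str
    genotypes: str
    anthro: str
    snp_panel: str | None = None


@dataclass
class PipelineConfig:
    """Configuration for a full run; exactly one of simulation/inputs."""

    simulation: simulate.SimulationConfig | None = None
    inputs: InputPaths | None = None
    seed: int = 0
    out_dir: str | None = None
    # genotype QC
    call_rate_threshold: float = 0.95
    max_missing: int = 5
    drop_hwe_failures: bool = True
    hwe_method: str = "chisq"
    hwe_alpha: float = 0.05
    # standardization
    age_degree: int = 5
    height_degree: int = 2
    var_degree: int = 3
    adult_band_years: float = 10.0
    adult_band_cap: float = 40.0
    # growth filters
    min_infant_records: int = 5
    max_slope_se: float = 0.4
    # modelling
    interaction_degree: int = 3
    include_age_main: bool = True
    make_plots: bool = False

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of a simulation block or input paths is required"
            )
        if not 0 < self.call_rate_threshold <= 1:
            raise ConfigurationError("call_rate_threshold must be in (0, 1]")
        if self.max_missing < 0:
            raise ConfigurationError("max_missing must be >= 0")

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim = dict(sim)
            if "offspring" in sim:
                sim["offspring"] = simulate.OffspringSpec(**sim["offspring"])
            if "schedule" in sim:
                sim["schedule"] = simulate.ScheduleSpec(**sim["schedule"])
            if "snp_panel" in sim:
                sim["snp_panel"] = tuple(simulate.SnpSpec(**s)
                                         for s in sim["snp_panel"])
            sim = simulate.SimulationConfig(**sim)
        inputs = d.pop("inputs", None)
        if inputs is not None:
            inputs = InputPaths(**inputs)
        return cls(simulation=sim, inputs=inputs, **d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self):
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Attrition accounting for a run: per-stage counts that must reconcile."""

    config_hash: str
    master_seed: int
    child_seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    version: str = ""

    def add_stage(self, name, n_in, n_out, exclusions=None):
        exclusions = dict(exclusions or {})
        if n_in != n_out + sum(exclusions.values()):
            raise InputError(
                f"manifest stage {name!r} does not reconcile: "
                f"{n_in} != {n_out} + {sum(exclusions.values())}"
            )
        self.stages[name] = {"in": int(n_in), "out": int(n_out),
                             "exclusions": {k: int(v) for k, v in exclusions.items()}}
        logger.info("stage %s: %d in, %d out, exclusions=%s",
                    name, n_in, n_out, exclusions)

    def validate(self):
        for name, st in self.stages.items():
            if st["in"] != st["out"] + sum(st["exclusions"].values()):
                raise InputError(f"manifest stage {name!r} does not reconcile")
        return True

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class PipelineResult:
    associations: pd.DataFrame
    effect_curve: pd.DataFrame
    score_summary: pd.DataFrame
    scores: pd.DataFrame
    snp_report: pd.DataFrame
    calibration: object
    manifest: RunManifest
    interaction: object
    fits: dict
    truth: object = None


def _check_pedigree(pedigree):
    ids = set(pedigree["individual_id"])
    mother = dict(zip(pedigree["individual_id"], pedigree["mother_id"]))
    for iid in ids:
        seen = set()
        cur = iid
        while cur in mother and mother[cur] in ids:
            if cur in seen:
                raise InputError("pedigree contains cyclic mother references")
            seen.add(cur)
            cur = mother[cur]
            if cur == iid:
                raise InputError("pedigree contains cyclic mother references")


def preprocess_cohort(pedigree, anthro, seed):
    """Twin exclusion and measurement completeness flags.

    One randomly chosen member of each twin pair is dropped (seeded);
    measurements with missing weight or height are flagged, not dropped —
    each downstream analysis uses the components it needs.
    """
    _check_pedigree(pedigree)
    rng = np.random.default_rng(seed)
    drop = []
    twin = pedigree.loc[pedigree["twin_id"].astype(str) != ""]
    for tid, sub in twin.groupby("twin_id", sort=True):
        members = list(sub["individual_id"])
        if len(members) >= 2:
            drop.append(members[rng.integers(len(members))])
    kept = pedigree.loc[~pedigree["individual_id"].isin(drop)].copy()
    anthro = anthro.loc[anthro["individual_id"].isin(set(kept["individual_id"]))].copy()
    anthro["missing_any"] = (~np.isfinite(anthro["weight_kg"].astype(float))
                             | ~np.isfinite(anthro["height_m"].astype(float)))
    return kept, anthro, {"twins_dropped": drop}


def _adult_band(ages, band_years, cap):
    band = np.floor(np.asarray(ages, dtype=float) / band_years) * band_years
    return np.minimum(band, cap)


def _gls_row(df, outcome_col, label, group_label):
    model = ClusteredGLS.from_dataframe(
        df, outcome_col, score="score", cluster="mother_id",
        village="village", birth_year="birth_year",
    )
    res = model.fit()
    ar = res.association_result(outcome=label, n=len(df))
    return {"age_group": group_label, "outcome": label, "n": ar.n,
            "coefficient": ar.coefficient, "se": ar.se, "ci_low": ar.ci_low,
            "ci_high": ar.ci_high, "pvalue": ar.pvalue}, res


def _three_level_row(df, label, group_label):
    model = ThreeLevelModel.from_dataframe(
        df, "z", score="score", family="mother_id",
        individual="individual_id", village="village", birth_year="birth_year",
    )
    res = model.fit()
    ar = res.association_result(outcome=label, n=df["individual_id"].nunique())
    return {"age_group": group_label, "outcome": label, "n": ar.n,
            "coefficient": ar.coefficient, "se": ar.se, "ci_low": ar.ci_low,
            "ci_high": ar.ci_high, "pvalue": ar.pvalue}, res


def run_pipeline(config):
    """Execute all stages in order; returns a :class:`PipelineResult`."""
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(3)
    seeds = {
        "simulation": int(child[0].generate_state(1)[0] % 2**31),
        "twin_exclusion": int(child[1].generate_state(1)[0] % 2**31),
        "hwe_sampling": int(child[2].generate_state(1)[0] % 2**31),
    }
    manifest = RunManifest(config_hash=config.config_hash(),
                           master_seed=config.seed, child_seeds=seeds)

    # ---- stage: inputs
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=seeds["simulation"])
        cohort = simulate.simulate_cohort(sim_cfg)
        pedigree, raw_gt, anthro = cohort.pedigree, cohort.genotypes, cohort.anthro
        anthro = anthro.drop(columns=["z_true"])
        panel = simulate.snp_panel_table(sim_cfg)
        truth = cohort.truth
    else:
        pedigree = io.read_pedigree(config.inputs.pedigree)
        raw_gt = io.read_genotypes(config.inputs.genotypes)
        anthro = io.read_anthro(config.inputs.anthro)
        panel = (io.read_snp_panel(config.inputs.snp_panel)
                 if config.inputs.snp_panel else None)
        truth = None

    # ---- stage: preprocess (twin exclusion)
    n0 = len(pedigree)
    pedigree, anthro, pre = preprocess_cohort(pedigree, anthro,
                                              seeds["twin_exclusion"])
    manifest.add_stage("preprocess_individuals", n0, len(pedigree),
                       {"twin_excluded": len(pre["twins_dropped"])})
    n_meas = len(anthro)
    usable_meas = int((~anthro["missing_any"]).sum())
    manifest.add_stage("measurements", n_meas, usable_meas,
                       {"missing_weight_or_height": n_meas - usable_meas})

    # ---- stage: genotype QC + combined score
    raw_gt = raw_gt.loc[raw_gt.index.isin(set(pedigree["individual_id"]))]
    mothers = pedigree.set_index("individual_id")["mother_id"]
    qc = genetics.run_genotype_qc(
        raw_gt, panel=panel, mothers=mothers,
        call_rate_threshold=config.call_rate_threshold,
        max_missing=config.max_missing, hwe_seed=seeds["hwe_sampling"],
        drop_hwe_failures=config.drop_hwe_failures,
        hwe_method=config.hwe_method, hwe_alpha=config.hwe_alpha,
    )
    manifest.add_stage(
        "genotype_individuals", len(raw_gt), len(qc.scores),
        {"excluded_missing_genotypes": len(qc.excluded_individuals)},
    )
    rep = qc.snp_report
    manifest.add_stage(
        "snps", len(rep), int(rep["scored"].sum()),
        {"failed_call_rate": int((~rep["pass_call_rate"]).sum()),
         "monomorphic": int((rep["monomorphic"]
                             & rep["pass_call_rate"]).sum()),
         "failed_hwe": int(rep["scored"].eq(False).sum()
                           - (~rep["pass_call_rate"]).sum()
                           - (rep["monomorphic"] & rep["pass_call_rate"]).sum())},
    )

    # analysis base: scored individuals with demographics
    demo = pedigree.set_index("individual_id")
    demo = demo.assign(birth_year=demo["birth_date"].astype(float))
    scores = qc.scores.join(demo[["mother_id", "sex", "village", "birth_year"]])
    meas = anthro.loc[~anthro["missing_any"]].merge(
        scores.reset_index().rename(columns={"index": "individual_id"}),
        on="individual_id", how="inner", suffixes=("", "_ped"),
    )

    # ---- stage: standardization
    cal = WfhCalibrationModel(
        meas, kind="weight_for_height", age_degree=config.age_degree,
        height_degree=config.height_degree, var_degree=config.var_degree,
    ).fit()
    zres = cal.zscore(meas)
    meas["z"] = zres["z"]

    # continuous weight-for-age / height-for-age for the infant slopes
    cal_wfa = WfhCalibrationModel(meas, kind="weight_for_age",
                                  age_degree=config.age_degree,
                                  var_degree=config.var_degree).fit()
    cal_hfa = WfhCalibrationModel(meas, kind="height_for_age",
                                  age_degree=config.age_degree,
                                  var_degree=config.var_degree).fit()
    meas["z_wfa"] = cal_wfa.zscore(meas)["z"]
    meas["z_hfa"] = cal_hfa.zscore(meas)["z"]

    # ---- cross-sectional frames
    rows = []
    fits = {}

    birth = meas.loc[meas["age"] <= BIRTH_AGE_MAX].sort_values("age")
    birth = birth.groupby("individual_id", as_index=False).first()
    if len(birth) >= 10:
        birth["zBW"] = group_zscore(birth["weight_kg"], birth["sex"])
        row, fits["zBW"] = _gls_row(birth, "zBW", "zBW", "birth")
        rows.append(row)

    anchors = growth.select_anchor_measurements(
        meas, id_col="individual_id", age_col="age", adult_min=ADULT_MIN_AGE,
    )
    two = anchors.dropna(subset=["idx_2y"])
    two_rows = meas.iloc[two["idx_2y"].astype(int)].copy()
    if len(two_rows) >= 10:
        two_rows["zWT_2y"] = group_zscore(two_rows["weight_kg"],
                                          two_rows["sex"], log_first=True)
        two_rows["zHT_2y"] = group_zscore(two_rows["height_m"],
                                          two_rows["sex"], log_first=True)
        for col, label in (("zWT_2y", "zWT"), ("zHT_2y", "zHT")):
            row, fits[f"{label}_2y"] = _gls_row(two_rows, col, label, "2 years")
            rows.append(row)

    adults = anchors.dropna(subset=["idx_adult"])
    adult_rows = meas.iloc[adults["idx_adult"].astype(int)].copy()
    if len(adult_rows) >= 10:
        band = _adult_band(adult_rows["age"], config.adult_band_years,
                           config.adult_band_cap)
        grp = adult_rows["sex"].astype(str) + ":" + band.astype(int).astype(str)
        adult_rows["zWT_ad"] = group_zscore(adult_rows["weight_kg"], grp,
                                            log_first=True)
        adult_rows["zHT_ad"] = group_zscore(adult_rows["height_m"], grp,
                                            log_first=True)
        bmi = adult_rows["weight_kg"] / adult_rows["height_m"] ** 2
        adult_rows["zBMI_ad"] = group_zscore(bmi, grp)
        for col, label in (("zWT_ad", "zWT"), ("zHT_ad", "zHT")):
            row, fits[f"{label}_adult"] = _gls_row(adult_rows, col, label,
                                                   "Adults")
            rows.append(row)

    # zWT-HT three-level models on the record subsets
    child_meas = meas.loc[meas["age"] <= ADULT_MIN_AGE]
    row, fits["zWTHT_child"] = _three_level_row(child_meas, "zWT-HT",
                                                "<=20 years")
    rows.append(row)
    adult_meas = meas.loc[meas["age"] > ADULT_MIN_AGE]
    if adult_meas["individual_id"].nunique() >= 10:
        row, fits["zWTHT_adult"] = _three_level_row(adult_meas, "zWT-HT",
                                                    ">20 years")
        rows.append(row)
    if len(adult_rows) >= 10:
        row, fits["zBMI_adult"] = _gls_row(adult_rows, "zBMI_ad", "zBMI",
                                           "Adults")
        rows.append(row)

    # ---- longitudinal growth parameters
    infant = meas.loc[meas["age"] <= 2.0]
    slopes_w = growth.infant_growth_table(
        infant, z_col="z_wfa", min_records=config.min_infant_records,
        max_se=config.max_slope_se,
    ).set_index("individual_id")
    slopes_h = growth.infant_growth_table(
        infant, z_col="z_hfa", min_records=config.min_infant_records,
        max_se=config.max_slope_se,
    ).set_index("individual_id")
    manifest.add_stage(
        "infant_weight_slopes", len(slopes_w),
        int(slopes_w["included"].sum()),
        {"filtered": int((~slopes_w["included"]).sum())},
    )
    for slopes, label in ((slopes_w, "WT growth"), (slopes_h, "LG growth")):
        inc = slopes.loc[slopes["included"]].join(scores, how="inner")
        if len(inc) >= 10:
            row, fits[label] = _gls_row(inc.reset_index(), "slope", label,
                                        "0-2 years")
            rows.append(row)

    # 2-20 y change: group-z anchors at ~2 y and first adult measurement
    both = anchors.dropna(subset=["idx_2y", "idx_adult"])
    if len(both) >= 10 and "zWT_2y" in two_rows and "zWT_ad" in adult_rows:
        z2 = two_rows.set_index("individual_id")
        za = adult_rows.set_index("individual_id")
        chg = pd.DataFrame({
            "dzWT": growth.childhood_change(
                z2.loc[both.index, "zWT_2y"], za.loc[both.index, "zWT_ad"]),
            "dzHT": growth.childhood_change(
                z2.loc[both.index, "zHT_2y"], za.loc[both.index, "zHT_ad"]),
        }, index=both.index).join(scores, how="inner")
        for col, label in (("dzWT", "zWT change"), ("dzHT", "zHT change")):
            row, fits[label] = _gls_row(chg.reset_index(), col, label,
                                        "2-20 years")
            rows.append(row)

    associations = pd.DataFrame(rows)

    # ---- gene-by-age interaction on all zWT-HT records
    inter_model = AgeInteractionModel.from_dataframe(
        meas, outcome="z", score="score", age="age", family="mother_id",
        individual="individual_id", village="village", birth_year="birth_year",
        degree=config.interaction_degree,
        include_age_main=config.include_age_main,
    )
    inter = inter_model.fit()
    slope = inter.linear_slope_raw()
    associations = pd.concat([associations, pd.DataFrame([{
        "age_group": "all ages", "outcome": "zWT-HT x age (linear)",
        "n": meas["individual_id"].nunique(), "coefficient": slope.coefficient,
        "se": slope.se, "ci_low": slope.ci_low, "ci_high": slope.ci_high,
        "pvalue": slope.pvalue,
    }])], ignore_index=True)

    grid = np.linspace(0.0, float(meas["age"].max()), 101)
    curve = inter.predict_effect_by_age(grid)

    # Figure-1 analogue: unadjusted mean z per integer score bin (first adult
    # measurement per individual)
    if len(adult_rows):
        adult_z = meas.loc[adults["idx_adult"].astype(int)]
        score_summary = score_distribution_summary(adult_z["score"],
                                                   adult_z["z"])
    else:
        score_summary = score_distribution_summary(meas["score"], meas["z"])

    result = PipelineResult(
        associations=associations, effect_curve=curve, score_summary=score_summary,
        scores=qc.scores, snp_report=qc.snp_report, calibration=cal,
        manifest=manifest, interaction=inter, fits=fits,
    )
    result.truth = truth
    manifest.validate()

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_tsv(associations, out / "associations.tsv")
        io.write_tsv(curve, out / "effect_by_age.tsv")
        io.write_tsv(score_summary, out / "score_distribution.tsv")
        io.write_tsv(qc.scores.reset_index(names="individual_id"),
                     out / "scores.tsv")
        io.write_tsv(qc.snp_report.reset_index(names="snp_id"),
                     out / "snp_qc.tsv")
        cal.save(out / "calibration.json")
        manifest.to_json(out / "manifest.json")
        if config.make_plots:
            from . import plots
            plots.plot_score_distribution(score_summary,
                                          out / "fig1_score_distribution.png")
            plots.plot_effect_by_age(curve, out / "fig2_effect_by_age.png")
    return result
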