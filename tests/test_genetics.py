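"""Genotype QC, HWE testing, imputation and the combined allele score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grsgrowth import InputError
from grsgrowth.genetics import (allele_frequencies, call_rates, compute_score,
                                encode_genotypes, hwe_chisq, hwe_exact,
                                hwe_test_sibships, impute_missing,
                                monomorphic_snps, qc_call_rate,
                                recode_triallelic, run_genotype_qc)
from grsgrowth.simulate import snp_panel_table

from conftest import small_config
from grsgrowth.simulate import simulate_cohort


def _gt(cols):
    return pd.DataFrame(cols, dtype=float)


def test_call_rate_pass_and_fail():
    full = _gt({"a": [0, 1, 2, 1] * 25})
    assert qc_call_rate(full, 0.95)["a"]
    partial = _gt({"a": [np.nan] * 6 + [1] * 94})
    assert not qc_call_rate(partial, 0.95)["a"]
    exactly = _gt({"a": [np.nan] * 5 + [1] * 95})
    assert qc_call_rate(exactly, 0.95)["a"]  # call rate == threshold passes


def test_call_rate_single_missing_individual():
    n = 1000
    df = _gt({f"s{j}": [1.0] * n for j in range(5)})
    df.iloc[0] = np.nan  # one individual entirely missing
    assert qc_call_rate(df, 0.95).all()
    assert np.allclose(call_rates(df), 0.999)


def test_empty_matrix_rejected():
    with pytest.raises(InputError):
        call_rates(pd.DataFrame())


def test_monomorphic_detection():
    df = _gt({
        "allzero": [0, 0, 0, 0],
        "alltwo": [2, 2, 2, 2],
        "allhet": [1, 1, 1, 1],   # both alleles observed: polymorphic
        "poly": [0, 1, 2, 1],
    })
    assert set(monomorphic_snps(df)) == {"allzero", "alltwo"}


def test_generator_monomorphic_snps_detected(small_cohort):
    panel = snp_panel_table(small_cohort.config)
    gt = encode_genotypes(small_cohort.genotypes, panel)
    configured = {s.snp_id for s in small_cohort.config.snp_panel
                  if s.monomorphic}
    assert configured <= set(monomorphic_snps(gt))


def test_recode_triallelic_counts_risk_alleles():
    calls = pd.Series(["A/A", "A/C", "C/G", "A/G", "G/G", None])
    out = recode_triallelic(calls, "A", alleles=("A", "C", "G"))
    assert list(out[:5]) == [2, 1, 0, 1, 0]
    assert np.isnan(out.iloc[5])


def test_recode_codomain(rng):
    codes = ["A", "C", "G"]
    calls = pd.Series(["/".join(rng.choice(codes, 2)) for _ in range(200)])
    out = recode_triallelic(calls, "A")
    assert set(out.unique()) <= {0.0, 1.0, 2.0}


def test_recode_unknown_allele_rejected():
    with pytest.raises(InputError):
        recode_triallelic(pd.Series(["A/T"]), "A", alleles=("A", "C", "G"))


def test_hwe_exact_proportions_give_zero_statistic():
    stat, p = hwe_chisq(25, 50, 25)
    assert stat == 0.0 and p == 1.0


def test_hwe_chisq_hand_value():
    # counts (10,10,10): freq 0.5, expected (7.5, 15, 7.5) -> X2 = 10/3
    stat, p = hwe_chisq(10, 10, 10)
    assert np.isclose(stat, 10.0 / 3.0)
    assert 0 < p < 1


def test_hwe_monomorphic_counts():
    stat, p = hwe_chisq(30, 0, 0)
    assert stat == 0.0 and p == 1.0


def test_hwe_exact_matches_enumeration():
    # brute-force enumeration of P(het | rare count) for a tiny sample
    n0, n1, n2 = 5, 2, 3
    n = n0 + n1 + n2
    n_rare = min(n1 + 2 * n2, n1 + 2 * n0)
    from math import comb
    hets = range(n_rare % 2, n_rare + 1, 2)

    def weight(h):
        homr = (n_rare - h) // 2
        homc = n - h - homr
        # multinomial count of genotype configurations x 2^het
        from math import factorial
        return (factorial(n) // (factorial(h) * factorial(homr)
                                 * factorial(homc))) * 2 ** h

    ws = {h: weight(h) for h in hets}
    total = sum(ws.values())
    probs = {h: w / total for h, w in ws.items()}
    p_obs = probs[n1]
    expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    assert np.isclose(hwe_exact(n0, n1, n2), expected, rtol=1e-10)


def test_hwe_sibship_sampling_is_seeded(small_cohort):
    panel = snp_panel_table(small_cohort.config)
    gt = encode_genotypes(small_cohort.genotypes, panel)
    mothers = small_cohort.pedigree.set_index("individual_id")["mother_id"]
    a = hwe_test_sibships(gt, mothers, seed=5)
    b = hwe_test_sibships(gt, mothers, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = hwe_test_sibships(gt, mothers, seed=6)
    assert not a["statistic"].equals(c["statistic"])


def test_hwe_skipped_with_few_sibships():
    gt = _gt({"s": [0, 1, 2]})
    mothers = pd.Series(["m1", "m1", "m2"], index=gt.index)
    with pytest.warns(UserWarning):
        out = hwe_test_sibships(gt, mothers, seed=0, min_samples=30)
    assert out["skipped"].all()


def test_imputation_value_is_twice_allele_frequency():
    df = _gt({"s": [0, 1, 1, 1, 0, np.nan] + [1] * 4})
    imputed, excluded, _ = impute_missing(df, max_missing=5)
    freq = np.nanmean(df["s"]) / 2.0
    assert np.isclose(imputed.loc[5, "s"], 2 * freq)
    assert len(excluded) == 0


def test_exclusion_threshold_six_of_28():
    cols = {f"s{j:02d}": [1.0] * 10 for j in range(28)}
    df = _gt(cols)
    df.iloc[0, :6] = np.nan   # missing 6 of 28: excluded
    df.iloc[1, :5] = np.nan   # missing 5 of 28: retained, imputed
    imputed, excluded, n_imputed = impute_missing(df, max_missing=5)
    assert list(excluded) == [0]
    assert 1 in imputed.index
    assert n_imputed.loc[1] == 5
    assert not imputed.isna().any().any()


def test_impute_all_missing_snp_rejected():
    df = _gt({"s": [np.nan, np.nan], "t": [1, 1]})
    with pytest.raises(InputError):
        impute_missing(df, max_missing=5)


def test_score_bounds_and_sum():
    n_snps = 28
    allrisk = _gt({f"s{j}": [2.0] for j in range(n_snps)})
    assert compute_score(allrisk)["score"].iloc[0] == 2 * n_snps
    norisk = _gt({f"s{j}": [0.0] for j in range(n_snps)})
    assert compute_score(norisk)["score"].iloc[0] == 0
    three = _gt({"a": [2.0], "b": [1.0], "c": [0.0]})
    assert compute_score(three)["score"].iloc[0] == 3


def test_score_requires_complete_matrix():
    with pytest.raises(InputError):
        compute_score(_gt({"a": [np.nan]}))


@given(st.permutations(list(range(6))))
def test_score_invariant_to_snp_order(perm):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.integers(0, 3, size=(20, 6)).astype(float),
                      columns=[f"s{j}" for j in range(6)])
    base = compute_score(df)["score"]
    shuffled = compute_score(df.iloc[:, list(perm)])["score"]
    pd.testing.assert_series_equal(base, shuffled)


def test_imputation_preserves_observed_mean():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.integers(0, 3, size=(500, 4)).astype(float),
                      columns=list("abcd"))
    mask = rng.random(df.shape) < 0.05
    observed_means = df.mask(mask).mean()
    imputed, _, _ = impute_missing(df.mask(mask), max_missing=3)
    pd.testing.assert_series_equal(imputed.mean(), observed_means,
                                   rtol=1e-12)


def test_imputed_score_unbiased_under_mcar():
    """Mean error of the imputed score vs the true score is ~0 under MCAR."""
    cfg = small_config(n_families=300, missing_rate=0.03, seed=17)
    cohort = simulate_cohort(cfg)
    panel = snp_panel_table(cfg)
    gt = encode_genotypes(cohort.genotypes, panel)
    scored = [s.snp_id for s in cfg.scored_snps]
    imputed, excluded, _ = impute_missing(gt[scored], max_missing=5)
    score = compute_score(imputed)["score"]
    truth = cohort.truth.true_score.drop(index=excluded, errors="ignore")
    err = (score - truth.loc[score.index]).to_numpy()
    mc_se = err.std(ddof=1) / np.sqrt(len(err))
    assert abs(err.mean()) <= 3 * mc_se


def test_run_genotype_qc_end_to_end(small_cohort):
    panel = snp_panel_table(small_cohort.config)
    mothers = small_cohort.pedigree.set_index("individual_id")["mother_id"]
    qc = run_genotype_qc(small_cohort.genotypes, panel=panel, mothers=mothers,
                         hwe_seed=1)
    n_scored = len(qc.scored_snps)
    assert n_scored <= 28
    assert (qc.scores["score"] >= 0).all()
    assert (qc.scores["score"] <= 2 * n_scored).all()
    assert not qc.snp_report.loc[qc.scored_snps, "monomorphic"].any()
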