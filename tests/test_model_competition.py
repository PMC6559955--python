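"""OLS/AIC engine, cis-window lookup and the four-family competition."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vmrgem import model_competition as mc
from vmrgem import synthetic_data
from vmrgem.containers import EnvironmentTable, GenotypeMatrix, ModelFamily


# ---------------------------------------------------------------------------
# fit_ols_aic


def test_aic_intercept_only_worked_example():
    """y = (1,2,3,5): RSS = 8.75, Gaussian AIC with the variance counted
    as a parameter is ~18.4825 (the AIC of lm(y ~ 1))."""
    r = mc.fit_ols_aic(np.array([1.0, 2, 3, 5]), np.ones((4, 1)))
    assert r.aic == pytest.approx(18.4825, abs=1e-4)
    assert r.n_used == 4


def test_aic_matches_loglik_oracle_on_random_designs(rng):
    """AIC equals 2k - 2 lnL with lnL from an independent OLS path."""
    for _ in range(20):
        n = int(rng.integers(20, 80))
        p = int(rng.integers(1, 6))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        y = X @ rng.standard_normal(p + 1) + rng.standard_normal(n)
        got = mc.fit_ols_aic(y, X)
        fit = sm.OLS(y, X).fit()
        k = X.shape[1] + 1  # coefficients + error variance
        assert got.aic == pytest.approx(2 * k - 2 * fit.llf, abs=1e-8)
        np.testing.assert_allclose(got.coefs, fit.params, atol=1e-10)
        np.testing.assert_allclose(got.ses, fit.bse, atol=1e-10)
        np.testing.assert_allclose(got.p_values, fit.pvalues, atol=1e-10)


def test_rank_deficiency_names_the_duplicate_column(rng):
    x = rng.standard_normal(30)
    X = np.column_stack([np.ones(30), x, x])
    with pytest.raises(mc.RankDeficientError, match="x_copy"):
        mc.fit_ols_aic(rng.standard_normal(30), X, names=["intercept", "x", "x_copy"])


def test_degenerate_perfect_fit_raises(rng):
    x = rng.standard_normal(30)
    X = np.column_stack([np.ones(30), x])
    with pytest.raises(mc.DegenerateFitError):
        mc.fit_ols_aic(2 + 3 * x, X)


def test_missing_rows_are_dropped(rng):
    x = rng.standard_normal(50)
    y = 0.5 * x + rng.standard_normal(50)
    y[:5] = np.nan
    r = mc.fit_ols_aic(y, np.column_stack([np.ones(50), x]))
    assert r.n_used == 45


# ---------------------------------------------------------------------------
# cis window


def test_cis_snps_boundary_and_chromosome():
    annot = pd.DataFrame(
        dict(chrom=["1", "1", "2"], pos=[2_000_000, 3_000_001, 2_000_000],
             ref_allele="A", alt_allele="G", maf=0.2, is_functional=[True, True, False]),
        index=pd.Index(["at_edge", "beyond", "other_chrom"], name="snp_id"),
    )
    got = mc.cis_snps("1", 1_000_000, annot)  # edge SNP is exactly 1 Mb away
    assert got == ["at_edge"]


def test_cis_snps_functional_restriction_and_brute_force(rng):
    m = 300
    annot = pd.DataFrame(
        dict(chrom=rng.choice(["1", "2"], m), pos=rng.integers(1, 5_000_000, m),
             ref_allele="A", alt_allele="G", maf=0.2,
             is_functional=rng.random(m) < 0.4),
        index=pd.Index([f"s{i}" for i in range(m)], name="snp_id"),
    )
    tag_chrom, tag_pos = "1", 2_500_000
    got = set(mc.cis_snps(tag_chrom, tag_pos, annot, functional_only=True))
    expect = {
        s for s, row in annot.iterrows()
        if row["chrom"] == tag_chrom and abs(row["pos"] - tag_pos) <= 1_000_000 and row["is_functional"]
    }
    assert got == expect


# ---------------------------------------------------------------------------
# competition


def test_planted_g_effect_wins_g_family():
    c = synthetic_data.single_locus_cohort(n_samples=500, family="G", beta_g=0.04, seed=42)
    v = mc.compete("cg_v000_0", c.meth, c.geno, c.env, c.cov)
    assert v.winner is ModelFamily.G
    assert v.winner_fit.snp_id == "snp_00000"
    assert set(v.family_bests) == set(ModelFamily)
    assert v.delta_aic >= 0


def test_bonferroni_uses_family_candidate_counts():
    c = synthetic_data.simulate_cohort(
        synthetic_data.CohortSpec(n_samples=200, n_cpgs=5, n_snps=4, n_envs=3, ld_block_size=1,
                                  vmr_layout=[synthetic_data.VmrLayout("1", 1_000_000, 3)], seed=3)
    )
    v = mc.compete("cg_v000_0", c.meth, c.geno, c.env, c.cov)
    fits = v.family_bests
    assert fits[ModelFamily.E].n_candidates == 3
    assert fits[ModelFamily.G].n_candidates == 4
    assert fits[ModelFamily.GplusE].n_candidates == 12
    assert fits[ModelFamily.GxE].n_candidates == 12
    for f in fits.values():
        assert f.p_bonf == pytest.approx(min(1.0, f.p_raw * f.n_candidates))


def test_no_cis_snp_flag():
    c = synthetic_data.single_locus_cohort(n_samples=120, seed=8)
    far = c.geno.annotation.assign(chrom="22")
    geno = GenotypeMatrix(c.geno.dosage, far)
    v = mc.compete("cg_v000_0", c.meth, geno, c.env, c.cov)
    assert v.no_cis_snp and v.winner is None


def test_monomorphic_snp_candidates_are_skipped():
    c = synthetic_data.single_locus_cohort(n_samples=150, seed=12)
    dosage = c.geno.dosage.copy()
    dosage["snp_00000"] = 0.0
    geno = GenotypeMatrix(dosage, c.geno.annotation)
    v = mc.compete("cg_v000_0", c.meth, geno, c.env, c.cov)
    # only the E family can be fitted; SNP-bearing families have no candidates
    assert set(v.family_bests) == {ModelFamily.E}


def test_nested_family_aic_gap_is_bounded():
    """Adding predictors can only lower RSS, so each richer family's best
    AIC is at most the nested family's AIC plus 2 per extra parameter."""
    for seed in range(5):
        c = synthetic_data.single_locus_cohort(n_samples=200, seed=seed)
        v = mc.compete("cg_v000_0", c.meth, c.geno, c.env, c.cov)
        aic = {f: v.family_bests[f].aic for f in ModelFamily}
        assert aic[ModelFamily.GplusE] <= aic[ModelFamily.G] + 2 + 1e-9
        assert aic[ModelFamily.GxE] <= aic[ModelFamily.GplusE] + 2 + 1e-9
        assert aic[ModelFamily.GxE] <= aic[ModelFamily.G] + 4 + 1e-9


def test_exact_ties_break_to_lexicographically_smaller_snp():
    c = synthetic_data.single_locus_cohort(n_samples=200, seed=21)
    dosage = c.geno.dosage.copy()
    dosage["snp_zz_copy"] = dosage["snp_00000"]
    annot = pd.concat([c.geno.annotation, c.geno.annotation.rename(index={"snp_00000": "snp_zz_copy"})])
    geno = GenotypeMatrix(dosage, annot)
    v = mc.compete("cg_v000_0", c.meth, geno, c.env, c.cov)
    assert v.family_bests[ModelFamily.G].snp_id == "snp_00000"


def test_verdict_invariant_to_candidate_order():
    c = synthetic_data.simulate_cohort(
        synthetic_data.CohortSpec(n_samples=150, n_cpgs=5, n_snps=6, n_envs=3, ld_block_size=1,
                                  vmr_layout=[synthetic_data.VmrLayout("1", 1_000_000, 3)], seed=17)
    )
    v1 = mc.compete("cg_v000_0", c.meth, c.geno, c.env, c.cov)
    rev = list(reversed(c.geno.snp_ids))
    geno = GenotypeMatrix(c.geno.dosage[rev], c.geno.annotation.loc[rev])
    env = EnvironmentTable(c.env.values[c.env.env_names[::-1]], c.env.categories[::-1])
    v2 = mc.compete("cg_v000_0", c.meth, geno, env, c.cov)
    assert v1.winner is v2.winner
    assert v1.winner_fit.snp_id == v2.winner_fit.snp_id
    assert v1.winner_fit.aic == pytest.approx(v2.winner_fit.aic)


# ---------------------------------------------------------------------------
# FDR


def test_adjust_fdr_step_up_examples():
    def verdict(tag, p):
        c = synthetic_data.single_locus_cohort(n_samples=120, seed=1)
        v = mc.compete("cg_v000_0", c.meth, c.geno, c.env, c.cov)
        v.tag_cpg = tag
        v.winner_fit.p_bonf = p
        return v

    vs = [verdict(f"t{i}", p) for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
    mc.adjust_fdr(vs)
    assert [v.p_fdr for v in vs] == pytest.approx([0.04, 0.04, 0.04, 0.04])

    single = [verdict("solo", 0.2)]
    mc.adjust_fdr(single)
    assert single[0].p_fdr == pytest.approx(0.2)
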