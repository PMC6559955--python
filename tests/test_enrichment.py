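"""Exact 2x2 tests, CpG-island context labelling, set and GWAS enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from vmrgem import enrichment, synthetic_data
from vmrgem.containers import FamilyFit, ModelFamily, ModelVerdict
from .conftest import make_genotype_matrix


def fisher_p_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration (probability-mass rule)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# fisher_2x2


def test_fisher_worked_example():
    r = enrichment.fisher_2x2(3, 1, 1, 3)
    assert r.p_two_sided == pytest.approx(34 / 70, abs=1e-12)
    assert r.odds_ratio == pytest.approx(9.0)
    assert r.direction == "enriched"


def test_fisher_zero_margin_gives_p_one():
    r = enrichment.fisher_2x2(0, 5, 0, 5)
    assert r.p_two_sided == 1.0
    assert r.direction == "none"
    assert np.isnan(r.odds_ratio)


def test_fisher_infinite_sample_odds_ratio():
    r = enrichment.fisher_2x2(5, 0, 2, 8)
    assert r.odds_ratio == np.inf
    assert r.direction == "enriched"


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(60):
        a, b, c, d = rng.integers(0, 15, size=4)
        if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
            continue
        got = enrichment.fisher_2x2(int(a), int(b), int(c), int(d), cmle=False)
        assert got.p_two_sided == pytest.approx(fisher_p_oracle(a, b, c, d), abs=1e-12)


def test_fisher_invariant_to_row_and_column_swaps(rng):
    a, b, c, d = 7, 3, 2, 9
    p0 = enrichment.fisher_2x2(a, b, c, d, cmle=False).p_two_sided
    assert enrichment.fisher_2x2(c, d, a, b, cmle=False).p_two_sided == pytest.approx(p0, abs=1e-12)
    assert enrichment.fisher_2x2(b, a, d, c, cmle=False).p_two_sided == pytest.approx(p0, abs=1e-12)


# ---------------------------------------------------------------------------
# CpG-island context


def _islands(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _cpg_annot(poss, chrom="1"):
    return pd.DataFrame(
        dict(chrom=chrom, pos=poss, island_relation="OpenSea", gene_feature="Body"),
        index=pd.Index([f"c{i}" for i in range(len(poss))], name="cpg_id"),
    )


def test_island_context_boundaries():
    track = _islands([("1", 10_000, 11_000, "i1")])
    annot = _cpg_annot([10_500, 9_000, 13_000, 7_999, 14_999, 5_000, 16_000])
    labels = enrichment.annotate_cpg_context(annot, track)
    assert labels["c0"] == "Island"
    assert labels["c1"] == "N_Shore"   # 1,000 bp before the island start
    assert labels["c2"] == "S_Shore"   # exactly 2,000 bp past the end: inclusive
    assert labels["c3"] == "N_Shelf"   # 2,001 bp out: just beyond shore range
    assert labels["c4"] == "S_Shelf"
    assert labels["c5"] == "OpenSea"
    assert labels["c6"] == "OpenSea"


def test_island_context_unknown_chromosome_defaults_to_opensea():
    track = _islands([("1", 10_000, 11_000, "i1")])
    annot = _cpg_annot([10_500], chrom="7")
    assert enrichment.annotate_cpg_context(annot, track)["c0"] == "OpenSea"


def test_island_context_matches_nearest_interval_scan(rng):
    starts = np.sort(rng.choice(np.arange(1, 500_000, 7000), 30, replace=False))
    track = _islands([("1", int(s), int(s + rng.integers(300, 1500)), "i") for s in starts])
    poss = rng.integers(1, 520_000, 300)
    labels = enrichment.annotate_cpg_context(_cpg_annot(list(poss)), track)
    for cpg, pos in zip(labels.index, poss):
        inside = ((track["start"] <= pos) & (pos <= track["end"])).any()
        if inside:
            assert labels[cpg] == "Island"
            continue
        dists = np.minimum(np.abs(track["start"] - pos), np.abs(track["end"] - pos))
        d = dists.min()
        if d <= 2000:
            assert labels[cpg].endswith("Shore")
        elif d <= 4000:
            assert labels[cpg].endswith("Shelf")
        else:
            assert labels[cpg] == "OpenSea"


# ---------------------------------------------------------------------------
# model-set enrichment


def _fake_verdict(tag, family):
    fit = FamilyFit(family=family, aic=0.0, coef=0.1, se=0.01, p_raw=0.001,
                    n_used=100, n_candidates=1)
    return ModelVerdict(tag_cpg=tag, winner=family, family_bests={family: fit}, delta_aic=1.0)


def test_enrichment_of_constructed_category_split():
    """All GxE tags in OpenSea, all other winners in Islands: OR = inf, p < 0.05."""
    verdicts, cats = [], {}
    for i in range(20):
        verdicts.append(_fake_verdict(f"gxe{i}", ModelFamily.GxE))
        cats[f"gxe{i}"] = "OpenSea"
    for i in range(20):
        verdicts.append(_fake_verdict(f"g{i}", ModelFamily.G))
        cats[f"g{i}"] = "Island"
    results = enrichment.enrich_model_sets(verdicts, pd.Series(cats))
    gxe_open = next(r for r in results if r.set_name == "GxE" and r.label == "OpenSea")
    assert gxe_open.odds_ratio == np.inf
    assert gxe_open.p_two_sided < 0.05


def test_enrichment_reciprocal_on_two_categories():
    verdicts, cats = [], {}
    rng = np.random.default_rng(4)
    for i in range(30):
        fam = ModelFamily.GxE if i % 2 else ModelFamily.G
        verdicts.append(_fake_verdict(f"t{i}", fam))
        cats[f"t{i}"] = "Island" if rng.random() < 0.4 else "OpenSea"
    results = enrichment.enrich_model_sets(verdicts, pd.Series(cats))
    for fam in ("G", "GxE"):
        pair = {r.label: r for r in results if r.set_name == fam}
        prod = pair["Island"].odds_ratio * pair["OpenSea"].odds_ratio
        if np.isfinite(prod):
            assert prod == pytest.approx(1.0)
        assert pair["Island"].p_two_sided == pytest.approx(pair["OpenSea"].p_two_sided, abs=1e-12)


def test_enrichment_single_member_category_runs():
    verdicts = [_fake_verdict("a", ModelFamily.G), _fake_verdict("b", ModelFamily.GxE)]
    cats = pd.Series({"a": "Island", "b": "OpenSea"})
    results = enrichment.enrich_model_sets(verdicts, cats)
    assert all(0 < r.p_two_sided <= 1 for r in results)


def test_enrichment_requires_categorized_tags():
    verdicts = [_fake_verdict("a", ModelFamily.G), _fake_verdict("b", ModelFamily.GxE)]
    with pytest.raises(ValueError, match="lack a category"):
        enrichment.enrich_model_sets(verdicts, pd.Series({"a": "Island"}))


# ---------------------------------------------------------------------------
# GWAS-hit enrichment with LD proxies


def _ld_cohort(seed, n_snps=40):
    spec = synthetic_data.CohortSpec(n_samples=300, n_cpgs=10, n_snps=n_snps, ld_block_size=4,
                                     vmr_layout=[synthetic_data.VmrLayout("1", 10_000, 2)], seed=seed)
    return synthetic_data.simulate_cohort(spec).geno


def test_gwas_enrichment_detects_planted_signal():
    g = _ld_cohort(seed=31)
    annot = g.annotation
    target = set(g.snp_ids[:8])  # two LD blocks
    gwas = pd.DataFrame(
        dict(snp_id=g.snp_ids, chrom=annot["chrom"].values, pos=annot["pos"].values,
             p=[1e-4 if s in target else 0.7 for s in g.snp_ids])
    )
    res = enrichment.gwas_enrichment({"planted": target}, g, gwas)
    assert res[0].odds_ratio > 1
    assert res[0].p_two_sided < 0.05


def test_gwas_enrichment_null_is_flat():
    rng = np.random.default_rng(77)
    g = _ld_cohort(seed=13)
    annot = g.annotation
    gwas = pd.DataFrame(
        dict(snp_id=g.snp_ids, chrom=annot["chrom"].values, pos=annot["pos"].values,
             p=rng.uniform(size=len(g.snp_ids)))
    )
    res = enrichment.gwas_enrichment({"set": set(g.snp_ids[:15])}, g, gwas, p_threshold=0.5)
    assert res[0].p_two_sided > 0.05


def test_gwas_enrichment_requires_position_matches(rng):
    g = make_genotype_matrix(rng.binomial(2, 0.3, size=(60, 5)).astype(float))
    gwas = pd.DataFrame(dict(snp_id=["x"], chrom=["9"], pos=[123], p=[0.01]))
    with pytest.raises(ValueError, match="build"):
        enrichment.gwas_enrichment({"set": set(g.snp_ids[:2])}, g, gwas)
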