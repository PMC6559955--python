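"""Fisher-exact enrichment of CpG/SNP sets against genomic categories.

All tests are 2x2 exact hypergeometric tests (two-sided, probability-mass
rule) at a nominal 0.05 level, reported with the sample odds ratio and the
conditional-MLE odds ratio.  Utilities cover CpG-island context annotation
from an island interval track, winner-family vs category enrichment, and
GWAS nominal-hit enrichment with LD-proxy expansion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EnrichmentResult, GenotypeMatrix, ModelVerdict
from .io_formats import ld_proxies

logger = logging.getLogger(__name__)

__all__ = ["fisher_2x2", "annotate_cpg_context", "enrich_sets", "enrich_model_sets", "gwas_enrichment"]


def fisher_2x2(a: int, b: int, c: int, d: int, label: str = "", set_name: str = "",
               cmle: bool = True) -> EnrichmentResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    a = in-set & in-category, b = in-set & not, c = background & in-category,
    d = background & not.  The two-sided p sums hypergeometric probabilities
    no larger than that of the observed table.  The sample odds ratio
    (a*d)/(b*c) is primary (+inf when b*c = 0 and a*d > 0); the
    conditional-MLE odds ratio is reported alongside.  A zero margin yields
    p = 1 and no direction.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return EnrichmentResult(label=label, set_name=set_name, a=a, b=b, c=c, d=d,
                                odds_ratio=np.nan, p_two_sided=1.0, direction="none",
                                odds_ratio_cmle=np.nan)
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = np.inf if a * d > 0 else np.nan
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    or_cmle = None
    if cmle:
        or_cmle = float(stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional").statistic)
    if np.isnan(odds) or odds == 1.0:
        direction = "none"
    else:
        direction = "enriched" if odds > 1.0 else "depleted"
    return EnrichmentResult(label=label, set_name=set_name, a=a, b=b, c=c, d=d,
                            odds_ratio=float(odds), p_two_sided=min(1.0, p),
                            direction=direction, odds_ratio_cmle=or_cmle)


def annotate_cpg_context(cpg_annotation: pd.DataFrame, island_track: pd.DataFrame,
                         shore_bp: int = 2000, shelf_bp: int = 4000) -> pd.Series:
    """CpG-island context per CpG from an island interval track.

    Island if the position falls inside an island (1-based inclusive);
    N_/S_Shore within ``shore_bp`` of the nearest island edge; N_/S_Shelf
    within ``shelf_bp``; OpenSea beyond.  N = lower-coordinate side.
    CpGs on chromosomes absent from the track fall back to OpenSea with a
    warning.
    """
    labels = {}
    by_chrom = {c: t.sort_values("start") for c, t in island_track.groupby("chrom")}
    for chrom, grp in by_chrom.items():
        starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
        if (starts[1:] <= ends[:-1]).any():
            raise ValueError(f"island intervals overlap on {chrom}")
    for cpg, row in cpg_annotation.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in by_chrom:
            logger.warning("CpG %s on chromosome %s absent from island track; labelling OpenSea", cpg, chrom)
            labels[cpg] = "OpenSea"
            continue
        grp = by_chrom[chrom]
        starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and starts[i] <= pos <= ends[i]:
            labels[cpg] = "Island"
            continue
        dist_north = pos - ends[i] if i >= 0 else np.inf  # island to the left
        dist_south = starts[i + 1] - pos if i + 1 < len(starts) else np.inf
        dist, side = min((dist_north, "S"), (dist_south, "N"))  # side names the CpG's side of the island
        if dist <= shore_bp:
            labels[cpg] = f"{side}_Shore"
        elif dist <= shelf_bp:
            labels[cpg] = f"{side}_Shelf"
        else:
            labels[cpg] = "OpenSea"
    return pd.Series(labels, name="island_relation").reindex(cpg_annotation.index)


def enrich_sets(sets: dict[str, set[str]], categories: pd.Series,
                background: set[str] | None = None, adjust: bool = False) -> list[EnrichmentResult]:
    """One 2x2 test per (set, category-label) pair.

    For each named set, the comparison group is ``background`` minus the set
    (default: all categorized ids not in the set).  With ``adjust``,
    Benjamini-Hochberg-adjusted p-values replace the raw ones.
    """
    universe = set(categories.index) if background is None else set(background)
    results = []
    for set_name, members in sets.items():
        members = members & set(categories.index)
        others = (universe | members) - members
        if not members:
            logger.info("set %s empty after categorization; skipped", set_name)
            continue
        for label in sorted(categories.unique()):
            in_cat = set(categories.index[categories == label])
            a = len(members & in_cat)
            b = len(members) - a
            c = len(others & in_cat)
            d = len(others) - c
            results.append(fisher_2x2(a, b, c, d, label=label, set_name=set_name))
    if adjust and results:
        _, q, _, _ = multipletests([r.p_two_sided for r in results], method="fdr_bh")
        for r, qi in zip(results, q):
            r.p_two_sided = float(qi)
    return results


def enrich_model_sets(verdicts: list[ModelVerdict], categories: pd.Series,
                      comparison: str = "vs_other_best_models",
                      background: set[str] | None = None) -> list[EnrichmentResult]:
    """Winner-family enrichment across category labels.

    ``vs_other_best_models``: tagCpGs best explained by one family are
    compared against tagCpGs best explained by any other family.
    ``vs_background``: each family's tags are compared against an explicit
    background set of CpG ids (e.g. non-VMR CpGs).
    """
    scored = [v for v in verdicts if v.winner is not None]
    missing = [v.tag_cpg for v in scored if v.tag_cpg not in categories.index]
    if missing:
        raise ValueError(f"{len(missing)} tagCpGs lack a category, e.g. {missing[0]!r}")
    by_family = {}
    for v in scored:
        by_family.setdefault(v.winner.value, set()).add(v.tag_cpg)
    if comparison == "vs_other_best_models":
        all_tags = {v.tag_cpg for v in scored}
        return enrich_sets(by_family, categories, background=all_tags)
    if comparison == "vs_background":
        if background is None:
            raise ValueError("vs_background comparison needs an explicit background set")
        out = []
        for fam, tags in by_family.items():
            out.extend(enrich_sets({fam: tags}, categories, background=tags | set(background)))
        return out
    raise ValueError(f"unknown comparison {comparison!r}")


def gwas_enrichment(snp_sets: dict[str, set[str]], g: GenotypeMatrix, gwas: pd.DataFrame,
                    background: set[str] | None = None, p_threshold: float = 0.05,
                    r2_min: float = 0.8, max_dist_bp: int = 1_000_000) -> list[EnrichmentResult]:
    """Enrichment of SNP sets for nominally significant GWAS hits.

    Each set member is expanded with its LD proxies (r^2 >= ``r2_min`` within
    ``max_dist_bp``); a member "hits" if it or any proxy position-matches a
    GWAS variant with p < ``p_threshold``.  Matching is by (chrom, pos) only.
    Members with neither a proxy beyond themselves nor a position match are
    excluded from both margins.  The background defaults to all SNPs in the
    matrix that are in no set.
    """
    gwas_pos = {}
    for _, row in gwas.iterrows():
        key = (str(row["chrom"]), int(row["pos"]))
        gwas_pos[key] = min(float(row["p"]), gwas_pos.get(key, 1.0))
    annot = g.annotation
    all_members = set().union(*snp_sets.values()) if snp_sets else set()
    bg = set(background) if background is not None else set(g.snp_ids) - all_members
    need_proxies = sorted((all_members | bg) & set(annot.index))
    proxies = ld_proxies(g, need_proxies, r2_min=r2_min, max_dist_bp=max_dist_bp)

    n_matched = 0

    def hit_status(snp: str) -> bool | None:
        nonlocal n_matched
        group = proxies.get(snp, {snp})
        matched = False
        hit = False
        for s in group:
            key = (str(annot.loc[s, "chrom"]), int(annot.loc[s, "pos"]))
            if key in gwas_pos:
                matched = True
                n_matched += 1
                if gwas_pos[key] < p_threshold:
                    hit = True
        if not matched and len(group) == 1:
            logger.info("SNP %s has no LD proxy and no GWAS position match; excluded", snp)
            return None
        return hit

    status = {s: hit_status(s) for s in need_proxies}
    if n_matched == 0:
        raise ValueError("no SNP positions match the GWAS table; check genome build")
    results = []
    bg_hits = [status[s] for s in bg if status.get(s) is not None]
    for set_name, members in snp_sets.items():
        mem_hits = [status[s] for s in members if status.get(s) is not None]
        a = sum(mem_hits)
        b = len(mem_hits) - a
        c = sum(bg_hits)
        d = len(bg_hits) - c
        results.append(fisher_2x2(a, b, c, d, label="gwas_nominal_hit", set_name=set_name))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        dict(label=r.label, set=r.set_name, a=r.a, b=r.b, c=r.c, d=r.d,
             odds_ratio=r.odds_ratio, odds_ratio_cmle=r.odds_ratio_cmle,
             p=r.p_two_sided, direction=r.direction)
        for r in results
    ]
    return pd.DataFrame(rows)
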