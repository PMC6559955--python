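"""Cross-cohort replication: random-effects meta-analysis and best-model
consistency.

Specific tagCpG-SNP-environment combinations discovered in one cohort are
meta-analysed with their estimates in a replication cohort using the
DerSimonian-Laird random-effects model.  A combination replicates when (i)
the effect has the same direction in both cohorts, (ii) the meta-analysis p
is smaller than the discovery-cohort p, and (iii) the FDR-corrected
meta-analysis p (across all combinations tested) is below 0.05.

``consistency`` compares winning model families across >= 2 cohorts on the
tagCpGs present in all of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MetaResult, ModelFamily, ModelVerdict

logger = logging.getLogger(__name__)

__all__ = ["DlMeta", "dl_meta", "replicate", "consistency"]

KEY_COLS = ["tag_cpg", "snp_id", "env_name", "family"]


@dataclass
class DlMeta:
    beta_pooled: float
    se_pooled: float
    p_meta: float
    tau2: float
    q_stat: float


def dl_meta(estimates: list[tuple[float, float]]) -> DlMeta:
    """DerSimonian-Laird random-effects pooling of (beta, se) estimates.

    Fixed-effect weights w = 1/se^2 give Q = sum w (beta - beta_fixed)^2;
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random weights
    w* = 1/(se^2 + tau^2) give the pooled estimate and a two-sided normal p.
    With one study the input is returned unchanged (tau^2 = 0).
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    beta = np.array([e[0] for e in estimates], float)
    se = np.array([e[1] for e in estimates], float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    beta_fixed = float((w * beta).sum() / w.sum())
    q = float((w * (beta - beta_fixed) ** 2).sum())
    k = len(beta)
    if k == 1:
        tau2 = 0.0
    else:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * beta).sum() / w_star.sum())
    se_pooled = float(1.0 / np.sqrt(w_star.sum()))
    z = pooled / se_pooled
    p = float(2 * stats.norm.sf(abs(z)))
    return DlMeta(beta_pooled=pooled, se_pooled=se_pooled, p_meta=min(1.0, p), tau2=tau2, q_stat=q)


def replicate(discovery: pd.DataFrame, replication: pd.DataFrame,
              alpha_fdr: float = 0.05) -> list[MetaResult]:
    """Meta-analyse matched combinations and apply the replication criterion.

    Both frames need columns tag_cpg, snp_id, env_name, family, beta, se, p.
    Combinations present in only one cohort are skipped with a log entry.
    The FDR universe is all combinations entering the meta-analysis.
    """
    for name, df in (("discovery", discovery), ("replication", replication)):
        missing = [c for c in KEY_COLS + ["beta", "se", "p"] if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks columns {missing}")
    disc = discovery.set_index(KEY_COLS)
    repl = replication.set_index(KEY_COLS)
    shared = disc.index.intersection(repl.index)
    for key in disc.index.difference(repl.index):
        logger.info("combination %s absent from replication cohort; skipped", key)
    if len(shared) == 0:
        raise ValueError("no combinations matched between cohorts")
    results: list[MetaResult] = []
    for key in shared:
        d, r = disc.loc[key], repl.loc[key]
        meta = dl_meta([(float(d["beta"]), float(d["se"])), (float(r["beta"]), float(r["se"]))])
        fam = key[3] if isinstance(key[3], ModelFamily) else ModelFamily(key[3])
        results.append(
            MetaResult(
                tag_cpg=key[0], snp_id=key[1], env_name=key[2], family=fam,
                beta_pooled=meta.beta_pooled, se_pooled=meta.se_pooled,
                p_meta=meta.p_meta, tau2=meta.tau2, q_stat=meta.q_stat,
                same_direction=bool(np.sign(d["beta"]) == np.sign(r["beta"]) and d["beta"] != 0),
                p_discovery=float(d["p"]),
            )
        )
    _, q, _, _ = multipletests([m.p_meta for m in results], method="fdr_bh")
    for m, qi in zip(results, q):
        m.p_meta_fdr = float(qi)
        m.replicated = bool(m.same_direction and m.p_meta < m.p_discovery and m.p_meta_fdr < alpha_fdr)
    return results


def meta_to_frame(results: list[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(tag_cpg=m.tag_cpg, snp_id=m.snp_id, env_name=m.env_name, family=m.family.value,
                 beta_pooled=m.beta_pooled, se_pooled=m.se_pooled, p_meta=m.p_meta, tau2=m.tau2,
                 q_stat=m.q_stat, same_direction=m.same_direction, p_discovery=m.p_discovery,
                 p_meta_fdr=m.p_meta_fdr, replicated=m.replicated)
            for m in results
        ]
    )


_FAMILY_TIE_ORDER = [ModelFamily.E, ModelFamily.G, ModelFamily.GplusE, ModelFamily.GxE]


def consistency(verdict_sets: dict[str, list[ModelVerdict]]) -> tuple[pd.DataFrame, dict]:
    """Best-model agreement across cohorts on shared tagCpGs.

    Restricted to tags with a winner in every cohort.  For each tag the modal
    winner and the number of agreeing cohorts are reported; modal ties are
    broken toward the simpler family and flagged.  The summary gives the
    fraction of tags reaching each agreement level and the winner composition
    of fully consistent tags.
    """
    if len(verdict_sets) < 2:
        raise ValueError("consistency needs at least 2 cohorts")
    cohorts = list(verdict_sets)
    winners: dict[str, dict[str, ModelFamily]] = {}
    for cohort, verdicts in verdict_sets.items():
        winners[cohort] = {v.tag_cpg: v.winner for v in verdicts if v.winner is not None}
    shared = set.intersection(*(set(w) for w in winners.values()))
    if not shared:
        raise ValueError("no tagCpGs shared across all cohorts")
    rows = []
    for tag in sorted(shared):
        fams = [winners[c][tag] for c in cohorts]
        counts = {f: fams.count(f) for f in set(fams)}
        top = max(counts.values())
        modal_cands = sorted((f for f, n in counts.items() if n == top),
                             key=_FAMILY_TIE_ORDER.index)
        rows.append(
            dict(
                tag_cpg=tag,
                **{f"winner_{c}": winners[c][tag].value for c in cohorts},
                n_cohorts_agreeing=top,
                modal_winner=modal_cands[0].value,
                modal_tie=len(modal_cands) > 1,
            )
        )
    table = pd.DataFrame(rows)
    n_cohorts = len(cohorts)
    levels = {
        f"frac_agree_ge_{k}": float((table["n_cohorts_agreeing"] >= k).mean())
        for k in range(2, n_cohorts + 1)
    }
    full = table[table["n_cohorts_agreeing"] == n_cohorts]
    composition = (
        full["modal_winner"].value_counts(normalize=True).to_dict() if len(full) else {}
    )
    summary = dict(
        n_shared_tags=len(table),
        n_cohorts=n_cohorts,
        **levels,
        fully_consistent_fraction=float(len(full) / len(table)),
        fully_consistent_composition=composition,
    )
    return table, summary
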