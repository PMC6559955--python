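"""Four-family model competition for tagCpG methylation.

For each tagCpG the four linear-model families are fitted over the cis
window:

    E    : beta ~ covariates + environment           (one fit per E)
    G    : beta ~ covariates + SNP                   (one fit per cis SNP)
    G+E  : beta ~ covariates + SNP + E               (one fit per pair)
    GxE  : beta ~ covariates + SNP + E + SNP x E     (one fit per pair)

Covariates are always child's sex, gestational age, the cell proportions
(one dropped as reference to keep the design full rank) and the leading
ancestry components.  Within each family the fit with minimal AIC is the
family best; the across-family winner is the best with minimal AIC, with
exact ties broken toward the simpler family.  AIC uses the Gaussian
log-likelihood at the MLE variance with the error variance counted as a
parameter, i.e. the AIC of a standard `lm` fit:

    lnL = -n/2 (ln 2*pi + ln(RSS/n) + 1),   AIC = 2 (p + 1) - 2 lnL

Raw p-values of each family's coefficient of interest are Bonferroni-adjusted
by the number of candidates actually fitted in that family, and winners'
p_bonf are FDR-adjusted across tagCpGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    CovariateTable,
    EnvironmentTable,
    FamilyFit,
    GenotypeMatrix,
    MethylationMatrix,
    ModelFamily,
    ModelVerdict,
)

logger = logging.getLogger(__name__)

__all__ = ["OlsResult", "fit_ols_aic", "cis_snps", "compete", "adjust_fdr", "verdicts_to_frame", "family_proportions"]


class DegenerateFitError(ValueError):
    """Raised when the residual sum of squares is (numerically) zero."""


class RankDeficientError(ValueError):
    """Raised when the design matrix is rank deficient; names the column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient: column {column!r} is collinear")


@dataclass
class OlsResult:
    aic: float
    coefs: np.ndarray
    ses: np.ndarray
    p_values: np.ndarray
    n_used: int


def fit_ols_aic(y: np.ndarray, design: np.ndarray, names: list[str] | None = None) -> OlsResult:
    """Ordinary least squares with Gaussian AIC and two-sided t-test p-values.

    ``design`` must include the intercept column.  Rows with any missing
    value are dropped.  The AIC parameter count is the number of estimated
    coefficients plus one for the error variance.
    """
    y = np.asarray(y, float)
    X = np.asarray(design, float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    names = names or [f"x{i}" for i in range(X.shape[1])]
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[mask], X[mask]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} complete rows, have {n}")
    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    rdiag = np.abs(np.diag(R))
    tol = rdiag.max() * max(n, p) * np.finfo(float).eps
    rank = int((rdiag > tol).sum())
    if rank < p:
        raise RankDeficientError(names[piv[rank]])
    coefs_piv = linalg.solve_triangular(R, Q.T @ y)
    coefs = np.empty(p)
    coefs[piv] = coefs_piv
    resid = y - X @ coefs
    rss = float(resid @ resid)
    if rss <= 1e-10 * max(1.0, float(y @ y)):
        raise DegenerateFitError("degenerate fit: residual sum of squares is zero")
    # (X'X)^-1 from R in pivoted order
    r_inv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv_piv = r_inv @ r_inv.T
    sigma2 = rss / (n - p)
    ses = np.empty(p)
    ses[piv] = np.sqrt(np.diag(xtx_inv_piv) * sigma2)
    tvals = coefs / ses
    p_values = 2 * stats.t.sf(np.abs(tvals), df=n - p)
    loglik = -n / 2 * (np.log(2 * np.pi) + np.log(rss / n) + 1)
    aic = 2 * (p + 1) - 2 * loglik
    return OlsResult(aic=float(aic), coefs=coefs, ses=ses, p_values=p_values, n_used=n)


def cis_snps(
    tag_chrom: str,
    tag_pos: int,
    snp_annotation: pd.DataFrame,
    window_bp: int = 1_000_000,
    functional_only: bool = False,
) -> list[str]:
    """SNPs on the tag's chromosome within ``window_bp`` up- or downstream
    (boundary inclusive); optionally restricted to functional-flagged SNPs."""
    sel = (snp_annotation["chrom"] == tag_chrom) & (
        (snp_annotation["pos"] - tag_pos).abs() <= window_bp
    )
    if functional_only:
        sel &= snp_annotation["is_functional"].astype(bool)
    return list(snp_annotation.index[sel])


def _align_samples(
    meth: MethylationMatrix,
    geno: GenotypeMatrix,
    env: EnvironmentTable,
    cov: CovariateTable,
) -> list[str]:
    samples = [s for s in meth.sample_ids if s in set(geno.sample_ids)]
    samples = [s for s in samples if s in set(env.values.index)]
    samples = [s for s in samples if s in set(cov.values.index)]
    if not samples:
        raise ValueError("no samples shared across methylation, genotype, environment and covariates")
    return samples


def _covariate_design(cov: pd.DataFrame, n_mds: int) -> tuple[np.ndarray, list[str]]:
    # drop the last cell proportion: the 7 proportions sum to ~1 and would be
    # collinear with the intercept
    cell_cols = [f"cell_{i}" for i in range(1, CovariateTable.N_CELL_PROPS)]
    mds_cols = [f"mds_{i}" for i in range(1, n_mds + 1)]
    names = ["intercept", "sex", "gestational_age"] + cell_cols + mds_cols
    X = np.column_stack(
        [np.ones(len(cov))] + [cov[c].to_numpy(float) for c in names[1:]]
    )
    return X, names


def compete(
    tag_cpg: str,
    meth: MethylationMatrix,
    geno: GenotypeMatrix,
    env: EnvironmentTable,
    cov: CovariateTable,
    window_bp: int = 1_000_000,
    functional_only: bool = False,
    n_mds: int = 2,
    select_by: str = "aic",
) -> ModelVerdict:
    """Run the four-family competition for one tagCpG.

    Returns a verdict with the per-family best fits, the winner, and the
    AIC margin to the runner-up family.  Tags with no cis SNP are flagged
    ``no_cis_snp`` (only the E family is fitted) and are excluded from
    winner statistics by default.  ``select_by`` may be ``"aic"`` (default)
    or ``"p"`` to pick within-family bests by smallest raw p-value instead.
    """
    if select_by not in ("aic", "p"):
        raise ValueError("select_by must be 'aic' or 'p'")
    samples = _align_samples(meth, geno, env, cov)
    y = meth.beta.loc[samples, tag_cpg].to_numpy(float)
    cov_df = cov.values.loc[samples]
    C, cov_names = _covariate_design(cov_df, n_mds)

    tag_row = meth.annotation.loc[tag_cpg]
    snp_ids = cis_snps(tag_row["chrom"], int(tag_row["pos"]), geno.annotation, window_bp, functional_only)
    env_vals = {e: env.values.loc[samples, e].to_numpy(float) for e in env.env_names}
    snp_vals = {s: geno.dosage.loc[samples, s].to_numpy(float) for s in snp_ids}

    def try_fit(cols: list[np.ndarray], names: list[str], interest: int) -> tuple | None:
        X = np.column_stack([C] + cols)
        try:
            fit = fit_ols_aic(y, X, cov_names + names)
        except (RankDeficientError, DegenerateFitError, ValueError) as exc:
            logger.debug("skipping candidate %s for %s: %s", names, tag_cpg, exc)
            return None
        j = C.shape[1] + interest
        return fit.aic, fit.coefs[j], fit.ses[j], fit.p_values[j], fit.n_used

    # candidate enumeration is deterministic: envs and SNPs in table order,
    # ties resolved lexicographically below
    candidates: dict[ModelFamily, list[tuple]] = {f: [] for f in ModelFamily}
    for e in env.env_names:
        r = try_fit([env_vals[e]], [e], 0)
        if r:
            candidates[ModelFamily.E].append((*r, None, e))
    for s in snp_ids:
        r = try_fit([snp_vals[s]], [s], 0)
        if r:
            candidates[ModelFamily.G].append((*r, s, None))
    for s in snp_ids:
        for e in env.env_names:
            r = try_fit([snp_vals[s], env_vals[e]], [s, e], 0)  # SNP slope adjusted
            if r:
                candidates[ModelFamily.GplusE].append((*r, s, e))
            r = try_fit(
                [snp_vals[s], env_vals[e], snp_vals[s] * env_vals[e]], [s, e, f"{s}:{e}"], 2
            )
            if r:
                candidates[ModelFamily.GxE].append((*r, s, e))

    family_bests: dict[ModelFamily, FamilyFit] = {}
    for fam, cands in candidates.items():
        if not cands:
            continue
        if select_by == "aic":
            key = lambda c: (c[0], c[5] or "", c[6] or "")  # noqa: E731
        else:
            key = lambda c: (c[3], c[5] or "", c[6] or "")  # noqa: E731
        aic, coef, se, p_raw, n_used, snp, envn = min(cands, key=key)
        family_bests[fam] = FamilyFit(
            family=fam, aic=aic, coef=coef, se=se, p_raw=p_raw, n_used=n_used,
            n_candidates=len(cands), snp_id=snp, env_name=envn,
        )

    no_cis = len(snp_ids) == 0
    if no_cis or not family_bests:
        return ModelVerdict(tag_cpg=tag_cpg, winner=None, family_bests=family_bests,
                            delta_aic=None, no_cis_snp=True)

    ordered = sorted(family_bests.values(), key=lambda f: (f.aic, f.family.complexity))
    winner = ordered[0].family
    delta = ordered[1].aic - ordered[0].aic if len(ordered) > 1 else np.inf
    return ModelVerdict(tag_cpg=tag_cpg, winner=winner, family_bests=family_bests,
                        delta_aic=float(delta), no_cis_snp=False)


def adjust_fdr(verdicts: list[ModelVerdict]) -> list[ModelVerdict]:
    """Benjamini-Hochberg step-up on winners' Bonferroni-adjusted p-values
    across all tagCpGs with a winner; modifies and returns the verdicts."""
    scored = [v for v in verdicts if v.winner is not None]
    if not scored:
        raise ValueError("no verdicts with a winner to adjust")
    pvals = np.array([v.winner_fit.p_bonf for v in scored])
    _, p_fdr, _, _ = multipletests(pvals, method="fdr_bh")
    for v, q in zip(scored, p_fdr):
        v.p_fdr = float(q)
    return verdicts


def verdicts_to_frame(verdicts: list[ModelVerdict]) -> pd.DataFrame:
    """Per-tag report: winner, chosen SNP/E, the four AICs, margin, p ladder."""
    rows = []
    for v in verdicts:
        aics = {f"aic_{fam.name}": (v.family_bests[fam].aic if fam in v.family_bests else np.nan)
                for fam in ModelFamily}
        w = v.winner_fit
        rows.append(
            dict(
                tag_cpg=v.tag_cpg,
                winner=v.winner.value if v.winner else "no_cis_snp",
                snp_id=w.snp_id if w else None,
                env_name=w.env_name if w else None,
                **aics,
                delta_aic=v.delta_aic,
                coef=w.coef if w else np.nan,
                se=w.se if w else np.nan,
                p_raw=w.p_raw if w else np.nan,
                p_bonf=w.p_bonf if w else np.nan,
                p_fdr=v.p_fdr,
            )
        )
    return pd.DataFrame(rows)


def family_proportions(verdicts: list[ModelVerdict]) -> dict[str, float]:
    """Fraction of tagCpGs won by each family (no-cis-SNP tags excluded)."""
    scored = [v for v in verdicts if v.winner is not None]
    if not scored:
        return {fam.value: np.nan for fam in ModelFamily}
    return {
        fam.value: sum(v.winner is fam for v in scored) / len(scored)
        for fam in ModelFamily
    }
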