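"""Detection of variably methylated regions (VMRs).

A VMR is a run of at least two top-decile-variability CpGs on the same
chromosome with at most 1 kb between consecutive members.  Variability is
measured per CpG by the unscaled median absolute deviation (MAD) of its beta
values, candidates are the CpGs whose MAD strictly exceeds the empirical
90th percentile (type-7 / linear-interpolation quantile, the R default), and
each region is represented downstream by its highest-MAD member (the tagCpG).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, Vmr

__all__ = ["compute_mad", "mad_scores", "select_candidates", "cluster_vmrs", "select_tag", "detect_vmrs"]


def compute_mad(beta_column: np.ndarray) -> float:
    """Unscaled MAD: median(|x - median(x)|), missing values excluded.

    No consistency constant is applied — this is a raw variability score,
    not a robust standard-deviation estimate.
    """
    x = np.asarray(beta_column, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("MAD needs at least 2 non-missing values")
    return float(np.median(np.abs(x - np.median(x))))


def mad_scores(meth: MethylationMatrix) -> pd.Series:
    """MAD per CpG column of a methylation matrix."""
    vals = meth.beta.to_numpy(float)
    med = np.nanmedian(vals, axis=0)
    scores = np.nanmedian(np.abs(vals - med), axis=0)
    return pd.Series(scores, index=meth.beta.columns, name="mad")


def select_candidates(mads: pd.Series, percentile: float = 0.90) -> set[str]:
    """CpGs whose MAD strictly exceeds the type-7 empirical quantile."""
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    if len(mads) < 10:
        raise ValueError("need at least 10 CpGs to pick a variability decile")
    threshold = float(np.quantile(mads.to_numpy(float), percentile, method="linear"))
    return set(mads.index[mads > threshold])


def cluster_vmrs(
    candidates: set[str],
    annotation: pd.DataFrame,
    max_gap_bp: int = 1000,
    min_probes: int = 2,
    break_on_noncandidate: bool = False,
) -> list[Vmr]:
    """Chain candidate CpGs into VMRs.

    Candidates are sorted by (chrom, pos) and chained while consecutive
    candidates sit on the same chromosome at most ``max_gap_bp`` apart
    (boundary inclusive); chains shorter than ``min_probes`` are dropped.
    By default intervening non-candidate probes are ignored; with
    ``break_on_noncandidate`` any annotated probe between two consecutive
    candidates breaks the chain.
    """
    cand = annotation.loc[annotation.index.isin(candidates)].sort_values(["chrom", "pos"])
    all_pos = annotation.sort_values(["chrom", "pos"]) if break_on_noncandidate else None

    vmrs: list[Vmr] = []
    chain: list[tuple[str, str, int]] = []  # (cpg_id, chrom, pos)

    def flush() -> None:
        if len(chain) >= min_probes:
            ids = [c[0] for c in chain]
            poss = [c[2] for c in chain]
            vmrs.append(
                Vmr(
                    vmr_id=f"vmr_{len(vmrs) + 1}",
                    chrom=chain[0][1],
                    start_pos=poss[0],
                    end_pos=poss[-1],
                    member_cpgs=ids,
                    member_pos=poss,
                    mad_scores=[],
                )
            )
        chain.clear()

    for cpg, row in cand.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chain and (chrom != chain[-1][1] or pos - chain[-1][2] > max_gap_bp):
            flush()
        elif chain and break_on_noncandidate:
            between = all_pos[
                (all_pos["chrom"] == chrom)
                & (all_pos["pos"] > chain[-1][2])
                & (all_pos["pos"] < pos)
                & ~all_pos.index.isin(candidates)
            ]
            if len(between):
                flush()
        chain.append((cpg, chrom, pos))
    flush()
    return vmrs


def select_tag(vmr: Vmr, meth: MethylationMatrix) -> Vmr:
    """Fill the tagCpG (max-MAD member, position tie-break) and its
    correlation with the per-sample mean beta over all members."""
    mads = [compute_mad(meth.beta[c].to_numpy(float)) for c in vmr.member_cpgs]
    best = max(range(len(mads)), key=lambda i: (mads[i], -vmr.member_pos[i]))
    member_beta = meth.beta[vmr.member_cpgs].to_numpy(float)
    region_mean = np.nanmean(member_beta, axis=1)
    tag_beta = member_beta[:, best]
    mask = np.isfinite(tag_beta) & np.isfinite(region_mean)
    r = float(np.corrcoef(tag_beta[mask], region_mean[mask])[0, 1])
    vmr.mad_scores = mads
    vmr.tag_cpg = vmr.member_cpgs[best]
    vmr.tag_vmr_mean_r = r
    return vmr


def detect_vmrs(
    meth: MethylationMatrix,
    percentile: float = 0.90,
    max_gap_bp: int = 1000,
    min_probes: int = 2,
    break_on_noncandidate: bool = False,
) -> list[Vmr]:
    """End-to-end VMR detection: MAD -> top decile -> chaining -> tag CpGs."""
    mads = mad_scores(meth)
    candidates = select_candidates(mads, percentile)
    vmrs = cluster_vmrs(candidates, meth.annotation, max_gap_bp, min_probes, break_on_noncandidate)
    return [select_tag(v, meth) for v in vmrs]


def vmrs_to_frame(vmrs: list[Vmr]) -> pd.DataFrame:
    """Tabular summary of detected VMRs (one row per region)."""
    rows = []
    for v in vmrs:
        rows.append(
            dict(
                vmr_id=v.vmr_id,
                chrom=v.chrom,
                start=v.start_pos,
                end=v.end_pos,
                n_probes=v.n_probes,
                members=",".join(v.member_cpgs),
                tag_cpg=v.tag_cpg,
                tag_mad=max(v.mad_scores) if v.mad_scores else np.nan,
                tag_vmr_mean_r=v.tag_vmr_mean_r,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["vmr_id", "chrom", "start", "end", "n_probes", "members", "tag_cpg", "tag_mad", "tag_vmr_mean_r"],
    )
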