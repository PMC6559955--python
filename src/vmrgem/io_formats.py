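"""Reading/writing cohort data, genotype QC, and linkage-disequilibrium tools.

Genotypes are read from VCF (v4.x, GT field, biallelic records only) or from
a plain dosage matrix, and always re-oriented so that dosage counts copies of
the *minor* allele as observed in the loaded cohort: if the ALT allele
frequency exceeds 0.5, dosages are flipped 0<->2 and the allele labels
swapped.  QC applies the standard array filters (call rate, MAF, exact-test
Hardy-Weinberg equilibrium), and the LD utilities implement pairwise r^2,
greedy sliding-window pruning and proxy lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    CPG_ANNOT_COLUMNS,
    SNP_ANNOT_COLUMNS,
    CovariateTable,
    EnvironmentTable,
    GenotypeMatrix,
    MethylationMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "read_methylation",
    "write_methylation",
    "read_environment",
    "write_environment",
    "read_covariates",
    "write_covariates",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_gwas_table",
    "hwe_exact_test",
    "genotype_qc",
    "QcReport",
    "ld_r2",
    "ld_prune",
    "ld_proxies",
]


# ---------------------------------------------------------------------------
# genotype I/O


def _orient_to_minor(dosage: np.ndarray, ref: str, alt: str) -> tuple[np.ndarray, str, str, float]:
    """Flip a dosage vector so it counts minor-allele copies.

    The orientation is recomputed from the loaded cohort, not taken from the
    VCF REF/ALT: returns (dosage, ref, alt, maf) after any flip.
    """
    obs = dosage[np.isfinite(dosage)]
    if obs.size == 0:
        return dosage, ref, alt, np.nan
    alt_freq = obs.sum() / (2 * obs.size)
    if alt_freq > 0.5:
        dosage = np.where(np.isfinite(dosage), 2.0 - dosage, np.nan)
        ref, alt = alt, ref
        alt_freq = 1.0 - alt_freq
    return dosage, ref, alt, float(alt_freq)


def read_genotypes(path: str | Path, fmt: str = "vcf", annot_path: str | Path | None = None) -> GenotypeMatrix:
    """Read genotypes from ``vcf`` or dosage-``matrix`` form.

    For ``matrix`` format, ``path`` is a TSV with snp_id rows and sample
    columns and ``annot_path`` the SNP annotation TSV.  Multi-allelic VCF
    records are skipped with a warning; duplicate snp_ids raise.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "matrix":
        if annot_path is None:
            raise ValueError("matrix format requires annot_path")
        dosage = pd.read_csv(path, sep="\t", index_col=0).T  # rows SNPs -> samples x SNPs
        dosage.index = dosage.index.astype(str)
        annot = pd.read_csv(annot_path, sep="\t", index_col=0)
        annot["chrom"] = annot["chrom"].astype(str)
        annot = annot.loc[dosage.columns]
        cols = {}
        for i, snp in enumerate(dosage.columns):
            vec, ref, alt, maf = _orient_to_minor(
                dosage[snp].to_numpy(float), str(annot["ref_allele"].iloc[i]), str(annot["alt_allele"].iloc[i])
            )
            cols[snp] = vec
            annot.loc[snp, ["ref_allele", "alt_allele", "maf"]] = [ref, alt, maf]
        out = pd.DataFrame(cols, index=dosage.index)
        if "is_functional" in annot:
            annot["is_functional"] = annot["is_functional"].astype(bool)
        return GenotypeMatrix(out, annot)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows = []
    annot_rows = []
    seen: set[str] = set()
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s at %s:%d", var.ID, var.CHROM, var.POS)
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in seen:
            raise ValueError(f"duplicate snp_id {snp_id!r} in {path}")
        seen.add(snp_id)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        dosage, ref, alt, maf = _orient_to_minor(dosage, var.REF, var.ALT[0])
        is_func = bool(var.INFO.get("FUNC", 0))
        evalue = var.INFO.get("FUNC_EVALUE")
        snp_ids.append(snp_id)
        rows.append(dosage)
        annot_rows.append(
            dict(
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref_allele=ref,
                alt_allele=alt,
                maf=maf,
                is_functional=is_func,
                functional_evalue=float(evalue) if evalue is not None else np.nan,
            )
        )
    vcf.close()
    dosage = pd.DataFrame(np.array(rows).T if rows else np.empty((len(samples), 0)), index=samples, columns=snp_ids)
    annot = pd.DataFrame(annot_rows, index=pd.Index(snp_ids, name="snp_id"))
    if annot.empty:
        annot = pd.DataFrame(columns=SNP_ANNOT_COLUMNS + ["functional_evalue"], index=pd.Index([], name="snp_id"))
    return GenotypeMatrix(dosage, annot)


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCFv4.2 with GT only.

    Dosages count minor-allele copies and the minor allele is written as ALT,
    so a write -> read round trip reproduces the matrix exactly.
    """
    annot = g.annotation
    order = annot.sort_values(["chrom", "pos"]).index
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(annot.loc[order, "chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=FUNC,Number=0,Type=Flag,Description="Predicted functional variant">\n')
        fh.write('##INFO=<ID=FUNC_EVALUE,Number=1,Type=Float,Description="Functional significance e-value">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids) + "\n")
        for snp in order:
            row = annot.loc[snp]
            info_parts = []
            if bool(row["is_functional"]):
                info_parts.append("FUNC")
                ev = row.get("functional_evalue", np.nan)
                if np.isfinite(ev):
                    info_parts.append(f"FUNC_EVALUE={ev:g}")
            info = ";".join(info_parts) or "."
            gts = "\t".join(gt_map.get(v, "./.") for v in g.dosage[snp].to_numpy(float))
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['ref_allele']}\t{row['alt_allele']}"
                f"\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# tabular I/O (methylation, environments, covariates, BED, GWAS)


def read_methylation(beta_path: str | Path, annot_path: str | Path) -> MethylationMatrix:
    """Read a beta-value TSV (cpg_id rows, sample columns) plus annotation."""
    beta = pd.read_csv(beta_path, sep="\t", index_col=0).T
    beta.index = beta.index.astype(str)
    annot = pd.read_csv(annot_path, sep="\t", index_col=0)
    annot["chrom"] = annot["chrom"].astype(str)
    missing = [c for c in beta.columns if c not in annot.index]
    if missing:
        raise ValueError(f"{len(missing)} CpGs lack annotation, e.g. {missing[0]!r}")
    return MethylationMatrix(beta, annot.loc[beta.columns, CPG_ANNOT_COLUMNS])


def write_methylation(m: MethylationMatrix, beta_path: str | Path, annot_path: str | Path) -> None:
    m.beta.T.to_csv(beta_path, sep="\t", index_label="cpg_id")
    m.annotation.to_csv(annot_path, sep="\t", index_label="cpg_id")


def read_environment(path: str | Path, categories_path: str | Path) -> EnvironmentTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    cats = pd.read_csv(categories_path, sep="\t", index_col=0)["category"]
    return EnvironmentTable(values, cats.loc[values.columns])


def write_environment(env: EnvironmentTable, path: str | Path, categories_path: str | Path) -> None:
    env.values.to_csv(path, sep="\t", index_label="sample_id")
    env.categories.rename("category").to_csv(categories_path, sep="\t", index_label="env_name")


def read_covariates(path: str | Path) -> CovariateTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return CovariateTable(values)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.values.to_csv(path, sep="\t", index_label="sample_id")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED track, converting 0-based half-open to 1-based inclusive.

    Returns a frame with columns chrom, start, end (1-based inclusive) and
    name (empty string when absent).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            rows.append(
                dict(
                    chrom=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    name=parts[3] if len(parts) > 3 else "",
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed_intervals(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive intervals back out as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            name = f"\t{row['name']}" if row.get("name", "") else ""
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}{name}\n")


def read_gwas_table(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary TSV with columns snp_id, chrom, pos, p."""
    tab = pd.read_csv(path, sep="\t")
    needed = {"snp_id", "chrom", "pos", "p"}
    if not needed <= set(tab.columns):
        raise ValueError(f"GWAS table needs columns {sorted(needed)}")
    tab["chrom"] = tab["chrom"].astype(str)
    return tab


# ---------------------------------------------------------------------------
# QC


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact test for Hardy-Weinberg equilibrium (Wigginton enumeration).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * n_hom_minor + n_het
    if rare > n:  # orient to the rarer allele
        rare = 2 * n - rare
    # feasible het counts share the parity of the rare-allele count
    het_lo = rare % 2
    hets = np.arange(het_lo, rare + 1, 2)
    # unnormalised probabilities via the recurrence
    # P(het+2)/P(het) = 4 * hom_r * hom_c / ((het+2) * (het+1))
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        het = hets[i - 1]
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        logp[i] = logp[i - 1] + np.log(4.0 * hom_r * hom_c) - np.log((het + 2.0) * (het + 1.0))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_het)
    if obs >= len(hets) or hets[obs] != n_het:
        raise ValueError("observed het count incompatible with allele counts")
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


@dataclass
class QcReport:
    """Per-SNP QC outcome: snp_id -> list of failed filters."""

    n_input: int
    n_kept: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    def reasons(self, snp_id: str) -> list[str]:
        return self.removed.get(snp_id, [])


def genotype_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.98,
    min_maf: float = 0.01,
    hwe_p_floor: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs on call rate, minor-allele frequency and exact-test HWE.

    Defaults mirror common array QC (call rate >= 98%, MAF >= 1%,
    HWE p > 1e-6); all thresholds are parameters because cohorts differ.
    """
    if len(g.sample_ids) < 2:
        raise ValueError("genotype QC needs at least 2 samples")
    removed: dict[str, list[str]] = {}
    keep: list[str] = []
    vals = g.dosage.to_numpy(float)
    for j, snp in enumerate(g.snp_ids):
        col = vals[:, j]
        obs = col[np.isfinite(col)]
        reasons = []
        call_rate = obs.size / col.size
        if call_rate < min_call_rate:
            reasons.append("call_rate")
        maf = obs.sum() / (2 * obs.size) if obs.size else 0.0
        maf = min(maf, 1 - maf)
        if maf < min_maf:
            reasons.append("maf")
        n_het = int((obs == 1).sum())
        n_hom_min = int((obs == 2).sum())
        n_hom_maj = int((obs == 0).sum())
        if obs.size and hwe_exact_test(n_het, n_hom_min, n_hom_maj) <= hwe_p_floor:
            reasons.append("hwe")
        if reasons:
            removed[snp] = reasons
        else:
            keep.append(snp)
    if not keep:
        raise ValueError("all SNPs removed by QC; review thresholds")
    out = GenotypeMatrix(g.dosage[keep], g.annotation.loc[keep])
    return out, QcReport(n_input=len(g.snp_ids), n_kept=len(keep), removed=removed)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete samples; invariant to 0<->2 allele flips.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 pairwise-complete samples")
    xc = x[mask] - x[mask].mean()
    yc = y[mask] - y[mask].mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0 or vy == 0:
        raise ValueError("monomorphic")
    return float((xc @ yc) ** 2 / (vx * vy))


def _r2_matrix(vals: np.ndarray) -> np.ndarray:
    """Pairwise r^2 with pairwise-complete handling (NaN-aware)."""
    n, m = vals.shape
    out = np.empty((m, m))
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            try:
                r2 = ld_r2(vals[:, i], vals[:, j])
            except ValueError:
                r2 = 0.0
            out[i, j] = out[j, i] = r2
    return out


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.2, window: int = 50, step: int = 5) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning.

    Within each window of ``window`` consecutive surviving SNPs (per
    chromosome, position-sorted), the later SNP of any pair with r^2 >
    ``r2_max`` is removed; the window advances by ``step`` and passes repeat
    until no within-window pair exceeds the threshold.
    """
    if step > window:
        raise ValueError("step must not exceed window")
    annot = g.annotation
    order = annot.sort_values(["chrom", "pos"]).index
    keep_ids: list[str] = []
    for chrom in annot.loc[order, "chrom"].unique():
        snps = [s for s in order if annot.loc[s, "chrom"] == chrom]
        vals = g.dosage[snps].to_numpy(float)
        alive = list(range(len(snps)))
        changed = True
        while changed:
            changed = False
            start = 0
            while start < len(alive):
                win = alive[start : start + window]
                drop: set[int] = set()
                for a_i in range(len(win)):
                    if win[a_i] in drop:
                        continue
                    for b_i in range(a_i + 1, len(win)):
                        if win[b_i] in drop:
                            continue
                        try:
                            r2 = ld_r2(vals[:, win[a_i]], vals[:, win[b_i]])
                        except ValueError:
                            continue
                        if r2 > r2_max:
                            drop.add(win[b_i])
                if drop:
                    changed = True
                    alive = [i for i in alive if i not in drop]
                if start + window >= len(alive):
                    break
                start += step
        keep_ids.extend(snps[i] for i in alive)
    keep_in_order = [s for s in g.snp_ids if s in set(keep_ids)]
    return GenotypeMatrix(g.dosage[keep_in_order], g.annotation.loc[keep_in_order])


def ld_proxies(
    g: GenotypeMatrix,
    index_snps: set[str] | list[str],
    r2_min: float = 0.8,
    max_dist_bp: int = 1_000_000,
) -> dict[str, set[str]]:
    """For each index SNP, all same-chromosome SNPs within ``max_dist_bp``
    with r^2 >= ``r2_min`` (the index SNP is always included)."""
    annot = g.annotation
    unknown = [s for s in index_snps if s not in annot.index]
    if unknown:
        raise KeyError(f"index SNPs not in genotype matrix: {unknown[:5]}")
    vals = g.dosage.to_numpy(float)
    col_of = {s: i for i, s in enumerate(g.snp_ids)}
    chroms = annot["chrom"].to_numpy()
    poss = annot["pos"].to_numpy()
    out: dict[str, set[str]] = {}
    for idx in index_snps:
        i = col_of[idx]
        proxies = {idx}
        near = np.flatnonzero((chroms == chroms[i]) & (np.abs(poss - poss[i]) <= max_dist_bp))
        for j in near:
            if j == i:
                continue
            try:
                if ld_r2(vals[:, i], vals[:, j]) >= r2_min:
                    proxies.add(g.snp_ids[j])
            except ValueError:
                continue
        out[idx] = proxies
    return out
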