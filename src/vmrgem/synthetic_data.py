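"""Synthetic neonatal-methylation cohorts with planted G/E/G+E/GxE effects.

The generator emulates the processed inputs of the analysis: a beta-value
matrix with planted variably methylated regions (VMRs), LD-structured
Hardy-Weinberg genotypes, a ten-exposure prenatal-environment table with
category labels, and the standard covariates (sex, gestational age, seven
cell proportions, ancestry components).  Effects on methylation are additive
on the beta-value scale, matching how the models are fitted downstream.

Structure of a cohort:

* **Genotypes** are drawn in LD blocks: each block has an anchor haplotype
  pair drawn from Hardy-Weinberg at a block-level MAF, and every SNP in the
  block copies the anchor alleles with high fidelity (a small per-allele
  "mutation" rate), inducing within-block correlation while preserving HWE.
* **Methylation** background CpGs are nearly constant (low idiosyncratic
  noise around a per-CpG mean); planted VMR members share a per-region,
  per-sample latent factor, giving them high MAD and high within-region
  correlation.  Covariate effects are added to every CpG so that covariate
  adjustment downstream is non-trivial.
* **Environments** mix continuous (standardised Gaussian) and binary
  (fixed prevalence) exposures with mild within-category correlation.
* **Effects** are planted per :class:`EffectSpec` as mean-centred additive
  terms, so planted coefficients equal the regression estimands exactly.

Betas are clipped to [0.01, 0.99]; the clipped fraction is recorded in the
truth record and should stay well below 1% at default effect sizes.

Reproducibility: a single seed drives everything through per-matrix
substreams (genotypes, covariates, environments, methylation, annotation),
so enlarging the CpG panel does not perturb the genotypes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CovariateTable,
    EnvironmentTable,
    GenotypeMatrix,
    MethylationMatrix,
    GENE_FEATURES,
)
from . import io_formats

logger = logging.getLogger(__name__)

__all__ = [
    "EffectSpec",
    "VmrLayout",
    "CohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "single_locus_cohort",
    "write_fixture",
    "DEFAULT_ENVIRONMENTS",
]

#: (name, kind, category, prevalence-if-binary) for the default ten exposures.
#: Binary prevalences sit in the range reported for real perinatal cohorts
#: (roughly 0.04-0.34) but are generator parameters, not assertions.
DEFAULT_ENVIRONMENTS: list[tuple[str, str, str, float | None]] = [
    ("maternal_depression", "continuous", "stress_glucocorticoid", None),
    ("maternal_anxiety", "continuous", "stress_glucocorticoid", None),
    ("betamethasone", "binary", "stress_glucocorticoid", 0.04),
    ("maternal_age", "continuous", "general_maternal", None),
    ("smoking", "binary", "general_maternal", 0.08),
    ("alcohol_use", "binary", "general_maternal", 0.10),
    ("parity", "binary", "general_maternal", 0.45),
    ("maternal_bmi", "continuous", "metabolic", None),
    ("gestational_diabetes", "binary", "metabolic", 0.11),
    ("hypertension", "binary", "metabolic", 0.09),
]

#: Dirichlet concentration for the seven cord-blood cell proportions
#: (granulocyte-dominated, as in reference-based deconvolution estimates).
CELL_ALPHA = np.array([6.0, 4.0, 2.0, 3.0, 3.0, 20.0, 2.0])


@dataclass
class EffectSpec:
    """A planted effect on one VMR-member CpG.

    ``beta_g`` is the per-minor-allele effect on the beta-value scale,
    ``beta_e`` the per-unit (per-SD for continuous) environment effect and
    ``beta_gxe`` the interaction coefficient.  ``noise_sd`` optionally
    overrides the member-level idiosyncratic noise of the target CpG.
    """

    target_cpg: str
    family: str = "none"  # none | E | G | GplusE | GxE
    snp_id: str | None = None
    env_name: str | None = None
    beta_g: float = 0.0
    beta_e: float = 0.0
    beta_gxe: float = 0.0
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        needs = {
            "none": (),
            "E": ("env_name",),
            "G": ("snp_id",),
            "GplusE": ("snp_id", "env_name"),
            "GxE": ("snp_id", "env_name"),
        }
        if self.family not in needs:
            raise ValueError(f"unknown effect family {self.family!r}")
        for attr in needs[self.family]:
            if getattr(self, attr) is None:
                raise ValueError(f"family {self.family} requires {attr}")
        if self.family == "G" and self.beta_g == 0:
            raise ValueError("family G requires beta_g != 0")
        if self.family == "E" and self.beta_e == 0:
            raise ValueError("family E requires beta_e != 0")
        if self.family == "GplusE" and (self.beta_g == 0 or self.beta_e == 0):
            raise ValueError("family GplusE requires beta_g != 0 and beta_e != 0")
        if self.family == "GxE" and self.beta_gxe == 0:
            raise ValueError("family GxE requires beta_gxe != 0")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class VmrLayout:
    """One planted region: ``n_probes`` CpGs from ``start_pos`` at fixed spacing."""

    chrom: str
    start_pos: int
    n_probes: int
    probe_spacing_bp: int = 400


def default_vmr_layout(n_regions: int = 20, probes_per_region: int = 3, chrom: str = "1",
                       first_pos: int = 1_000_000, region_spacing_bp: int = 200_000,
                       probe_spacing_bp: int = 400) -> list[VmrLayout]:
    return [
        VmrLayout(chrom=chrom, start_pos=first_pos + i * region_spacing_bp,
                  n_probes=probes_per_region, probe_spacing_bp=probe_spacing_bp)
        for i in range(n_regions)
    ]


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; spec + seed is reproducible."""

    n_samples: int = 500
    n_cpgs: int = 5000
    n_snps: int = 2000
    n_envs: int = 10
    vmr_layout: list[VmrLayout] = field(default_factory=default_vmr_layout)
    ld_block_size: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_specs: list[EffectSpec] = field(default_factory=list)
    seed: int = 0
    n_mds: int = 2
    # generator noise model
    background_noise_sd: float = 0.01
    vmr_factor_sd: float = 0.05
    vmr_member_noise_sd: float = 0.02
    ld_mutation_rate: float = 0.02
    background_spacing_bp: int = 2000
    env_category_rho: float = 0.2
    functional_fraction: float = 0.3
    missing_dosage_rate: float = 0.0

    def __post_init__(self) -> None:
        n_planted = sum(v.n_probes for v in self.vmr_layout)
        if n_planted > self.n_cpgs:
            raise ValueError("vmr_layout plants more CpGs than n_cpgs")
        if not 1 <= self.n_envs <= len(DEFAULT_ENVIRONMENTS):
            raise ValueError(f"n_envs must be in 1..{len(DEFAULT_ENVIRONMENTS)}")
        if not 2 <= self.n_mds <= 5:
            raise ValueError("n_mds must be in 2..5")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth used by tests."""

    meth: MethylationMatrix
    geno: GenotypeMatrix
    env: EnvironmentTable
    cov: CovariateTable
    truth: dict

    def __iter__(self):
        return iter((self.meth, self.geno, self.env, self.cov))


def _member_ids(layout: list[VmrLayout]) -> tuple[list[str], list[str], list[int]]:
    ids, chroms, poss = [], [], []
    for i, region in enumerate(layout):
        for j in range(region.n_probes):
            ids.append(f"cg_v{i:03d}_{j}")
            chroms.append(region.chrom)
            poss.append(region.start_pos + j * region.probe_spacing_bp)
    return ids, chroms, poss


def _simulate_genotypes(spec: CohortSpec, rng: np.random.Generator,
                        pos_lo: int, pos_hi: int, chrom: str) -> GenotypeMatrix:
    n, m = spec.n_samples, spec.n_snps
    positions = np.sort(rng.integers(pos_lo, pos_hi, size=m))
    snp_ids = [f"snp_{i:05d}" for i in range(m)]
    dosage = np.empty((n, m))
    mafs = np.empty(m)
    for start in range(0, m, spec.ld_block_size):
        block = range(start, min(start + spec.ld_block_size, m))
        maf = rng.uniform(*spec.maf_range)
        anchors = rng.random((n, 2)) < maf  # two haplotypes per sample
        for j in block:
            mut = rng.random((n, 2)) < spec.ld_mutation_rate
            redraw = rng.random((n, 2)) < maf
            hap = np.where(mut, redraw, anchors)
            dosage[:, j] = hap.sum(axis=1)
            mafs[j] = maf
    if spec.missing_dosage_rate > 0:
        miss = rng.random((n, m)) < spec.missing_dosage_rate
        dosage = np.where(miss, np.nan, dosage)
    # orient to the observed minor allele
    ref = rng.choice(list("ACGT"), size=m)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    obs_maf = np.empty(m)
    for j in range(m):
        col = dosage[:, j]
        obs = col[np.isfinite(col)]
        freq = obs.sum() / (2 * obs.size) if obs.size else 0.0
        if freq > 0.5:
            dosage[:, j] = np.where(np.isfinite(col), 2 - col, np.nan)
            ref[j], alt[j] = alt[j], ref[j]
            freq = 1 - freq
        obs_maf[j] = freq
    is_func = rng.random(m) < spec.functional_fraction
    evalue = np.where(is_func, 10 ** rng.uniform(-9, np.log10(5e-5), size=m), np.nan)
    samples = [f"s{i:04d}" for i in range(n)]
    annot = pd.DataFrame(
        dict(chrom=chrom, pos=positions, ref_allele=ref, alt_allele=alt,
             maf=obs_maf, is_functional=is_func, functional_evalue=evalue),
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(pd.DataFrame(dosage, index=samples, columns=snp_ids), annot)


def _simulate_environment(spec: CohortSpec, rng: np.random.Generator,
                          samples: list[str]) -> EnvironmentTable:
    defs = DEFAULT_ENVIRONMENTS[: spec.n_envs]
    rho = spec.env_category_rho
    cat_factor = {c: rng.normal(size=spec.n_samples)
                  for c in {d[2] for d in defs}}
    cols, cats = {}, {}
    for name, kind, category, prev in defs:
        z = np.sqrt(rho) * cat_factor[category] + np.sqrt(1 - rho) * rng.normal(size=spec.n_samples)
        if kind == "continuous":
            cols[name] = z
        else:
            x = (z > stats.norm.ppf(1 - prev)).astype(float)
            if x.sum() in (0, len(x)):  # degenerate draw at small n: force 2 levels
                x[rng.integers(len(x))] = 1 - x[0]
            cols[name] = x
        cats[name] = category
    values = pd.DataFrame(cols, index=samples)
    return EnvironmentTable(values, pd.Series(cats).loc[values.columns])


def _simulate_covariates(spec: CohortSpec, rng: np.random.Generator,
                         samples: list[str]) -> CovariateTable:
    n = spec.n_samples
    cells = rng.dirichlet(CELL_ALPHA, size=n)
    data = dict(
        sex=rng.integers(0, 2, size=n).astype(float),
        gestational_age=rng.normal(39.5, 1.5, size=n),
    )
    for i in range(7):
        data[f"cell_{i + 1}"] = cells[:, i]
    for i in range(spec.n_mds):
        data[f"mds_{i + 1}"] = rng.normal(size=n)
    return CovariateTable(pd.DataFrame(data, index=samples))


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a full cohort from a :class:`CohortSpec`.

    Returns a :class:`SyntheticCohort`; iterating it yields
    (methylation, genotypes, environment, covariates).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_geno, rng_cov, rng_env, rng_meth, rng_annot = (
        np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(5)
    )

    member_ids, member_chroms, member_pos = _member_ids(spec.vmr_layout)
    n_bg = spec.n_cpgs - len(member_ids)
    bg_chrom = spec.vmr_layout[0].chrom if spec.vmr_layout else "1"
    same_chrom_end = max(
        [p for p, c in zip(member_pos, member_chroms) if c == bg_chrom], default=0
    )
    bg_start = same_chrom_end + 10_000
    bg_ids = [f"cg_b{i:05d}" for i in range(n_bg)]
    bg_pos = [bg_start + i * spec.background_spacing_bp for i in range(n_bg)]

    cpg_ids = member_ids + bg_ids
    chroms = member_chroms + [bg_chrom] * n_bg
    poss = member_pos + bg_pos

    pos_lo = max(1, (min(poss) if poss else 1) - 500_000)
    pos_hi = (max(poss) if poss else 1) + 500_000
    geno = _simulate_genotypes(spec, rng_geno, pos_lo, pos_hi, bg_chrom)
    samples = geno.sample_ids
    cov = _simulate_covariates(spec, rng_cov, samples)
    env = _simulate_environment(spec, rng_env, samples)

    n = spec.n_samples
    beta = np.empty((n, spec.n_cpgs))
    # covariate contributions (centred so CpG means are unaffected)
    cov_mat = np.column_stack(
        [
            cov.values["sex"] - 0.5,
            cov.values["gestational_age"] - 39.5,
        ]
        + [cov.values[f"cell_{i + 1}"] - cov.values[f"cell_{i + 1}"].mean() for i in range(7)]
        + [cov.values[f"mds_{i + 1}"] for i in range(spec.n_mds)]
    )
    cov_scales = np.concatenate([[0.004, 0.0015], np.full(7, 0.02), np.full(spec.n_mds, 0.002)])

    col = 0
    member_noise = {}
    for i, region in enumerate(spec.vmr_layout):
        mu = rng_meth.uniform(0.2, 0.8)
        u = rng_meth.normal(0.0, spec.vmr_factor_sd, size=n)
        loadings = rng_meth.uniform(0.7, 1.3, size=region.n_probes)
        for j in range(region.n_probes):
            coefs = rng_meth.normal(size=cov_mat.shape[1]) * cov_scales
            noise = rng_meth.normal(0.0, 1.0, size=n)
            beta[:, col] = mu + loadings[j] * u + cov_mat @ coefs
            member_noise[col] = noise  # scaled later (effect specs may override sd)
            col += 1
    for _ in range(n_bg):
        mu = rng_meth.uniform(0.15, 0.85)
        coefs = rng_meth.normal(size=cov_mat.shape[1]) * cov_scales
        beta[:, col] = mu + cov_mat @ coefs + rng_meth.normal(0.0, spec.background_noise_sd, size=n)
        col += 1

    # planted effects (mean-centred additive terms on the beta scale)
    member_index = {cid: k for k, cid in enumerate(member_ids)}
    noise_override: dict[int, float] = {}
    for eff in spec.effect_specs:
        if eff.target_cpg not in member_index:
            raise ValueError(
                f"effect target {eff.target_cpg!r} is not a planted VMR member; "
                "effects must land in plantable regions"
            )
        k = member_index[eff.target_cpg]
        term = np.zeros(n)
        d = e = None
        if eff.snp_id is not None:
            if eff.snp_id not in geno.dosage.columns:
                raise ValueError(f"unknown snp_id {eff.snp_id!r} in effect spec")
            d = geno.dosage[eff.snp_id].to_numpy(float)
            d = np.where(np.isfinite(d), d, np.nanmean(d))
        if eff.env_name is not None:
            if eff.env_name not in env.values.columns:
                raise ValueError(f"unknown env_name {eff.env_name!r} in effect spec")
            e = env.values[eff.env_name].to_numpy(float)
        if eff.beta_g and d is not None:
            term += eff.beta_g * (d - d.mean())
        if eff.beta_e and e is not None:
            term += eff.beta_e * (e - e.mean())
        if eff.beta_gxe and d is not None and e is not None:
            de = d * e
            term += eff.beta_gxe * (de - de.mean())
        beta[:, k] += term
        if eff.noise_sd is not None:
            noise_override[k] = eff.noise_sd

    for k, noise in member_noise.items():
        sd = noise_override.get(k, spec.vmr_member_noise_sd)
        beta[:, k] += sd * noise

    clipped = float(((beta < 0.01) | (beta > 0.99)).mean())
    if clipped >= 0.01:
        logger.warning("%.2f%% of beta values clipped to [0.01, 0.99]", 100 * clipped)
    beta = np.clip(beta, 0.01, 0.99)

    island_track = _island_track(rng_annot, chroms, poss)
    from .enrichment import annotate_cpg_context  # deferred: avoids import cycle at module load

    annot = pd.DataFrame(
        dict(chrom=chroms, pos=poss), index=pd.Index(cpg_ids, name="cpg_id")
    )
    annot["island_relation"] = annotate_cpg_context(annot, island_track).to_numpy()
    annot["gene_feature"] = rng_annot.choice(
        GENE_FEATURES, size=len(cpg_ids), p=[0.08, 0.08, 0.09, 0.05, 0.35, 0.05, 0.30]
    )
    meth = MethylationMatrix(pd.DataFrame(beta, index=samples, columns=cpg_ids), annot)

    truth = dict(
        seed=spec.seed,
        clipped_fraction=clipped,
        vmrs=_truth_vmrs(spec.vmr_layout, member_ids),
        effect_specs=[asdict(e) for e in spec.effect_specs],
        island_track=island_track,
    )
    return SyntheticCohort(meth=meth, geno=geno, env=env, cov=cov, truth=truth)


def _truth_vmrs(layout: list[VmrLayout], member_ids: list[str]) -> list[dict]:
    out, k = [], 0
    for region in layout:
        out.append(
            dict(chrom=region.chrom, start_pos=region.start_pos, n_probes=region.n_probes,
                 members=member_ids[k : k + region.n_probes])
        )
        k += region.n_probes
    return out


def _island_track(rng: np.random.Generator, chroms: list[str], poss: list[int]) -> pd.DataFrame:
    """Non-overlapping CpG-island intervals spanning the simulated CpG zone."""
    rows = []
    for chrom in sorted(set(chroms)):
        cpos = [p for p, c in zip(poss, chroms) if c == chrom]
        lo, hi = min(cpos) - 5000, max(cpos) + 5000
        grid = np.arange(lo, hi, 10_000)
        n_before = len(rows)
        for g in grid:
            if rng.random() < 0.5:  # half the grid cells carry an island
                start = int(g + rng.integers(0, 4000))
                length = int(rng.integers(300, 1500))
                rows.append(dict(chrom=chrom, start=max(1, start), end=start + length, name="island"))
        if len(rows) == n_before:  # tiny regions can draw no island at all
            rows.append(dict(chrom=chrom, start=max(1, int(lo)), end=max(1, int(lo)) + 500, name="island"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def single_locus_cohort(
    n_samples: int = 500,
    family: str = "none",
    beta_g: float = 0.0,
    beta_e: float = 0.0,
    beta_gxe: float = 0.0,
    noise_sd: float = 0.03,
    maf: float = 0.3,
    seed: int = 0,
    env_name: str = "maternal_depression",
) -> SyntheticCohort:
    """A minimal cohort for calibration studies: one 3-probe VMR, one cis
    SNP, one continuous environment.  The planted effect (if any) targets
    the region's first member, ``cg_v000_0``."""
    effects = []
    if family != "none":
        effects = [
            EffectSpec(
                target_cpg="cg_v000_0", family=family, snp_id="snp_00000",
                env_name=env_name if family in ("E", "GplusE", "GxE") else None,
                beta_g=beta_g, beta_e=beta_e, beta_gxe=beta_gxe, noise_sd=noise_sd,
            )
        ]
    spec = CohortSpec(
        n_samples=n_samples,
        n_cpgs=3,
        n_snps=1,
        n_envs=1,
        vmr_layout=[VmrLayout(chrom="1", start_pos=1_000_000, n_probes=3)],
        maf_range=(maf, maf),
        effect_specs=effects,
        seed=seed,
        vmr_member_noise_sd=noise_sd,
    )
    return simulate_cohort(spec)


def write_fixture(cohort: SyntheticCohort, out_dir: str | Path, force: bool = False) -> dict:
    """Write a cohort in the package's external formats plus a truth manifest.

    Emits genotypes.vcf, methylation.tsv + cpg_annotation.tsv,
    environment.tsv + environment_categories.tsv, covariates.tsv,
    islands.bed and truth.json; returns the manifest dict.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.vcf",
        "methylation": out / "methylation.tsv",
        "cpg_annotation": out / "cpg_annotation.tsv",
        "environment": out / "environment.tsv",
        "environment_categories": out / "environment_categories.tsv",
        "covariates": out / "covariates.tsv",
        "islands": out / "islands.bed",
        "truth": out / "truth.json",
    }
    io_formats.write_genotypes_vcf(cohort.geno, paths["genotypes"])
    io_formats.write_methylation(cohort.meth, paths["methylation"], paths["cpg_annotation"])
    io_formats.write_environment(cohort.env, paths["environment"], paths["environment_categories"])
    io_formats.write_covariates(cohort.cov, paths["covariates"])
    io_formats.write_bed_intervals(cohort.truth["island_track"], paths["islands"])
    manifest = dict(
        seed=cohort.truth["seed"],
        clipped_fraction=cohort.truth["clipped_fraction"],
        vmrs=cohort.truth["vmrs"],
        effect_specs=cohort.truth["effect_specs"],
        files={k: str(v) for k, v in paths.items()},
    )
    with open(paths["truth"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
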