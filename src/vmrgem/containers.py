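"""In-memory containers for cohort-level methylation, genotype and phenotype data.

All matrices are stored as pandas DataFrames indexed by sample id, one column
per feature (CpG, SNP, environment or covariate).  Genomic coordinates are
1-based inclusive throughout (Illumina-manifest / VCF convention); BED input
is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GENE_FEATURES = ("TSS200", "TSS1500", "5UTR", "FirstExon", "Body", "3UTR", "Intergenic")
ENV_CATEGORIES = ("stress_glucocorticoid", "general_maternal", "metabolic")

#: Columns required in a CpG annotation frame (indexed by cpg_id).
CPG_ANNOT_COLUMNS = ["chrom", "pos", "island_relation", "gene_feature"]
#: Columns required in a SNP annotation frame (indexed by snp_id).
SNP_ANNOT_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele", "maf", "is_functional"]


class ModelFamily(str, Enum):
    """The four competing model families for a tagCpG.

    Ordered by parsimony: exact-AIC ties are broken in favour of the simpler
    family (E < G < G+E < GxE).
    """

    E = "E"
    G = "G"
    GplusE = "G+E"
    GxE = "GxE"

    @property
    def complexity(self) -> int:
        return _FAMILY_ORDER[self]


_FAMILY_ORDER = {
    ModelFamily.E: 0,
    ModelFamily.G: 1,
    ModelFamily.GplusE: 2,
    ModelFamily.GxE: 3,
}


def _check_annotation(annot: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in annot.columns]
    if missing:
        raise ValueError(f"{what} annotation lacks columns {missing}")
    if annot.index.has_duplicates:
        dup = annot.index[annot.index.duplicated()][0]
        raise ValueError(f"duplicate {what} id {dup!r}")
    if (annot["pos"] < 1).any():
        raise ValueError(f"{what} annotation has pos < 1 (coordinates are 1-based)")


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta-value matrix with per-CpG genomic annotation.

    ``beta`` is indexed by sample id with one column per CpG; ``annotation``
    is indexed by cpg_id with columns chrom, pos, island_relation,
    gene_feature, in the same order as the beta columns.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        _check_annotation(self.annotation, CPG_ANNOT_COLUMNS, "CpG")
        if list(self.beta.columns) != list(self.annotation.index):
            raise ValueError("beta columns and CpG annotation rows must align 1:1 in order")
        vals = self.beta.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if np.isnan(vals).all(axis=0).any():
            raise ValueError("a CpG column is entirely missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix (0/1/2, NaN = missing)."""

    dosage: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        _check_annotation(self.annotation, SNP_ANNOT_COLUMNS, "SNP")
        if list(self.dosage.columns) != list(self.annotation.index):
            raise ValueError("dosage columns and SNP annotation rows must align 1:1 in order")
        vals = self.dosage.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        bad_maf = (self.annotation["maf"] < 0) | (self.annotation["maf"] > 0.5)
        if bad_maf.any():
            raise ValueError("maf must lie in [0, 0.5] after minor-allele orientation")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)


@dataclass
class EnvironmentTable:
    """Prenatal-environment matrix (samples x exposures) with category labels.

    Continuous exposures are real-valued; binary ones are coded 0/1.  Each
    exposure carries one of the three category labels used in the enrichment
    summaries (stress/glucocorticoid, general maternal, metabolic).
    """

    values: pd.DataFrame
    categories: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.categories.index):
            raise ValueError("environment columns and category labels must align")
        bad = set(self.categories) - set(ENV_CATEGORIES)
        if bad:
            raise ValueError(f"unknown environment categories {sorted(bad)}")
        for name, col in self.values.items():
            obs = col.dropna().unique()
            if len(obs) < 2:
                raise ValueError(f"environment {name!r} has fewer than 2 distinct values")
            if len(obs) == 2 and not set(np.unique(obs)) <= {0.0, 1.0}:
                raise ValueError(f"binary environment {name!r} must be coded 0/1")

    @property
    def env_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CovariateTable:
    """Regression covariates: sex, gestational age, cell proportions, ancestry.

    Columns: ``sex`` (0/1), ``gestational_age`` (weeks), ``cell_1``..``cell_7``
    (proportions in [0,1], summing to <= 1 + 1e-6 per sample) and
    ``mds_1``..``mds_k`` ancestry components (k between 2 and 5).
    """

    values: pd.DataFrame

    N_CELL_PROPS = 7

    def __post_init__(self) -> None:
        cols = self.values.columns
        needed = ["sex", "gestational_age"] + self.cell_columns
        missing = [c for c in needed if c not in cols]
        if missing:
            raise ValueError(f"covariate table lacks columns {missing}")
        if not 2 <= len(self.mds_columns) <= 5:
            raise ValueError("covariate table must carry 2-5 ancestry (mds_*) components")
        if self.values.isna().any().any():
            raise ValueError("covariate table must have no missing values")
        cells = self.values[self.cell_columns].to_numpy(float)
        if cells.min() < 0 or cells.max() > 1:
            raise ValueError("cell proportions must lie in [0, 1]")
        if (cells.sum(axis=1) > 1 + 1e-6).any():
            raise ValueError("cell proportions must sum to <= 1 per sample")

    @property
    def cell_columns(self) -> list[str]:
        return [f"cell_{i}" for i in range(1, self.N_CELL_PROPS + 1)]

    @property
    def mds_columns(self) -> list[str]:
        return sorted(
            (c for c in self.values.columns if c.startswith("mds_")),
            key=lambda c: int(c.split("_")[1]),
        )


@dataclass
class Vmr:
    """A variably methylated region: >=2 candidate CpGs with <=1 kb gaps.

    ``tag_cpg`` is the member with maximal MAD (ties broken by smallest
    position) and ``tag_vmr_mean_r`` its Pearson correlation with the
    per-sample mean beta over all members.
    """

    vmr_id: str
    chrom: str
    start_pos: int
    end_pos: int
    member_cpgs: list[str]
    member_pos: list[int]
    mad_scores: list[float]
    tag_cpg: str | None = None
    tag_vmr_mean_r: float | None = None

    def __post_init__(self) -> None:
        if len(self.member_cpgs) < 2:
            raise ValueError("a VMR needs at least 2 member CpGs")
        if self.member_pos != sorted(self.member_pos):
            raise ValueError("VMR members must be sorted by position")
        if self.tag_cpg is not None and self.tag_cpg not in self.member_cpgs:
            raise ValueError("tag_cpg must be a member of the VMR")

    @property
    def n_probes(self) -> int:
        return len(self.member_cpgs)


@dataclass
class FamilyFit:
    """Best fit within one model family for one tagCpG."""

    family: ModelFamily
    aic: float
    coef: float
    se: float
    p_raw: float
    n_used: int
    n_candidates: int
    p_bonf: float = field(init=False)
    snp_id: str | None = None
    env_name: str | None = None

    def __post_init__(self) -> None:
        self.p_bonf = min(1.0, self.p_raw * self.n_candidates)


@dataclass
class ModelVerdict:
    """Outcome of the four-family AIC competition for one tagCpG."""

    tag_cpg: str
    winner: ModelFamily | None
    family_bests: dict[ModelFamily, FamilyFit]
    delta_aic: float | None
    no_cis_snp: bool = False
    p_fdr: float | None = None

    @property
    def winner_fit(self) -> FamilyFit | None:
        return None if self.winner is None else self.family_bests[self.winner]


@dataclass
class EnrichmentResult:
    """A 2x2 exact-test outcome (set membership x category membership)."""

    label: str
    set_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float
    direction: str
    odds_ratio_cmle: float | None = None


@dataclass
class MetaResult:
    """Random-effects meta-analysis of one tagCpG-SNP-environment combination."""

    tag_cpg: str
    snp_id: str
    env_name: str
    family: ModelFamily
    beta_pooled: float
    se_pooled: float
    p_meta: float
    tau2: float
    q_stat: float
    same_direction: bool
    p_discovery: float
    p_meta_fdr: float | None = None
    replicated: bool | None = None
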