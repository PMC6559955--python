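import numpy as np
import pandas as pd
import pytest

from vmrgem.containers import GenotypeMatrix


def make_genotype_matrix(dosage, positions=None, chrom="1", is_functional=None,
                         snp_ids=None, sample_ids=None):
    """Build a GenotypeMatrix from a raw samples x SNPs dosage array."""
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    snp_ids = snp_ids or [f"snp_{j:04d}" for j in range(m)]
    sample_ids = sample_ids or [f"s{i:04d}" for i in range(n)]
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    mafs = []
    for j in range(m):
        col = dosage[:, j]
        obs = col[np.isfinite(col)]
        f = obs.sum() / (2 * obs.size) if obs.size else 0.0
        mafs.append(min(f, 1 - f))
    annot = pd.DataFrame(
        dict(
            chrom=chrom if isinstance(chrom, list) else [chrom] * m,
            pos=positions,
            ref_allele="A",
            alt_allele="G",
            maf=mafs,
            is_functional=is_functional if is_functional is not None else [False] * m,
            functional_evalue=np.nan,
        ),
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(pd.DataFrame(dosage, index=sample_ids, columns=snp_ids), annot)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
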