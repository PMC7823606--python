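import numpy as np
import pandas as pd
import pytest

from grsmr.datatypes import GenotypeMatrix, PhenotypeTable, SnpMeta


def make_snp(snp_id, maf=0.2, info=None, ea="A", oa="G", chrom="1", pos=100):
    return SnpMeta(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                   other_allele=oa, maf=maf, info=info)


def genotypes_from_array(dosages, mafs=None, infos=None):
    """GenotypeMatrix around a literal dosage array, metadata filled in."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = []
    for j in range(m):
        p = dosages[:, j].mean() / 2.0
        maf = min(p, 1 - p) if mafs is None else mafs[j]
        snps.append(make_snp(f"rs{j + 1:03d}", maf=maf,
                             info=None if infos is None else infos[j], pos=j + 1))
    return GenotypeMatrix(dosages, snps, [f"S{i}" for i in range(n)])


def phenotypes_from_arrays(apn_raw, dr, **covariates):
    df = pd.DataFrame({"subject_id": [f"S{i}" for i in range(len(apn_raw))],
                       "apn_raw": apn_raw, "dr": dr})
    for name, vals in covariates.items():
        df[name] = vals
    return PhenotypeTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cohort(rng):
    """A 400-subject, 6-SNP cohort with a real exposure signal."""
    n, m = 400, 6
    dosages = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    g = genotypes_from_array(dosages)
    lin = 0.3 * (dosages[:, 0] - 0.6) + rng.standard_normal(n)
    apn = np.exp(2.5 + 0.8 * (lin - lin.mean()) / lin.std())
    dr = rng.binomial(1, 0.35, size=n)
    return g, phenotypes_from_arrays(apn, dr)
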