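import numpy as np
import pandas as pd
import pytest

from paleoburden import synthdata
from paleoburden.io_formats import GenotypePanel, GwasTable


def make_panel(
    dosage,
    ploidy,
    ages=None,
    ref_alt=None,
    continents=None,
    hg=None,
    snp_ids=None,
):
    """Hand-build a small GenotypePanel for unit tests."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ploidy = np.asarray(ploidy, dtype=int)
    if snp_ids is None:
        snp_ids = [f"rs{j + 1}" for j in range(m)]
    if ref_alt is None:
        ref_alt = [("A", "G")] * m
    variants = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": (np.arange(m) + 1) * 1000,
            "ref": [r for r, _ in ref_alt],
            "alt": [a for _, a in ref_alt],
        }
    )
    sample_ids = [f"S{i + 1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_bp": np.zeros(n) if ages is None else np.asarray(ages, float),
            "continent": "Europe" if continents is None else continents,
            "hg_ancestry": np.nan if hg is None else np.asarray(hg, float),
        }
    )
    return GenotypePanel(
        sample_ids=sample_ids,
        variants=variants,
        dosage=dosage,
        ploidy=ploidy,
        meta=meta,
    )


def make_gwas_df(records):
    """records: list of (snp_id, pos, ea, oa, beta, pvalue, maf)."""
    return GwasTable(
        pd.DataFrame(
            [
                {
                    "snp_id": r[0],
                    "chrom": "1",
                    "pos": r[1],
                    "effect_allele": r[2],
                    "other_allele": r[3],
                    "beta": r[4],
                    "pvalue": r[5],
                    "maf": r[6],
                }
                for r in records
            ]
        )
    )


@pytest.fixture
def small_config():
    return synthdata.SynthConfig(n_snps=120, missing_rate=0.3, samples_per_leaf=3)


@pytest.fixture
def small_gwas(small_config):
    gwas, truth = synthdata.make_gwas(small_config, seed=11)
    return gwas, truth


@pytest.fixture
def small_panel(small_config, small_gwas):
    gwas, _ = small_gwas
    return synthdata.make_ancient_panel(small_config, gwas, seed=12)
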