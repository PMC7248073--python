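"""Risk-allele orientation and the per-individual mean risk-allele dosage.

The burden statistic for individual *i* is the plain average of risk-allele
copy counts over the SNPs with a genotype call in that individual:

    f_i = (1/J_i) * sum_j G_ij

where G_ij counts copies of the risk allele. No division by ploidy is
performed unless ``normalise`` is on, so diploid burdens live in [0, 2] and
pseudo-haploid burdens in [0, 1]; mixed-ploidy panels therefore require
``normalise=True`` to be comparable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from paleoburden.io_formats import GenotypePanel, GwasTable

logger = logging.getLogger(__name__)


def orient_risk(gwas: GwasTable) -> pd.DataFrame:
    """Map each SNP to its risk allele (the allele that increases log-odds).

    Returns a frame indexed by snp_id with columns risk_allele, other_allele,
    risk_beta (= |beta|), pvalue and maf. SNPs with beta exactly 0 have no
    defined risk allele and are excluded.
    """
    df = gwas.df
    nonzero = df["beta"] != 0.0
    n_ambiguous = int((~nonzero).sum())
    if n_ambiguous:
        logger.warning("orient_risk: excluded %d SNPs with beta == 0", n_ambiguous)
    df = df.loc[nonzero]
    pos = df["beta"] > 0
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].to_numpy(),
            "risk_allele": np.where(pos, df["effect_allele"], df["other_allele"]),
            "other_allele": np.where(pos, df["other_allele"], df["effect_allele"]),
            "risk_beta": df["beta"].abs().to_numpy(),
            "pvalue": df["pvalue"].to_numpy(),
            "maf": df["maf"].to_numpy(),
        }
    ).set_index("snp_id", drop=False)
    return out


def oriented_dosage(
    panel: GenotypePanel, risk: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix re-oriented so entries count copies of the risk allele.

    Returns ``(G, used)`` where ``G`` is samples x kept-variants with nan for
    missing calls and ``used`` is the boolean mask over panel variants that
    were matched to the orientation table. A panel variant is dropped when it
    is absent from ``risk`` or when its REF/ALT pair does not consist of the
    risk and other alleles.
    """
    v = panel.variants
    used = np.zeros(panel.n_variants, dtype=bool)
    flip = np.zeros(panel.n_variants, dtype=bool)
    risk_alleles = risk["risk_allele"]
    other_alleles = risk["other_allele"]
    for j, snp_id in enumerate(v["snp_id"]):
        if snp_id not in risk.index:
            continue
        ra = risk_alleles[snp_id]
        oa = other_alleles[snp_id]
        ref, alt = v.at[j, "ref"], v.at[j, "alt"]
        if {ref, alt} != {ra, oa}:
            logger.warning(
                "allele mismatch for %s: panel %s/%s vs GWAS %s/%s; dropped",
                snp_id, ref, alt, ra, oa,
            )
            continue
        used[j] = True
        flip[j] = alt != ra  # dosage counts ALT; flip when risk is REF
    g = panel.dosage[:, used].astype(float)
    fl = flip[used]
    ploidy = panel.ploidy[:, None].astype(float)
    g[:, fl] = ploidy - g[:, fl]
    return g, used


def f_adhd(
    panel: GenotypePanel,
    risk: pd.DataFrame,
    normalise: bool = False,
) -> pd.DataFrame:
    """Per-individual mean risk-allele dosage over called SNPs.

    Returns one row per retained sample: sample_id, age_bp, continent,
    hg_ancestry, J (number of called risk SNPs) and f_adhd. Samples with no
    called risk SNP are excluded with a warning. With ``normalise`` on,
    dosages are divided by sample ploidy first, giving f in [0, 1].
    """
    if not normalise and len(set(panel.ploidy.tolist())) > 1:
        raise ValueError(
            "mixed-ploidy panel: raw burdens are not comparable across "
            "ploidies; use normalise=True"
        )
    g, _ = oriented_dosage(panel, risk)
    if g.shape[1] == 0:
        raise ValueError("no panel variant could be matched to the orientation")
    if normalise:
        g = g / panel.ploidy[:, None]
    called = ~np.isnan(g)
    j_counts = called.sum(axis=1)
    keep = j_counts >= 1
    if not keep.all():
        logger.warning(
            "f_adhd: excluded %d samples with zero called risk SNPs",
            int((~keep).sum()),
        )
    with np.errstate(invalid="ignore"):
        f = np.nansum(g, axis=1) / np.maximum(j_counts, 1)
    out = panel.meta.copy()
    out["J"] = j_counts
    out["f_adhd"] = f
    return out.loc[keep].reset_index(drop=True)


def population_f_adhd(
    panel: GenotypePanel,
    risk: pd.DataFrame,
    group_by: str = "continent",
    normalise: bool = False,
) -> pd.DataFrame:
    """Per-individual burden with a ``group`` column for between-group tests."""
    res = f_adhd(panel, risk, normalise=normalise)
    res = res.rename(columns={group_by: "group"}) if group_by != "group" else res
    if "group" not in res.columns:
        raise KeyError(f"metadata has no column {group_by!r}")
    return res
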