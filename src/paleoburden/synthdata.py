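"""Synthetic generators for every input the pipeline consumes.

Each generator is a pure function of (config, seed). Alongside the analysis
inputs, generators return "truth" sidecars (true risk allele, true category,
simulation parameters) that tests use for end-to-end recovery checks; the
analysis code never reads them.

Positions are laid on a single synthetic chromosome at a fixed spacing
(default 1 kb, giving several 1-Mb blocks for the block-flip null).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from paleoburden import abcdl
from paleoburden.io_formats import (
    AncestralMap,
    GenotypePanel,
    GwasTable,
)

BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Knobs for all synthetic generators; see field comments for semantics."""

    n_snps: int = 400
    # minor-allele frequency spectrum: Beta(a, b) scaled to (0, 0.5], truncated
    maf_beta_a: float = 0.5
    maf_beta_b: float = 0.5
    maf_min: float = 0.01
    # effect sizes: null SNPs ~ Normal(0, beta_sd); a fraction of SNPs is made
    # genome-wide significant with inflated |beta| coherent with p <= 1e-8
    beta_sd: float = 0.01
    frac_significant: float = 0.05
    gwas_n: int = 50000  # effective sample size in the Wald p construction
    # ancient-panel dynamics (per-generation trend and drift on the tree)
    gamma: float = 0.0
    d: float = 1e-6
    tree: abcdl.SampleTree | None = None
    samples_per_leaf: int = 4
    missing_rate: float = 0.4
    pseudo_haploid: bool = True
    age_jitter: float = 250.0
    f0_bounds: tuple[float, float] = (0.05, 0.95)
    # ancestral-state enrichment: P(ancestral == risk) per category
    ancestral_enrichment_sig: float = 0.5
    ancestral_enrichment_null: float = 0.5
    # SDS coupling: mean tSDS of the most significant p-bin is -sds_coupling
    sds_coupling: float = 0.0
    sds_bin_size: int = 1000
    # archaic tags: fraction of SNPs tagged, P(archaic allele == risk),
    # P(tag is Altai-homozygous)
    tag_fraction: float = 0.25
    tag_enrichment: float = 0.5
    tag_altai_prob: float = 0.9
    # genome layout
    chrom: str = "1"
    position_spacing: int = 1000

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in (
            "frac_significant",
            "missing_rate",
            "ancestral_enrichment_sig",
            "ancestral_enrichment_null",
            "tag_fraction",
            "tag_enrichment",
            "tag_altai_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)

    def get_tree(self) -> abcdl.SampleTree:
        return self.tree if self.tree is not None else abcdl.default_tree()


def _draw_maf(config: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    maf = rng.beta(config.maf_beta_a, config.maf_beta_b, size=n) / 2.0
    while True:
        low = maf < config.maf_min
        if not low.any():
            return maf
        maf[low] = rng.beta(config.maf_beta_a, config.maf_beta_b, low.sum()) / 2.0


def make_gwas(
    config: SynthConfig, seed: int = 0
) -> tuple[GwasTable, pd.DataFrame]:
    """Synthetic GWAS summary table plus truth sidecar.

    p-values follow a Wald construction: z = beta / se with
    se = 1/sqrt(2 N maf (1-maf)). The significant fraction gets |z| drawn
    uniformly in [6, 12] (hence p <= 1e-8) and beta back-solved from z, so
    effect size, MAF and p stay mutually coherent.
    """
    rng = np.random.default_rng(seed)
    n = config.n_snps
    snp_id = np.array([f"rs{i + 1}" for i in range(n)])
    pos = (np.arange(n) + 1) * config.position_spacing
    # two distinct alleles per SNP (A/T and C/G pairs arise naturally)
    first = rng.integers(0, 4, size=n)
    offset = rng.integers(1, 4, size=n)
    ea = BASES[first]
    oa = BASES[(first + offset) % 4]
    maf = _draw_maf(config, n, rng)
    se = 1.0 / np.sqrt(2.0 * config.gwas_n * maf * (1.0 - maf))
    beta = rng.normal(0.0, config.beta_sd, size=n)
    sig = rng.random(n) < config.frac_significant
    z_sig = rng.uniform(6.0, 12.0, size=int(sig.sum()))
    sign = rng.choice([-1.0, 1.0], size=int(sig.sum()))
    beta[sig] = sign * z_sig * se[sig]
    z = beta / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.clip(pvalue, np.nextafter(0, 1), 1.0)
    df = pd.DataFrame(
        {
            "snp_id": snp_id,
            "chrom": config.chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "pvalue": pvalue,
            "maf": maf,
        }
    )
    risk_allele = np.where(beta > 0, ea, oa)
    category = np.where(
        pvalue <= 1e-8,
        "significant",
        np.where(pvalue >= 0.9, "non_associated", "intermediate"),
    )
    truth = pd.DataFrame(
        {
            "snp_id": snp_id,
            "true_risk_allele": risk_allele,
            "category": category,
        }
    )
    return GwasTable(df), truth


def make_ancestral(
    config: SynthConfig,
    gwas: GwasTable,
    truth: pd.DataFrame,
    seed: int = 0,
) -> AncestralMap:
    """Ancestral-allele map with category-dependent risk enrichment.

    In the significant category the ancestral allele equals the true risk
    allele with probability ``ancestral_enrichment_sig``; everywhere else
    with ``ancestral_enrichment_null``.
    """
    rng = np.random.default_rng(seed)
    t = truth.set_index("snp_id")
    alleles: dict[str, str] = {}
    coords: dict[str, tuple[str, int]] = {}
    for row in gwas.df.itertuples():
        tr = t.loc[row.snp_id]
        prob = (
            config.ancestral_enrichment_sig
            if tr["category"] == "significant"
            else config.ancestral_enrichment_null
        )
        risk = tr["true_risk_allele"]
        other = row.other_allele if risk == row.effect_allele else row.effect_allele
        alleles[row.snp_id] = risk if rng.random() < prob else other
        coords[row.snp_id] = (str(row.chrom), int(row.pos))
    return AncestralMap(alleles=alleles, coords=coords)


def _hg_ancestry(age_bp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Logistic function of age plus noise: older samples more HG-like."""
    z = (np.asarray(age_bp, float) - 20000.0) / 5000.0
    hg = 1.0 / (1.0 + np.exp(-z)) + rng.normal(0.0, 0.1, size=len(age_bp))
    return np.clip(hg, 0.0, 1.0)


def make_ancient_panel(
    config: SynthConfig,
    gwas: GwasTable,
    seed: int = 0,
) -> GenotypePanel:
    """Dated panel whose risk-allele frequencies evolved on the sample tree.

    Root risk-allele frequencies are drawn per locus from ``f0_bounds`` and
    propagated down the tree with (gamma, d); individuals at each leaf draw
    pseudo-haploid (Bernoulli) or diploid (Binomial) risk-allele dosages from
    the leaf frequency, which are then re-encoded as ALT dosages against
    randomly assigned REF/ALT labels. Missingness is i.i.d.; sample ages are
    the leaf ages with uniform jitter.
    """
    rng = np.random.default_rng(seed)
    tree = config.get_tree()
    n = config.n_snps
    f0 = rng.uniform(*config.f0_bounds, size=(1, n))
    leaf_freqs: dict[int, np.ndarray] = {}
    # single simulation pass but we need per-leaf per-locus frequencies,
    # not just means, so walk the tree here
    freqs = {0: f0[0]}
    for i in range(1, tree.n_nodes):
        p = int(tree.parent[i])
        freqs[i] = abcdl.simulate_branch(
            freqs[p], config.gamma, config.d, float(tree.dt[i]), rng
        )
    for li in tree.leaf_indices:
        leaf_freqs[int(li)] = freqs[int(li)]

    if tree.ages_bp is not None:
        leaf_ages = {int(i): float(tree.ages_bp[i]) for i in tree.leaf_indices}
    else:  # derive ages from depths: deepest leaf is the youngest
        depth = tree.depths()
        max_d = depth[tree.leaf_indices].max()
        leaf_ages = {
            int(i): (max_d - depth[i]) * abcdl.GENERATION_TIME_YEARS
            for i in tree.leaf_indices
        }

    risk_allele = np.where(
        gwas.df["beta"] > 0, gwas.df["effect_allele"], gwas.df["other_allele"]
    )
    protect_allele = np.where(
        gwas.df["beta"] > 0, gwas.df["other_allele"], gwas.df["effect_allele"]
    )
    risk_is_alt = rng.random(n) < 0.5
    ref = np.where(risk_is_alt, protect_allele, risk_allele)
    alt = np.where(risk_is_alt, risk_allele, protect_allele)

    ploidy_val = 1 if config.pseudo_haploid else 2
    sample_ids: list[str] = []
    ages: list[float] = []
    rows: list[np.ndarray] = []
    for li in tree.leaf_indices:
        name = tree.names[li]
        f = leaf_freqs[int(li)]
        for k in range(config.samples_per_leaf):
            sample_ids.append(f"{name}_{k}")
            ages.append(
                max(
                    0.0,
                    leaf_ages[int(li)]
                    + rng.uniform(-config.age_jitter, config.age_jitter),
                )
            )
            dosage_risk = rng.binomial(ploidy_val, f).astype(float)
            dosage_alt = np.where(risk_is_alt, dosage_risk, ploidy_val - dosage_risk)
            miss = rng.random(n) < config.missing_rate
            dosage_alt[miss] = np.nan
            rows.append(dosage_alt)

    dosage = np.vstack(rows)
    ages_arr = np.array(ages)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_bp": ages_arr,
            "continent": "Europe",
            "hg_ancestry": _hg_ancestry(ages_arr, rng),
        }
    )
    variants = pd.DataFrame(
        {
            "snp_id": gwas.df["snp_id"],
            "chrom": gwas.df["chrom"],
            "pos": gwas.df["pos"],
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypePanel(
        sample_ids=sample_ids,
        variants=variants,
        dosage=dosage,
        ploidy=np.full(len(sample_ids), ploidy_val),
        meta=meta,
    )


def make_modern_panels(
    config: SynthConfig,
    gwas: GwasTable,
    groups: dict[str, float],
    n_per_group: int = 100,
    seed: int = 0,
) -> GenotypePanel:
    """Diploid panel of modern groups with per-group risk-frequency offsets.

    Each SNP gets a base risk-allele frequency from ``f0_bounds``; group g
    draws Binomial(2, clip(base + offset_g)) dosages per individual. Group
    labels go in the continent metadata column; age_bp is 0.
    """
    rng = np.random.default_rng(seed)
    n = config.n_snps
    base = rng.uniform(*config.f0_bounds, size=n)
    risk_allele = np.where(
        gwas.df["beta"] > 0, gwas.df["effect_allele"], gwas.df["other_allele"]
    )
    protect_allele = np.where(
        gwas.df["beta"] > 0, gwas.df["other_allele"], gwas.df["effect_allele"]
    )
    risk_is_alt = rng.random(n) < 0.5
    ref = np.where(risk_is_alt, protect_allele, risk_allele)
    alt = np.where(risk_is_alt, risk_allele, protect_allele)

    sample_ids: list[str] = []
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for group in sorted(groups):
        freq = np.clip(base + groups[group], 0.0, 1.0)
        for k in range(n_per_group):
            sample_ids.append(f"{group}_{k}")
            labels.append(group)
            dosage_risk = rng.binomial(2, freq).astype(float)
            rows.append(np.where(risk_is_alt, dosage_risk, 2.0 - dosage_risk))
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_bp": 0.0,
            "continent": labels,
            "hg_ancestry": np.nan,
        }
    )
    variants = pd.DataFrame(
        {
            "snp_id": gwas.df["snp_id"],
            "chrom": gwas.df["chrom"],
            "pos": gwas.df["pos"],
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypePanel(
        sample_ids=sample_ids,
        variants=variants,
        dosage=np.vstack(rows),
        ploidy=np.full(len(sample_ids), 2),
        meta=meta,
    )


def make_sds(
    config: SynthConfig, gwas: GwasTable, seed: int = 0
) -> pd.DataFrame:
    """SDS table with tunable coupling to GWAS significance.

    With coupling c, the ``sds_bin_size`` most significant SNPs (by GWAS p,
    ties by position) have tSDS ~ Normal(-c, 1) — so the top-significance bin
    has mean tSDS -c — and the coupling decays exponentially (scale one bin)
    for the remaining SNPs, giving a monotone signal-vs-significance profile.
    The reported SDS is signed to a randomly chosen reference allele.
    """
    rng = np.random.default_rng(seed)
    df = gwas.df
    n = len(df)
    order = np.lexsort(
        (df["pos"].to_numpy(), df["chrom"].astype(str).to_numpy(),
         df["pvalue"].to_numpy())
    )
    b = min(config.sds_bin_size, n)
    rank = np.empty(n, dtype=float)
    rank[order] = np.arange(n)
    decay = np.exp(-np.maximum(0.0, rank - b + 1) / b)
    tsds = rng.normal(-config.sds_coupling * decay, 1.0)
    risk = np.where(df["beta"] > 0, df["effect_allele"], df["other_allele"])
    other = np.where(df["beta"] > 0, df["other_allele"], df["effect_allele"])
    ref_is_risk = rng.random(n) < 0.5
    ref_allele = np.where(ref_is_risk, risk, other)
    sds = np.where(ref_is_risk, tsds, -tsds)
    return pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["chrom"],
            "pos": df["pos"],
            "sds_reference_allele": ref_allele,
            "sds": sds,
        }
    )


def make_tags(
    config: SynthConfig, gwas: GwasTable, seed: int = 0
) -> pd.DataFrame:
    """Archaic tag-SNP table with tunable risk enrichment.

    A ``tag_fraction`` of SNPs is tagged; the archaic allele equals the risk
    allele with probability ``tag_enrichment``; each tag is Altai-homozygous
    with probability ``tag_altai_prob``.
    """
    rng = np.random.default_rng(seed)
    df = gwas.df
    n = len(df)
    n_tags = max(1, int(round(config.tag_fraction * n)))
    idx = rng.choice(n, size=n_tags, replace=False)
    idx.sort()
    sub = df.iloc[idx]
    risk = np.where(sub["beta"] > 0, sub["effect_allele"], sub["other_allele"])
    other = np.where(sub["beta"] > 0, sub["other_allele"], sub["effect_allele"])
    is_risk = rng.random(n_tags) < config.tag_enrichment
    return pd.DataFrame(
        {
            "snp_id": sub["snp_id"].to_numpy(),
            "archaic_allele": np.where(is_risk, risk, other),
            "altai_homozygous": rng.random(n_tags) < config.tag_altai_prob,
        }
    )


def write_all(config: SynthConfig, outdir: str | Path, seed: int = 0) -> dict:
    """Generate every input and write it under ``outdir``; returns the paths.

    Stage seeds are derived deterministically from the master seed so each
    generator stays a pure function of (config, seed).
    """
    from paleoburden import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(6)]

    gwas, truth = make_gwas(config, seed=seeds[0])
    panel = make_ancient_panel(config, gwas, seed=seeds[1])
    modern = make_modern_panels(
        config, gwas, groups={"Africa": 0.02, "Europe": 0.0}, seed=seeds[2]
    )
    ancestral = make_ancestral(config, gwas, truth, seed=seeds[3])
    sds = make_sds(config, gwas, seed=seeds[4])
    tags = make_tags(config, gwas, seed=seeds[5])

    paths = {
        "gwas": outdir / "gwas.tsv",
        "truth": outdir / "truth.tsv",
        "ancient_vcf": outdir / "ancient.vcf",
        "ancient_meta": outdir / "ancient_meta.tsv",
        "modern_vcf": outdir / "modern.vcf",
        "modern_meta": outdir / "modern_meta.tsv",
        "ancestral": outdir / "ancestral.bed",
        "sds": outdir / "sds.tsv",
        "tags": outdir / "tags.tsv",
    }
    io_formats.write_gwas_summary(gwas, paths["gwas"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    io_formats.write_genotypes_vcf(panel, paths["ancient_vcf"], paths["ancient_meta"])
    io_formats.write_genotypes_vcf(modern, paths["modern_vcf"], paths["modern_meta"])
    io_formats.write_ancestral_bed(ancestral, paths["ancestral"])
    io_formats.write_sds_table(sds, paths["sds"])
    io_formats.write_tag_snps(tags, paths["tags"])
    return {k: str(v) for k, v in paths.items()}
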