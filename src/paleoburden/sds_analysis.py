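"""Recent polygenic-adaptation test via trait-aligned singleton density scores.

tSDS is the SDS value signed to the trait risk allele. SNPs are sorted by
GWAS p-value (ties broken by chrom, pos), partitioned into consecutive bins
of fixed size, and the Spearman rank correlation is taken between the bin
mean tSDS and the bin mean p-value. The null flips the tSDS sign of all SNPs
in each 1-Mb genomic block together with probability 0.5; because sign flips
leave the p-ordering untouched, the binning is fixed across draws. The null
correlations are summarised by a fitted normal and the one-tail p is the
upper-tail probability at the observed correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from paleoburden.trend_tests import NullDistribution

MB = 1_000_000


def align_tsds(sds: pd.DataFrame, risk: pd.DataFrame) -> pd.DataFrame:
    """Sign SDS values to the trait risk allele.

    ``sds`` needs columns snp_id, chrom, pos, sds_reference_allele, sds;
    ``risk`` is the orientation frame from :func:`paleoburden.burden.orient_risk`.
    SNPs absent from either table, or whose SDS reference allele matches
    neither GWAS allele, are dropped. Returns snp_id, chrom, pos, tsds,
    pvalue.
    """
    cols = risk[["snp_id", "risk_allele", "other_allele", "pvalue"]]
    merged = sds.merge(cols.reset_index(drop=True), on="snp_id", how="inner")
    ref = merged["sds_reference_allele"]
    is_risk = ref == merged["risk_allele"]
    is_other = ref == merged["other_allele"]
    merged = merged[is_risk | is_other].copy()
    sign = np.where(merged["sds_reference_allele"] == merged["risk_allele"], 1.0, -1.0)
    merged["tsds"] = sign * merged["sds"].to_numpy(float)
    return merged[["snp_id", "chrom", "pos", "tsds", "pvalue"]].reset_index(drop=True)


def _sorted_bins(df: pd.DataFrame, bin_size: int) -> np.ndarray:
    """Positional bin assignment after sorting by (pvalue, chrom, pos)."""
    pval = df["pvalue"].to_numpy(float)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(np.int64)
    order = np.lexsort((pos, chrom, pval))
    bins = np.empty(len(df), dtype=int)
    bins[order] = np.arange(len(df)) // bin_size
    return bins


def binned_spearman(
    df: pd.DataFrame, bin_size: int = 1000, per_snp: bool = False
) -> tuple[float, int]:
    """Spearman correlation between binned tSDS and GWAS p-value.

    SNPs are sorted by p ascending and cut into consecutive bins of
    ``bin_size`` (the final partial bin is retained). By default the
    correlation is between bin mean tSDS and bin mean p; with ``per_snp`` the
    correlation is between each SNP's tSDS and its bin mean p. Returns
    (rho, n_bins).
    """
    if df.empty:
        raise ValueError("no SNPs")
    bins = _sorted_bins(df.reset_index(drop=True), bin_size)
    n_bins = int(bins.max()) + 1
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    tsds = df["tsds"].to_numpy(float)
    pval = df["pvalue"].to_numpy(float)
    mean_t = np.bincount(bins, weights=tsds) / np.bincount(bins)
    mean_p = np.bincount(bins, weights=pval) / np.bincount(bins)
    if per_snp:
        rho = stats.spearmanr(tsds, mean_p[bins]).statistic
    else:
        rho = stats.spearmanr(mean_t, mean_p).statistic
    rho = 0.0 if np.isnan(rho) else float(rho)
    return rho, n_bins


def block_index(chrom: np.ndarray, pos: np.ndarray, block_size: int = MB) -> np.ndarray:
    """Genomic block ids: [k*block, (k+1)*block) per chromosome."""
    chrom = np.asarray(chrom).astype(str)
    pos = np.asarray(pos, dtype=np.int64)
    key = pd.Series([f"{c}:{p // block_size}" for c, p in zip(chrom, pos)])
    return key.astype("category").cat.codes.to_numpy()


def block_flip_null(
    df: pd.DataFrame,
    bin_size: int = 1000,
    block_size: int = MB,
    n: int = 1000,
    seed: int = 0,
    per_snp: bool = False,
) -> NullDistribution:
    """Block-flip null for the binned Spearman correlation.

    Each draw flips the tSDS sign of every SNP in a 1-Mb block together with
    probability 0.5 and recomputes the correlation with the same bins. The n
    null correlations are fitted with a normal distribution and the one-tail
    p is P(N(mu, sigma) > rho_obs).
    """
    df = df.reset_index(drop=True)
    tsds = df["tsds"].to_numpy(float)
    if np.all(tsds == 0):
        raise ValueError("degenerate input: all tSDS are zero")
    blocks = block_index(df["chrom"].to_numpy(), df["pos"].to_numpy(), block_size)
    n_blocks = int(blocks.max()) + 1
    if n_blocks < 2:
        raise ValueError("need at least 2 genomic blocks")
    rho_obs, _ = binned_spearman(df, bin_size, per_snp=per_snp)

    bins = _sorted_bins(df, bin_size)
    n_bins = int(bins.max()) + 1
    pval = df["pvalue"].to_numpy(float)
    bin_counts = np.bincount(bins)
    mean_p = np.bincount(bins, weights=pval) / bin_counts
    # M[b, k] = sum of tsds over SNPs in p-bin b and genomic block k, so a
    # draw's bin means are (M @ signs) / bin_counts
    m = np.zeros((n_bins, n_blocks))
    np.add.at(m, (bins, blocks), tsds)

    rng = np.random.default_rng(seed)
    signs = np.where(rng.random((n_blocks, n)) < 0.5, -1.0, 1.0)
    bin_means = (m @ signs) / bin_counts[:, None]
    rank_p = stats.rankdata(mean_p)
    draws = np.empty(n)
    for k in range(n):
        if per_snp:
            flipped = tsds * signs[blocks, k]
            r = stats.spearmanr(flipped, mean_p[bins]).statistic
        else:
            r = stats.spearmanr(bin_means[:, k], rank_p).statistic
        draws[k] = 0.0 if np.isnan(r) else r
    mu, sigma = float(np.mean(draws)), float(np.std(draws, ddof=1))
    if sigma == 0:
        raise ValueError("degenerate null: zero variance")
    p = float(stats.norm.sf(rho_obs, loc=mu, scale=sigma))
    # p from a fitted normal can sit below the empirical floor; keep the
    # container invariant by flooring at 1/(n+1)
    p = min(max(p, 1.0 / (n + 1)), 1.0)
    return NullDistribution(
        observed=rho_obs,
        null_draws=draws,
        p_empirical=p,
        method="block_flip",
        n_draws=n,
        seed=seed,
    )
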