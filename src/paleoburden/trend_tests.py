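"""Temporal-trend and covariate analyses of the burden statistic.

Sign convention: all trend statistics correlate the burden with calendar
time, i.e. with ``-age_bp``, so a burden that declines toward the present
yields a negative Kendall tau. Empirical p-values from randomization nulls
are one-tailed in the direction of the observed statistic and use the
add-one rule (1 + #{at least as extreme}) / (n + 1), so they are never 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from paleoburden.burden import oriented_dosage
from paleoburden.io_formats import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Observed statistic plus resampling null draws and empirical p."""

    observed: float
    null_draws: np.ndarray
    p_empirical: float
    method: str  # flip_risk | block_flip | permute_beta | maf_resample
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        self.null_draws = np.asarray(self.null_draws, dtype=float)
        if len(self.null_draws) != self.n_draws:
            raise ValueError("null_draws length does not match n_draws")
        lo = 1.0 / (self.n_draws + 1)
        if not (lo <= self.p_empirical <= 1.0):
            raise ValueError("p_empirical outside [1/(n+1), 1]")


def empirical_p(observed: float, null_draws: np.ndarray) -> float:
    """One-tailed add-one empirical p in the direction of the observed value."""
    null_draws = np.asarray(null_draws, dtype=float)
    if observed >= 0:
        extreme = int(np.sum(null_draws >= observed))
    else:
        extreme = int(np.sum(null_draws <= observed))
    return (1 + extreme) / (len(null_draws) + 1)


def kendall_trend(f: np.ndarray, age_bp: np.ndarray) -> tuple[float, float]:
    """Kendall tau-b between burden and calendar time (-age_bp).

    Negative tau means the burden declines toward the present.
    """
    f = np.asarray(f, dtype=float)
    age_bp = np.asarray(age_bp, dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 samples")
    res = stats.kendalltau(-age_bp, f)
    tau = 0.0 if np.isnan(res.statistic) else float(res.statistic)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return tau, p


def _null_burdens(
    panel: GenotypePanel, risk: pd.DataFrame, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed burden, flip-null burden matrix (n x samples) and sample mask.

    Each null draw re-assigns every SNP's risk allele uniformly at random,
    which maps the oriented dosage G -> ploidy - G for the flipped SNPs.
    With C the called mask and J the per-sample call count,

        f_null = f_obs + [(ploidy - 2 G) * C] @ flips / J

    so the full null matrix is a single matrix product.
    """
    g, _ = oriented_dosage(panel, risk)
    called = ~np.isnan(g)
    j_counts = called.sum(axis=1)
    keep = j_counts >= 1
    g = g[keep]
    called = called[keep]
    j_counts = j_counts[keep]
    ploidy = panel.ploidy[keep][:, None].astype(float)
    f_obs = np.nansum(g, axis=1) / j_counts
    delta = np.where(called, ploidy - 2 * np.nan_to_num(g), 0.0)
    # flips: snps x draws, one Bernoulli(0.5) per SNP per draw (SNP-major order)
    flips = (rng.random((g.shape[1], n)) < 0.5).astype(float)
    f_null = f_obs[:, None] + (delta @ flips) / j_counts[:, None]
    return f_obs, f_null.T, keep


def flip_null_trend(
    panel: GenotypePanel,
    risk: pd.DataFrame,
    n: int = 10000,
    seed: int = 0,
) -> NullDistribution:
    """Randomization null for the burden/time Kendall trend.

    Each draw flips every SNP's risk orientation with probability 0.5,
    recomputes all per-sample burdens, and re-estimates tau against calendar
    time; the empirical p is one-tailed toward the observed tau.
    """
    if n < 100:
        warnings.warn("fewer than 100 null draws gives an unstable empirical p")
    rng = np.random.default_rng(seed)
    f_obs, f_null, keep = _null_burdens(panel, risk, n, rng)
    age = panel.meta["age_bp"].to_numpy(float)[keep]
    tau_obs, _ = kendall_trend(f_obs, age)
    time = -age
    draws = np.empty(n)
    for k in range(n):
        r = stats.kendalltau(time, f_null[k]).statistic
        draws[k] = 0.0 if np.isnan(r) else r
    return NullDistribution(
        observed=tau_obs,
        null_draws=draws,
        p_empirical=empirical_p(tau_obs, draws),
        method="flip_risk",
        n_draws=n,
        seed=seed,
    )


def continent_regression(
    f: np.ndarray, age_bp: np.ndarray, continent: np.ndarray
) -> pd.DataFrame:
    """OLS of burden on sample age with a binary continent covariate.

    Continent is coded 0/1 against the alphabetically first level (logged as
    the reference). Returns a frame with coef, stderr and pvalue rows for
    intercept, age_bp and continent. A near-singular design triggers a
    condition-number warning.
    """
    import statsmodels.api as sm

    f = np.asarray(f, dtype=float)
    age_bp = np.asarray(age_bp, dtype=float)
    continent = np.asarray(continent)
    levels = sorted(set(continent.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 continent levels, got {levels}")
    logger.info("continent_regression: reference level %s", levels[0])
    code = (continent == levels[1]).astype(float)
    x = sm.add_constant(np.column_stack([age_bp, code]))
    if np.linalg.cond(x) > 1e10:
        warnings.warn("ill-conditioned design matrix (collinear covariates)")
    fit = sm.OLS(f, x).fit()
    return pd.DataFrame(
        {
            "term": ["intercept", "age_bp", f"continent[{levels[1]}]"],
            "coef": fit.params,
            "stderr": fit.bse,
            "pvalue": fit.pvalues,
        }
    )


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    r = stats.kendalltau(x, y).statistic
    return 0.0 if np.isnan(r) else float(r)


def partial_kendall(
    f: np.ndarray, hg_ancestry: np.ndarray, age_bp: np.ndarray
) -> tuple[float, float]:
    """Partial Kendall correlation of burden vs HG ancestry given sample time.

        tau_xy.z = (tau_xy - tau_xz * tau_yz) / sqrt((1-tau_xz^2)(1-tau_yz^2))

    The p-value uses the normal approximation for a first-order partial tau
    (as in R's ppcor), two-sided.
    """
    f = np.asarray(f, dtype=float)
    hg = np.asarray(hg_ancestry, dtype=float)
    time = -np.asarray(age_bp, dtype=float)
    t_xy = _tau_b(f, hg)
    t_xz = _tau_b(f, time)
    t_yz = _tau_b(hg, time)
    denom = np.sqrt((1 - t_xz**2) * (1 - t_yz**2))
    if denom == 0:
        raise ValueError("degenerate: burden or ancestry fully determined by time")
    tau_p = (t_xy - t_xz * t_yz) / denom
    n = len(f)
    m = n - 1  # one controlling variable
    if m < 3:
        raise ValueError("too few samples for a partial correlation")
    se = np.sqrt(2.0 * (2.0 * m + 5.0) / (9.0 * m * (m - 1.0)))
    z = tau_p / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(tau_p), float(p)


def group_compare(
    f_group_a: np.ndarray, f_group_b: np.ndarray
) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum test of group A burdens exceeding group B."""
    res = stats.mannwhitneyu(
        np.asarray(f_group_a, float),
        np.asarray(f_group_b, float),
        alternative="greater",
    )
    return float(res.statistic), float(res.pvalue)


def weighted_kendall(
    beta_a: np.ndarray,
    beta_b: np.ndarray,
    weights: np.ndarray | None = None,
    pvalues: np.ndarray | None = None,
) -> float:
    """Weighted Kendall tau-a between two effect-size vectors.

    Each pair (i, j) contributes w_i * w_j times the sign of concordance,
    normalised by the total pair weight; ties contribute 0 to the numerator
    but full weight to the denominator (tau-a). With equal weights this is
    exactly tau-a. If ``weights`` is omitted, ``-log10(pvalues)`` is used.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if weights is None:
        if pvalues is None:
            raise ValueError("provide weights or pvalues")
        weights = -np.log10(np.asarray(pvalues, dtype=float))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not (len(a) == len(b) == len(w)):
        raise ValueError("length mismatch")
    sign_a = np.sign(a[:, None] - a[None, :])
    sign_b = np.sign(b[:, None] - b[None, :])
    pair_w = w[:, None] * w[None, :]
    iu = np.triu_indices(len(a), k=1)
    num = float(np.sum(pair_w[iu] * sign_a[iu] * sign_b[iu]))
    den = float(np.sum(pair_w[iu]))
    if den == 0:
        raise ValueError("all pair weights are zero")
    return num / den
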