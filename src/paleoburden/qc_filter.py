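"""Missingness filters, GWAS-p subsetting and windowed VIF-based LD pruning.

The intended pipeline order is individuals -> variants -> GWAS subset ->
LD prune; the variant call-rate filter is defined relative to the samples
retained by the individual filter, so the order matters.

All thresholds are strict: a sample is removed when its missing fraction is
strictly above ``max_missing``, a variant when its call rate is strictly
below ``min_callrate``, and a SNP is retained when its GWAS p-value is
strictly below ``p_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from paleoburden.io_formats import GenotypePanel, GwasTable

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Counts of samples/variants surviving each stage."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, stage: str, n_samples: int, n_variants: int) -> None:
        self.stages.append((stage, n_samples, n_variants))

    def to_tsv(self) -> str:
        lines = ["stage\tn_samples\tn_variants"]
        lines += [f"{s}\t{n}\t{m}" for s, n, m in self.stages]
        return "\n".join(lines) + "\n"


def filter_individuals(
    panel: GenotypePanel, max_missing: float = 0.5
) -> GenotypePanel:
    """Drop samples whose missing-call fraction is strictly above the cutoff."""
    if panel.n_samples == 0:
        raise ValueError("empty panel")
    keep = panel.missing_fraction() <= max_missing
    if not keep.any():
        raise ValueError("all samples removed by missingness filter")
    if keep.all():
        return panel
    logger.info("filter_individuals: removed %d samples", int((~keep).sum()))
    return panel.subset_samples(keep)


def filter_variants(
    panel: GenotypePanel, min_callrate: float = 0.9
) -> GenotypePanel:
    """Drop variants called in strictly fewer than ``min_callrate`` of samples."""
    keep = panel.call_rate() >= min_callrate
    if keep.all():
        return panel
    logger.info("filter_variants: removed %d variants", int((~keep).sum()))
    return panel.subset_variants(keep)


def subset_by_gwas_p(
    panel: GenotypePanel, gwas: GwasTable, p_threshold: float = 0.01
) -> GenotypePanel:
    """Keep only variants present in the GWAS table with p strictly below cutoff."""
    sig = set(gwas.df.loc[gwas.df["pvalue"] < p_threshold, "snp_id"])
    keep = panel.variants["snp_id"].isin(sig).to_numpy()
    return panel.subset_variants(keep)


def _window_vifs(x: np.ndarray) -> np.ndarray:
    """VIF of each column of ``x`` regressed on the remaining columns.

    Columns are mean-imputed, centred dosages. A column with zero variance
    gets VIF 1 (it carries no LD information); perfect collinearity gives inf.
    """
    n, k = x.shape
    vifs = np.ones(k)
    if k < 2:
        return vifs
    sd = x.std(axis=0)
    for j in range(k):
        if sd[j] == 0:
            continue
        others = np.delete(np.arange(k), j)
        others = others[sd[others] > 0]
        if others.size == 0:
            continue
        a = x[:, others]
        y = x[:, j]
        coef, _, _, _ = np.linalg.lstsq(a, y, rcond=None)
        resid = y - a @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            vifs[j] = np.inf
        else:
            vifs[j] = 1.0 / (1.0 - r2)
    return vifs


def ld_prune(
    panel: GenotypePanel,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> list[str]:
    """Greedy windowed variance-inflation pruning (plink ``--indep`` style).

    Within each window of ``window`` consecutive variants (advancing by
    ``step``), variants still retained are jointly examined: while any has a
    VIF above ``vif_threshold``, the one with the largest VIF (ties broken by
    lowest variant index) is removed and VIFs are recomputed. Missing dosages
    are mean-imputed per variant before the regression. Returns the ids of
    retained variants in panel order; deterministic for fixed input.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    if not (window > step >= 1):
        raise ValueError("require window > step >= 1")
    if vif_threshold <= 1:
        raise ValueError("vif_threshold must exceed 1")

    m = panel.n_variants
    dosage = panel.dosage.astype(float)
    # mean-impute per variant (columns that are entirely missing become 0)
    col_mean = np.nanmean(
        np.where(np.isnan(dosage), np.nan, dosage), axis=0, keepdims=True
    )
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    imputed = np.where(np.isnan(dosage), col_mean, dosage)
    imputed = imputed - imputed.mean(axis=0, keepdims=True)

    retained = np.ones(m, dtype=bool)
    start = 0
    while True:
        stop = min(start + window, m)
        idx = np.flatnonzero(retained[start:stop]) + start
        while idx.size >= 2:
            vifs = _window_vifs(imputed[:, idx])
            worst = np.max(vifs)
            if worst <= vif_threshold:
                break
            # largest VIF, ties by lowest variant index
            drop_local = int(np.flatnonzero(vifs == worst)[0])
            retained[idx[drop_local]] = False
            idx = np.delete(idx, drop_local)
        if stop >= m:
            break
        start += step
    snp_ids = panel.variants["snp_id"].to_numpy()
    return [str(s) for s in snp_ids[retained]]


def run_qc(
    panel: GenotypePanel,
    gwas: GwasTable,
    max_missing: float = 0.5,
    min_callrate: float = 0.9,
    p_threshold: float = 0.01,
    ld_window: int = 50,
    ld_step: int = 5,
    ld_vif: float = 2.0,
) -> tuple[GenotypePanel, QcReport]:
    """Full QC pipeline in the canonical order; returns panel + stage report."""
    report = QcReport()
    report.record("input", panel.n_samples, panel.n_variants)
    panel = filter_individuals(panel, max_missing)
    report.record("individual_missingness", panel.n_samples, panel.n_variants)
    panel = filter_variants(panel, min_callrate)
    report.record("variant_callrate", panel.n_samples, panel.n_variants)
    panel = subset_by_gwas_p(panel, gwas, p_threshold)
    report.record("gwas_p_subset", panel.n_samples, panel.n_variants)
    kept = set(ld_prune(panel, ld_window, ld_step, ld_vif))
    panel = panel.subset_variants(panel.variants["snp_id"].isin(kept).to_numpy())
    report.record("ld_prune", panel.n_samples, panel.n_variants)
    return panel, report
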