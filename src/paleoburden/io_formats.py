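"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Tables are tab-delimited with a header line; gzip is handled transparently
  by extension (``.gz``).
* VCF coordinates and GWAS positions are 1-based; BED intervals are 0-based
  half-open, so a single base at 1-based position ``p`` is the interval
  ``[p-1, p)``.
* Joins between tables are keyed on ``snp_id``; ``(chrom, pos)`` is used as a
  consistency check and a mismatch is an error.
* Pseudo-haploid samples are stored with ploidy 1 and dosages in {0, 1};
  dosages are never rescaled at read time.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

GWAS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "pvalue",
    "maf",
]

#: continent labels accepted in sample metadata (free-form values are allowed
#: but these are the ones the pipeline's comparisons use)
CONTINENTS = ("Europe", "Africa")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


@dataclass
class GwasTable:
    """Validated per-SNP association summaries.

    ``df`` holds one row per SNP with columns :data:`GWAS_COLUMNS`. Rows that
    violated the invariants at read time are counted in ``n_rejected`` and
    listed in ``rejections`` (row number, reason).
    """

    df: pd.DataFrame
    n_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"GWAS table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[pd.Series]:
        return (row for _, row in self.df.iterrows())

    def by_snp(self) -> pd.DataFrame:
        return self.df.set_index("snp_id", drop=False)


def _validate_gwas_row(row: pd.Series) -> str | None:
    """Return a rejection reason, or None if the row is valid."""
    ea, oa = str(row["effect_allele"]), str(row["other_allele"])
    if ea not in VALID_BASES or oa not in VALID_BASES:
        return "allele not in {A,C,G,T}"
    if ea == oa:
        return "effect_allele equals other_allele"
    try:
        beta = float(row["beta"])
        p = float(row["pvalue"])
        maf = float(row["maf"])
        pos = int(row["pos"])
    except (TypeError, ValueError):
        return "unparsable numeric field"
    if not np.isfinite(beta):
        return "non-finite beta"
    if not (0.0 < p <= 1.0):
        return "pvalue outside (0,1]"
    if not (0.0 < maf <= 0.5):
        return "maf outside (0,0.5]"
    if pos < 1:
        return "non-positive position"
    return None


def read_gwas_summary(path: str | Path) -> GwasTable:
    """Read a tab-delimited GWAS summary file into a validated table.

    Rows violating the record invariants are dropped and reported via the
    returned table's ``rejections`` attribute; a missing required column is a
    :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df[GWAS_COLUMNS]
    rejections: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        reason = _validate_gwas_row(row)
        if reason is not None:
            keep[i] = False
            rejections.append((int(i), reason))
    if rejections:
        logger.warning("%s: rejected %d malformed rows", path, len(rejections))
    out = df.loc[keep].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    out[["beta", "pvalue", "maf"]] = out[["beta", "pvalue", "maf"]].astype(float)
    return GwasTable(out, n_rejected=len(rejections), rejections=rejections)


def write_gwas_summary(table: GwasTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype panels (VCF + per-sample metadata)
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Samples x SNPs dosage matrix with per-sample metadata.

    ``dosage[i, j]`` counts copies of the ALT allele of variant ``j`` carried
    by sample ``i``; missing calls are ``nan``. ``ploidy[i]`` is 1 for
    pseudo-haploid samples and 2 for diploids. ``variants`` has one row per
    column of ``dosage`` with columns snp_id, chrom, pos, ref, alt; ``meta``
    one row per sample with columns sample_id, age_bp, continent, hg_ancestry
    (hg_ancestry may be nan).
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray  # float matrix, nan = missing
    ploidy: np.ndarray  # int per sample
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variants length does not match dosage columns")
        if len(self.ploidy) != n:
            raise ValueError("ploidy length does not match sample count")
        if len(self.meta) != n:
            raise ValueError("meta rows do not match sample count")
        called = ~np.isnan(self.dosage)
        if np.any(self.dosage[called] > self.ploidy[:, None].repeat(m, 1)[called]):
            raise ValueError("dosage exceeds sample ploidy")
        ages = self.meta["age_bp"].to_numpy(float)
        if not np.all(np.isfinite(ages)) or np.any(ages < 0):
            raise ValueError("age_bp must be finite and non-negative")
        self.variants = self.variants.reset_index(drop=True)
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=1)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of samples with a call."""
        return (~np.isnan(self.dosage)).mean(axis=0)

    def subset_samples(self, mask: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :],
            ploidy=self.ploidy[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            ploidy=self.ploidy.copy(),
            meta=self.meta.copy(),
        )


META_COLUMNS = ["sample_id", "age_bp", "continent", "hg_ancestry"]


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "continent": str})
    for col in ("sample_id", "age_bp"):
        if col not in meta.columns:
            raise FormatError(f"{path}: metadata missing column {col!r}")
    if "continent" not in meta.columns:
        meta["continent"] = "Europe"
    if "hg_ancestry" not in meta.columns:
        meta["hg_ancestry"] = np.nan
    return meta[META_COLUMNS]


def read_genotypes_vcf(path: str | Path, meta_path: str | Path) -> GenotypePanel:
    """Load a VCF (GT only) plus a metadata TSV keyed by sample id.

    Haploid GT calls yield ploidy 1 with dosages in {0,1}; diploid calls
    ploidy 2 with dosages in {0,1,2}. ``.`` and ``./.`` become missing.
    Multi-allelic sites are skipped with a warning. A VCF sample absent from
    the metadata is an error.
    """
    meta_all = read_sample_metadata(meta_path).set_index("sample_id", drop=False)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        absent = [s for s in samples if s not in meta_all.index]
        if absent:
            raise FormatError(f"samples missing from metadata: {absent}")
        rows = []
        dosages: list[np.ndarray] = []
        ploidy = np.zeros(len(samples), dtype=int)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"skipping multi-allelic or ALT-less site at {rec.chrom}:{rec.pos}"
                )
                continue
            col = np.full(len(samples), np.nan)
            for i, name in enumerate(samples):
                gt = rec.samples[name]["GT"]
                if gt is None:
                    continue
                alleles = [a for a in gt if a is not None]
                if not alleles:
                    continue
                ploidy[i] = max(ploidy[i], len(gt))
                col[i] = float(sum(alleles))
            rows.append(
                {
                    "snp_id": rec.id if rec.id else f"{rec.chrom}:{rec.pos}",
                    "chrom": str(rec.chrom),
                    "pos": int(rec.pos),
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                }
            )
            dosages.append(col)
    # samples with no called genotype at all default to haploid
    ploidy[ploidy == 0] = 1
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosage = (
        np.column_stack(dosages) if dosages else np.empty((len(samples), 0))
    )
    meta = meta_all.loc[samples].reset_index(drop=True)
    return GenotypePanel(
        sample_ids=samples,
        variants=variants,
        dosage=dosage,
        ploidy=ploidy,
        meta=meta,
    )


def write_genotypes_vcf(
    panel: GenotypePanel, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write a panel as an uncompressed VCF 4.2 file (+ optional metadata TSV)."""
    path = Path(path)
    chroms = sorted(panel.variants["chrom"].unique(), key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        order = panel.variants.sort_values(["chrom", "pos"]).index.to_numpy()
        for j in order:
            v = panel.variants.iloc[j]
            gts = []
            for i in range(panel.n_samples):
                d = panel.dosage[i, j]
                k = int(panel.ploidy[i])
                if np.isnan(d):
                    gts.append("." if k == 1 else "./.")
                elif k == 1:
                    gts.append(str(int(d)))
                else:
                    a = int(d)
                    gts.append("1/1" if a == 2 else ("0/1" if a == 1 else "0/0"))
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['snp_id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    if meta_path is not None:
        panel.meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ancestral-allele map (BED5)
# ---------------------------------------------------------------------------


@dataclass
class AncestralMap:
    """snp_id -> ancestral base, with (chrom, 1-based pos) for cross-checks."""

    alleles: dict[str, str]
    coords: dict[str, tuple[str, int]]

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.alleles

    def get(self, snp_id: str) -> str | None:
        return self.alleles.get(snp_id)

    def check_coords(self, snp_id: str, chrom: str, pos: int) -> None:
        if snp_id in self.coords and self.coords[snp_id] != (str(chrom), int(pos)):
            raise FormatError(
                f"coordinate mismatch for {snp_id}: ancestral map has "
                f"{self.coords[snp_id]}, expected ({chrom}, {pos})"
            )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_ancestral_bed(path: str | Path) -> AncestralMap:
    """Read a BED5-like file: chrom, start, end, snp_id, ancestral base.

    BED is 0-based half-open, so a record covering the single 1-based position
    ``p`` has start ``p-1`` and end ``p``. Records whose allele is not a
    single A/C/G/T base are treated as missing and skipped.
    """
    alleles: dict[str, str] = {}
    coords: dict[str, tuple[str, int]] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: expected 5 BED columns")
            chrom, start, end, snp_id, base = parts[:5]
            start, end = int(start), int(end)
            if end != start + 1:
                raise FormatError(
                    f"{path}:{ln}: SNP interval must span exactly one base"
                )
            base = base.upper()
            if base not in VALID_BASES:
                continue  # inconclusive alignment -> missing
            alleles[snp_id] = base
            coords[snp_id] = (str(chrom), start + 1)  # BED start -> 1-based pos
    return AncestralMap(alleles=alleles, coords=coords)


def write_ancestral_bed(anc: AncestralMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for snp_id, base in anc.alleles.items():
            chrom, pos = anc.coords[snp_id]
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{snp_id}\t{base}\n")


# ---------------------------------------------------------------------------
# SDS scores
# ---------------------------------------------------------------------------

SDS_COLUMNS = ["snp_id", "chrom", "pos", "sds_reference_allele", "sds"]


def read_sds_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited SDS table; rows with non-finite scores rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in SDS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df[SDS_COLUMNS].copy()
    df["sds"] = pd.to_numeric(df["sds"], errors="coerce")
    bad = ~np.isfinite(df["sds"].to_numpy(float))
    bad |= ~df["sds_reference_allele"].isin(list(VALID_BASES)).to_numpy()
    if bad.any():
        logger.warning("%s: rejected %d invalid SDS rows", path, int(bad.sum()))
    out = df.loc[~bad].reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    return out


def write_sds_table(df: pd.DataFrame, path: str | Path) -> None:
    df[SDS_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Archaic tag SNPs
# ---------------------------------------------------------------------------

TAG_COLUMNS = ["snp_id", "archaic_allele", "altai_homozygous"]


def read_tag_snps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    missing = [c for c in TAG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df[TAG_COLUMNS].copy()
    bad = ~df["archaic_allele"].isin(list(VALID_BASES)).to_numpy()
    if bad.any():
        logger.warning("%s: rejected %d invalid tag rows", path, int(bad.sum()))
    df = df.loc[~bad].reset_index(drop=True)
    df["altai_homozygous"] = df["altai_homozygous"].astype(bool)
    return df


def write_tag_snps(df: pd.DataFrame, path: str | Path) -> None:
    df[TAG_COLUMNS].to_csv(path, sep="\t", index=False)


def crosscheck_coords(
    gwas: GwasTable, other: pd.DataFrame, label: str = "table"
) -> None:
    """Verify (chrom, pos) agreement for snp_ids shared with the GWAS table.

    Raises :class:`FormatError` on the first mismatch.
    """
    g = gwas.df.set_index("snp_id")
    shared = other[other["snp_id"].isin(g.index)]
    for _, row in shared.iterrows():
        grow = g.loc[row["snp_id"]]
        if str(grow["chrom"]) != str(row["chrom"]) or int(grow["pos"]) != int(
            row["pos"]
        ):
            raise FormatError(
                f"{label}: coordinate mismatch for {row['snp_id']} "
                f"({row['chrom']}:{row['pos']} vs GWAS "
                f"{grow['chrom']}:{grow['pos']})"
            )
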