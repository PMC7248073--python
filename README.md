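# paleoburden

Evolutionary analyses of GWAS-defined risk-allele burden in dated ancient
genomes: per-individual burden, temporal-trend tests with randomization
nulls, ancestral-allele enrichment, an ABC estimator of the per-generation
selection trend with neural summary statistics, a trait-SDS recent-adaptation
test, and archaic-introgression enrichment. Every analysis is exercisable on
synthetic data generated by the package itself — no external downloads.

## Modules

| module | what it does |
| --- | --- |
| `io_formats` | validated readers/writers: GWAS TSV, VCF + sample metadata, BED5 ancestral map, SDS and tag-SNP tables |
| `qc_filter` | sample-missingness and variant call-rate filters, GWAS-p subsetting, windowed VIF LD pruning |
| `burden` | risk-allele orientation from effect signs; per-individual mean risk-allele dosage |
| `trend_tests` | Kendall trend vs calendar time, risk-flip randomization null, OLS with continent covariate, partial Kendall, rank-sum group test, weighted Kendall |
| `ancestral_enrichment` | ancestral-vs-derived risk 2x2 odds ratio with a MAF-binned label-resampling null |
| `abcdl` | Brownian frequency simulator on a dated 8-leaf sample tree; ensembles of small Elliott-activation nets (RPROP-, dropout) as learned summary statistics; ABC rejection + local-linear adjustment; factor-2 validation |
| `sds_analysis` | trait-aligned SDS, p-sorted binning, Spearman correlation, 1-Mb block-flip null with normal-approximated one-tail p |
| `introgression` | mean archaic-oriented effect size over Altai-homozygous tag SNPs with a sign-flip null |
| `synthdata` | seeded generators for all of the above, with truth sidecars for recovery tests |
| `cli` | `paleoburden` command with per-stage subcommands and a full `run` pipeline + manifest |

## CLI

```bash
# generate a synthetic dataset
paleoburden synth --out data/ --seed 1

# individual stages
paleoburden qc --vcf data/ancient.vcf --meta data/ancient_meta.tsv \
    --gwas data/gwas.tsv --out qc/
paleoburden burden --vcf qc/qc_panel.vcf --meta qc/qc_meta.tsv \
    --gwas data/gwas.tsv --out burden.tsv
paleoburden trend --vcf qc/qc_panel.vcf --meta qc/qc_meta.tsv \
    --gwas data/gwas.tsv --out trend/ --nulls 10000 --seed 1
paleoburden ancestral --gwas data/gwas.tsv --ancestral-bed data/ancestral.bed \
    --out ancestral.json
paleoburden sds --gwas data/gwas.tsv --sds data/sds.tsv --out sds.json
paleoburden introgression --gwas data/gwas.tsv --tags data/tags.tsv \
    --out introgression.json
paleoburden abcdl --burden-tsv burden.tsv --out abcdl/

# or the whole pipeline on synthetic data, with a reproducibility manifest
paleoburden run --config run.yaml --out results/ --seed 7
```

`run` derives one seed per stage from the global seed, records input hashes
and seeds in `results/manifest.json`, and re-running with the same config is
byte-identical. `--only STAGE` re-runs a single stage and fails with a clear
error if an upstream output is missing.

## Conventions worth knowing

- Trend statistics correlate burden with calendar time (`-age_bp`), so a
  burden declining toward the present gives a negative Kendall tau.
- The burden is the plain average of risk-allele copies over called SNPs:
  diploid values live in [0, 2], pseudo-haploid in [0, 1]. Mixed-ploidy
  panels require `normalise=True`.
- Empirical p-values from randomization nulls use the add-one rule and are
  one-tailed; they are never exactly 0.
- QC thresholds are strict inequalities (missingness "above 50%", call rate
  "below 90%", GWAS p "below 0.01").
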