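# coreset-gbs

Genetic-diversity analysis, distance-based core-collection selection, and
mixed-linear-model GWAS for genotyping-by-sequencing (GBS) SNP panels.

The package implements a complete, reproducible pipeline:

1. **QC filtering** (`qc_filtering`) — hard INFO-threshold filtering
   (QUAL/QD/FS/MQ/MQRankSum/ReadPosRankSum), biallelic-only, MAF ≥ 0.05 and
   missingness ≤ 10%, and sliding-window LD pruning (50-site windows, step
   10, r² ≤ 0.2 on dosage correlations).
2. **Diversity statistics** (`popgen_stats`) — allele/genotype frequencies,
   MAF, polymorphism information content (PIC), observed heterozygosity,
   identity-by-state (IBS) genetic distances, and per-group diversity
   summaries with frequency spectra.
3. **Tree building** (`nj_tree`) — square-root (Euclidean) transform of IBS
   dissimilarities, Saitou–Nei neighbor joining with deterministic
   tie-breaking, site-bootstrap bipartition supports, and longest-edge
   group cutting.
4. **Core-collection selection** (`core_selection`) — stepwise
   maximum-length-subtree pruning (greedy shortest-terminal-edge removal
   with edge merging), sphericity-index stopping curves with automatic knee
   detection, synonym detection at a configurable Euclidean-distance
   threshold (default 0.0008), and core-vs-whole diversity retention
   evaluation.
5. **Leaf-size phenotypes** (`phenotypes`) — MLSI = MLL/MLW and
   MLA = 0.75·MLW·MLL derivation, descriptive statistics with
   SPSS-convention skewness/kurtosis and closed-form standard errors, and
   Pearson correlations within and across seasons.
6. **Mixed-model GWAS** (`gwas_mlm`) — Q+K / P+K single-marker mixed linear
   models with REML variance components by spectral decomposition, P3D and
   exact modes, Bonferroni thresholds, genomic-inflation (λ) diagnostics,
   and per-SNP allele-class effect reporting.
7. **Synthetic data** (`synthetic_data`) — seeded Balding–Nichols panels
   with admixture and two-season trait simulation with planted causal SNPs,
   for end-to-end testing without external data.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks
(statistical calibration, core retention, NJ exactness, oracles).

## Command line

All stages are exposed under one entry point:

```bash
coreset-gbs simulate --n-samples 400 --n-sites 5000 --seed 7 \
    --out-vcf sim.vcf --out-pheno pheno.tsv --out-truth truth.json --out-q q.tsv

coreset-gbs filter --vcf sim.vcf --maf 0.05 --max-missing 0.10 \
    --ld-window 50 --ld-step 10 --ld-r2 0.2 --out kept.vcf --report report.tsv

coreset-gbs stats --vcf kept.vcf --out-prefix stats/
coreset-gbs tree --distances stats/distances.phylip --out tree.nwk
coreset-gbs core --tree tree.nwk --distances stats/distances.phylip \
    --target 198 --out core.txt --trace trace.tsv --synonyms syn.tsv
coreset-gbs core-eval --vcf kept.vcf --core core.txt --out eval.tsv

coreset-gbs pheno --in pheno.tsv --out summary.tsv --corr corr.tsv
coreset-gbs gwas --vcf kept.vcf --pheno pheno.tsv --trait MLL \
    --covar q.tsv --kinship ibs-similarity --mode p3d --out assoc.tsv
```

Two YAML-config pipelines chain the stages and write run manifests with
seeds and output checksums:

```bash
coreset-gbs run-core --config core.yaml
coreset-gbs run-gwas --config gwas.yaml
```

## Conventions worth knowing

* Genotypes are ALT-allele dosages in {0, 1, 2} with −1 as the missing
  sentinel; major/minor alleles are assigned from observed frequencies, not
  REF/ALT order.
* Heterozygote–heterozygote IBS distance is 0 (full allele sharing).
* The sphericity index is implemented as mean/max pairwise distance within
  the retained set — a documented artifact convention.
* LD r² is the squared Pearson correlation of dosages (composite LD); no
  phasing is attempted.
* Allele-class effects are genotype-class mean deviations from the grand
  mean of phenotyped, genotyped accessions.
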