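# islandadapt

A landscape-genomics analysis pipeline for detecting and projecting climate
adaptation from population resequencing data: SNP filtering, selective-sweep
scanning with a composite μ statistic, latent-factor genotype–environment
association (GEA), and Risk of Non-Adaptedness (RONA) under future climate
scenarios. It is aimed at population geneticists studying range-restricted
species — the motivating design is a tropical island tree sampled as 5
populations × 6 diploid individuals — and ships synthetic-data generators
that reproduce the statistical structure every stage assumes, so the whole
pipeline is testable without the original resequencing data.

## The statistics at the core

**Sweep scan.** A hard selective sweep leaves three local signatures:
reduced polymorphism, a site-frequency spectrum shifted toward low- and
high-frequency derived variants, and elevated linkage disequilibrium on
each flank of the selected site with reduced LD across it. For each sliding
window of W SNPs the scan computes

- μ_var = ((p_W − p_1)/R)·(S/W): window bp span relative to the
  chromosome's mean SNP spacing (R = chromosome span, S = its SNP count),
- μ_sfs = (c_low + c_high)/W: fraction of window SNPs with derived count
  ≤ k or ≥ n − k,
- μ_ld = mean within-flank r² / (mean cross-flank r² + ε),

and their product μ. Windows above the genome-wide top-0.05% quantile of μ
are merged into candidate sweep regions.

**GEA.** Population structure is absorbed by K latent factors (truncated
SVD of the centered dosage matrix). Each environmental variable e is tested
per SNP by least squares of dosage on [1, e, U]; z-scores are recalibrated
by the genomic inflation factor λ = median(z²)/median(χ²₁), converted to
q-values (Storey, with Benjamini–Hochberg fallback for small batches), and
SNPs with q < 0.01 become candidates.

**RONA.** For each candidate SNP a linear model of allele frequency on its
environmental variable f = a + b·e is fitted; RONA for a population and
variable is the r²-weighted mean of |f̂(e_future) − f̂(e_current)| over its
SNPs — the average allele-frequency shift required to track the projected
environment.

## Worked example

```
$ python analysis/01_simulate_cohort.py
cohort: 30 samples x 20000 SNPs on 12 chromosomes
populations: DLS, JFL, QSX, QXL, SMX
planted adaptive loci: 200 (slopes 0.10-0.30 per SD of environment)

$ python analysis/02_filter_snps.py
input SNPs:            20000
removed (missingness): 0
removed (MAF < 0.05):  473
removed (LD r2 > 0.1): 16538
retained:              2989
```

The MAF rule removes loci whose minor allele is nearly absent from the 60
sampled chromosomes; LD pruning then thins locally correlated SNPs so that
no within-window pair exceeds r² = 0.1 — at 30 samples the r² noise floor
makes this threshold aggressive, which is the realistic behavior of this
pruning rule on small cohorts. `analysis/04_gea_scan.py` then
prints, for the filtered cohort:

```
candidate SNPs (union over variables): 6
recovery benchmark (10 seeds): power = 0.87, empirical FDR = 0.05
null calibration: KS(p, uniform) = 0.006
```

Six candidates from 200 planted loci reflects the honest power of a
30-individual design at FDR < 1%; the benchmark line shows the same
estimator recovering planted loci at 0.87 power when each deme has 60
individuals. `analysis/05_rona_projection.py` prunes correlated variables
(|r| > 0.8) and prints per-population RONA under the two scenario layers:

```
SSP126: mean RONA 0.071; per population DLS=0.076, JFL=0.076, QSX=0.060, ...
SSP585: mean RONA 0.187; per population DLS=0.222, JFL=0.210, QSX=0.124, ...
```

i.e. tracking the strong-emission environmental shift would require about
a 0.19 average allele-frequency change at climate-associated loci, three
times the mild-scenario requirement.

The same stages run from a single config:

```
islandadapt pipeline --config run.yaml      # filter -> sweep -> GEA -> RONA
islandadapt simulate gea --out demo --seed 1
islandadapt sweep demo.vcf --out demo_scan
```

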