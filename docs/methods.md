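# Methods

This note documents the models behind each pipeline stage, the synthetic
data the package tests itself against, and the numerical and design choices
that were genuinely open.

## Data model and filtering

Genotypes are unphased diploid ALT-dosages (0/1/2) with an explicit missing
sentinel excluded from every sum; `/` and `|` separators in VCF genotypes
are read identically because no stage uses phase. VCF coordinates stay
1-based internally; every exported interval file is BED (0-based,
half-open). REF is treated as the ancestral allele wherever a
derived/ancestral distinction matters (the sweep scan's SFS factor); a
folded mode is available where that assumption is unwanted.

Filtering applies missingness first (rate > 0.1 removed), then MAF < 0.05
computed on the remaining non-missing genotypes, then LD pruning in sliding
windows of 50 SNPs advanced by 10: while any within-window pair of kept
SNPs has dosage-r² above 0.1, the currently highest-r² pair is resolved by
dropping its lower-MAF member (tie: the later-positioned SNP). The classic
pruning command defines no tie order, so this deterministic rule is the
package's own; the post-condition — no surviving within-window pair above
threshold — is what the tests verify by brute force. r² is always the
squared Pearson correlation of dosage vectors over pairwise-complete
samples: the data are unphased, so haplotype r² is never defined. The
filter order (missingness → MAF → LD) is configurable since the original
workflow does not state it.

## Sweep scan

Each sliding window of W SNPs (default 50, even; one-SNP step;
per-chromosome) is scored by three factors and their product μ:

- μ_var = ((p_W − p_1)/R)·(S/W), with R the chromosome's analyzed span and
  S its SNP count. Neutral expectation ≈ 1; a local polymorphism deficit
  stretches the window over more bp.
- μ_sfs = (c_low + c_high)/W where c_low counts derived allele counts
  ≤ k_low (default 1) and c_high counts ≥ n − k_low; folded mode counts
  minor-allele counts ≤ k_low. Range [0, 1].
- μ_ld = ((r̄²_left + r̄²_right)/2)/(r̄²_cross + ε) over the window's two
  halves, with ε = 10⁻⁶ a positive guard and monomorphic pairs
  contributing r² = 0.

The motivating analysis describes the three sweep signatures only
qualitatively; these concrete factor definitions are this package's contract,
chosen so each factor is oracle-testable and has an interpretable neutral
scale. The genome-wide significance threshold is the empirical
(1 − 0.0005) quantile of μ over all windows (a single genome-wide
significance line); windows above it merge into regions by SNP-span overlap.
Windows are assigned to their SNP-span midpoint, making every μ quantity
invariant to uniform rescaling of coordinates. The scan is oracle-checked
against a direct per-window recomputation to 1e-12.

Whether such scans should pool individuals or run per population is
often left unstated; the scan takes whatever sample set it is given (pooled by default).

## Latent-factor GEA

The latent-factor association model is implemented as PCA-adjusted least
squares with genomic-inflation recalibration: factors U are the top-K left
singular vectors (scaled by singular values) of the column-centered,
mean-imputed dosage matrix, with signs fixed by each column's
largest-magnitude entry; each environmental variable (population-level
values expanded to samples, standardized) is tested per SNP by OLS of
dosage on [1, e, U] with t-tests at df = n − K − 2. The named
latent-factor tool's ridge/MCMC internals are replaced deliberately: the
contract — structure-corrected per-locus tests with calibrated p-values —
is preserved in a deterministic, closed-form estimator.

Calibration divides z² by λ = median(z²)/median(χ²₁) and takes the upper
χ²₁ tail. q-values use Storey's estimator (π₀ from the λ-grid
0.05…0.95 with a cubic smoothing spline, evaluated at the grid's end)
falling back to Benjamini–Hochberg (π₀ = 1) below 100 p-values. Candidates
are q < 0.01 per variable (pooling across variables is available);
the union across variables is reported with per-variable counts, and 1-Mb
non-overlapping windows summarize genomic clustering together with the
Pearson correlation of per-chromosome candidate counts against chromosome
span.

### Confounding at few sites

With one environmental value per population, a deme-constant variable is a
linear combination of deme indicators. Under full-rank five-deme
Balding–Nichols structure the per-locus deme drift deviations span the
whole 4-dimensional deme space, so after removing K < 4 factors every SNP
retains deme-level noise that correlates with any deme-constant variable —
measured genomic inflation reaches λ ≈ 13 at F_ST = 0.1 with 60 diploids
per deme, and λ-recalibration then protects the false-discovery rate at
the cost of nearly all power. This is an identifiability limit of the
design (5 sites), not an estimator defect. The package's recovery
benchmark therefore uses the generator's rank-2 structure mode (below),
where the factor model's assumption holds and power/FDR are meaningful;
runs on full-rank structure are retained as the stress case.

## Synthetic data

**Structure.** Balding–Nichols by default: ancestral frequency
p0 ~ U(0.05, 0.95) per SNP, deme frequency Beta(p0(1−F)/F, (1−p0)(1−F)/F)
at F = target F_ST, genotypes binomial; positions uniform without ties on
12 synthetic chromosomes. Defaults mirror the motivating design
(5 populations × 6 diploids); Weir–Cockerham recovery is verified at
F_ST ∈ {0.05, 0.1, 0.2} within ±0.02. The alternative `latent_rank = K`
mode draws deme deviations from a K-factor linear model with variance
matched to F_ST; out-of-range frequencies are handled by rescaling the
locus's whole deviation profile, because clipping would push deme profiles
out of the low-rank span and measurably fattens the null tail of the
association test.

**Environment.** Seven equicorrelated (r = 0.3) standard-normal bioclim
variables per site; future layers add deterministic shifts of +0.5 SD
("SSP126") and +1.5 SD ("SSP585") — end-of-century shifts of one to two
spatial standard deviations are the realistic range for the strong-emission
contrast the projections target. Planted associations rebuild a locus's deme
frequencies as clamp(p0 + b·z(e), 0.02, 0.98) with |b| ~ U(0.1, 0.3) per
SD of environment and random sign, then redraw genotypes binomially; the
clamp bounds keep the association signal away from fixation. Slopes of
0.1–0.3 per SD correspond to strong local adaptation — the regime GEA
methods are expected to detect.

**Sweeps.** A discrete-generation forward Wright–Fisher simulation:
infinite-sites mutation on a continuous axis, uniform recombination
(Poisson crossovers per gamete), multiplicative per-copy selection (1+s),
burn-in of 10N generations from a monomorphic start, then a single
beneficial copy introduced at the selected position with rejection
restarts (each attempt on its own spawned random stream, so runs are
reproducible regardless of how many attempts fail) until fixation;
haplotypes are sampled at fixation and paired into diploids. Forward
simulation was chosen over coalescent machinery so the sweep's SFS and LD
signatures arise mechanistically rather than being imposed.

Desk scaling: N = 200 diploids with μ = 2×10⁻⁶/bp/generation
(θ = 4Nμ = 1.6×10⁻³/bp, ≈ 1,300 sample-segregating SNPs per 200 kb at 50
haplotypes) and ρ = 5×10⁻⁷/bp. The per-generation mutation rate reported
for the target species (8.21×10⁻¹⁰) is kept as a package constant; the
forward rates are scaled up as N is scaled down, preserving the
population-scaled θ within the realistic range while keeping a replicate
in seconds. Neutral runs reproduce Watterson's expected segregating-site
count within 15%.

## Sweep-localization behavior

The localization benchmark (20 replicates at N = 200, s = 0.05, 200 kb,
50 haplotypes) scans with 100-SNP windows so one window spans roughly the
expected sweep footprint s/(ρ·ln 2Ns) ≈ 30 kb; sub-footprint windows
localize measurably worse. At 2Ns = 20 drift noise is substantial: the
arg-max μ window centers within 25 kb of the true site in roughly 70–80%
of replicates across the explored design space, with misses concentrated
at the footprint edges where the flanking-LD factor peaks (the swept
core's surviving SNPs are mostly recent singletons, which dilute
within-half r² at the true center). Stronger selection relative to drift
sharpens this rapidly; the benchmark deliberately sits in the weak-sweep
regime.

## RONA

Environmental variables are first pruned: while any pair exceeds |r| = 0.8
across sites, the highest-|r| pair is resolved by dropping its
lower-priority member (priority is user-supplied, e.g. model contribution
scores; absent that, minus the variable's mean |r| with the others, so the
most redundant variable drops first; ties drop the lexicographically later
name). Per candidate SNP, allele frequency (per-population frequencies by
default, or per-individual dosage/2) is regressed on its variable; RONA
per population, variable and scenario is the r²-weighted mean of
|f̂(e_future) − f̂(e_current)| with predictions clipped to [0, 1]
(unclipped mode exists for the analytic identities: zero shift ⇒ RONA 0;
a perfect line with uniform shift Δ ⇒ RONA = |b|Δ; affine re-scaling of
both environment layers leaves RONA unchanged). r² weighting follows the
upstream implementation's fit-quality weighting and the standard reporting
of per-variable mean r²; uniform weighting is available for sensitivity
analysis. The per-SNP significance filter beyond GEA candidacy is off by
default (min_r2 = 0) since candidates already come from the GEA stage.
With one site per population the per-individual and per-population modes
coincide up to averaging, so both are provided.

## What the synthetic tests do and do not show

The generators reproduce the statistical structure each stage assumes:
F_ST-controlled differentiation, exactly linear frequency–environment
relationships at planted loci, and mechanistic hard sweeps. They do not
emulate linked background selection, isolation-by-distance, spatially
autocorrelated environments, genotyping error, or reference bias — so
green tests certify the estimators against their own model assumptions,
not performance on any particular empirical dataset. Headline counts from any particular empirical dataset (millions of
filtered SNPs, per-variable candidate tallies) depend on that dataset and
its climate rasters and are not reproducible at desk scale; the acceptance
script instead reports the simulation-based quantities above.

## Numerical notes

- Degenerate regressions (zero-variance SNP after imputation) report
  p = 1 by convention; a constant environmental variable is an error
  naming the variable.
- Empirical quantiles use linear interpolation (numpy default); the
  neutral exceedance of the top-quantile threshold is definitionally the
  quantile up to that interpolation.
- The LD guard ε = 10⁻⁶ only prevents division by zero; r̄²_cross at the
  sampling-noise floor (~1/n) still produces large μ_ld, which is part of
  the statistic's intended sensitivity.
- All generators are pure functions of their seed (verified); the pipeline
  runner derives stage manifests from parameter hashes, so a re-run with
  an unchanged config is byte-identical and a deleted output re-executes
  only its own stage.
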