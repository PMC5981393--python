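# Methods

This note records the models, defaults and numerical choices behind
`gwascoloc`, and what the synthetic-data tests do and do not demonstrate
about real cohort data.

## Synthetic genotypes and traits

Genotypes follow a block-LD haplotype model. Each independent block draws
one minor-allele frequency f ~ Uniform(maf_range); each haplotype is a
latent AR(ρ_lat) Gaussian chain thresholded at Φ⁻¹(f), and a dosage is the
sum of two independent haplotypes, so genotypes are in Hardy–Weinberg
proportions by construction. Thresholding attenuates correlation, so
ρ_lat is calibrated per block (Brent root-finding on the bivariate-normal
orthant probability) such that *observed* adjacent-allele correlation
equals the requested `rho`; correlation then decays roughly geometrically
with distance inside a block and is zero across blocks. Variants sit on
one chromosome at fixed 5 kb spacing. This is deliberately minimal: no
recombination hotspots, no allele-frequency spectrum, no population
structure, no missingness or genotyping error. Passing tests show the
*statistics* behave as designed under controlled LD; they cannot certify
behaviour under real human LD maps.

Phenotypes are built on a latent liability: genetic effects are specified
per causal variant on the standardized-dosage scale, Gaussian noise is
scaled so the genetic variance fraction equals `heritability_like`, and an
optional confounder (e.g. BMI, itself N(21, 3²) kg/m²) adds a standardized
effect. The liability is observed directly (quantitative), cut at the
(1 − prevalence) quantile (binary; default prevalence 0.1, set to ~0.02
when emulating menstrual fever), or cut at empirical quantiles into
ordered levels. Default ordinal cut points: the 5-level pain scale uses
cumulative probabilities (0.15, 0.35, 0.55, 0.80) — a right-heavy
distribution in which most respondents report some pain; the 8-level bust
code uses (0.04, 0.22, 0.52, 0.76, 0.89, 0.95, 0.98), concentrated on
codes 1–3. The source cohort's stage-specific phenotype distributions are
not published beyond counts, so these are declared defaults, not
inferences. Expression traits add causal dosage effects (default 0.6 per
standardized dosage) to unit Gaussian noise and are standardized to
mean 0 / sd 1, matching the convention under which eQTL betas are
interpreted with sdY = 1.

All randomness flows from explicit integer seeds; a run is bit-identical
under the same seed. Two study stages are emulated as disjoint sample
draws from one simulated panel.

## Association layer

Ordinal traits enter linear regression after encoding (bust codes 0–7
used as integers; pain levels mapped to NRS 0/1/2/5/10, which linearises
severity against pain-medicine use). The covariate screen includes PC1 and
PC2 always and adds Age or BMI when univariately associated with the
phenotype at P < 0.05; the screen runs per stage (matching per-stage GWAS
followed by meta-analysis) and is invariant to affine rescaling of a
candidate. Missing phenotype values are handled complete-case per trait.

The HWE test is the exact conditional test: given the allele counts, the
probabilities of all heterozygote counts no more likely than the observed
one are summed; it is implemented with log-gamma weights and verified
against a full exact-rational enumeration for totals ≤ 200. Linear scans
use Frisch–Waugh residualization (numerically identical to per-variant
multiple regression, including degrees of freedom); logistic fits come
from statsmodels, with perfect separation flagged rather than reported as
a huge SE. Fixed-effects meta-analysis is inverse-variance weighting with
allele alignment (a swapped effect/other pair flips the beta sign;
irreconcilable pairs are dropped with a warning); a variant present in a
single stage passes through unchanged, which reproduces the behaviour of
traits collected in only one stage. The chromosome-X case is treated as
autosomal dosage, appropriate for an all-female cohort. FDR is
Benjamini–Hochberg step-up (the standard reading of "FDR"), and
replication FDR is computed within the lookup set of previously reported
SNPs, not genome-wide.

## Signal refinement

Clustering of significant variants is single-linkage within a maximum gap,
default 1 Mb — the analysis this models never quantifies "neighboring",
and 1 Mb matches the ±2 Mb regional-imputation intent; it is configurable.
A cluster counts as a signal only when more than one genotyped SNP passes
the nominal threshold. The top SNP is the smallest p, ties broken by
larger |z| then lower position (the tie-break is our choice). Conditional
statistics are computed on the pooled stages with a stage-indicator
covariate so Z_A, Z_B and Z_B|A come from one analysis; r²_equiv uses
chi-square statistics and RSS uses |z|, per their respective definitions.
Negative r²_equiv values are finite-sample artifacts: they are reported
unclipped and flagged below −0.05. D′ comes from EM phasing of two-locus
dosage pairs (the only phase ambiguity is the double heterozygote); r² is
the composite dosage correlation squared. A summary-statistic
approximation z_B|A = (z_B − r·z_A)/√(1−r²) is provided and agrees with
the exact genotype-based scan (correlation > 0.95 on matched panels).

## eQTL decomposition and input selection

The greedy assignment iterates SNPs by decreasing |z| (ties by position):
each seed captures unassigned SNPs with combined-panel r² > 0.05, unless
RSS/r² exceeds the ratio threshold, in which case the SNP stays unassigned
and may seed its own signal later. The ratio threshold defaults to 3 (the
most conservative of the candidate values 3/5/10 about merging);
seeding stops when no unassigned SNP reaches p < 1e-4 (the stopping rule
is our choice; there is no canonical one). With one LD panel the combined
r² is that panel's value. Before colocalization, SNPs assigned to
non-target signals are masked out; an eQTL signal is tested only when it
shares at least one highly ranked SNP with the GWAS signal (GWAS
r²_equiv > 0.7 and eQTL RSS > 0.7, both strict). For multi-tissue
statistics, FE beta/SE inputs are used when |Z_FE| and |Z_RE2| correlate
at Pearson r > 0.8 (strict), otherwise RE2 p-values with MAF and sample
size; RE2 statistics are consumed as inputs, never computed.

## Colocalization

Wakefield log-ABFs use prior effect variances W = 0.15² (quantitative,
sdY = 1) and 0.2² (log-odds scale, case-control), with per-SNP causal
priors p1 = p2 = 1e-4 and p12 = 1e-5 — the conventional ABF defaults, all
configurable. Posteriors are accumulated in log space (logsumexp); the H3
term subtracts the matched-SNP mass from the product of single-trait sums,
guarded against cancellation. The p-value input path reconstructs z from
the two-sided normal p and approximates V = 1/(2 n f (1−f)).

SMR uses T = z₁²z₂²/(z₁²+z₂²) against χ²₁. HEIDI filters neighbors of the
top eQTL SNP to eQTL p < 1.57e-3 and LD r² to the top in (0.05, 0.9),
capping at the 20 strongest (SMR-tool conventions); with fewer than 3
usable neighbors the result is flagged `not-computed` rather than left
silently significant. Wald-ratio deviations are standardized with a
delta-method covariance built from signed LD correlations, and the sum of
squared standardized deviations is referred to the eigenvalue-weighted
chi-square null via Ruben's series of central chi-square CDFs (coefficients
are non-negative and sum to one, so the truncation error is bounded by the
unaccumulated mass; the series is stopped below 1e-9, comfortably inside
the 1e-6 absolute accuracy target). Because the covariance is a
delta-method approximation, the test runs slightly conservative in
simulation (type-I ≈ 0.03–0.05 at the 0.05 level).

Decision tiers follow the thresholds stated in the README; when ABF runs
on RE2 p-values while SMR uses FE statistics the two outputs can disagree,
and both are always reported side by side, never reconciled.

## Annotation

Gene categories are evaluated per (variant, gene) pair in the order
within → upstream → downstream, so each pair gets at most one category;
"within" uses transcript bounds (the transcript file is what the gene
models carry; CDS bounds are not available in it). Upstream/downstream are
strand-aware (5′/3′ of the transcript) with strict < 100 kb and < 40 kb
windows; a plus-strand-literal mode is available. The closest gene (by
nearest transcript edge, ties to the lower position) is reported only when
the three window categories are empty, and "genes (all)" is the union or
that fallback. Coordinates are 1-based inclusive internally; BED exports
are 0-based half-open.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use panels of 8–40 variants at 1,500–5,000
samples, 200 replicates for the r²_equiv calibration, 50 for eQTL signal
recovery, 1,000 summary-level replicates for HEIDI calibration, 30
pipeline replicates for end-to-end classification (top z ≈ 8 in both
traits), and a 5,000-variant null scan for λ_GC. These sizes give stable
Monte-Carlo estimates for the quantities asserted while keeping a full run
in the tens of seconds.

## Known limitations

- Single-causal-variant assumption throughout the ABF machinery; no
  SuSiE-style multi-causal colocalization and no proportional tests.
- The LD generator produces block-diagonal correlation only; conclusions
  about boundary behaviour under long-range LD are out of reach.
- Logistic scans loop per variant (statsmodels) and are markedly slower
  than the vectorized linear path; fine at regional scale, not
  genome-wide.
- Genotype and summary-statistic imputation, PCA/IBD sample QC and
  multi-tissue RE2 meta-analysis are out of scope; their outputs are
  consumed as inputs where needed.
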