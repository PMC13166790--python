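# Methods

`mcpmr` implements a proteome-wide two-sample Mendelian randomization (MR)
workflow for screening circulating plasma proteins as candidate drug
targets for multisite chronic pain (MCP, the count of body sites with
chronic pain, 0–7), together with the validation layers such a screen
needs — replication, directionality, linkage-versus-causality tests,
colocalization, mediation — and a synthetic GWAS generator that makes the
whole workflow testable without any external data.

## Causal model and estimators

All analyses operate on GWAS marginal summary statistics. For an
instrument SNP j with effect `beta_gx,j` (SE `se_gx,j`) on a protein and
`beta_gy,j` (SE `se_gy,j`) on the outcome, after allele harmonisation:

- **Wald ratio** (single instrument): `beta = beta_gy/beta_gx`, first-order
  SE `se_gy/|beta_gx|`. A second-order option adding the exposure-side
  variance term exists but is off by default, matching standard two-sample
  practice where instruments are genome-wide significant and the
  exposure-side noise is negligible.
- **IVW**: inverse-variance weighted mean of the per-SNP Wald ratios,
  algebraically the weighted regression of `beta_gy` on `beta_gx` through
  the origin with weights `1/se_gy^2`. The random-effects variant inflates
  the fixed-effect SE multiplicatively by `sqrt(Q/(k-1))` when Cochran's Q
  exceeds its degrees of freedom and is otherwise identical to fixed —
  so it is always the safe default and is what the pipeline uses.
- **Cochran's Q** with k−1 df for heterogeneity; **Egger regression**
  (free intercept, weights `1/se_gy^2`, instruments oriented to positive
  exposure effect, k−2-df t-test on the intercept) for directional
  pleiotropy; an **MR-PRESSO-style test** whose observed statistic is the
  weighted leave-one-out residual sum of squares and whose null is built
  by parametric simulation (default 1000 draws, mandatory explicit seed;
  the global p is the plain fraction of simulated RSS at or above the
  observed one and can be exactly 0 at finite simulation count). Outliers
  are flagged per-SNP at a Bonferroni-corrected 0.05.
- **Steiger directionality**: variance explained summed over instruments
  on each side via `R^2 = 2·EAF·(1−EAF)·beta^2`, compared by Fisher z
  transform. Ties count as *not* correctly oriented (conservative).
- **Instrument strength**: `F = R^2·(N−2)/(1−R^2)` with the same `R^2`.
  Both formulas presuppose variance-standardised phenotypes; the selection
  function refuses to F-filter when the caller cannot assert that scale.

Multiple testing uses Benjamini–Hochberg FDR (statsmodels); the
independent step-up oracle in the tests guards the delegation.

## Instrument selection

Cis-pQTL instruments per protein: p < 5e-8; within 1 Mb of the
protein-coding gene's transcription start site (closed interval, plain
chromosome strings); outside the MHC (chr6 26–34 Mb, closed, variant
position); greedy LD clumping at r² < 0.001 within a ±10 Mb
center-to-center window (best p first, ties broken by chromosome,
position, SNP id); F > 10. All clump survivors are kept as instruments,
not just the single lead SNP. SNPs absent from the LD reference are
treated as unlinked and logged. Every threshold is a `RunConfig` field and
is echoed into the run log.

Harmonisation aligns the outcome onto the exposure's effect allele;
swapped labels negate the outcome beta and complement its frequency.
Palindromic (A/T, C/G) single-base variants are strand-ambiguous: they are
dropped when either trait's EAF is within 0.08 of 0.5 and otherwise
oriented by frequency concordance. Indels are never palindromic.
Duplicate SNP ids are a hard error, surfacing upstream faults rather than
silently deduplicating.

## SMR and HEIDI

The SMR statistic at the top cis-QTL is
`T = z_gx²·z_gy²/(z_gx²+z_gy²) ~ χ²(1)`. HEIDI tests whether SNPs in LD
with the top QTL estimate the same ratio: deviations `d_i = b_i − b_top`
have a delta-method covariance combining the per-SNP ratio variances with
the LD-induced correlation of marginal z-scores (two-sample design, so
exposure and outcome errors are independent);
`T_HEIDI = Σ (d_i/sd_i)²` is referred to the matching eigenvalue-weighted
χ² mixture. The mixture tail probability uses Imhof's integral
(scipy quadrature, absolute tolerance 1e-12) with two guards: an exact
scaled-χ² shortcut when all eigenvalues are equal, and a two-moment
Satterthwaite fallback if the integration fails. Eligibility follows the
published SMR tool's conventions: 0.05 < r² < 0.9 against the top SNP,
exposure p < 1.57e-3, at most 20 SNPs (strongest exposure association
first, ties by SNP id); fewer than 3 eligible SNPs yields an absent
("NA") HEIDI p rather than a fabricated one. HEIDI "pass" defaults to
p ≥ 0.01.

## Colocalization

Wakefield approximate Bayes factors
`log ABF = ½[log(1−r) + r·z²]`, `r = W/(W+se²)`, with effect-prior SD
W^0.5 = 0.15 for quantitative traits and 0.2 for binary ones, under the
single-causal-variant-per-trait assumption. Hypothesis sums are
accumulated in log space; H3 (two distinct causal variants) is the full
cross-product minus the shared-variant diagonal, computed with
`log1p(−exp(·))` rather than naive subtraction. Priors default to
p1 = p2 = 1e-4, p12 = 1e-5. The locus is ±500 kb around the lead
cis-pQTL. Two pass thresholds are carried deliberately: PPH4 > 0.8 as
"strong evidence", and a separate configurable tiering threshold
(default 0.6) because published target-tiering practice tolerates lower
PPH4 when PPH3+PPH4 is high; both are logged per run.

## Mediation

For a risk factor R, mediator protein M and outcome Y, with MR estimates
β1 (R→M), β2 (M→Y) and total effect c′ (R→Y): indirect effect β1β2, Sobel
SE `sqrt(β2²se1² + β1²se2²)`, proportion mediated β1β2/c′ with a
first-order delta CI over (β1, β2, c′) treated as independent (a
two-sample idealisation; real cohorts overlap, and a c′-fixed two-term
variant is available). Proportions are reported as percentages. A pathway
is *reliable* only if Sobel p < 0.05, the indirect and total effects
agree in sign, and the total-effect Egger intercept shows no pleiotropy
(p ≥ 0.05) — pleiotropic totals are excluded regardless of the Sobel
result.

## Evidence tiers

For each discovery-significant protein: tier 3 if replication evidence is
unavailable or negative; otherwise tier 1 if SMR, HEIDI, colocalization,
reverse-MR nullity and Steiger all pass, tier 2 if any fails. A
validation that could not be run (e.g. HEIDI with < 3 eligible SNPs) does
not count as a failure. Replication itself requires nominal p < 0.05 with
direction consistent with discovery. The classifier is a pure function;
the tests enumerate all 64 flag combinations against an independently
written rule table.

## Synthetic data generator

The generator emulates the statistical structure of the study's inputs,
not their genomic realism:

- **Genotypes**: per LD block, two haplotype-level latent Gaussian AR(1)
  vectors (adjacent correlation ρ, default 0.8) thresholded at each SNP's
  MAF quantile and summed — Hardy–Weinberg 0/1/2 dosages with
  geometrically decaying LD. MAFs are uniform on (0.05, 0.45); cohorts
  share MAFs but draw independent panels (two-sample designs).
- **Traits**: linear genetic values plus Gaussian noise, standardized
  before per-SNP simple regression so the `R²` formula used for F and
  Steiger is exact on the emitted scale. The MCP outcome is simulated as
  a standardized quantitative trait — the real phenotype is a 0–7 count,
  which large-cohort GWAS analyse with linear models anyway. Binary
  phenome traits use a logistic liability with summary statistics from
  linear regression on the 0/1 outcome (biobank practice), carrying
  case counts for the >500-cases filter.
- **Scenarios**: single-locus H0–H4 layouts for colocalization (H4's
  outcome effect is `theta` times the exposure effect at the shared
  variant), multi-instrument `effect_mr`/`null_mr`, and a
  `mediation_chain` with c′ = β1β2 + direct.
- **Study layout**: each protein, risk factor, and the outcome's own
  polygenic background occupies several independent mini-blocks on its
  own chromosome with one causal variant per block, so clumping leaves
  multiple independent cis instruments per protein (as in the real
  proteome) and reverse MR has genuine outcome instruments. Replication
  is a smaller independent cohort (default n = 5000) covering only a
  subset of proteins: at the published replication cohort's actual size
  (hundreds of samples) no variant can reach p < 5e-8 at desk-scale
  effect sizes, so incomplete coverage is modelled as per-protein data
  availability, which is also what limited the original replication.
- **Summary-level fast path**: for repetition-heavy calibration, marginal
  estimates are drawn directly from their exact sampling distribution
  (independent instruments) or from the standard multivariate-normal
  z-score model `z ~ N(R·z_true, R)` over an LD block. This is the same
  data-generating process the genotype route converges to and runs three
  orders of magnitude faster; the genotype route is still exercised
  directly by the colocalization scenario checks and the end-to-end
  pipeline.

What passing tests on these data do **not** show: robustness to
imputation noise, allele-frequency mismatch between cohorts, sample
overlap, non-European LD, genuine recombination-map LD structure, or
winner's-curse effects of instrument selection in finite proteomes.

## Problem sizes and numerical choices

Default study scale (the analysis drivers): 12 proteins × 4 blocks × 8
SNPs plus risk factors and outcome background (512 variants), cohort
sizes 20k (proteins, risk factors), 50k (outcome), 5k (replication) —
seconds on one CPU. Calibration checks use 2000 replicates (IVW, Egger
nulls), 1000 (HEIDI null), 500 (recovery), 200 (mediation coverage,
Steiger), 100 (PRESSO, coloc H4 at n = 50k genotype-level). These sizes
give Monte-Carlo standard errors a few times smaller than the acceptance
bands.

p-values are floored at 1e-300 to stay inside (0, 1]; empirical LD is
clipped to [−1, 1] with unit diagonal; LD matrices must be symmetric to
1e-8; coloc posteriors renormalise after the log-sum-exp; Egger on
exactly colinear data reports a zero-variance exact fit rather than
dividing by zero. PRESSO seeds are derived deterministically from the run
seed, so whole-pipeline reruns are byte-identical.

## Known limitations

- Single-causal-variant assumption in colocalization (no SuSiE-style
  multi-signal decomposition).
- First-order ratio SEs and the HEIDI delta covariance assume strong
  instruments; both degrade for weak top QTLs.
- The mediation CI treats the three MR estimates as independent.
- No correlated-instrument IVW; clumping is assumed to have removed LD.
- The generator's AR(1) blocks cannot produce long-range LD such as the
  real MHC; the MHC filter is exercised positionally, not structurally.
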