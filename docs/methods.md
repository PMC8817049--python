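# Methods

`medtwas` implements a distal mediator-enriched transcriptome-wide
association (TWAS) pipeline together with a synthetic multi-omic cohort
generator that reproduces the statistical structure the pipeline assumes.
This note documents the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic data does and does not
emulate.

## Generative model of the synthetic cohort

**Genotypes.** Variants live on independent LD blocks, one block per
chromosome. Within a block each haplotype is a latent AR(1) Gaussian with
adjacent-variant correlation `ld_rho` (default 0.7, roughly the
adjacent-marker LD of a dense array at kilobase spacing), thresholded at
the Gaussian quantile of a per-variant MAF drawn uniformly from
`maf_range` (default 0.05–0.5). Dosage = sum of two independent
haplotypes, so every variant is in Hardy–Weinberg equilibrium, blocks are
exactly independent, and expected LD has a closed form — which is what
makes the LD-dependent oracle tests of the burden machinery possible.
Using one block per chromosome makes block membership and the cis/distal
dichotomy coincide: all variants of a block are within 1 Mb of a feature
placed on it, and everything else is distal.

**Mediators.** Each mediator (regulatory-protein transcript, miRNA, or
CpG site, cycling in that order) occupies its own block, has 1–3 cis-QTLs
drawn from the block, and cis-heritability `h2_mediator` (default 0.4).
Intensities are emitted scaled to zero mean, unit variance — the scale
every scan operates on. CpG mediators are simulated directly on the
M-value scale, the scale used for statistics; the β↔M transforms
(`beta_value`, `m_value`) are provided for format fidelity, with the
logit taken base 2.

**Gene expression.** A gene's expression is

    y = (local SNP effects) + Σ_m γ_m · (mediator m intensity) + ε,

with the local genetic variance `h2_local` (default 0.2) and, for a
`mediation_fraction` of genes, the coefficient γ sized so the *genetic*
variance reaching the gene through each mediator's cis-QTLs equals
`h2_distal` (default 0.2): γ = sqrt(h2_distal / h2_mediator). The
mediator's environmental variance, γ²(1 − h2_mediator), is therefore part
of the gene's non-genetic variance — which is exactly the property the
mediation tests need: conditioning on the mediator intensity removes the
distal SNP–gene association entirely. Defaults sum to total expression
heritability 0.4, matching reported mean SNP-heritability of placental
expression (≈0.39). Realized (sample) variance components are recorded in
a truth ledger for recovery tests.

**GWAS.** An independent cohort is drawn from the same variant panel; the
trait is a standard-normal-weighted sum of gene *genetic* values, scaled
so they explain `trait_h2ge` (default 0.05) of trait variance, plus
Gaussian environment. Per-variant Z-scores come from marginal simple
regressions. A third, smaller cohort serves as the LD reference —
mirroring the training-cohort / consortium-GWAS / 1000 Genomes separation
of a real analysis, with no shared samples anywhere.

What the generator does **not** emulate: realistic recombination maps and
inter-block LD, imputation uncertainty, allele-frequency–dependent
architectures, sex chromosomes, relatedness, batch effects, case/control
ascertainment, and population stratification (the covariate table carries
null covariates so adjustment code paths are exercised, not confounding).
Calibration and power results on this generator therefore demonstrate the
statistical machinery, not robustness to those real-data complications.

## Association scans

All scans residualize outcome and predictor on the covariates (plus
intercept) and use per-pair correlation statistics with degrees of
freedom n − k − 2, which reproduces the slope, SE, and t of the full
multiple regression (Frisch–Waugh–Lovell); a brute-force per-pair OLS
oracle is kept in the test suite. Cis means same chromosome and within
±1 Mb (closed interval); distal is everything else. Benjamini–Hochberg
FDR is applied within each scan family (eQTL, mediator-QTL,
mediator-gene), matching the per-analysis FDR convention of TWAS
pipelines. Monomorphic predictors are emitted with NA statistics and a
degeneracy flag rather than silently dropped.

## Expression heritability (model gate)

Heritability per gene uses MAF/LD-stratified variance components
(GREML-LDMS style): variants are binned by MAF and by an LD score
computed from the panel itself (2 × 2 bins by default — the stable
maximum at cohort-scale n), a GRM per stratum is built from standardized
dosages, and strata are fit jointly by REML. Numerically, the GRM is kept
in factored form W = Z/√m so all algebra is O(m²)–O(m³) in variant count,
never sample count: the single-stratum path maximizes the exact spectral
profile likelihood (no iteration); the multi-stratum path runs EM-REML
via the Woodbury identity, asserting the restricted likelihood is
non-decreasing every step (EM's guarantee) and flagging non-convergence
after 500 iterations. The test against h² = 0 uses the boundary-corrected
50:50 χ²₀:χ²₁ likelihood-ratio null, the standard choice for a variance
component constrained to be non-negative; a fit that never leaves the
boundary reports p = 1. A GRM with no eigenvalue spread (e.g. identity)
is flagged unidentifiable with h² = 0.

## Expression models

Three routes share one weight format (SNP → weight on the
standardized-dosage scale, tagged local/distal with mediator provenance):

* **local** — elastic net with mixing fixed at 0.5 and penalty chosen by
  inner 5-fold CV (20-point penalty grid), or a ridge-equivalent BLUP
  from a single-GRM mixed model (`method="lmm"`).
* **MeTWAS** — mediators associated with the gene at FDR < 0.05 (at most
  5, strongest first) each get a local elastic-net model; their in-sample
  imputed intensities enter the gene's elastic net as fixed effects
  alongside the cis-SNPs. The exported distal SNP weight is the
  chain-of-regressions product (mediator coefficient) × (SNP weight in
  the mediator's model), so composed-weight prediction equals the
  two-stage prediction exactly — required for summary-statistic testing.
* **DePMA** — distal-eQTLs at P < 1e-6 that are cis mediator-QTLs
  (FDR < 0.05) are screened by a permutation test (default B = 1000,
  (1 + count)/(B + 1) smoothing so p is never 0) of the absolute total
  mediation effect, TME = total − direct effect with the direct effect
  conditioning on the mediator set; a variant fully collinear with its
  mediators is treated as fully mediated (direct effect 0), and nearly
  collinear mediator sets get a ridge-stabilized direct fit, flagged.
  Surviving variants join the cis-SNPs in the final elastic net.

Cross-validation is fivefold, seeded, stratification-free; out-of-fold
predictions are pooled, R² is the squared correlation between observed
and predicted, and the McNemar adjustment 1 − (1 − R²)(n − 1)/(n − 2)
(ν = 1) is applied once. Both stages of MeTWAS and the final DePMA fit
are refit inside each fold; mediator *selection* and TME screening use
the full-sample scans, as in the reference two-stage designs. A model
enters TWAS only with heritability P < 0.05 and CV adjusted R² ≥ 0.01.

## TWAS tests

Harmonization matches variants by (chrom, pos), flips Z for swapped
alleles, drops strand-ambiguous (A/T, C/G) variants by default, and skips
a gene when under 50% of its absolute weight mass matches. The burden
statistic is w·Z / √(w Σ w′) against N(0,1); Σ is the reference-panel
correlation matrix shrunk as (1 − λ)Σ̂ + λI with λ = 0.1, which keeps Σ
positive definite at reference-panel n. The permutation test shuffles the
weight-to-SNP assignment (B = 1000) and is triggered below the
transcriptome-wide threshold 2.5e-6. The added-last statistic is the
conditional residual of the distal weighted score given the local one
under their joint bivariate normal; fully collinear distal weights are
flagged untestable. On individual genotypes, GReX = standardized dosages
× weights (missing variants contribute zero, coverage reported) with
linear or logistic Wald scans.

## Expression-mediated heritability

Gene LD scores are l_i = Σ_j r²(GReX_i, GReX_j) over the model set, self
included, computed in the reference panel. h²GE is the OLS slope of the
per-gene χ² on l rescaled by M/N, with a 200-block delete-one-block
jackknife SE and a one-sided test of h²GE > 0; the intercept (1 under the
model) is reported as a diagnostic. Expression-level genetic correlation
regresses the Z-score cross product of two traits on the same l,
normalizes by √(h²GE,1 · h²GE,2), clamps to [−1, 1] (flagged), and is
refused when either h²GE is non-positive. Point estimates are invariant
to gene ordering; jackknife SEs depend weakly on the blocking. h²GE
standardized by a trait's SNP-h² is a ratio the caller forms; genome-wide
SNP-level LD-score regression is out of scope and SNP-h² is an input.

## Follow-up analyses

**GBAT.** The regulator's GReX is predicted from its cis-SNPs by ridge
with the penalty chosen by leave-one-out error *of the regulator* (closed
form via the hat matrix, so no refitting), and the target is regressed on
the LOO prediction (t-test, df = n − 2 − k). LOO is essential: in-sample
prediction leaks the regulator's environmental noise into the predictor
and inflates the scan whenever regulator and target co-express; the test
suite demonstrates the inflation of the naive variant. A near-constant
LOO prediction (no cis signal) is flagged untestable.

**Egger MR.** Inverse-variance weighted regression of per-instrument
outcome effects on exposure effects *with* intercept; slope = causal
effect, intercept = directional pleiotropy, 95% CI via the t distribution
on k − 2 df. At least 3 instruments are required; a greedy selector
(exposure P < 1e-3, LD-pruned at r² < 0.1, optional direct-outcome
screen; all thresholds exposed) is provided.

**qPCR / DE utilities.** ΔΔCT fold change 2^(−ΔΔCT) with per-sample
computation and mean ± SD summaries; the differential-expression call
requires |log2FC| above a threshold and p below the Bonferroni level
α/m. The fold-change threshold is exposed (`lfc_threshold`, default 1.0)
rather than fixed, because conventions differ between 0.5 and 1 even
within a single study.

## Designed operating points

The experiments module fixes the study conditions the acceptance checks
run at: training n = 300 with h2_local = h2_distal = 0.2 for the model
comparison; analytic GWAS summary statistics at N = 50,000 with per-gene
trait variance 0.004 (a strong TWAS gene, |Z| in the low teens) for the
added-last power arm; M = 1,000 genes at h²GE = 0.05 for heritability
recovery; n = 5,000 with 500 causal-tagging variants for REML recovery;
n = 149 (an external-validation-sized cohort) for GBAT calibration.
These sizes were chosen once as representative desk-scale versions of the
corresponding real analyses.

## Known limitations

Cohort-scale REML SEs are reported only for the single-stratum spectral
path; the EM path reports the LR p-value without an SE. The burden
calibration inherits a small conservatism/anticonservatism trade-off from
LD shrinkage (λ = 0.1) when the reference panel is small. The generator's
exact in-sample variance scaling makes realized heritabilities less
dispersed than a fully random-effects simulation; recovery tolerances in
the tests account for the residual Monte-Carlo error only.
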