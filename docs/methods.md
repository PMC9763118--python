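# Methods

This note records the models, numerical choices and limitations behind
`pathprs`, in the spirit of a statistical software appendix.

## Scores

All scores are "standard weighted allele" sums `raw_i = Σ_j d_ij β̂_j`
over imputed effect-allele dosages, standardized across samples so
downstream odds ratios are per SD of PRS.  Three filters select the
variants `j` of a configuration:

1. **SNP-set membership.**  The genome-wide distance set is all variants;
   the genome-wide eQTL set (one per resource) keeps variants with a
   nominally significant (strict p < 0.05) cis-association with *any*
   gene; pathway sets restrict to the pathway's merged gene list.  The
   distance rule is gene body ± `flank_bp` (default 50 kb), inclusive on
   both bounds, anchored to the gene body rather than the TSS (the usual
   choice in gene-set PRS tools; the TSS anchor applies only to the cis
   window).  The cis window is `|pos − TSS| ≤ 1 Mb`, inclusive, and hence
   strand-dependent.
2. **LD clumping.**  Greedy: rank by discovery p (ties: smaller position,
   then lexicographic id); the best unclaimed variant becomes an index and
   claims all unclaimed variants on its chromosome within `window_bp`
   (1 Mb) at dosage r² ≥ 0.1.  LD is estimated in the target sample's
   dosages — no external reference panel is configured, matching common
   PRS-tool defaults.  Clumping runs once, genome-wide; pathway sets are
   intersected with the genome-wide index pool afterwards.  This keeps
   pathway scores and their permutation nulls in the same clumped
   universe and makes SNP accounting consistent; clumping within each
   pathway separately would let two pathways retain mutually correlated
   variants and would require re-clumping every permutation null.
3. **p-value threshold.**  `pval ≤ pt`, non-strict.  Main analysis:
   pt ≤ 0.05 genome-wide, pt ≤ 1 for pathways (so thinly covered pathways
   are not reduced to a handful of SNPs); the sensitivity analysis swaps
   the two.

Allele harmonization keeps a variant when the discovery and genotype
allele pairs match (sign +1) or are swapped (sign −1, beta negated);
strand-ambiguous A/T and C/G variants and outright pair mismatches are
dropped with counts.  Strand flips against complement alleles are *not*
attempted: inputs are assumed strand-aligned, as the synthetic data are
and as imputed cohort data typically are after QC.

## Association statistics

Logistic regression of status on the standardized score plus the first
five principal components of the column-standardized dosage matrix
(computed exactly via the sample-Gram eigendecomposition; component signs
fixed so the largest-magnitude loading is positive).  Reported:

* OR per SD with 95 % Wald CI `exp(β ± 1.96 SE)` and two-sided Wald p.
  Wald intervals are the PRS-literature standard; profile-likelihood
  intervals would differ only in tiny samples.
* **Nagelkerke ΔR²** — `R²_N(full) − R²_N(covariates-only)` with
  `R²_N = [1 − exp(2(L₀ − L)/n)] / [1 − exp(2 L₀/n)]`, `L₀` the
  intercept-only log-likelihood.
* **Liability-scale R²** — the ascertainment-corrected case-control
  transformation: with prevalence K, sample case fraction P, threshold
  `t = Φ⁻¹(1−K)`, `z = φ(t)`, `m = z/K`,
  `C = K²(1−K)² / (z² P(1−P))`, `θ = m(P−K)/(1−K) · (m(P−K)/(1−K) − t)`,
  `R²_l = C·R²_o / (1 + C·θ·R²_o)`.  The observed-scale input `R²_o` is
  selectable: the Nagelkerke ΔR² (default, mirroring common practice in
  PRS reports) or a linear-model ΔR² of the 0/1 status on the score given
  covariates (the scale the correction is actually derived for).  The two
  differ modestly; neither is presented as canonical, and the flag
  `liability_input` switches them.
* **AUROC** without covariates, trapezoidal/Mann–Whitney with ties
  counted ½.
* **Bonferroni** threshold `α/m` over the m enumerated scores (0.05/18 in
  the two-resource, five-pathway design).  The exact value 0.0027(7) is
  conventionally printed truncated to 0.0027; the package reports the
  exact quotient and truncates only for display.

A Newton–Raphson logistic solver with step-halving (ridge 1e-10 on the
Hessian; non-convergence or |β| > 50 flagged as separation) backs the
permutation loop, where tens of thousands of small fits are needed;
`fit_logistic` itself uses statsmodels and the two agree to ~1e-8 in
log-likelihood (tested).

The batch negative-control filter regresses batch membership on each
variant's dosage (cases only, exactly two batches), then applies
Benjamini–Hochberg at FDR 5 %; flagged variants are candidates for
removal as genotyping-batch artifacts.

## Competitive enrichment

The association-strength metric is the covariate-adjusted Nagelkerke ΔR²
of the PRS term — monotone in the likelihood-ratio statistic, so ranking
and ties are well defined.  For each pathway score, `n_perm` (default
10 000) random variant sets are drawn uniformly without replacement from
the genome-wide post-clump, post-threshold pool of the same mapping
scheme, **matched on the pathway set's post-clump SNP count**;
`x = #{null ΔR² ≥ observed}` (ties conservatively count against the
pathway) and `p = max(x, 1)/n_perm`, so 10 000 permutations can report
p-values down to 1e-4 but never 0.  Sampling from the already-clumped
pool avoids re-clumping per draw and keeps null and observed scores on
identical footing.  Null sets are not stratified by chromosome or MAF;
plain uniform sampling is the documented choice.  Each configuration
receives an independent seed substream from the run's global seed, so
identical (inputs, seed) reproduce `x` exactly.

## Synthetic data

The generator emulates a first-episode-psychosis-style study:

* **Genotypes.**  One pseudo-chromosome, variants every 2 kb, LD blocks of
  10 variants.  Haplotypes follow a one-factor latent-Gaussian model:
  within a block, variant latents share a factor `u`; the allele is 1 when
  the latent falls below the MAF quantile; dosage = two haplotypes.
  Because thresholding attenuates correlation, the latent loading is
  tetrachoric-inverted per block so the realized *allele* correlation hits
  the configured `within_block_r` (default 0.8; realized median within-
  block dosage r² ≈ 0.64, between-block r² ≈ 0).  Variants in a block
  share a base MAF with ±0.03 jitter, as variants in strong LD do.  A
  `subpop_maf_shift` toggle creates a two-subpopulation ancestry axis for
  principal-component tests.
* **Phenotype.**  Liability = `√h² · g_std + √(1−h²) · ε` with
  `g_std` the standardized true genetic score; disease when liability
  exceeds `Φ⁻¹(1−K)` (K = 0.7 % by default).  The case-control sample is
  then ascertained to case fraction P (default 0.6, matching the
  roughly 60/40 case-control splits of the motivating cohorts).  Because
  only causal variants determine liability, the sampler genotypes the
  whole population pool at causal variants only, ascertains, and fills in
  the remaining variants of retained individuals from their exact
  conditional distribution given the stored block factors — the same
  joint law as genotyping the full pool (an internal bit-identity check
  asserts the causal columns match), at a fraction of the cost.
* **Causal architecture.**  ~1 % of variants causal
  (`h² = 0.3` split equally in variance); the designated pathway's
  variant span carries a five-fold per-variant causal density by default,
  with the overall density held at `prop_causal`.
* **Discovery GWAS.**  `β̂ = β + N(0, se²)`, `se = 1/√(N·2·maf(1−maf))`
  with effective N = 50 000; p two-sided Wald.  Marginal effects ignore
  LD between causal and tagging variants — discovery betas are centred on
  each variant's own true effect — so LD-tagging inflation of
  neighbouring variants is not emulated.
* **eQTLs.**  Every variant-gene pair inside the cis window is emitted;
  a spike fraction are "true" eQTLs with log-uniform small p-values, the
  rest uniform.  Two resources with different spike fractions stand in
  for a small- and a large-sample eQTL database.
* **Gene sets.**  Genes tiled every ~200 kb; round-robin assignment to
  five pathways; each pathway split into two overlapping "keyword" member
  sets so the merge step is exercised.

What passing tests on these data do **not** show: behaviour under real
human LD (long-range, variable block sizes), allele-frequency-dependent
genetic architectures, confounded population structure, genotyping error
or missingness (dosages are complete by construction), or multi-ancestry
weight portability.

## Problem sizes and numerical choices

* Calibration and power suites run at reduced but adequate scale chosen
  for desk-scale reproducibility: null calibration with 200 replicate
  random "pathways" (600 samples, 2 000 variants, 500 permutations);
  power/recovery over 20 seeds of the default conditions (2 000 samples,
  5 000 variants, 300 permutations per pathway).  The defaults themselves
  (10 000 permutations) remain the production setting.
* Floating-point: dosage validation tolerance 1e-6; score standardization
  exact to 1e-10; the permutation engine guards `llf_full ≥ llf_null`
  against solver jitter before forming ΔR².
* Degenerate inputs are fatal early: empty SNP sets after filtering,
  zero-variance scores, single-class phenotypes, p-values outside (0, 1].
  Monomorphic columns yield r² = 0 in LD computations with a warning
  (they should be MAF-filtered upstream).
* Coordinates are 1-based inclusive internally; BED converts on I/O.
  The dosage-TSV dialect (samples in rows, companion variant-metadata
  table) is defined by this package since no interchange standard exists
  for plain-text dosages; VCF with the DS FORMAT field is the
  self-contained alternative.

## Known limitations

* Competitive nulls are size-matched but not MAF- or chromosome-matched.
* The eQTL scheme treats resources independently; no meta-analysis or
  colocalisation across resources.
* No shrinkage or Bayesian weighting of discovery betas; clumping and
  thresholding only, by design.
* The batch filter supports exactly two genotyping batches.
* Human curation steps of pathway construction (keyword retrieval and
  manual pruning of database gene sets) are outside the package; the
  synthetic keyword sets stand in for them.
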