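"""Build a genome-wide PRS: harmonize, clump, threshold, score, associate.

Reproduces the classic clumping-and-thresholding workflow: align discovery
GWAS alleles with the genotypes, keep LD-independent variants
(r^2 < 0.1 within 1 Mb), apply the p-value threshold pt <= 0.05, form the
weighted-allele score, and regress case-control status on it with five
genotype principal components as ancestry covariates.
"""

from pathprs import (
    ClumpConfig,
    LiabilityParams,
    PathwaySnpSet,
    Phenotype,
    PrsConfig,
    SimConfig,
    associate_prs,
    clump,
    compute_pcs,
    compute_prs,
    harmonize_alleles,
    simulate_case_control_study,
)

study = simulate_case_control_study(SimConfig(n_samples=800, n_variants=2_000,
                                              n_genes=20, seed=3))
stats, report = harmonize_alleles(study.summary_stats, study.dosages.variants)
print(f"harmonized {report.n_kept} variants "
      f"({report.n_flipped} strand-consistent allele swaps, "
      f"{report.n_palindromic_dropped} palindromic dropped)")

clumped = clump(stats, study.dosages, ClumpConfig(r2_threshold=0.1,
                                                  window_bp=1_000_000))
print(f"LD clumping kept {len(clumped)} index variants of {report.n_kept}")

gw_set = PathwaySnpSet("genome_wide", "distance", "",
                       tuple(study.dosages.variant_ids))
score = compute_prs(study.dosages, stats, PrsConfig(0.05, gw_set), clumped)
print(f"PRS built from {score.n_snps_used} variants at pt <= 0.05")

pcs = compute_pcs(study.dosages, 5)
pheno = Phenotype(study.phenotype.sample_ids, study.phenotype.status, pcs)
res = associate_prs(pheno, score, LiabilityParams(0.007, pheno.case_fraction))
print(f"OR per SD = {res.or_per_sd:.2f} "
      f"[{res.ci_low:.2f}-{res.ci_high:.2f}], p = {res.pval:.2e}")
print(f"Nagelkerke delta-R2 = {res.nagelkerke_r2:.3f}, "
      f"liability-scale R2 = {res.liability_r2:.3f}, AUROC = {res.auroc:.3f}")

# An OR per SD well above 1 with p far below 0.0027 (the Bonferroni level
# for 18 scores) is the expected signature of a well-powered genome-wide
# score; the liability R2 restates the variance explained at 0.7%
# population prevalence, removing the case-oversampling distortion.
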