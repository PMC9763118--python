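"""Competitive enrichment: is a pathway-PRS better than random SNP sets?

A pathway score can associate with disease merely because any large SNP set
of a polygenic trait does.  The competitive test recomputes the association
strength (covariate-adjusted Nagelkerke delta-R2) for random variant sets of
the same size drawn from the genome-wide clumped pool, and reports
p = x / n_perm, where x counts the null sets doing at least as well.
"""

from pathprs import (
    ClumpConfig,
    SimConfig,
    clump,
    compute_pcs,
    harmonize_alleles,
    map_snps_by_distance,
    run_enrichment,
    simulate_case_control_study,
)

# near the default study conditions: with ~50 causal variants the enriched
# pathway's advantage is reliably detectable (smaller panels are too noisy)
study = simulate_case_control_study(SimConfig(n_samples=1_500, n_variants=4_000,
                                              n_genes=40, seed=9))
stats, _ = harmonize_alleles(study.summary_stats, study.dosages.variants)
pool = clump(stats, study.dosages, ClumpConfig())
pcs = compute_pcs(study.dosages, 5)

merged = study.merged_pathways
print(f"pool: {len(pool)} clumped variants; "
      f"enriched pathway: {study.truth.enriched_pathway}")
for pathway in merged.names:
    pset = map_snps_by_distance(
        study.dosages.variants, study.genes, list(merged[pathway]),
        flank_bp=50_000, name=pathway,
    )
    res = run_enrichment(
        pset, dosages=study.dosages, stats=stats, pool_ids=pool,
        status=study.phenotype.status, covariates=pcs,
        n_perm=500, seed=42,
    )
    flag = " <-- enriched by construction" \
        if pathway == study.truth.enriched_pathway else ""
    print(f"{pathway}: delta-R2 = {res.observed_stat:.4f}, "
          f"x = {res.x}/{res.n_perm}, competitive p = {res.competitive_p:.3f}"
          f"{flag}")

# The pathway carrying five-fold causal density should show a small
# competitive p (x near 0), while the other four hover anywhere in (0, 1]:
# their scores are no better than random same-size SNP sets.
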