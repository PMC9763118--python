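"""Generator calibration: MAF, LD structure, liability model, GWAS noise."""

import numpy as np
import pytest
from scipy import stats as sps

from pathprs.simulate import (
    SimConfig,
    simulate_case_control_study,
    simulate_eqtls,
    simulate_gene_sets,
    simulate_genotypes,
    simulate_phenotype,
    simulate_summary_stats,
)


def _cfg(**kw):
    base = dict(n_samples=500, n_variants=300, n_genes=6, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestGenotypes:
    def test_realized_mafs_match_targets(self):
        cfg = _cfg(n_samples=5_000)
        dm, truth = simulate_genotypes(cfg)
        realized = dm.dosages.mean(axis=0) / 2
        assert np.abs(realized - truth.maf).max() <= 0.02

    def test_zero_correlation_limit(self):
        cfg = _cfg(n_samples=2_000, within_block_r=0.0)
        dm, _ = simulate_genotypes(cfg)
        c = np.corrcoef(dm.dosages, rowvar=False)
        iu = np.triu_indices_from(c, 1)
        assert (c[iu] ** 2).mean() <= 2 / cfg.n_samples

    def test_within_block_r2_tracks_target(self):
        cfg = _cfg(n_samples=2_000, n_variants=400, n_genes=8, within_block_r=0.9)
        dm, _ = simulate_genotypes(cfg)
        r2 = []
        for b in range(40):
            c = np.corrcoef(dm.dosages[:, b * 10:(b + 1) * 10], rowvar=False)
            r2.extend((c[np.triu_indices(10, 1)] ** 2).tolist())
        assert 0.6 <= np.median(r2) <= 0.95

    def test_between_block_r2_near_zero(self):
        cfg = _cfg(n_samples=2_000, n_variants=400, n_genes=8, within_block_r=0.9)
        dm, _ = simulate_genotypes(cfg)
        first_of_block = dm.dosages[:, ::10]
        c = np.corrcoef(first_of_block, rowvar=False)
        iu = np.triu_indices_from(c, 1)
        assert (c[iu] ** 2).mean() <= 2 / cfg.n_samples

    def test_deterministic_given_seed(self):
        cfg = _cfg()
        a, _ = simulate_genotypes(cfg)
        b, _ = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variants == b.variants

    def test_block_larger_than_panel_fatal(self):
        with pytest.raises(ValueError, match="ld_block_size"):
            _cfg(ld_block_size=1000)


class TestPhenotype:
    def test_h2_zero_means_no_genotype_association(self):
        import dataclasses

        cfg = _cfg(
            n_samples=1_500, h2_liability=0.0, prevalence=0.3, case_fraction=0.3
        )
        dm, truth = simulate_genotypes(cfg)
        target = dataclasses.replace(cfg, n_samples=1_000)
        pheno, truth2 = simulate_phenotype(dm, target, truth)
        sub = dm.subset_samples(pheno.sample_ids)
        g = (sub.dosages - 2 * truth.maf) @ truth.beta_std
        r = np.corrcoef(g, pheno.status)[0, 1]
        assert abs(r) < 4 / np.sqrt(len(g))

    def test_pool_case_count_matches_binomial_expectation(self):
        # liability thresholding at prevalence K yields ~K*N cases in a pool
        from pathprs.simulate import _liability_and_status

        cfg = _cfg(n_samples=20_000, n_variants=100, n_genes=4, n_pathways=2, prevalence=0.05,
                   case_fraction=0.5, h2_liability=0.3)
        dm, truth = simulate_genotypes(cfg)
        g_raw = (dm.dosages - 2 * truth.maf) @ truth.beta_std
        _, status = _liability_and_status(g_raw, cfg, np.random.default_rng(2))
        expected = cfg.prevalence * cfg.n_samples
        sd = np.sqrt(cfg.prevalence * (1 - cfg.prevalence) * cfg.n_samples)
        assert abs(status.sum() - expected) <= 4 * sd

    def test_h2_recovered_from_liability_decomposition(self):
        import dataclasses

        pool_cfg = SimConfig(
            n_samples=100_000, n_variants=100, n_genes=4, n_pathways=2, h2_liability=0.3,
            prevalence=0.5, case_fraction=0.5, seed=8,
        )
        dm, truth = simulate_genotypes(pool_cfg)
        target_cfg = dataclasses.replace(pool_cfg, n_samples=80_000)
        pheno, truth2 = simulate_phenotype(dm, target_cfg, truth)
        sub = dm.subset_samples(pheno.sample_ids)
        z = (sub.dosages - 2 * truth.maf) / np.sqrt(
            2 * truth.maf * (1 - truth.maf)
        )
        g = z @ truth.beta_std
        g = (g - g.mean()) / g.std()
        h2_hat = np.corrcoef(g, truth2.liability)[0, 1] ** 2
        assert h2_hat == pytest.approx(0.3, abs=0.02)

    def test_too_few_cases_fatal(self):
        cfg = _cfg(n_samples=400, prevalence=0.01, case_fraction=0.6)
        dm, truth = simulate_genotypes(cfg)  # pool of 400: ~4 cases expected
        with pytest.raises(ValueError, match="larger pool"):
            simulate_phenotype(dm, cfg, truth)

    def test_ascertained_case_fraction_exact(self, small_study, small_cfg):
        status = small_study.phenotype.status
        assert status.sum() == round(small_cfg.n_samples * small_cfg.case_fraction)
        assert len(status) == small_cfg.n_samples


class TestSummaryStats:
    def test_infinite_discovery_sample_recovers_true_betas(self):
        cfg = _cfg()
        dm, truth = simulate_genotypes(cfg)
        stats = simulate_summary_stats(truth, dm.variants, int(1e12), seed=3)
        assert np.abs(stats.beta - truth.beta_allele).max() < 1e-4

    def test_null_variant_pvalues_uniform(self):
        cfg = _cfg(n_variants=2_000, n_genes=10, prop_causal=0.01)
        dm, truth = simulate_genotypes(cfg)
        stats = simulate_summary_stats(truth, dm.variants, 20_000, seed=3)
        null_p = stats.pval[~truth.causal]
        assert sps.kstest(null_p, "uniform").pvalue > 0.01

    def test_causal_chisq_scales_with_discovery_n(self):
        cfg = _cfg(n_variants=2_000, n_genes=10, prop_causal=0.05, seed=9)
        dm, truth = simulate_genotypes(cfg)

        def mean_excess_chisq(N, seed):
            stats = simulate_summary_stats(truth, dm.variants, N, seed=seed)
            se = 1 / np.sqrt(N * 2 * truth.maf * (1 - truth.maf))
            z = stats.beta / se
            return (z[truth.causal] ** 2).mean() - 1

        lo = mean_excess_chisq(10_000, 1)
        hi = mean_excess_chisq(40_000, 2)
        assert 2.5 <= hi / lo <= 6.0  # fourfold N -> ~fourfold signal


class TestEqtlsAndGeneSets:
    def test_records_confined_to_cis_windows(self):
        cfg = _cfg(n_variants=2_000, n_genes=2, n_pathways=2)  # chromosome spans 4 Mb
        dm, _ = simulate_genotypes(cfg)
        genes = [g for g in _genes_of(cfg)]
        table = simulate_eqtls(dm.variants, genes, cfg, seed_rng(1))
        pos = {v.variant_id: v.pos for v in dm.variants}
        tss = {g.gene_id: g.tss for g in genes}
        d = np.array(
            [abs(pos[r.variant_id] - tss[r.gene_id]) for r in
             table.records.itertuples()]
        )
        assert d.max() <= cfg.cis_bp
        far_variants = [
            v.variant_id for v in dm.variants
            if all(abs(v.pos - t) > cfg.cis_bp for t in tss.values())
        ]
        assert far_variants  # the layout does leave variants outside all windows
        emitted = set(table.records["variant_id"])
        assert not (set(far_variants) & emitted)

    def test_zero_spike_gives_uniform_pvalues(self):
        cfg = _cfg(n_variants=1_000, n_genes=4, n_pathways=2)
        dm, _ = simulate_genotypes(cfg)
        table = simulate_eqtls(
            dm.variants, _genes_of(cfg), cfg, seed_rng(2), spike_frac=0.0
        )
        assert sps.kstest(table.records["pval"], "uniform").pvalue > 0.01

    def test_enriched_pathway_concentrates_causal_variants(self):
        cfg = SimConfig(n_variants=5_000, n_genes=50, seed=13)
        dm, truth = simulate_genotypes(cfg)
        mask = truth.enriched_variant_mask
        density_in = truth.causal[mask].mean()
        density_out = truth.causal[~mask].mean()
        assert density_in > 2 * density_out  # configured factor is 5
        share = truth.causal[mask].sum() / truth.causal.sum()
        f, m_in, m_out = 5, mask.sum(), (~mask).sum()
        expected_share = f * m_in / (f * m_in + m_out)
        assert share >= 0.5 * expected_share

    def test_gene_sets_cover_all_genes_and_overlap_within_pathway(self):
        cfg = _cfg(n_genes=15, n_pathways=5)
        genes = _genes_of(cfg)
        coll, groups, enriched = simulate_gene_sets(genes, cfg)
        assert enriched in groups
        assert len(groups) == 5
        union = set()
        for name in coll.names:
            union |= set(coll[name])
        assert union == {g.gene_id for g in genes}
        for pathway, members in groups.items():
            sets = [set(coll[m]) for m in members]
            assert sets[0] & sets[1]  # keyword sets overlap


class TestStudyDeterminism:
    def test_identical_config_bit_identical_study(self, small_cfg, small_study):
        again = simulate_case_control_study(small_cfg)
        assert np.array_equal(again.dosages.dosages, small_study.dosages.dosages)
        assert again.phenotype.sample_ids == small_study.phenotype.sample_ids
        np.testing.assert_array_equal(
            again.summary_stats.pval, small_study.summary_stats.pval
        )
        for name in again.eqtl_tables:
            np.testing.assert_array_equal(
                again.eqtl_tables[name].records["pval"],
                small_study.eqtl_tables[name].records["pval"],
            )

    def test_causal_columns_of_study_match_pool_stage(self, small_study):
        # internal cross-check: the conditional fill-in reproduced the
        # ascertainment-stage causal dosages exactly (asserted in the
        # generator); here we just confirm causal variants are polymorphic
        causal_cols = small_study.dosages.dosages[:, small_study.truth.causal]
        assert (causal_cols.std(axis=0) > 0).all()


def seed_rng(seed):
    return np.random.default_rng(seed)


def _genes_of(cfg):
    from pathprs.simulate import _build_scaffold

    return _build_scaffold(cfg).genes
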