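"""Association statistics vs closed-form, brute-force and calibration oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from pathprs.association import (
    LiabilityParams,
    Phenotype,
    auroc,
    batch_negative_control_filter,
    bonferroni_threshold,
    compute_pcs,
    fit_logistic,
    liability_r2,
    nagelkerke_delta_r2,
    nagelkerke_r2,
    _logistic_fit,
)
from pathprs.io import DosageMatrix, VariantMeta
from pathprs.scoring import ScoreVector
from pathprs.simulate import SimConfig, simulate_genotypes


def _score(values):
    values = np.asarray(values, dtype=float)
    std = (values - values.mean()) / values.std() if values.std() > 0 else values
    return ScoreVector([f"s{i}" for i in range(len(values))], values, std, 1)


def _pheno(status, covariates=None):
    return Phenotype([f"s{i}" for i in range(len(status))], status, covariates)


class TestComputePcs:
    def test_pc1_separates_two_subpopulations(self):
        cfg = SimConfig(
            n_samples=300, n_variants=400, n_genes=8, subpop_maf_shift=0.2, seed=4
        )
        dm, _ = simulate_genotypes(cfg)
        pcs = compute_pcs(dm, 5)
        group_a, group_b = pcs[:150, 0], pcs[150:, 0]
        assert np.sign(group_a.mean()) != np.sign(group_b.mean())
        gap = abs(group_a.mean() - group_b.mean())
        pooled_sd = np.sqrt((group_a.var() + group_b.var()) / 2)
        assert gap > 3 * pooled_sd

    def test_components_orthogonal(self, small_study):
        pcs = compute_pcs(small_study.dosages, 5)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.diag(gram).max()

    def test_variant_permutation_leaves_pcs_unchanged(self, small_study):
        dm = small_study.dosages
        perm = np.random.default_rng(9).permutation(dm.n_variants)
        dm_perm = DosageMatrix(
            dm.sample_ids,
            [dm.variants[j] for j in perm],
            dm.dosages[:, perm],
        )
        a = compute_pcs(dm, 3)
        b = compute_pcs(dm_perm, 3)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_k_beyond_rank_fatal(self):
        variants = [VariantMeta(f"v{j}", "1", j + 1, "A", "G") for j in range(4)]
        col = np.linspace(0, 2, 3)[:, None]
        dm = DosageMatrix(["a", "b", "c"], variants, np.tile(col, (1, 4)))
        with pytest.raises(ValueError, match="rank|dimensions"):
            compute_pcs(dm, 3)


class TestFitLogistic:
    def test_two_by_two_table_matches_cross_product_ratio(self):
        # exposed cases a=30, exposed controls b=20, unexposed cases c=10,
        # unexposed controls d=40 -> OR = (30*40)/(20*10) = 6
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [30, 20, 10, 40])
        y = np.repeat([1, 0, 1, 0], [30, 20, 10, 40])
        score = ScoreVector([f"s{i}" for i in range(100)], x, x, 1)
        fit = fit_logistic(_pheno(y), score, with_covariates=False)
        assert fit.odds_ratio == pytest.approx(6.0, rel=1e-6)
        assert fit.ci_low < 6.0 < fit.ci_high

    def test_null_pvalues_uniform_and_calibrated(self):
        # PRS independent of status: Wald p uniform over replicates
        r = np.random.default_rng(77)
        n, reps = 300, 500
        pvals = np.empty(reps)
        for b in range(reps):
            y = r.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            score = _score(r.standard_normal(n))
            pvals[b] = fit_logistic(_pheno(y), score, with_covariates=False).pval
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
        rejection = (pvals < 0.05).mean()
        assert 0.031 <= rejection <= 0.069

    def test_ci_symmetric_around_coef_on_log_scale(self, rng):
        y = rng.integers(0, 2, 200)
        score = _score(rng.standard_normal(200))
        fit = fit_logistic(_pheno(y), score, with_covariates=False)
        log_lo = np.log(fit.ci_low)
        log_hi = np.log(fit.ci_high)
        assert (log_lo + log_hi) / 2 == pytest.approx(fit.coef, abs=1e-10)
        assert log_hi - fit.coef == pytest.approx(1.96 * fit.se, abs=1e-10)

    def test_perfect_separation_flagged_not_raised(self):
        y = np.repeat([0, 1], 20)
        score = _score(np.repeat([-1.0, 1.0], 20))
        fit = fit_logistic(_pheno(y), score, with_covariates=False)
        assert not fit.converged

    def test_fast_solver_matches_statsmodels(self, rng):
        y = rng.integers(0, 2, 250)
        cov = rng.standard_normal((250, 3))
        score = _score(y * 0.8 + rng.standard_normal(250))
        fit = fit_logistic(_pheno(y, cov), score, with_covariates=True)
        X = np.column_stack([np.ones(250), cov, score.std_score])
        beta, covm, llf, converged = _logistic_fit(X, y.astype(float))
        assert converged
        assert llf == pytest.approx(fit.llf, abs=1e-8)
        assert beta[-1] == pytest.approx(fit.coef, abs=1e-7)
        assert np.sqrt(covm[-1, -1]) == pytest.approx(fit.se, rel=1e-5)


class TestNagelkerke:
    @staticmethod
    def _reference(llf, ll0, n):
        # independent transcription of the formula
        return (1 - np.exp(-2 * (llf - ll0) / n)) / (1 - np.exp(2 * ll0 / n))

    def test_full_equals_null_gives_zero(self):
        assert nagelkerke_delta_r2(-40.0, -40.0, -60.0, 100) == pytest.approx(0.0)

    def test_matches_independent_transcription(self, rng):
        for _ in range(20):
            ll0 = -rng.uniform(50, 300)
            ll_null = ll0 + rng.uniform(0, 20)
            ll_full = ll_null + rng.uniform(0, 20)
            n = int(rng.integers(50, 1000))
            expected = self._reference(ll_full, ll0, n) - self._reference(
                ll_null, ll0, n
            )
            got = nagelkerke_delta_r2(ll_full, ll_null, ll0, n)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_non_nested_inputs_fatal(self):
        with pytest.raises(ValueError, match="not nested"):
            nagelkerke_delta_r2(-50.0, -40.0, -60.0, 100)

    def test_invariant_to_affine_rescaling_of_prs(self, rng):
        y = rng.integers(0, 2, 300)
        raw = y * 0.7 + rng.standard_normal(300)
        results = []
        for a, b in [(1.0, 0.0), (3.5, -2.0)]:
            score = _score(a * raw + b)
            fit = fit_logistic(_pheno(y), score, with_covariates=False)
            results.append(
                nagelkerke_delta_r2(fit.llf, fit.llf_null, fit.llf_intercept, fit.n)
            )
        assert results[0] == pytest.approx(results[1], abs=1e-8)


class TestLiabilityR2:
    @staticmethod
    def _reference(r2, K, P):
        # independent transcription of the ascertainment-corrected formula
        t = sps.norm.ppf(1 - K)
        z = sps.norm.pdf(t)
        m = z / K
        C = K * (1 - K) / z**2 * K * (1 - K) / (P * (1 - P))
        theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - t)
        return C * r2 / (1 + C * theta * r2)

    def test_zero_maps_to_zero(self):
        assert liability_r2(0.0, LiabilityParams(0.007, 0.5)) == 0.0

    def test_no_ascertainment_reduces_to_simple_scaling(self):
        K = 0.1
        params = LiabilityParams(K, K)
        t = sps.norm.ppf(1 - K)
        z = sps.norm.pdf(t)
        factor = K**2 * (1 - K) ** 2 / (z**2 * K * (1 - K))
        for r2 in (0.01, 0.1, 0.3):
            assert liability_r2(r2, params) == pytest.approx(factor * r2, rel=1e-10)

    def test_matches_independent_transcription_on_grid(self):
        for r2 in (0.0, 0.01, 0.05, 0.2, 0.6):
            for K in (0.007, 0.05, 0.2):
                for P in (0.3, 0.5, 0.614):
                    got = liability_r2(r2, LiabilityParams(K, P))
                    assert got == pytest.approx(
                        self._reference(r2, K, P), abs=1e-10
                    )

    def test_strictly_increasing_in_observed_r2(self):
        params = LiabilityParams(0.007, 0.6)
        grid = [liability_r2(r2, params) for r2 in np.linspace(0, 1, 30)]
        assert all(b > a for a, b in zip(grid, grid[1:]))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(np.array([0.1, 0.2, 0.9]), np.array([0, 0, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert auroc(np.ones(10), np.repeat([0, 1], 5)) == pytest.approx(0.5)

    def test_matches_all_pairs_count(self, rng):
        s = rng.standard_normal(200)
        s[::7] = s[0]  # inject ties
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        cases = s[y == 1]
        controls = s[y == 0]
        wins = sum(
            1.0 if c > d else (0.5 if c == d else 0.0)
            for c in cases
            for d in controls
        )
        expected = wins / (len(cases) * len(controls))
        assert auroc(s, y) == pytest.approx(expected, abs=1e-12)

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc(np.arange(5.0), np.zeros(5))


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_threshold_exact(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_eighteen_tests_printed_precision(self):
        # 0.05/18 = 0.0027(7); truncated at 4 decimals it prints as 0.0027
        thr = bonferroni_threshold(0.05, 18)
        assert thr == pytest.approx(0.05 / 18, rel=1e-12)
        assert int(thr * 1e4) / 1e4 == 0.0027


class TestBatchNegativeControl:
    def _dosages(self, cols, prefix="s"):
        variants = [
            VariantMeta(f"v{j}", "1", (j + 1) * 1000, "A", "G")
            for j in range(cols.shape[1])
        ]
        samples = [f"{prefix}{i}" for i in range(cols.shape[0])]
        return DosageMatrix(samples, variants, cols)

    def test_null_batches_remove_almost_nothing(self, rng):
        cols = rng.binomial(2, 0.3, size=(300, 60)).astype(float)
        labels = np.repeat(["b1", "b2"], 150)
        removed = batch_negative_control_filter(self._dosages(cols), labels)
        assert len(removed) <= 2  # FDR control on 60 null variants

    def test_planted_frequency_difference_is_removed(self, rng):
        cols = rng.binomial(2, 0.3, size=(400, 30)).astype(float)
        cols[:200, 0] = rng.binomial(2, 0.1, 200)
        cols[200:, 0] = rng.binomial(2, 0.9, 200)
        labels = np.repeat(["b1", "b2"], 200)
        removed = batch_negative_control_filter(self._dosages(cols), labels)
        assert "v0" in removed

    def test_zero_fdr_removes_nothing(self, rng):
        cols = rng.binomial(2, 0.5, size=(50, 5)).astype(float)
        labels = np.repeat(["b1", "b2"], 25)
        assert batch_negative_control_filter(self._dosages(cols), labels, 0.0) == []

    def test_single_batch_warns_and_removes_nothing(self, rng):
        cols = rng.binomial(2, 0.5, size=(50, 5)).astype(float)
        with pytest.warns(UserWarning, match="single batch"):
            removed = batch_negative_control_filter(
                self._dosages(cols), np.repeat("b1", 50)
            )
        assert removed == []
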