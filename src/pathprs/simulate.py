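"""Synthetic data with the statistical structure the pipeline assumes.

Generates every input the analysis consumes — LD-block-structured dosages,
a noisy external discovery GWAS over true polygenic effects, cis-eQTL
tables enriched near transcription start sites, keyword-style gene sets,
and liability-threshold case-control phenotypes with configurable
pathway-concentrated heritability and case ascertainment — on a single
pseudo-chromosome, so every module and the end-to-end run are testable
without downloads.

Genotype model
--------------
Haplotypes come from a one-factor latent-Gaussian model: within an LD block
of ``ld_block_size`` variants, the latent for variant ``j`` on one
haplotype is ``z_j = sqrt(r) u + sqrt(1 - r) e_j`` with a block-shared
factor ``u``, giving every within-block latent pair correlation ``r`` and
zero correlation across blocks.  The allele is 1 when ``z_j`` falls below
the variant's MAF quantile; the dosage is the sum over the two haplotypes.
Thresholding attenuates the correlation, so realized dosage r^2 sits below
``within_block_r**2``; variants within a block share a similar MAF (a base
value with small jitter), as variants in strong LD do in real data.

Phenotype model
---------------
Liability = sqrt(h2) * standardized true genetic score
+ sqrt(1 - h2) * N(0, 1); disease when liability exceeds the population
prevalence quantile.  Case-control samples are then ascertained to a target
case fraction, exactly as a clinical cohort oversamples cases.  For rare
prevalence the population pool implied by the target case count is large,
so the efficient sampler generates only causal-variant genotypes (which
fully determine liability) for the whole pool, ascertains, and then fills
in the remaining variants of the retained individuals from their exact
conditional distribution given the stored block factors — the same joint
law as genotyping the whole pool, at a fraction of the cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats as sps

from . import io as pio
from .association import Phenotype
from .io import (
    DosageMatrix,
    EqtlTable,
    GeneAnnotation,
    GeneSetCollection,
    SummaryStats,
    VariantMeta,
)
from .mapping import map_snps_by_distance, merge_gene_sets

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_summary_stats",
    "simulate_eqtls",
    "simulate_gene_sets",
    "simulate_case_control_study",
    "write_study",
]

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror a first-episode-psychosis-style design: a target sample
    of 2,000 with 60% cases ascertained from a population where the disorder
    has 0.7% prevalence, 5,000 common variants in 10-variant LD blocks,
    liability heritability 0.3 spread over ~1% causal variants, one pathway
    carrying five-fold causal density, and external GWAS weights from an
    effective discovery sample of 50,000.
    """

    n_samples: int = 2_000
    n_variants: int = 5_000
    n_genes: int = 50
    ld_block_size: int = 10
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_liability: float = 0.3
    prop_causal: float = 0.01
    pathway_enrichment_factor: float = 5.0
    prevalence: float = 0.007
    case_fraction: float = 0.6
    discovery_n: int = 50_000
    n_pathways: int = 5
    eqtl_spike_frac: float = 0.15
    variant_spacing_bp: int = 2_000
    gene_length_bp: int = 20_000
    flank_bp: int = 50_000
    cis_bp: int = 1_000_000
    subpop_maf_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ld_block_size > self.n_variants:
            raise ValueError("ld_block_size exceeds n_variants")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if not (0 <= self.h2_liability < 1):
            raise ValueError("h2_liability must lie in [0, 1)")
        for name in ("prop_causal", "prevalence", "case_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.pathway_enrichment_factor < 1:
            raise ValueError("pathway_enrichment_factor must be >= 1")
        if self.discovery_n <= 0:
            raise ValueError("discovery_n must be positive")
        last_gene_end = (self.n_genes - 1) * self._gene_spacing() + self.gene_length_bp
        if last_gene_end > self.n_variants * self.variant_spacing_bp:
            raise ValueError("genes do not fit on the simulated chromosome")

    def _gene_spacing(self) -> int:
        # tile genes across the chromosome (~200 kb apart at default sizes)
        return (self.n_variants * self.variant_spacing_bp) // self.n_genes


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    maf: np.ndarray
    block_id: np.ndarray
    causal: np.ndarray  # bool per variant
    beta_std: np.ndarray  # effect per standardized genotype
    beta_allele: np.ndarray  # effect per effect-allele count
    enriched_pathway: str
    enriched_variant_mask: np.ndarray  # bool: variant maps to enriched pathway
    liability: np.ndarray | None = None  # per retained sample
    status: np.ndarray | None = None


@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, generated from one SimConfig."""

    config: SimConfig
    dosages: DosageMatrix
    phenotype: Phenotype
    truth: SimTruth
    summary_stats: SummaryStats
    genes: list[GeneAnnotation]
    gene_sets: GeneSetCollection  # keyword-style member sets
    groups: dict[str, list[str]]  # pathway -> member set names
    eqtl_tables: dict[str, EqtlTable]

    @property
    def merged_pathways(self) -> GeneSetCollection:
        return merge_gene_sets(self.gene_sets, self.groups)


# ---------------------------------------------------------------------------
# scaffold: variants, genes, gene sets, causal architecture
# ---------------------------------------------------------------------------


def _latent_rho_for_target(maf: float, target: float) -> float:
    """Latent-Gaussian correlation giving a target allele correlation.

    Thresholding attenuates correlation, so hitting a target phi
    (Pearson correlation of the 0/1 alleles, hence of dosages) requires a
    larger latent rho; solved by bisection on the bivariate normal
    orthant probability at equal thresholds.
    """
    if target <= 0:
        return 0.0
    t = sps.norm.ppf(maf)
    q = maf * (1 - maf)

    def phi_of(rho: float) -> float:
        p11 = sps.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([t, t])
        return (p11 - maf * maf) / q

    lo, hi = target, 1.0 - 1e-9
    if phi_of(hi) < target:
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if phi_of(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


def _rho_interpolator(target: float) -> "np.ndarray | object":
    """rho(maf) on a MAF grid, linearly interpolated (per-config cache)."""
    grid = np.linspace(0.01, 0.5, 21)
    rhos = np.array([_latent_rho_for_target(m, target) for m in grid])
    return lambda maf: np.interp(maf, grid, rhos)


@dataclass
class _Scaffold:
    variants: list[VariantMeta]
    maf: np.ndarray
    thresholds: np.ndarray  # latent quantile per variant
    latent_rho: np.ndarray  # per-block latent factor loading squared
    block_id: np.ndarray
    genes: list[GeneAnnotation]
    gene_sets: GeneSetCollection
    groups: dict[str, list[str]]
    enriched_pathway: str
    enriched_variant_mask: np.ndarray
    causal: np.ndarray
    beta_std: np.ndarray
    beta_allele: np.ndarray


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _build_scaffold(cfg: SimConfig) -> _Scaffold:
    rng_layout, rng_causal = _substreams(cfg.seed, 8)[:2]
    m = cfg.n_variants
    pos = (np.arange(m, dtype=np.int64) + 1) * cfg.variant_spacing_bp
    block_id = np.arange(m) // cfg.ld_block_size
    n_blocks = int(block_id[-1]) + 1

    lo, hi = cfg.maf_range
    base = rng_layout.uniform(lo, hi, size=n_blocks)
    jitter = rng_layout.uniform(-0.03, 0.03, size=m)
    maf = np.clip(base[block_id] + jitter, lo, hi)
    thresholds = sps.norm.ppf(maf)
    latent_rho = np.asarray(_rho_interpolator(cfg.within_block_r)(base))

    pair_idx = rng_layout.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = [
        VariantMeta(
            f"var{j:05d}", "1", int(pos[j]),
            _ALLELE_PAIRS[pair_idx[j]][0], _ALLELE_PAIRS[pair_idx[j]][1],
        )
        for j in range(m)
    ]

    spacing = cfg._gene_spacing()
    genes = [
        GeneAnnotation(
            f"gene{i:03d}", "1",
            start=i * spacing + 1,
            end=i * spacing + cfg.gene_length_bp,
            strand="+" if i % 2 == 0 else "-",
        )
        for i in range(cfg.n_genes)
    ]

    gene_sets, groups, enriched = simulate_gene_sets(genes, cfg)
    merged = merge_gene_sets(gene_sets, groups)
    enriched_set = map_snps_by_distance(
        variants, genes, list(merged[enriched]), cfg.flank_bp, name=enriched
    )
    mask = np.zeros(m, dtype=bool)
    mask[[int(v[3:]) for v in enriched_set.variant_ids]] = True

    # per-variant causal probability: factor-times denser inside the
    # enriched pathway, overall density prop_causal
    m_in = int(mask.sum())
    m_out = m - m_in
    f = cfg.pathway_enrichment_factor
    p_out = cfg.prop_causal * m / (f * m_in + m_out)
    p_in = min(f * p_out, 1.0)
    causal = rng_causal.random(m) < np.where(mask, p_in, p_out)
    if causal.sum() < 2:  # degenerate draw at tiny m
        causal[rng_causal.choice(m, size=2, replace=False)] = True

    beta_std = np.zeros(m)
    n_causal = int(causal.sum())
    beta_std[causal] = rng_causal.standard_normal(n_causal) * math.sqrt(
        max(cfg.h2_liability, 1e-12) / n_causal
    )
    beta_allele = beta_std / np.sqrt(2 * maf * (1 - maf))
    return _Scaffold(
        variants, maf, thresholds, latent_rho, block_id, genes, gene_sets,
        groups, enriched, mask, causal, beta_std, beta_allele,
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _draw_dosages(
    rng: np.random.Generator,
    n: int,
    thresholds: np.ndarray,
    block_id: np.ndarray,
    latent_rho: np.ndarray,
    u_fixed: dict[int, np.ndarray] | None = None,
    e_fixed: dict[int, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosages for ``n`` individuals plus the block factors used.

    ``latent_rho`` is the per-block latent factor weight (tetrachoric-
    inverted so realized allele correlation matches the configured target).
    ``u_fixed``/``e_fixed`` pin the latent block factor of given blocks and
    the idiosyncratic noise of given variant columns (arrays shaped
    ``(n, 2)``), enabling exact conditional fill-in of ascertained samples.
    Returns ``(dosage, u, e)`` with ``u`` of shape (n, n_blocks, 2) and
    ``e`` of shape (n, m, 2).
    """
    m = len(thresholds)
    n_blocks = int(block_id[-1]) + 1
    sr = np.sqrt(latent_rho)[block_id]
    se = np.sqrt(1.0 - latent_rho)[block_id]
    u = rng.standard_normal((n, n_blocks, 2))
    e = rng.standard_normal((n, m, 2))
    if u_fixed:
        for b, vals in u_fixed.items():
            u[:, b, :] = vals
    if e_fixed:
        for j, vals in e_fixed.items():
            e[:, j, :] = vals
    dosage = np.zeros((n, m))
    for h in (0, 1):
        z = sr * u[:, block_id, h] + se * e[:, :, h]
        dosage += z < thresholds
    return dosage, u, e


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[DosageMatrix, SimTruth]:
    """Unascertained genotypes for ``cfg.n_samples`` individuals.

    With ``subpop_maf_shift > 0`` the second half of the samples uses
    per-variant MAFs shifted by the given amount in a random direction —
    a two-subpopulation toggle that creates an ancestry axis for principal
    component tests.
    """
    scaffold = _build_scaffold(cfg)
    if rng is None:
        rng = _substreams(cfg.seed, 8)[2]
    n = cfg.n_samples
    if cfg.subpop_maf_shift > 0:
        n_a = n // 2
        direction = np.where(rng.random(cfg.n_variants) < 0.5, -1.0, 1.0)
        maf_b = np.clip(
            scaffold.maf + direction * cfg.subpop_maf_shift, 0.005, 0.995
        )
        thr_b = sps.norm.ppf(maf_b)
        dose_a, _, _ = _draw_dosages(
            rng, n_a, scaffold.thresholds, scaffold.block_id, scaffold.latent_rho
        )
        dose_b, _, _ = _draw_dosages(
            rng, n - n_a, thr_b, scaffold.block_id, scaffold.latent_rho
        )
        dosage = np.vstack([dose_a, dose_b])
    else:
        dosage, _, _ = _draw_dosages(
            rng, n, scaffold.thresholds, scaffold.block_id, scaffold.latent_rho
        )
    samples = [f"s{i:07d}" for i in range(n)]
    matrix = DosageMatrix(samples, scaffold.variants, dosage)
    truth = SimTruth(
        scaffold.maf, scaffold.block_id, scaffold.causal, scaffold.beta_std,
        scaffold.beta_allele, scaffold.enriched_pathway,
        scaffold.enriched_variant_mask,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------


def _genetic_score(
    dosage: np.ndarray, maf: np.ndarray, beta_std: np.ndarray
) -> np.ndarray:
    z = (dosage - 2 * maf) / np.sqrt(2 * maf * (1 - maf))
    return z @ beta_std


def _liability_and_status(
    g_raw: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    sd = g_raw.std()
    g = (g_raw - g_raw.mean()) / sd if sd > 0 else np.zeros_like(g_raw)
    liability = math.sqrt(cfg.h2_liability) * g + math.sqrt(
        1 - cfg.h2_liability
    ) * rng.standard_normal(len(g))
    status = (liability > sps.norm.isf(cfg.prevalence)).astype(int)
    return liability, status


def _ascertain(
    status: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Indices of the ascertained sample: target case fraction P."""
    n_cases = round(cfg.n_samples * cfg.case_fraction)
    n_controls = cfg.n_samples - n_cases
    cases = np.flatnonzero(status == 1)
    controls = np.flatnonzero(status == 0)
    if len(cases) < n_cases:
        raise ValueError(
            f"pool produced {len(cases)} cases but {n_cases} are required; "
            "use a larger pool"
        )
    if len(controls) < n_controls:
        raise ValueError(
            f"pool produced {len(controls)} controls but {n_controls} are "
            "required; use a larger pool"
        )
    chosen = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ]
    )
    rng.shuffle(chosen)
    return chosen


def simulate_phenotype(
    dosages: DosageMatrix, cfg: SimConfig, truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> tuple[Phenotype, SimTruth]:
    """Liability-threshold phenotype over a genotype pool, then ascertainment.

    The pool is ``dosages`` (every sample in it receives a liability); the
    returned phenotype covers the ascertained subsample, whose ids index
    into ``dosages`` — subset the matrix with ``subset_samples`` to align.
    Raises when the pool yields too few cases (or controls) to reach the
    target case fraction.
    """
    if rng is None:
        rng = _substreams(cfg.seed, 8)[3]
    g_raw = _genetic_score(dosages.dosages, truth.maf, truth.beta_std)
    liability, status = _liability_and_status(g_raw, cfg, rng)
    chosen = _ascertain(status, cfg, rng)
    sample_ids = [dosages.sample_ids[i] for i in chosen]
    pheno = Phenotype(sample_ids, status[chosen])
    truth_out = replace(truth, liability=liability[chosen], status=status[chosen])
    return pheno, truth_out


# ---------------------------------------------------------------------------
# discovery GWAS summary statistics
# ---------------------------------------------------------------------------


def simulate_summary_stats(
    truth: SimTruth,
    variants: list[VariantMeta],
    discovery_n: int,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> SummaryStats:
    """Noisy external-GWAS estimates of the true per-allele effects.

    ``beta_hat = beta + N(0, se^2)`` with the standard GWAS standard error
    ``se = 1 / sqrt(N * 2 maf (1 - maf))``; p-values are two-sided Wald.
    Null variants therefore carry uniform p; causal-variant chi-square
    grows linearly in the discovery sample size.
    """
    if discovery_n <= 0:
        raise ValueError("discovery_n must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    se = 1.0 / np.sqrt(discovery_n * 2 * truth.maf * (1 - truth.maf))
    beta_hat = truth.beta_allele + se * rng.standard_normal(len(se))
    z = beta_hat / se
    pval = np.clip(2 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)
    return SummaryStats(list(variants), beta_hat, pval)


# ---------------------------------------------------------------------------
# eQTLs and gene sets
# ---------------------------------------------------------------------------


def simulate_eqtls(
    variants: list[VariantMeta],
    genes: list[GeneAnnotation],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    spike_frac: float | None = None,
    source: str = "eqtl",
) -> EqtlTable:
    """cis-eQTL records: every variant-gene pair within the cis window.

    A ``spike_frac`` share of cis pairs are "true" eQTLs with log-uniform
    small p-values; the rest draw uniform p.  Pairs outside the cis window
    are never emitted, so a spike fraction of zero gives a purely uniform
    table.
    """
    import pandas as pd

    if rng is None:
        rng = _substreams(cfg.seed, 8)[4]
    if spike_frac is None:
        spike_frac = cfg.eqtl_spike_frac
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    vids = np.array([v.variant_id for v in variants])
    rows_v: list[np.ndarray] = []
    rows_g: list[np.ndarray] = []
    for g in genes:
        close = np.abs(pos - g.tss) <= cfg.cis_bp
        rows_v.append(vids[close])
        rows_g.append(np.full(close.sum(), g.gene_id))
    variant_col = np.concatenate(rows_v)
    gene_col = np.concatenate(rows_g)
    n = len(variant_col)
    pvals = rng.uniform(0, 1, size=n)
    spike = rng.random(n) < spike_frac
    pvals[spike] = 10.0 ** (-rng.uniform(2, 8, size=int(spike.sum())))
    table = pd.DataFrame(
        {"variant_id": variant_col, "gene_id": gene_col, "pval": pvals}
    )
    return EqtlTable(table, source=source)


def simulate_gene_sets(
    genes: list[GeneAnnotation], cfg: SimConfig
) -> tuple[GeneSetCollection, dict[str, list[str]], str]:
    """Keyword-style gene sets grouped into pathways.

    Genes are dealt round-robin into ``n_pathways`` pathways; each pathway
    contributes two overlapping "keyword" member sets (emulating merged
    database retrievals).  The designated enriched pathway — co-located
    with the elevated causal density — is the first one.
    """
    n_p = cfg.n_pathways
    sets: dict[str, tuple[str, ...]] = {}
    groups: dict[str, list[str]] = {}
    for p in range(n_p):
        members = [g.gene_id for i, g in enumerate(genes) if i % n_p == p]
        if not members:
            raise ValueError("more pathways than genes")
        cut = max(1, (2 * len(members)) // 3)
        name = f"pathway_{p + 1}"
        sets[f"{name}_kw1"] = tuple(members[:cut])
        sets[f"{name}_kw2"] = tuple(members[len(members) - cut:])
        groups[name] = [f"{name}_kw1", f"{name}_kw2"]
    return GeneSetCollection(sets), groups, "pathway_1"


# ---------------------------------------------------------------------------
# full ascertained study
# ---------------------------------------------------------------------------


def simulate_case_control_study(
    cfg: SimConfig, pool_margin: float = 1.2
) -> SimulatedStudy:
    """Generate a complete ascertained case-control study.

    Exact two-stage sampler: (1) causal-variant genotypes for the whole
    population pool (sized so the expected case yield covers the target
    with ``pool_margin`` headroom), liabilities, ascertainment;
    (2) conditional fill-in of the non-causal variants for the retained
    individuals given their stored block factors and causal latents.
    Deterministic given ``cfg``: identical configs give bit-identical data.
    """
    streams = _substreams(cfg.seed, 8)
    rng_pool, rng_pheno, rng_eqtl, rng_fill, rng_stats, rng_eqtl2 = (
        streams[2], streams[3], streams[4], streams[5], streams[6], streams[7]
    )
    scaffold = _build_scaffold(cfg)
    n_cases = round(cfg.n_samples * cfg.case_fraction)
    pool_n = max(
        cfg.n_samples,
        int(math.ceil(n_cases / cfg.prevalence * pool_margin)),
    )

    causal_idx = np.flatnonzero(scaffold.causal)
    cblocks = np.unique(scaffold.block_id[causal_idx])
    cblock_pos = {int(b): k for k, b in enumerate(cblocks)}
    col_in_cb = np.array(
        [cblock_pos[int(scaffold.block_id[j])] for j in causal_idx]
    )

    # stage 1: causal genotypes for the pool
    rho_c = scaffold.latent_rho[scaffold.block_id[causal_idx]]
    sr_c, se_c = np.sqrt(rho_c), np.sqrt(1.0 - rho_c)
    u_pool = rng_pool.standard_normal((pool_n, len(cblocks), 2)).astype(np.float32)
    e_pool = rng_pool.standard_normal((pool_n, len(causal_idx), 2)).astype(np.float32)
    thr_c = scaffold.thresholds[causal_idx]
    dose_c = np.zeros((pool_n, len(causal_idx)), dtype=np.float32)
    for h in (0, 1):
        # float64 arithmetic so the stage-2 fill-in reproduces these
        # thresholded alleles bit-for-bit
        z = sr_c * u_pool[:, col_in_cb, h].astype(np.float64) \
            + se_c * e_pool[:, :, h].astype(np.float64)
        dose_c += (z < thr_c).astype(np.float32)
    g_raw = _genetic_score(
        dose_c.astype(float), scaffold.maf[causal_idx], scaffold.beta_std[causal_idx]
    )
    liability, status = _liability_and_status(g_raw, cfg, rng_pheno)
    chosen = _ascertain(status, cfg, rng_pheno)

    # stage 2: conditional fill-in for the retained individuals
    u_fixed = {
        int(b): u_pool[chosen, k, :].astype(float) for b, k in cblock_pos.items()
    }
    e_fixed = {
        int(j): e_pool[chosen, k, :].astype(float)
        for k, j in enumerate(causal_idx)
    }
    dosage, _, _ = _draw_dosages(
        rng_fill, len(chosen), scaffold.thresholds, scaffold.block_id,
        scaffold.latent_rho, u_fixed=u_fixed, e_fixed=e_fixed,
    )
    assert np.array_equal(dosage[:, causal_idx], dose_c[chosen].astype(float))

    sample_ids = [f"s{i:07d}" for i in chosen]
    dosages = DosageMatrix(sample_ids, scaffold.variants, dosage)
    pheno = Phenotype(sample_ids, status[chosen])
    truth = SimTruth(
        scaffold.maf, scaffold.block_id, scaffold.causal, scaffold.beta_std,
        scaffold.beta_allele, scaffold.enriched_pathway,
        scaffold.enriched_variant_mask,
        liability=liability[chosen], status=status[chosen],
    )
    stats = simulate_summary_stats(
        truth, scaffold.variants, cfg.discovery_n, rng_stats
    )
    eqtls = {
        "eqtl_small": simulate_eqtls(
            scaffold.variants, scaffold.genes, cfg, rng_eqtl,
            spike_frac=cfg.eqtl_spike_frac / 2, source="eqtl_small",
        ),
        "eqtl_large": simulate_eqtls(
            scaffold.variants, scaffold.genes, cfg, rng_eqtl2,
            spike_frac=cfg.eqtl_spike_frac, source="eqtl_large",
        ),
    }
    return SimulatedStudy(
        cfg, dosages, pheno, truth, stats, scaffold.genes,
        scaffold.gene_sets, scaffold.groups, eqtls,
    )


# ---------------------------------------------------------------------------
# writing a study to standard-format files
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input of a study as standard-format text files."""
    import pandas as pd
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosages": out / "dosages.tsv",
        "variants": out / "variants.tsv",
        "summary_stats": out / "summary_stats.tsv",
        "genes": out / "genes.bed",
        "gene_sets": out / "gene_sets.gmt",
        "phenotype": out / "phenotype.tsv",
        "groups": out / "groups.yaml",
        "truth": out / "truth.tsv",
    }
    pio.write_dosages_tsv(study.dosages, paths["dosages"])
    pio.write_variant_table(study.dosages.variants, paths["variants"])
    pio.write_summary_stats(study.summary_stats, paths["summary_stats"])
    pio.write_gene_annotation(study.genes, paths["genes"])
    pio.write_gene_sets(study.gene_sets, paths["gene_sets"])
    pio.write_phenotype_table(
        study.phenotype.sample_ids, study.phenotype.status, paths["phenotype"]
    )
    with open(paths["groups"], "w") as fh:
        yaml.safe_dump(
            {"groups": study.groups, "enriched_pathway": study.truth.enriched_pathway},
            fh,
        )
    for name, table in study.eqtl_tables.items():
        paths[f"eqtl:{name}"] = out / f"{name}.tsv"
        pio.write_eqtl_table(table, paths[f"eqtl:{name}"])
    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in study.dosages.variants],
            "maf": study.truth.maf,
            "causal": study.truth.causal.astype(int),
            "beta_std": study.truth.beta_std,
            "beta_allele": study.truth.beta_allele,
            "in_enriched_pathway": study.truth.enriched_variant_mask.astype(int),
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
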