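"""Allele harmonization, LD clumping and weighted-allele PRS computation.

The score for sample ``i`` is the standard weighted allele sum
``raw_i = sum_j dosage_ij * beta_j`` over the variants surviving three
filters: membership in the configured SNP set, survival of genome-wide
greedy LD clumping (r^2 < 0.1 within 1 Mb by default), and a discovery
GWAS p-value at or below the threshold ``pt``.  Scores are standardized
across samples, so downstream odds ratios are per SD of PRS.

Clumping uses LD estimated from the target sample's dosages (no external
reference panel), and pathway restriction happens *after* genome-wide
clumping by intersecting with the genome-wide index-variant pool — this
keeps pathway scores and their matched-size permutation nulls in the same
clumped pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import DosageMatrix, SummaryStats, VariantMeta
from .mapping import PathwaySnpSet

__all__ = [
    "ClumpConfig",
    "PrsConfig",
    "ScoreVector",
    "HarmonizationReport",
    "harmonize_alleles",
    "ld_r2",
    "clump",
    "compute_prs",
]


@dataclass(frozen=True)
class ClumpConfig:
    """Greedy clumping parameters: LD cutoff and physical window."""

    r2_threshold: float = 0.1
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass(frozen=True)
class PrsConfig:
    """One PRS configuration: p-value threshold, SNP set, clumping rule."""

    pt: float
    snp_set: PathwaySnpSet
    clump: ClumpConfig = field(default_factory=ClumpConfig)

    def __post_init__(self) -> None:
        if not (0 < self.pt <= 1):
            raise ValueError("pt must lie in (0, 1]")


@dataclass
class ScoreVector:
    """Raw and standardized PRS per sample, plus the SNP count used."""

    sample_ids: list[str]
    raw_score: np.ndarray
    std_score: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        self.raw_score = np.asarray(self.raw_score, dtype=float)
        self.std_score = np.asarray(self.std_score, dtype=float)
        if self.raw_score.shape != (len(self.sample_ids),):
            raise ValueError("raw_score length does not match sample count")
        if self.std_score.shape != self.raw_score.shape:
            raise ValueError("std_score length does not match raw_score")


@dataclass
class HarmonizationReport:
    """Bookkeeping from allele harmonization."""

    n_kept: int
    n_flipped: int  # beta negated (effect/other swapped in the GWAS)
    n_palindromic_dropped: int
    n_mismatch_dropped: int
    n_missing_from_genotypes: int
    sign: dict[str, int] = field(default_factory=dict)  # variant_id -> +1/-1


def harmonize_alleles(
    stats: SummaryStats, geno_variants: Sequence[VariantMeta]
) -> tuple[SummaryStats, HarmonizationReport]:
    """Align GWAS effect alleles to the genotype orientation.

    For each variant present in both inputs: if the GWAS effect/other pair
    equals the genotype pair, beta is kept; if the pair is swapped, beta is
    negated; strand-ambiguous (A/T, C/G) variants and allele-pair mismatches
    are dropped with counts.  The returned stats follow the genotype file's
    variant order and allele orientation.  Zero overlap is fatal.
    """
    stats_idx = {v.variant_id: i for i, v in enumerate(stats.variants)}
    variants: list[VariantMeta] = []
    betas: list[float] = []
    pvals: list[float] = []
    sign: dict[str, int] = {}
    n_flip = n_palin = n_mismatch = 0
    n_missing = 0
    for gv in geno_variants:
        i = stats_idx.get(gv.variant_id)
        if i is None:
            n_missing += 1
            continue
        sv = stats.variants[i]
        if sv.is_palindromic or gv.is_palindromic:
            n_palin += 1
            continue
        if (sv.effect_allele, sv.other_allele) == (gv.effect_allele, gv.other_allele):
            s = 1
        elif (sv.other_allele, sv.effect_allele) == (gv.effect_allele, gv.other_allele):
            s = -1
            n_flip += 1
        else:
            n_mismatch += 1
            continue
        variants.append(gv)
        betas.append(s * stats.beta[i])
        pvals.append(stats.pval[i])
        sign[gv.variant_id] = s
    if not variants:
        raise ValueError("no variants overlap between summary stats and genotypes")
    report = HarmonizationReport(
        n_kept=len(variants),
        n_flipped=n_flip,
        n_palindromic_dropped=n_palin,
        n_mismatch_dropped=n_mismatch,
        n_missing_from_genotypes=n_missing,
        sign=sign,
    )
    return SummaryStats(variants, np.array(betas), np.array(pvals)), report


def ld_r2(dosages: DosageMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation between two dosage columns.

    A monomorphic (zero-variance) column yields r^2 = 0 with a warning;
    such variants should have been MAF-filtered upstream.
    """
    x = dosages.dosages[:, i]
    y = dosages.dosages[:, j]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance dosage column in ld_r2; returning 0")
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def _standardized_columns(dosages: np.ndarray) -> np.ndarray:
    """Column-standardized copy; zero-variance columns become all-zero."""
    mean = dosages.mean(axis=0)
    sd = dosages.std(axis=0)
    z = dosages - mean
    nz = sd > 0
    z[:, nz] /= sd[nz]
    z[:, ~nz] = 0.0
    return z


def clump(
    stats: SummaryStats,
    dosages: DosageMatrix,
    cfg: ClumpConfig = ClumpConfig(),
) -> list[str]:
    """Greedy LD clumping; returns index-variant ids in selection order.

    Variants are ranked by GWAS p (ties broken by smaller position, then
    lexicographic id).  Repeatedly the best unclaimed variant becomes an
    index and claims every unclaimed variant on the same chromosome within
    ``window_bp`` whose dosage r^2 with it is >= ``r2_threshold``.  Every
    retained pair within the window therefore has r^2 below the threshold.
    """
    ids = stats.variant_ids
    cols = dosages.column_indices(ids)  # KeyError if stats not subset of dosages
    n = len(ids)
    pos = np.array([v.pos for v in stats.variants], dtype=np.int64)
    chroms = np.array([v.chrom for v in stats.variants])
    z = _standardized_columns(dosages.dosages[:, cols])
    n_samples = dosages.n_samples

    order = sorted(range(n), key=lambda k: (stats.pval[k], pos[k], ids[k]))
    alive = np.ones(n, dtype=bool)
    index_ids: list[str] = []
    # zero-variance columns can never reach the r^2 threshold (z is all-zero)
    for k in order:
        if not alive[k]:
            continue
        alive[k] = False
        index_ids.append(ids[k])
        cand = np.flatnonzero(
            alive & (chroms == chroms[k]) & (np.abs(pos - pos[k]) <= cfg.window_bp)
        )
        if cand.size == 0:
            continue
        r = z[:, cand].T @ z[:, k] / n_samples
        alive[cand[r * r >= cfg.r2_threshold]] = False
    return index_ids


def compute_prs(
    dosages: DosageMatrix,
    stats: SummaryStats,
    cfg: PrsConfig,
    clumped_ids: Sequence[str] | None = None,
) -> ScoreVector:
    """Standard weighted-allele PRS for one configuration.

    The scored variants are ``cfg.snp_set`` intersected with the clumped
    index pool and with ``{pval <= cfg.pt}`` (non-strict, matching the
    threshold's "pt <= x" definition).  ``clumped_ids`` should be the
    genome-wide clump result; when omitted, clumping is run here on
    ``stats`` against ``dosages``.  An empty final set, or a score with zero
    variance across samples, is fatal.
    """
    if clumped_ids is None:
        clumped_ids = clump(stats, dosages, cfg.clump)
    clumped = set(clumped_ids)
    in_set = set(cfg.snp_set.variant_ids)
    passing = {
        v for v, p in zip(stats.variant_ids, stats.pval) if p <= cfg.pt
    }
    chosen = [
        vid for vid in dosages.variant_ids
        if vid in in_set and vid in clumped and vid in passing
    ]
    if not chosen:
        raise ValueError(
            f"no variants left for configuration {cfg.snp_set.label!r} at pt={cfg.pt}"
        )
    sub = stats.select(chosen)
    cols = dosages.column_indices(chosen)
    raw = dosages.dosages[:, cols] @ sub.beta
    sd = raw.std()
    if sd == 0:
        raise ValueError(
            f"zero-variance score for configuration {cfg.snp_set.label!r}"
        )
    std = (raw - raw.mean()) / sd
    return ScoreVector(list(dosages.sample_ids), raw, std, len(chosen))
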