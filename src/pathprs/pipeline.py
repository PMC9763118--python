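"""Orchestration of the multi-configuration PRS experiment.

One run enumerates every PRS configuration — the cross of mapping schemes
(distance plus each named eQTL source) with genome-wide and per-pathway
variant sets — scores each, computes the association statistics, and runs
the competitive permutation test for the pathway configurations.  With two
eQTL sources and five pathways this is the 18-score design: three
genome-wide and fifteen pathway scores.

The global seed is expanded into independent per-configuration substreams,
so a rerun with the same inputs and seed reproduces every number exactly,
and individual configurations could be recomputed in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .association import (
    LiabilityParams,
    Phenotype,
    associate_prs,
    bonferroni_threshold,
    compute_pcs,
)
from .enrichment import run_enrichment
from .io import (
    DosageMatrix,
    EqtlTable,
    GeneAnnotation,
    GeneSetCollection,
    SummaryStats,
)
from .mapping import (
    GENOME_WIDE,
    SCHEME_DISTANCE,
    SCHEME_EQTL,
    build_all_snp_sets,
    merge_gene_sets,
)
from .scoring import ClumpConfig, PrsConfig, clump, compute_prs, harmonize_alleles

__all__ = ["RunConfig", "PrsConfigSpec", "enumerate_configs", "analyze", "run_all"]

logger = logging.getLogger("pathprs")


@dataclass
class RunConfig:
    """Inputs and knobs of one full experiment.

    Path fields may stay ``None`` when :func:`analyze` is called with
    in-memory objects.  ``pt_main_gw`` applies to genome-wide scores and
    ``pt_main_pathway`` to pathway scores; the sensitivity analysis swaps
    them.
    """

    dosages_path: str | None = None
    variants_path: str | None = None  # companion table for dosage TSVs
    summary_stats_path: str | None = None
    genes_path: str | None = None
    gene_sets_path: str | None = None
    phenotype_path: str | None = None
    eqtl_paths: dict[str, str] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)
    pathways: list[str] = field(default_factory=list)
    pt_main_gw: float = 0.05
    pt_main_pathway: float = 1.0
    sensitivity: bool = False
    n_perm: int = 10_000
    alpha: float = 0.05
    prevalence: float = 0.007
    n_pcs: int = 5
    flank_bp: int = 50_000
    cis_bp: int = 1_000_000
    eqtl_p_max: float = 0.05
    clump_r2: float = 0.1
    clump_window_bp: int = 1_000_000
    liability_input: str = "nagelkerke"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for pt in (self.pt_main_gw, self.pt_main_pathway):
            if not (0 < pt <= 1):
                raise ValueError("pt thresholds must lie in (0, 1]")
        if not self.pathways:
            self.pathways = list(self.groups)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown run-config key(s): {sorted(unknown)}")
        return cls(**raw)

    @property
    def clump_config(self) -> ClumpConfig:
        return ClumpConfig(self.clump_r2, self.clump_window_bp)


@dataclass(frozen=True)
class PrsConfigSpec:
    """One enumerated configuration: identity plus its p-value threshold."""

    name: str
    scheme: str
    source: str  # eQTL resource name; empty for the distance scheme
    pathway: str | None  # None for genome-wide
    pt: float


def enumerate_configs(run: RunConfig) -> list[PrsConfigSpec]:
    """All (1 + S) genome-wide plus P x (1 + S) pathway configurations."""
    pt_gw = run.pt_main_pathway if run.sensitivity else run.pt_main_gw
    pt_pw = run.pt_main_gw if run.sensitivity else run.pt_main_pathway
    schemes: list[tuple[str, str]] = [(SCHEME_DISTANCE, "")]
    schemes += [(SCHEME_EQTL, src) for src in run.eqtl_paths]
    configs: list[PrsConfigSpec] = []
    for scheme, src in schemes:
        suffix = f":{src}" if src else ""
        configs.append(
            PrsConfigSpec(f"{GENOME_WIDE}|{scheme}{suffix}", scheme, src, None, pt_gw)
        )
    for pathway in run.pathways:
        for scheme, src in schemes:
            suffix = f":{src}" if src else ""
            configs.append(
                PrsConfigSpec(
                    f"{pathway}|{scheme}{suffix}", scheme, src, pathway, pt_pw
                )
            )
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate configuration names")
    return configs


def _config_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def analyze(
    run: RunConfig,
    dosages: DosageMatrix,
    summary_stats: SummaryStats,
    phenotype: Phenotype,
    genes: Sequence[GeneAnnotation],
    gene_sets: GeneSetCollection,
    eqtl_tables: Mapping[str, EqtlTable] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Run every configuration on in-memory inputs.

    Returns the per-configuration results table (schema
    :data:`pathprs.io.RESULT_COLUMNS`), the enrichment table, and the
    machine-readable stage log.
    """
    t0 = time.time()
    eqtl_tables = dict(eqtl_tables or {})
    if set(eqtl_tables) != set(run.eqtl_paths):
        # in-memory callers may not set eqtl_paths; align them
        run.eqtl_paths = {name: "" for name in eqtl_tables}
    stages: list[dict] = []

    def log(stage: str, **info) -> None:
        entry = {"stage": stage, "elapsed_s": round(time.time() - t0, 3), **info}
        stages.append(entry)
        logger.info("%s %s", stage, json.dumps(info, default=str))

    dosages = dosages.subset_samples(phenotype.sample_ids)
    stats, report = harmonize_alleles(summary_stats, dosages.variants)
    log(
        "harmonize",
        n_in=len(summary_stats.variants), n_out=report.n_kept,
        n_flipped=report.n_flipped,
        n_palindromic_dropped=report.n_palindromic_dropped,
        n_mismatch_dropped=report.n_mismatch_dropped,
    )
    clumped_ids = clump(stats, dosages, run.clump_config)
    log("clump", n_in=report.n_kept, n_out=len(clumped_ids))

    merged = (
        merge_gene_sets(gene_sets, run.groups) if run.groups else gene_sets
    )
    if run.pathways:
        merged = GeneSetCollection(
            {p: merged[p] for p in run.pathways}
        )
    snp_sets = build_all_snp_sets(
        dosages.variants, list(genes), merged, eqtl_tables,
        flank_bp=run.flank_bp, p_max=run.eqtl_p_max, cis_bp=run.cis_bp,
    )
    by_key = {(s.name, s.scheme, s.source_label): s for s in snp_sets}
    log("snp_sets", n_sets=len(snp_sets))

    pcs = compute_pcs(dosages, run.n_pcs) if run.n_pcs > 0 else None
    phenotype = Phenotype(phenotype.sample_ids, phenotype.status, pcs)
    log("pcs", k=run.n_pcs)

    configs = enumerate_configs(run)
    m_tests = len(configs)
    bonf = bonferroni_threshold(run.alpha, m_tests)
    liability = LiabilityParams(run.prevalence, phenotype.case_fraction)
    seeds = _config_seeds(run.seed, m_tests)

    pval_lookup = dict(zip(stats.variant_ids, stats.pval))
    clumped_set = set(clumped_ids)

    def pool_for(spec: PrsConfigSpec) -> list[str]:
        gw = by_key[(GENOME_WIDE, spec.scheme, spec.source)]
        members = set(gw.variant_ids)
        return [
            vid for vid in dosages.variant_ids
            if vid in members and vid in clumped_set
            and pval_lookup.get(vid, 2.0) <= spec.pt
        ]

    result_rows: list[dict] = []
    enrich_rows: list[dict] = []
    for spec, cfg_seed in zip(configs, seeds):
        snp_set = by_key[(spec.pathway or GENOME_WIDE, spec.scheme, spec.source)]
        prs_cfg = PrsConfig(spec.pt, snp_set, run.clump_config)
        score = compute_prs(dosages, stats, prs_cfg, clumped_ids)
        assoc = associate_prs(
            phenotype, score, liability, liability_input=run.liability_input
        )
        row = {
            "name": spec.name,
            "scheme": spec.scheme,
            "source": spec.source,
            "pathway": spec.pathway or "",
            "pt": spec.pt,
            "n_snps": assoc.n_snps,
            "odds_ratio": assoc.or_per_sd,
            "ci_low": assoc.ci_low,
            "ci_high": assoc.ci_high,
            "pval": assoc.pval,
            "competitive_pval": np.nan,
            "nagelkerke_r2": assoc.nagelkerke_r2,
            "liability_r2": assoc.liability_r2,
            "auroc": assoc.auroc,
            "bonferroni_alpha": bonf,
        }
        if spec.pathway is not None:
            pool = pool_for(spec)
            enr = run_enrichment(
                snp_set,
                dosages=dosages, stats=stats, pool_ids=pool,
                status=phenotype.status, covariates=phenotype.covariates,
                n_perm=run.n_perm, seed=cfg_seed,
            )
            row["competitive_pval"] = enr.competitive_p
            enrich_rows.append(
                {
                    "name": spec.name,
                    "pathway": spec.pathway,
                    "scheme": spec.scheme,
                    "source": spec.source,
                    "observed_stat": enr.observed_stat,
                    "x": enr.x,
                    "n_perm": enr.n_perm,
                    "competitive_p": enr.competitive_p,
                    "seed": enr.seed,
                }
            )
        result_rows.append(row)
        log("config", name=spec.name, n_snps=assoc.n_snps, pt=spec.pt)

    results = pd.DataFrame(result_rows)
    enrichment = pd.DataFrame(enrich_rows)
    log("done", n_configs=m_tests, bonferroni_alpha=bonf)
    return results, enrichment, stages


def run_all(run: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """File-based end-to-end run; writes results into ``run.out_dir``.

    Reads every input named in ``run``, executes :func:`analyze`, and — if
    an output directory is configured — writes ``results.tsv``,
    ``enrichment.tsv``, a plain-text ``run.log`` and a machine-readable
    ``run.json`` sidecar.  Fully reproducible from (inputs, seed).
    """
    required = {
        "dosages_path": run.dosages_path,
        "summary_stats_path": run.summary_stats_path,
        "genes_path": run.genes_path,
        "gene_sets_path": run.gene_sets_path,
        "phenotype_path": run.phenotype_path,
    }
    missing = [k for k, v in required.items() if not v]
    if missing:
        raise ValueError(f"run config is missing input path(s): {missing}")

    handler: logging.Handler | None = None
    if run.out_dir:
        out = Path(run.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        dosages = pio.read_dosages(run.dosages_path, run.variants_path)
        summary_stats = pio.read_summary_stats(run.summary_stats_path)
        genes = pio.read_gene_annotation(run.genes_path)
        gene_sets = pio.read_gene_sets(run.gene_sets_path)
        pheno_df = pio.read_phenotype_table(run.phenotype_path)
        phenotype = Phenotype(
            pheno_df["sample_id"].tolist(), pheno_df["status"].to_numpy()
        )
        eqtl_tables = {
            name: pio.read_eqtl_table(path, source=name)
            for name, path in run.eqtl_paths.items()
        }
        results, enrichment, stages = analyze(
            run, dosages, summary_stats, phenotype, genes, gene_sets, eqtl_tables
        )
        if run.out_dir:
            out = Path(run.out_dir)
            pio.write_results(results, out / "results.tsv")
            enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            with open(out / "run.json", "w") as fh:
                json.dump(
                    {"config": asdict(run), "stages": stages}, fh, indent=2,
                    default=str,
                )
        return results, enrichment
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
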