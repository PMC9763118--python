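"""Variant-to-pathway mapping: distance-based and eQTL-based SNP sets.

Two linking schemes produce the variant subsets scored downstream:

* ``distance`` — a variant belongs to a pathway if it falls inside a member
  gene's body extended by a flanking buffer (default 50 kb, both bounds
  inclusive).  The genome-wide distance set is simply all variants.
* ``eqtl`` — a variant belongs if an eQTL resource links it to a pathway
  gene with nominal significance (p strictly below 0.05 by default) and the
  variant lies within the cis window (default 1 Mb, inclusive) of that
  gene's transcription start site.  The genome-wide eQTL set relaxes the
  pathway-gene condition to any gene.

The flanking buffer is anchored to the gene body (not the TSS), the usual
choice in gene-set PRS tools; the cis window is TSS-anchored and therefore
strand-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    EqtlTable,
    FormatError,
    GeneAnnotation,
    GeneSetCollection,
    VariantMeta,
)

__all__ = [
    "SCHEME_DISTANCE",
    "SCHEME_EQTL",
    "GENOME_WIDE",
    "ALL_GENES",
    "PathwaySnpSet",
    "merge_gene_sets",
    "map_snps_by_distance",
    "filter_eqtls",
    "build_all_snp_sets",
]

SCHEME_DISTANCE = "distance"
SCHEME_EQTL = "eqtl"
GENOME_WIDE = "genome_wide"

#: sentinel for filter_eqtls: keep eQTLs significant for *any* gene
ALL_GENES = "ALL"

DEFAULT_FLANK_BP = 50_000
DEFAULT_CIS_BP = 1_000_000
DEFAULT_EQTL_P_MAX = 0.05


@dataclass(frozen=True)
class PathwaySnpSet:
    """A named variant subset produced by one mapping scheme.

    ``name`` is the pathway name or ``genome_wide``; ``source_label``
    identifies the eQTL resource (empty for the distance scheme).
    Variant ids are unique and keep the genotype file's variant order.
    """

    name: str
    scheme: str
    source_label: str
    variant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scheme not in (SCHEME_DISTANCE, SCHEME_EQTL):
            raise ValueError(f"unknown mapping scheme {self.scheme!r}")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"snp set {self.name!r} has duplicate variant ids")

    @property
    def label(self) -> str:
        src = f":{self.source_label}" if self.source_label else ""
        return f"{self.name}|{self.scheme}{src}"

    def __len__(self) -> int:
        return len(self.variant_ids)


def merge_gene_sets(
    collection: GeneSetCollection, groups: Mapping[str, Sequence[str]]
) -> GeneSetCollection:
    """Union the member gene sets of each pathway into one set per pathway.

    ``groups`` maps a pathway name to the names of its member sets in
    ``collection``; an unknown member name is fatal.  Gene order within the
    merged set is first occurrence across members.
    """
    merged: dict[str, tuple[str, ...]] = {}
    for pathway, members in groups.items():
        unknown = [m for m in members if m not in collection]
        if unknown:
            raise FormatError(
                f"pathway {pathway!r} references unknown gene set(s) {unknown}"
            )
        genes: dict[str, None] = {}
        for m in members:
            genes.update(dict.fromkeys(collection[m]))
        merged[pathway] = tuple(genes)
    return GeneSetCollection(merged)


def _pathway_gene_annotations(
    genes: Sequence[GeneAnnotation], pathway_genes: Sequence[str]
) -> list[GeneAnnotation]:
    by_id = {g.gene_id: g for g in genes}
    missing = [g for g in pathway_genes if g not in by_id]
    if missing:
        raise FormatError(
            f"pathway gene(s) absent from annotation: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    return [by_id[g] for g in pathway_genes]


def map_snps_by_distance(
    variants: Sequence[VariantMeta],
    genes: Sequence[GeneAnnotation],
    pathway_genes: Sequence[str],
    flank_bp: int = DEFAULT_FLANK_BP,
    *,
    name: str = "",
    source_label: str = "",
) -> PathwaySnpSet:
    """Variants within ``flank_bp`` of any pathway gene body (inclusive).

    A variant is included iff it shares a chromosome with some pathway gene
    and ``gene.start - flank_bp <= pos <= gene.end + flank_bp``.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    annots = _pathway_gene_annotations(genes, pathway_genes)

    chrom = np.array([v.chrom for v in variants])
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    keep = np.zeros(len(variants), dtype=bool)
    for g in annots:
        on_chrom = chrom == g.chrom
        keep |= on_chrom & (pos >= g.start - flank_bp) & (pos <= g.end + flank_bp)
    ids = tuple(v.variant_id for v, k in zip(variants, keep) if k)
    return PathwaySnpSet(name or "pathway", SCHEME_DISTANCE, source_label, ids)


def filter_eqtls(
    eqtls: EqtlTable,
    variants: Sequence[VariantMeta],
    genes: Sequence[GeneAnnotation],
    pathway_genes: Sequence[str] | str = ALL_GENES,
    p_max: float = DEFAULT_EQTL_P_MAX,
    cis_bp: int = DEFAULT_CIS_BP,
    *,
    name: str = "",
    source_label: str = "",
) -> PathwaySnpSet:
    """Variants that are nominally significant cis-eQTLs of pathway genes.

    A variant is included iff some record ``(variant, gene)`` satisfies all
    of: ``pval < p_max`` (strict), the gene belongs to ``pathway_genes``
    (or any gene when :data:`ALL_GENES`), and the variant lies within
    ``cis_bp`` of the gene's TSS (``|pos - tss| <= cis_bp``).  An empty
    result warns and returns an empty set — the caller decides whether that
    is fatal.
    """
    if not (0 < p_max <= 1):
        raise ValueError("p_max must lie in (0, 1]")
    if isinstance(pathway_genes, str):
        if pathway_genes != ALL_GENES:
            raise ValueError("pathway_genes must be a list of ids or ALL_GENES")
        gene_ids = None
    else:
        gene_ids = set(pathway_genes)
        _pathway_gene_annotations(genes, pathway_genes)  # existence check

    gene_meta = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
        }
    )
    var_meta = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "var_chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
        }
    )
    rec = eqtls.records
    rec = rec[rec["pval"] < p_max]
    if gene_ids is not None:
        rec = rec[rec["gene_id"].isin(gene_ids)]
    rec = rec.merge(gene_meta, on="gene_id").merge(var_meta, on="variant_id")
    rec = rec[
        (rec["var_chrom"] == rec["gene_chrom"])
        & ((rec["pos"] - rec["tss"]).abs() <= cis_bp)
    ]
    hits = set(rec["variant_id"])
    ids = tuple(v.variant_id for v in variants if v.variant_id in hits)
    label = name or ("pathway" if gene_ids is not None else GENOME_WIDE)
    if not ids:
        warnings.warn(f"eQTL filter produced an empty set for {label!r}")
    return PathwaySnpSet(label, SCHEME_EQTL, source_label or eqtls.source, ids)


def build_all_snp_sets(
    variants: Sequence[VariantMeta],
    genes: Sequence[GeneAnnotation],
    merged_pathways: GeneSetCollection,
    eqtl_sources: Mapping[str, EqtlTable],
    *,
    flank_bp: int = DEFAULT_FLANK_BP,
    p_max: float = DEFAULT_EQTL_P_MAX,
    cis_bp: int = DEFAULT_CIS_BP,
) -> list[PathwaySnpSet]:
    """Build the full experiment's variant sets.

    Returns ``(1 + S)`` genome-wide sets followed by ``P * (1 + S)`` pathway
    sets, where ``S`` is the number of eQTL sources and ``P`` the number of
    pathways — with two sources and five pathways this is the 18-score
    design.  The genome-wide distance set contains all variants.
    """
    sets: list[PathwaySnpSet] = [
        PathwaySnpSet(
            GENOME_WIDE,
            SCHEME_DISTANCE,
            "",
            tuple(v.variant_id for v in variants),
        )
    ]
    for src, table in eqtl_sources.items():
        sets.append(
            filter_eqtls(
                table, variants, genes, ALL_GENES, p_max, cis_bp,
                name=GENOME_WIDE, source_label=src,
            )
        )
    for pathway in merged_pathways.names:
        pg = list(merged_pathways[pathway])
        sets.append(
            map_snps_by_distance(variants, genes, pg, flank_bp, name=pathway)
        )
        for src, table in eqtl_sources.items():
            sets.append(
                filter_eqtls(
                    table, variants, genes, pg, p_max, cis_bp,
                    name=pathway, source_label=src,
                )
            )
    return sets
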