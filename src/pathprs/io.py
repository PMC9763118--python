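"""Readers, writers and in-memory containers for the formats the pipeline touches.

Every downstream module works on the domain types defined here
(:class:`VariantMeta`, :class:`DosageMatrix`, :class:`SummaryStats`,
:class:`GeneAnnotation`, :class:`GeneSetCollection`, :class:`EqtlTable`),
so format quirks stay in this module.  Validation is strict: a file that
violates a stated invariant either produces a counted row drop (reported on
the returned object and via ``warnings``) or a fatal :class:`FormatError`,
never silent acceptance.

Conventions
-----------
* Genomic coordinates are 1-based inclusive everywhere in memory.  BED input
  (0-based half-open) is converted on read and back on write.
* Dosages are expected effect-allele counts in ``[0, 2]`` with no missing
  entries (imputed dosages are assumed upstream).
* All text formats are UTF-8 TSV; gzip is handled transparently
  (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "VariantMeta",
    "DosageMatrix",
    "SummaryStats",
    "GeneAnnotation",
    "GeneSetCollection",
    "EqtlTable",
    "read_summary_stats",
    "write_summary_stats",
    "read_dosages",
    "write_dosages_tsv",
    "write_variant_table",
    "write_dosages_vcf",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "read_eqtl_table",
    "write_eqtl_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_results",
    "write_results",
    "RESULT_COLUMNS",
]

_BASES = frozenset("ACGT")
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

DOSAGE_TOL = 1e-6  # slack when validating dosages against [0, 2]


class FormatError(ValueError):
    """A file violated the format contract in a non-recoverable way."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantMeta:
    """Identity of a biallelic SNP: locus plus effect/other allele pair."""

    variant_id: str
    chrom: str
    pos: int  # 1-based bp
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise FormatError("variant_id must be non-empty")
        if self.pos < 1:
            raise FormatError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _BASES:
                raise FormatError(
                    f"{self.variant_id}: allele {allele!r} is not one of A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.variant_id}: effect and other allele are equal")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G pairs."""
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC_PAIRS

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate {what} {dup!r}")


@dataclass
class DosageMatrix:
    """Samples x variants additive dosage matrix with variant metadata.

    ``dosages[i, j]`` is the expected effect-allele count of sample ``i`` at
    variant ``j``; column ``j`` corresponds to ``variants[j]``.
    """

    sample_ids: list[str]
    variants: list[VariantMeta]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(self.sample_ids) == 0:
            raise FormatError("dosage matrix has no samples")
        if len(self.variants) == 0:
            raise FormatError("dosage matrix has no variants")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise FormatError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if not np.isfinite(self.dosages).all():
            raise FormatError("dosage matrix contains non-finite entries")
        lo, hi = self.dosages.min(), self.dosages.max()
        if lo < -DOSAGE_TOL or hi > 2 + DOSAGE_TOL:
            j = int(np.argmax(np.maximum(-self.dosages, self.dosages - 2).max(axis=0)))
            raise FormatError(
                f"dosage outside [0, 2] at variant {self.variants[j].variant_id!r} "
                f"(range [{lo:.6g}, {hi:.6g}])"
            )
        np.clip(self.dosages, 0.0, 2.0, out=self.dosages)
        _check_unique_ids(self.sample_ids, "sample id")
        _check_unique_ids([v.variant_id for v in self.variants], "variant id")

    @cached_property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @cached_property
    def _col_index(self) -> dict[str, int]:
        return {vid: j for j, vid in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column_indices(self, variant_ids: Iterable[str]) -> np.ndarray:
        """Column indices for the given variant ids (KeyError if absent)."""
        idx = self._col_index
        return np.array([idx[v] for v in variant_ids], dtype=np.intp)

    def subset_samples(self, sample_ids: Sequence[str]) -> "DosageMatrix":
        row = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([row[s] for s in sample_ids], dtype=np.intp)
        return DosageMatrix(list(sample_ids), self.variants, self.dosages[rows])

    def subset_variants(self, variant_ids: Sequence[str]) -> "DosageMatrix":
        cols = self.column_indices(variant_ids)
        return DosageMatrix(
            self.sample_ids,
            [self.variants[j] for j in cols],
            self.dosages[:, cols],
        )


@dataclass
class SummaryStats:
    """Discovery-GWAS effect sizes and p-values, aligned with ``variants``."""

    variants: list[VariantMeta]
    beta: np.ndarray
    pval: np.ndarray
    n_dropped: int = 0  # invalid rows discarded on read

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.pval = np.asarray(self.pval, dtype=float)
        n = len(self.variants)
        if n == 0:
            raise FormatError("summary statistics contain no valid variants")
        if self.beta.shape != (n,) or self.pval.shape != (n,):
            raise FormatError("beta/pval length does not match variant count")
        if not np.isfinite(self.beta).all():
            raise FormatError("non-finite beta in summary statistics")
        if ((self.pval <= 0) | (self.pval > 1) | ~np.isfinite(self.pval)).any():
            raise FormatError("p-values must lie in (0, 1]")
        _check_unique_ids([v.variant_id for v in self.variants], "variant id")

    @cached_property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @cached_property
    def _row_index(self) -> dict[str, int]:
        return {vid: i for i, vid in enumerate(self.variant_ids)}

    def select(self, variant_ids: Sequence[str]) -> "SummaryStats":
        rows = [self._row_index[v] for v in variant_ids]
        return SummaryStats(
            [self.variants[i] for i in rows], self.beta[rows], self.pval[rows]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "beta": self.beta,
                "pval": self.pval,
            }
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body with strand; ``tss`` is start on '+' and end on '-'."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("gene_id must be non-empty")
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics); genes are exact-string identifiers."""

    sets: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not name:
                raise FormatError("gene set with empty name")
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise FormatError(f"gene set {name!r} contains an empty gene id")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate genes")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def n_genes_union(self) -> int:
        union: set[str] = set()
        for genes in self.sets.values():
            union.update(genes)
        return len(union)


@dataclass
class EqtlTable:
    """(variant, gene, p-value) association records from one eQTL resource."""

    records: pd.DataFrame  # columns: variant_id, gene_id, pval
    source: str = ""

    def __post_init__(self) -> None:
        needed = ["variant_id", "gene_id", "pval"]
        missing = [c for c in needed if c not in self.records.columns]
        if missing:
            raise FormatError(f"eQTL table missing column(s) {missing}")
        self.records = self.records[needed].reset_index(drop=True)
        p = self.records["pval"].to_numpy(dtype=float)
        if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
            raise FormatError("eQTL p-values must lie in (0, 1]")
        if self.records.duplicated(["variant_id", "gene_id"]).any():
            dup = self.records[self.records.duplicated(["variant_id", "gene_id"])]
            pair = dup.iloc[0]
            raise FormatError(
                f"duplicate eQTL record for ({pair['variant_id']}, {pair['gene_id']})"
            )

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_SUMSTAT_FIELDS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "pval")


def read_summary_stats(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> SummaryStats:
    """Read a tab-separated GWAS summary-statistics file.

    Parameters
    ----------
    path
        TSV (optionally gzipped) with one row per variant.
    dialect
        Optional map from the canonical field names
        (``variant_id, chrom, pos, effect_allele, other_allele, beta, pval``)
        to the column names actually present in the file.  Published summary
        statistics use no single schema, so the mapping is configurable.

    Rows with a p-value outside ``(0, 1]``, non-ACGT or equal alleles, or a
    non-finite beta are dropped; the count is reported in
    ``SummaryStats.n_dropped`` and as a warning.  A missing column or zero
    surviving rows is fatal.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    rename = {dialect.get(f, f): f for f in _SUMSTAT_FIELDS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns=rename)

    variants: list[VariantMeta] = []
    betas: list[float] = []
    pvals: list[float] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        try:
            beta = float(row.beta)
            pval = float(row.pval)
            if not (0 < pval <= 1) or not math.isfinite(beta):
                raise FormatError("invalid beta/pval")
            vm = VariantMeta(
                str(row.variant_id), str(row.chrom), int(row.pos),
                str(row.effect_allele).upper(), str(row.other_allele).upper(),
            )
        except (FormatError, ValueError):
            n_dropped += 1
            continue
        variants.append(vm)
        betas.append(beta)
        pvals.append(pval)
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} invalid summary-stat row(s)")
    if not variants:
        raise FormatError(f"{path}: no valid summary-statistics rows")
    return SummaryStats(variants, np.array(betas), np.array(pvals), n_dropped)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    stats.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dosages
# ---------------------------------------------------------------------------


def read_dosages(
    path: str | Path, variants_path: str | Path | None = None
) -> DosageMatrix:
    """Read genotype dosages from a VCF (``DS`` FORMAT field) or a dosage TSV.

    VCF input is self-contained (alleles come from REF/ALT; the effect allele
    is ALT, which the DS field counts).  The TSV dialect is defined by this
    package: samples in rows, first column ``sample_id``, remaining header
    cells variant ids — variant metadata then comes from the companion
    variant table written by :func:`write_variant_table` (``variants_path``).
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if ".vcf" in suffixes:
        return _read_dosages_vcf(path)
    if variants_path is None:
        raise FormatError(
            "dosage TSV input requires a companion variant metadata table"
        )
    return _read_dosages_tsv(path, variants_path)


def _read_dosages_vcf(path: Path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples")
    variants: list[VariantMeta] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is None:
            raise FormatError(f"{path}: FORMAT field DS absent at {rec.ID or rec.POS}")
        if len(rec.ALT) != 1:
            raise FormatError(f"{path}: multi-allelic record at {rec.ID or rec.POS}")
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variants.append(
            VariantMeta(vid, str(rec.CHROM), int(rec.POS), rec.ALT[0], rec.REF)
        )
        col = np.asarray(ds, dtype=float).reshape(-1)
        if col.shape[0] != len(samples):
            raise FormatError(f"{path}: DS count mismatch at {vid}")
        if (col < -DOSAGE_TOL).any() or (col > 2 + DOSAGE_TOL).any():
            raise FormatError(f"{path}: dosage outside [0, 2] at variant {vid!r}")
        columns.append(col)
    if not variants:
        raise FormatError(f"{path}: VCF contains no variant records")
    return DosageMatrix(samples, variants, np.column_stack(columns))


def read_variant_table(path: str | Path) -> list[VariantMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return [
        VariantMeta(r.variant_id, r.chrom, int(r.pos), r.effect_allele, r.other_allele)
        for r in df.itertuples(index=False)
    ]


def _read_dosages_tsv(path: Path, variants_path: str | Path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2 or df.columns[0] != "sample_id":
        raise FormatError(f"{path}: dosage TSV must start with a 'sample_id' column")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: dosage TSV contains no samples")
    sample_ids = df["sample_id"].astype(str).tolist()
    meta = {v.variant_id: v for v in read_variant_table(variants_path)}
    variant_ids = [str(c) for c in df.columns[1:]]
    missing = [v for v in variant_ids if v not in meta]
    if missing:
        raise FormatError(
            f"{path}: variant(s) absent from metadata table: {missing[:5]}"
        )
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = np.where((dosages < -DOSAGE_TOL) | (dosages > 2 + DOSAGE_TOL))
    if bad[0].size:
        raise FormatError(
            f"{path}: dosage outside [0, 2] at variant {variant_ids[bad[1][0]]!r}"
        )
    return DosageMatrix(sample_ids, [meta[v] for v in variant_ids], dosages)


def write_dosages_tsv(dosages: DosageMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dosages.dosages, columns=dosages.variant_ids)
    df.insert(0, "sample_id", dosages.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_variant_table(variants: Sequence[VariantMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)


def write_dosages_vcf(dosages: DosageMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with a single DS FORMAT field.

    REF is the other allele and ALT the effect allele, so DS values are
    effect-allele dosages, matching the reader's convention.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    chroms = []
    for v in dosages.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,'
            'Description="Estimated alternate allele dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.sample_ids)
            + "\n"
        )
        order = sorted(
            range(dosages.n_variants),
            key=lambda j: (chroms.index(dosages.variants[j].chrom),
                           dosages.variants[j].pos),
        )
        for j in order:
            v = dosages.variants[j]
            values = "\t".join(f"{d:.6g}" for d in dosages.dosages[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.other_allele}\t"
                f"{v.effect_allele}\t.\t.\t.\tDS\t{values}\n"
            )


# ---------------------------------------------------------------------------
# gene annotation (BED-like) and gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a 6-column BED (chrom, start, end, gene_id, score, strand).

    BED is 0-based half-open; coordinates are converted to the package's
    1-based inclusive convention (internal start = BED start + 1).
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 6:
        raise FormatError(f"{path}: expected >= 6 BED columns, got {df.shape[1]}")
    for row in df.itertuples(index=False):
        chrom, start0, end, gene_id, _score, strand = row[:6]
        start0, end = int(start0), int(end)
        if start0 < 0 or start0 >= end:
            raise FormatError(f"{path}: invalid BED interval for {gene_id!r}")
        if gene_id in seen:
            raise FormatError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        genes.append(GeneAnnotation(str(gene_id), str(chrom), start0 + 1, end, strand))
    if not genes:
        raise FormatError(f"{path}: no gene records")
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start - 1 for g in genes],  # back to BED 0-based
            "end": [g.end for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False, header=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then gene ids, tab-separated.

    The description column is discarded; duplicate genes within a set are
    deduplicated (first occurrence kept); duplicate set names are fatal.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    sets: dict[str, tuple[str, ...]] = {}
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line with fewer than 3 fields")
            name, genes = parts[0], parts[2:]
            if name in sets:
                raise FormatError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = tuple(dict.fromkeys(g for g in genes if g))
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# eQTL tables
# ---------------------------------------------------------------------------


def read_eqtl_table(path: str | Path, source: str = "") -> EqtlTable:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene_id": str})
    missing = [c for c in ("variant_id", "gene_id", "pval") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return EqtlTable(df, source=source or Path(path).stem)


def write_eqtl_table(table: EqtlTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes and results
# ---------------------------------------------------------------------------


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a sample_id/status TSV; status must be 0 (control) or 1 (case)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id", "status") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    status = df["status"].to_numpy()
    if not np.isin(status, (0, 1)).all():
        raise FormatError(f"{path}: status values must be 0 or 1")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df[["sample_id", "status"]]


def write_phenotype_table(
    sample_ids: Sequence[str], status: Sequence[int], path: str | Path
) -> None:
    pd.DataFrame({"sample_id": sample_ids, "status": status}).to_csv(
        path, sep="\t", index=False
    )


#: per-configuration result schema (one row per PRS configuration)
RESULT_COLUMNS = [
    "name",
    "scheme",
    "source",
    "pathway",
    "pt",
    "n_snps",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "pval",
    "competitive_pval",
    "nagelkerke_r2",
    "liability_r2",
    "auroc",
    "bonferroni_alpha",
]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"results table missing column(s) {missing}")
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: results table missing column(s) {missing}")
    return df
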