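"""Readers and writers for the external representations the pipeline touches.

Dialects, all plain text:

* expression: TSV, genes in rows (first column ``gene_id``), samples in
  columns; a companion metadata TSV keyed by sample ID with columns
  ``run_id``, ``experiment_id``, ``study_id``, ``tissue_label``,
  ``treatment_label``.
* genotypes: VCF 4.x (plain or bgzipped) that *includes invariant sites*
  (records with ALT "."), diploid genotypes, missing calls as ``./.``.
* site classes: BED-derived TSV with columns
  ``chrom  start  end  gene_id  class`` using 0-based half-open intervals.
* gene table: TSV with ``NA`` for missing values.

Coordinate convention: VCF positions are 1-based; BED-like intervals are
0-based half-open; every position stored internally is 1-based.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("specsel")

META_COLUMNS = ("run_id", "experiment_id", "study_id", "tissue_label", "treatment_label")


class FormatError(ValueError):
    """Malformed or invariant-violating input file."""


class SiteClass(enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"
    INVARIANT = "invariant"


class VariantSite(NamedTuple):
    """One genotyped coding site.

    ``n_chromosomes`` counts non-missing genotyped chromosomes (2 per
    called diploid genotype); ``p_ref``/``p_alt`` are allele frequencies
    over those chromosomes only.
    """

    chrom: str
    pos: int  # 1-based
    gene_id: str
    site_class: SiteClass
    n_chromosomes: int
    p_ref: float
    p_alt: float


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene ID with sample IDs as
    columns; ``samples_meta`` is indexed by sample ID and carries
    ``run_id``, ``experiment_id``, ``study_id``, ``tissue_label`` and
    ``treatment_label``.
    """

    values: pd.DataFrame
    samples_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric TPM values")
        if not np.isfinite(arr).all():
            raise FormatError("non-finite TPM values")
        if (arr < 0).any():
            raise FormatError("negative TPM values")
        missing = [s for s in self.values.columns if s not in self.samples_meta.index]
        if missing:
            raise FormatError(f"samples without metadata: {missing[:5]}")
        for col in ("tissue_label", "treatment_label"):
            if col not in self.samples_meta.columns:
                raise FormatError(f"metadata missing column {col!r}")
            sub = self.samples_meta.loc[list(self.values.columns), col]
            if sub.isna().any() or (sub.astype(str).str.len() == 0).any():
                raise FormatError(f"empty {col} for some samples")

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, sample_ids].copy(),
            self.samples_meta.loc[sample_ids].copy(),
        )

    def meta_of(self, field_name: str) -> pd.Series:
        """Metadata field aligned to the matrix's sample order."""
        return self.samples_meta.loc[list(self.values.columns), field_name]


@dataclass
class SiteClassTable:
    """Per-gene CDS intervals with a missense/synonymous class label.

    Intervals arrive 0-based half-open (BED convention) and must not
    overlap within a gene.
    """

    intervals: pd.DataFrame  # chrom, start, end, gene_id, class

    _trees: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gene_id", "class"}
        if not required.issubset(self.intervals.columns):
            raise FormatError(f"site class table needs columns {sorted(required)}")
        if (self.intervals["end"] <= self.intervals["start"]).any():
            raise FormatError("empty or inverted interval in site class table")
        for gene_id, grp in self.intervals.groupby("gene_id"):
            srt = grp.sort_values("start")
            if (srt["start"].to_numpy()[1:] < srt["end"].to_numpy()[:-1]).any():
                raise FormatError(f"overlapping intervals for gene {gene_id}")
        for chrom, grp in self.intervals.groupby("chrom"):
            tree = IntervalTree()
            for start, end, gene_id, cls in zip(
                grp["start"], grp["end"], grp["gene_id"], grp["class"]
            ):
                tree[start:end] = (gene_id, str(cls))
            self._trees[chrom] = tree

    def lookup(self, chrom: str, pos: int) -> tuple[str, str] | None:
        """(gene_id, class) covering a 1-based position, or None."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos - 1]
        if not hits:
            return None
        return next(iter(hits)).data

    def class_counts(self) -> pd.DataFrame:
        """Genotypable-site counts per gene and class (interval lengths)."""
        df = self.intervals.assign(n=self.intervals["end"] - self.intervals["start"])
        return df.pivot_table(index="gene_id", columns="class", values="n", aggfunc="sum", fill_value=0)


@dataclass
class GeneCovariates:
    """Per-gene length (introns/UTRs included), GC fraction, family size."""

    table: pd.DataFrame  # indexed by gene_id: length_bp, gc_fraction, family_size

    def __post_init__(self) -> None:
        t = self.table
        if (t["length_bp"] <= 0).any():
            raise FormatError("length_bp must be positive")
        gc = t["gc_fraction"]
        if ((gc < 0) | (gc > 1)).any():
            raise FormatError("gc_fraction outside [0, 1]")
        if (t["family_size"] < 1).any():
            raise FormatError("family_size must be >= 1")


# ---------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TPM TSV and its sample-metadata TSV.

    Samples present in the matrix but missing from the metadata are
    rejected; duplicate gene or sample IDs and negative or non-numeric
    TPM values raise :class:`FormatError`.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns.name = None
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric TPM value: {exc}") from exc
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample IDs in metadata")
    return ExpressionMatrix(values, meta)


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if meta_path is not None:
        matrix.samples_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# site classes and covariates


def read_site_classes(path: str | Path) -> SiteClassTable:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "class"],
        dtype={"chrom": str, "start": int, "end": int, "gene_id": str, "class": str},
        comment="#",
    )
    return SiteClassTable(df)


def read_gene_covariates(path: str | Path) -> GeneCovariates:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return GeneCovariates(df)


# ---------------------------------------------------------------------------
# VCF


def read_sites_vcf(
    path: str | Path, class_table: SiteClassTable
) -> dict[str, list[VariantSite]]:
    """Read genotyped sites from a VCF (invariant records included).

    Multiallelic records and indels are skipped (counted and logged);
    malformed genotype fields skip the record.  ``n_chromosomes`` is
    twice the number of non-missing diploid calls.  Variant sites take
    their class from the interval table; invariant records are classed
    :attr:`SiteClass.INVARIANT`.  A VCF with no invariant records logs a
    warning because downstream diversity denominators then cover variant
    sites only.
    """
    from cyvcf2 import VCF

    sites: dict[str, list[VariantSite]] = {}
    n_multi = n_indel = n_bad = n_invariant = 0
    vcf = VCF(str(path))
    for rec in vcf:
        alts = [a for a in rec.ALT if a not in (".",)]
        if len(alts) > 1:
            n_multi += 1
            continue
        if len(alts) == 1 and (len(rec.REF) != 1 or len(alts[0]) != 1 or alts[0] == "*"):
            n_indel += 1
            continue
        hit = class_table.lookup(rec.CHROM, rec.POS)
        if hit is None:
            continue
        gene_id, cls = hit
        try:
            gts = rec.genotypes  # [allele1, allele2, phased]
            n_chrom = 0
            alt_count = 0
            for g in gts:
                a, b = g[0], g[1]
                for allele in (a, b):
                    if allele >= 0:
                        n_chrom += 1
                        alt_count += int(allele == 1)
        except Exception:  # malformed genotype field
            n_bad += 1
            continue
        if n_chrom == 0:
            continue
        invariant = len(alts) == 0 or alt_count == 0
        if len(alts) == 0:
            n_invariant += 1
        p_alt = 0.0 if invariant else alt_count / n_chrom
        site = VariantSite(
            chrom=rec.CHROM,
            pos=rec.POS,
            gene_id=gene_id,
            site_class=SiteClass.INVARIANT if invariant else SiteClass(cls),
            n_chromosomes=n_chrom,
            p_ref=1.0 - p_alt,
            p_alt=p_alt,
        )
        sites.setdefault(gene_id, []).append(site)
    if n_multi or n_indel or n_bad:
        logger.info(
            "VCF %s: skipped %d multiallelic, %d indel, %d malformed records",
            path, n_multi, n_indel, n_bad,
        )
    if n_invariant == 0:
        logger.warning(
            "VCF %s contains no invariant records; diversity denominators "
            "will cover variant sites only", path,
        )
    return sites


# ---------------------------------------------------------------------------
# gene table

GENE_TABLE_COLUMNS = [
    "gene_id", "tau_treatment", "tau_tissue", "avg_expr", "length_bp",
    "gc_fraction", "family_size", "pi", "pi_n", "pi_s", "tajima_d",
    "p_n_count", "p_s_count", "d_n_count", "d_s_count", "dos", "d_n", "d_s",
    "saturated", "one_to_one",
]


def write_gene_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write the assembled per-gene table as TSV with NA for missing."""
    cols = [c for c in GENE_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
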