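"""Pairwise dN/dS by the Nei-Gojobori (1986) counting method.

The estimator works on gapless codon alignments of two sequences and has
three steps: (i) count the expected numbers of nonsynonymous (N) and
synonymous (S) *sites* per sequence from the mutational opportunities of
each codon; (ii) count nonsynonymous and synonymous *differences* (Nd,
Sd) by averaging over all substitution pathways between each codon pair;
(iii) convert the proportions pN = Nd/N and pS = Sd/S into distances dN
and dS with the Jukes-Cantor multiple-hit correction.

Stop-codon conventions differ between published implementations.  By
default a single-base change into a stop codon is counted as a
nonsynonymous change (``stop_mutations="nonsynonymous"``); the
alternative of excluding stop changes from the per-position denominator
is available via ``stop_mutations="exclude"``.  Either way each sense
codon contributes exactly 3 sites.

Genetic code: standard nuclear code (translation table 1).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("specsel")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))  # 61 codons
AA = dict(_TABLE.forward_table)  # codon -> amino acid, sense codons only

StopConvention = Literal["nonsynonymous", "exclude"]


@dataclass(frozen=True)
class SiteCounts:
    """Expected nonsynonymous (N) and synonymous (S) site counts."""

    n_sites: float
    s_sites: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.n_sites + other.n_sites, self.s_sites + other.s_sites)


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two aligned, gapless coding sequences (equal length, length % 3 == 0)."""

    gene_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length not a multiple of 3")
        if "-" in self.seq_a or "-" in self.seq_b:
            raise ValueError(f"{self.gene_id}: alignment must be gapless")

    def codons(self) -> Iterator[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class DivergenceEstimate:
    """NG86 pairwise divergence for one gene.

    ``saturated`` is set when dS > 1 or when the Jukes-Cantor correction
    is undefined (p >= 3/4); saturated genes are conventionally excluded
    from dN-based analyses.
    """

    gene_id: str
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    p_n: float | None
    p_s: float | None
    d_n: float | None
    d_s: float | None
    saturated: bool

    @property
    def dn_ds(self) -> float | None:
        if self.d_n is None or self.d_s is None or self.d_s == 0:
            return None
        return self.d_n / self.d_s


def codon_site_counts(
    codon: str, stop_mutations: StopConvention = "nonsynonymous"
) -> SiteCounts:
    """N and S site counts for a single sense codon.

    Each position contributes a synonymous fraction equal to the number
    of its three possible single-base changes that preserve the amino
    acid, over the number of changes counted at that position (3, or
    fewer when changes to stops are excluded from the denominator).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        counted = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                if stop_mutations == "exclude":
                    continue
                counted += 1  # counts as a nonsynonymous opportunity
                continue
            counted += 1
            if AA[mutant] == aa:
                syn += 1
        s += syn / counted if counted else 0.0
    return SiteCounts(n_sites=3.0 - s, s_sites=s)


def count_sequence_sites(
    seq: str, stop_mutations: StopConvention = "nonsynonymous"
) -> SiteCounts:
    """Sum of per-codon site counts over a gapless coding sequence.

    Codons containing ambiguous bases or encoding stops are skipped
    (with a log entry); the caller is responsible for skipping the same
    codons in a partner sequence to keep N, S, Nd and Sd consistent.
    """
    if len(seq) % 3 != 0:
        raise ValueError("sequence length not a multiple of 3")
    total = SiteCounts(0.0, 0.0)
    skipped = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if not _is_countable(codon):
            skipped += 1
            continue
        total = total + _site_counts_cached(codon, stop_mutations)
    if skipped:
        logger.debug("count_sequence_sites: skipped %d codons", skipped)
    return total


def _is_countable(codon: str) -> bool:
    return codon in AA


_SITE_CACHE: dict[tuple[str, str], SiteCounts] = {}


def _site_counts_cached(codon: str, stop_mutations: StopConvention) -> SiteCounts:
    key = (codon, stop_mutations)
    if key not in _SITE_CACHE:
        _SITE_CACHE[key] = codon_site_counts(codon, stop_mutations)
    return _SITE_CACHE[key]


def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) differences.

    All orderings of the differing positions are enumerated; each
    ordering is a pathway of single-base steps classified step by step.
    Pathways passing through a stop codon are dropped whenever at least
    one stop-free pathway exists; if every pathway crosses a stop, all
    pathways are averaged with steps into or out of stops counted as
    nonsynonymous.
    """
    key = (codon_a, codon_b)
    cached = _DIFF_CACHE.get(key)
    if cached is not None:
        return cached
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return (0.0, 0.0)
    valid: list[tuple[int, int]] = []  # (nd, sd) per stop-free pathway
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        nd = sd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                through_stop = True
                nd += 1
            elif AA[cur] == AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if through_stop else valid).append((nd, sd))
    paths = valid if valid else fallback
    nd_avg = sum(p[0] for p in paths) / len(paths)
    sd_avg = sum(p[1] for p in paths) / len(paths)
    _DIFF_CACHE[key] = (nd_avg, sd_avg)
    return nd_avg, sd_avg


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def jukes_cantor(p: float) -> float | None:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); None when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_dnds(
    pair: CodonAlignmentPair, stop_mutations: StopConvention = "nonsynonymous"
) -> DivergenceEstimate:
    """NG86 divergence estimate for one aligned codon pair.

    Codons where either sequence carries an ambiguous base or a stop are
    dropped from both sequences, so site and difference counts stay on
    the same codon set.  N and S are the means of the two sequences'
    site counts.  ``p_s``/``d_s`` are None when S = 0.
    """
    sites_a = SiteCounts(0.0, 0.0)
    sites_b = SiteCounts(0.0, 0.0)
    nd = sd = 0.0
    skipped = 0
    for ca, cb in pair.codons():
        if not (_is_countable(ca) and _is_countable(cb)):
            skipped += 1
            continue
        sites_a = sites_a + _site_counts_cached(ca, stop_mutations)
        sites_b = sites_b + _site_counts_cached(cb, stop_mutations)
        d_n, d_s = codon_pair_differences(ca, cb)
        nd += d_n
        sd += d_s
    if skipped:
        logger.debug("pairwise_dnds %s: skipped %d codon pairs", pair.gene_id, skipped)
    n_sites = (sites_a.n_sites + sites_b.n_sites) / 2.0
    s_sites = (sites_a.s_sites + sites_b.s_sites) / 2.0
    p_n = nd / n_sites if n_sites > 0 else None
    p_s = sd / s_sites if s_sites > 0 else None
    d_n = jukes_cantor(p_n) if p_n is not None else None
    d_s = jukes_cantor(p_s) if p_s is not None else None
    saturated = (p_n is not None and d_n is None) or (
        p_s is not None and (d_s is None or d_s > 1.0)
    )
    return DivergenceEstimate(
        gene_id=pair.gene_id,
        nd=nd,
        sd=sd,
        n_sites=n_sites,
        s_sites=s_sites,
        p_n=p_n,
        p_s=p_s,
        d_n=d_n,
        d_s=d_s,
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_codon_pair_fasta(path: str | Path, gene_id: str | None = None) -> CodonAlignmentPair:
    """Read a two-sequence aligned FASTA as a codon pair."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned sequences, got {len(records)}")
    gid = gene_id if gene_id is not None else Path(path).stem
    return CodonAlignmentPair(gid, str(records[0].seq).upper(), str(records[1].seq).upper())


def write_codon_pair_fasta(pair: CodonAlignmentPair, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pair.gene_id}_a\n{pair.seq_a}\n>{pair.gene_id}_b\n{pair.seq_b}\n")


def divergence_table(estimates: list[DivergenceEstimate]):
    """Long-form divergence results as a DataFrame."""
    import pandas as pd

    rows = []
    for e in estimates:
        rows.append(
            {
                "gene_id": e.gene_id, "N": e.n_sites, "S": e.s_sites,
                "DN": e.nd, "DS": e.sd, "pN": e.p_n, "pS": e.p_s,
                "dN": e.d_n, "dS": e.d_s, "dNdS": e.dn_ds,
                "saturated": e.saturated,
            }
        )
    return pd.DataFrame(rows)
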