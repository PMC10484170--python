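"""Per-gene within-species selection statistics.

Implements the site-wise decomposition of Tajima's D used throughout the
package: for each biallelic variant site *i* with n_i non-missing
chromosomes,

    pi_i      = (n_i / (n_i - 1)) * (1 - p_ref^2 - p_alt^2)
    theta_w_i = 1 / a_i,           a_i = sum_{j=1}^{n_i - 1} 1/j
    var_i     = [ (n_i + 1) / (3 (n_i - 1)) - 1/a_i ] / a_i
    d_i       = (pi_i - theta_w_i) / sqrt(var_i)

var_i equals the Tajima (1989) variance of (pi - thetaW) with the number
of segregating sites fixed at one, and d_i is therefore a single-site
Tajima's D.  The gene-level statistic is the unweighted mean of d_i over
the gene's variant sites.  Sites with n_i < 4 are excluded from D: the
variance term is zero (hence d_i undefined) at n_i in {2, 3}.

Nucleotide diversity uses the ratio-of-sums estimator over genotyped
sites (variant plus invariant): per site with n non-missing chromosomes
and alternate-allele count c, differences = c(n - c) and comparisons =
n(n - 1)/2; the per-site estimate is sum(differences)/sum(comparisons).
That per-site value is scaled by the number of genotyped sites in the
analysis and divided by a site-count denominator — the NG86 N or S site
counts for piN and piS, or the CDS length for overall pi — so each
statistic is a diversity *per nonsynonymous (synonymous, total) site*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_formats import SiteClass, VariantSite

logger = logging.getLogger("specsel")

MIN_CHROMOSOMES_FOR_D = 4


@dataclass(frozen=True)
class SiteStat:
    """Single-site diversity components (see module docstring)."""

    pi_i: float
    theta_w_i: float
    a_i: float
    var_i: float
    d_i: float


@dataclass
class GeneSelectionStats:
    """Joined per-gene selection statistics."""

    gene_id: str
    pi_all: float | None = None
    pi_n: float | None = None
    pi_s: float | None = None
    tajima_d: float | None = None
    p_n_count: int = 0
    p_s_count: int = 0
    d_n_count: float | None = None
    d_s_count: float | None = None
    dos: float | None = None
    n_sites_used: int = 0


def harmonic_number(n: int) -> float:
    """a_n = sum_{j=1}^{n-1} 1/j, summed in ascending j."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    return sum(1.0 / j for j in range(1, n))


def site_pi(site: VariantSite) -> float | None:
    """Per-site heterozygosity with the n/(n-1) small-sample factor."""
    if site.n_chromosomes < 2:
        return None
    if site.site_class is SiteClass.INVARIANT or site.p_alt == 0.0:
        return 0.0
    n = site.n_chromosomes
    return (n / (n - 1.0)) * (1.0 - site.p_ref**2 - site.p_alt**2)


def site_theta_w(n: int) -> float:
    """Watterson's theta for one segregating site: 1/a_n."""
    return 1.0 / harmonic_number(n)


def site_d_variance(n: int) -> float:
    """Variance of (pi_i - theta_w_i) with one segregating site.

    Equals Tajima's e1 coefficient (b1, c1 route) evaluated at S = 1;
    positive for all n >= 4, zero at n in {2, 3}.
    """
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    a = harmonic_number(n)
    return ((n + 1.0) / (3.0 * (n - 1.0)) - 1.0 / a) / a


def site_stat(site: VariantSite) -> SiteStat | None:
    """All single-site components, or None when the site is excluded.

    Sites with fewer than four non-missing chromosomes are excluded
    (variance zero or fragile) and logged by the caller.
    """
    n = site.n_chromosomes
    if n < MIN_CHROMOSOMES_FOR_D:
        return None
    var = site_d_variance(n)
    if var <= 0:
        return None
    a = harmonic_number(n)
    pi = site_pi(site)
    theta = 1.0 / a
    d = (pi - theta) / math.sqrt(var)
    return SiteStat(pi_i=pi, theta_w_i=theta, a_i=a, var_i=var, d_i=d)


def site_d(site: VariantSite) -> float | None:
    stat = site_stat(site)
    return None if stat is None else stat.d_i


def gene_tajima_d(sites: list[VariantSite]) -> float | None:
    """Unweighted mean of single-site D over a gene's variant sites.

    Invariant sites are ignored; variant sites excluded by the n >= 4
    rule are dropped from the average (logged).  None when no variant
    site yields a defined d_i.
    """
    ds = []
    n_excluded = 0
    for site in sites:
        if site.site_class is SiteClass.INVARIANT or site.p_alt == 0.0:
            continue
        d = site_d(site)
        if d is None:
            n_excluded += 1
        else:
            ds.append(d)
    if n_excluded:
        logger.debug("gene_tajima_d: %d variant sites excluded (n < 4)", n_excluded)
    if not ds:
        return None
    return float(np.mean(ds))


def pi_ratio_of_sums(n: np.ndarray, alt_count: np.ndarray) -> float | None:
    """Per-site diversity as sum(differences) / sum(comparisons).

    ``n`` and ``alt_count`` are per-site arrays of non-missing
    chromosome counts and alternate-allele counts (0 for invariant
    sites).  None when there are no comparable sites.
    """
    n = np.asarray(n, dtype=float)
    c = np.asarray(alt_count, dtype=float)
    usable = n >= 2
    if not usable.any():
        return None
    diffs = (c[usable] * (n[usable] - c[usable])).sum()
    comps = (n[usable] * (n[usable] - 1.0) / 2.0).sum()
    if comps == 0:
        return None
    return float(diffs / comps)


def gene_pi(
    sites: list[VariantSite],
    class_filter: SiteClass | None,
    n_sites_included: int | None = None,
    denominator_sites: float | None = None,
) -> float | None:
    """Class-restricted nucleotide diversity for one gene.

    ``class_filter`` keeps sites of that class plus invariant sites
    (None keeps every genotyped site).  The ratio-of-sums per-site
    estimate is multiplied by ``n_sites_included`` (default: the number
    of genotyped sites in the filtered analysis) and divided by
    ``denominator_sites`` (NG86 N or S, or CDS length; default: same as
    ``n_sites_included``, i.e. plain per-genotyped-site diversity).
    """
    if class_filter is None:
        kept = sites
    else:
        kept = [
            s for s in sites
            if s.site_class is class_filter or s.site_class is SiteClass.INVARIANT
        ]
    if not kept:
        return None
    n = np.array([s.n_chromosomes for s in kept], dtype=float)
    c = np.array([round(s.p_alt * s.n_chromosomes) for s in kept], dtype=float)
    per_site = pi_ratio_of_sums(n, c)
    if per_site is None:
        return None
    if n_sites_included is None:
        n_sites_included = len(kept)
    if denominator_sites is None:
        denominator_sites = float(n_sites_included)
    if denominator_sites == 0:
        return None
    return per_site * n_sites_included / denominator_sites


def count_polymorphisms(sites: list[VariantSite]) -> tuple[int, int]:
    """(PN, PS): counts of missense and synonymous variant sites."""
    pn = ps = 0
    for s in sites:
        if s.site_class is SiteClass.INVARIANT or s.p_alt == 0.0:
            continue
        if s.site_class is SiteClass.MISSENSE:
            pn += 1
        elif s.site_class is SiteClass.SYNONYMOUS:
            ps += 1
    return pn, ps


def direction_of_selection(
    dn_count: float, ds_count: float, pn_count: int, ps_count: int
) -> float | None:
    """DoS = DN/(DN+DS) - PN/(PN+PS); None when either sum is zero.

    Positive values indicate an excess of nonsynonymous divergence over
    nonsynonymous polymorphism (adaptive signature); negative values
    indicate segregating deleterious variation.
    """
    if min(dn_count, ds_count, pn_count, ps_count) < 0:
        raise ValueError("counts must be non-negative")
    div = dn_count + ds_count
    poly = pn_count + ps_count
    if div == 0 or poly == 0:
        return None
    return dn_count / div - pn_count / poly


# ---------------------------------------------------------------------------
# vectorized single-site Tajima's D (used by the simulation experiments)

_HARMONIC_CACHE: dict[int, float] = {}


def _harmonic(n: int) -> float:
    if n not in _HARMONIC_CACHE:
        _HARMONIC_CACHE[n] = harmonic_number(n)
    return _HARMONIC_CACHE[n]


def site_d_array(n: np.ndarray, alt_count: np.ndarray) -> np.ndarray:
    """Single-site D for arrays of (n, alt count); NaN where excluded."""
    n = np.asarray(n, dtype=int)
    c = np.asarray(alt_count, dtype=float)
    nf = n.astype(float)
    a = np.array([_harmonic(int(v)) if v >= 2 else np.nan for v in n])
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = c / nf
        pi = (nf / (nf - 1.0)) * (1.0 - (1.0 - p_alt) ** 2 - p_alt**2)
        var = ((nf + 1.0) / (3.0 * (nf - 1.0)) - 1.0 / a) / a
        d = (pi - 1.0 / a) / np.sqrt(var)
    d[(n < MIN_CHROMOSOMES_FOR_D)] = np.nan
    return d


def gene_stats(
    sites: list[VariantSite],
    gene_id: str,
    n_nonsyn_sites: float | None = None,
    n_syn_sites: float | None = None,
    cds_length: float | None = None,
    dn_count: float | None = None,
    ds_count: float | None = None,
) -> GeneSelectionStats:
    """Assemble all within-species statistics for one gene.

    ``n_nonsyn_sites``/``n_syn_sites`` are NG86 N and S (denominators
    for piN and piS); ``cds_length`` scales overall pi; ``dn_count`` and
    ``ds_count`` (between-species difference counts) enable DoS.
    """
    miss = [s for s in sites if s.site_class in (SiteClass.MISSENSE, SiteClass.INVARIANT)]
    syn = [s for s in sites if s.site_class in (SiteClass.SYNONYMOUS, SiteClass.INVARIANT)]
    pn, ps = count_polymorphisms(sites)
    stats = GeneSelectionStats(gene_id=gene_id, n_sites_used=len(sites))
    stats.pi_all = gene_pi(sites, None, len(sites), cds_length or float(len(sites)))
    if n_nonsyn_sites:
        stats.pi_n = gene_pi(miss, None, len(miss), n_nonsyn_sites)
    if n_syn_sites:
        stats.pi_s = gene_pi(syn, None, len(syn), n_syn_sites)
    stats.tajima_d = gene_tajima_d(sites)
    stats.p_n_count, stats.p_s_count = pn, ps
    stats.d_n_count, stats.d_s_count = dn_count, ds_count
    if dn_count is not None and ds_count is not None:
        stats.dos = direction_of_selection(dn_count, ds_count, pn, ps)
    return stats
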