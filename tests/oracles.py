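"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different route from the library code:
translation goes through Bio.Seq, pathway enumeration is a recursive
search, Tajima's D uses the full textbook coefficient set, and partial
correlation is computed by residualizing ranks.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq
from scipy import stats

BASES = "ACGT"


_TRANSLATE_CACHE: dict[str, str] = {}


def translate(codon: str) -> str:
    if codon not in _TRANSLATE_CACHE:
        _TRANSLATE_CACHE[codon] = str(Seq(codon).translate())
    return _TRANSLATE_CACHE[codon]


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


def oracle_site_counts(codon: str, stop_mutations: str = "nonsynonymous"):
    """(N, S) by scanning all nine single-base mutants of a codon."""
    aa = translate(codon)
    s_total = 0.0
    for pos in range(3):
        syn = counted = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if is_stop(mutant):
                if stop_mutations == "nonsynonymous":
                    counted += 1
                continue
            counted += 1
            syn += translate(mutant) == aa
        if counted:
            s_total += syn / counted
    return 3.0 - s_total, s_total


def oracle_pair_differences(codon_a: str, codon_b: str):
    """(nd, sd) by recursive enumeration of substitution pathways."""

    def walk(cur: str, remaining: tuple[int, ...]):
        # yields (nd, sd, hit_stop) for each completion order
        if not remaining:
            yield 0, 0, False
            return
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            step_stop = is_stop(cur) or is_stop(nxt)
            syn = (not step_stop) and translate(cur) == translate(nxt)
            rest = remaining[:i] + remaining[i + 1 :]
            for nd, sd, hit in walk(nxt, rest):
                yield nd + (0 if syn else 1), sd + (1 if syn else 0), hit or step_stop
        return

    diff = tuple(i for i in range(3) if codon_a[i] != codon_b[i])
    paths = list(walk(codon_a, diff))
    clean = [(nd, sd) for nd, sd, hit in paths if not hit]
    use = clean if clean else [(nd, sd) for nd, sd, _ in paths]
    return (
        sum(p[0] for p in use) / len(use) if use else 0.0,
        sum(p[1] for p in use) / len(use) if use else 0.0,
    )


def sense_codons():
    return [
        a + b + c
        for a, b, c in itertools.product(BASES, repeat=3)
        if not is_stop(a + b + c)
    ]


def tajima_d_textbook(n: int, s: int, pi_hat: float) -> float:
    """Classic Tajima's D from the full coefficient set (a1..e2)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1.0)
    return (pi_hat - s / a1) / np.sqrt(var)


def pi_hat_single_site(n: int, alt: int) -> float:
    """Average pairwise differences for one biallelic site."""
    return alt * (n - alt) / (n * (n - 1) / 2.0)


def partial_spearman_residual(x, y, covs) -> float:
    """Partial Spearman via Pearson correlation of rank residuals."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if covs is None or covs.shape[1] == 0:
        return float(stats.pearsonr(rx, ry).statistic)
    rz = np.column_stack(
        [np.ones(len(rx))] + [stats.rankdata(covs[:, j]) for j in range(covs.shape[1])]
    )
    bx, *_ = np.linalg.lstsq(rz, rx, rcond=None)
    by, *_ = np.linalg.lstsq(rz, ry, rcond=None)
    return float(stats.pearsonr(rx - rz @ bx, ry - rz @ by).statistic)
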