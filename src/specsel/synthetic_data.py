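"""Ground-truth generators for every input the pipeline consumes.

Every generator is a pure function of (config, seed): reruns are
bit-identical, and each returns a truth record alongside the data so
recovery can be tested.  Components:

* :func:`simulate_zinb_matrix` / :func:`zinb_specificity_experiment` —
  the zero-inflated negative-binomial experiment demonstrating how
  zeros couple average expression to the specificity index tau.
* :func:`simulate_expression_study` — treatment-structured TPM matrices
  with study-level batch shifts, for tau recovery and SVA behavior.
* :func:`simulate_genotypes` — per-gene genotyped sites with
  neutral-SFS allele frequencies and planted per-site theta.
* :func:`simulate_codon_pair_set` — codon alignments with planted dN/dS.
* :func:`simulate_joined_study` — gene-level latent traits drawn from a
  Gaussian copula with a planted *partial*-correlation matrix, pushed
  through expression, genotype and codon-pair generation so the
  end-to-end analysis can be checked against the planted structure.

Negative-binomial parameterization: (size, success probability) with
mean size * (1 - p) / p, i.e. numpy's convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import popgen_stats
from .codon_evolution import (
    AA,
    BASES,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignmentPair,
    pairwise_dnds,
)
from .io_formats import ExpressionMatrix, SiteClass, VariantSite


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-component child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# ZINB specificity experiment


@dataclass(frozen=True)
class ZINBParams:
    """Zero-inflated negative-binomial matrix parameters.

    Each entry is zero with probability 1 - prob_nonzero, otherwise a
    draw from NB(nb_size, nb_prob).  Columns form n_groups blocks of
    reps_per_group replicate columns.
    """

    nb_size: int = 100
    nb_prob: float = 0.1
    prob_nonzero: float = 0.4
    n_groups: int = 5
    reps_per_group: int = 5
    n_genes: int = 100
    n_matrices: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nb_prob < 1:
            raise ValueError("nb_prob must be in (0, 1)")
        if not 0 <= self.prob_nonzero <= 1:
            raise ValueError("prob_nonzero must be in [0, 1]")


def simulate_zinb_matrix(
    params: ZINBParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One genes x (groups * reps) ZINB matrix."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    shape = (params.n_genes, params.n_groups * params.reps_per_group)
    nonzero = rng.random(shape) < params.prob_nonzero
    counts = rng.negative_binomial(params.nb_size, params.nb_prob, size=shape)
    return np.where(nonzero, counts, 0).astype(float)


def zinb_specificity_experiment(params: ZINBParams) -> pd.DataFrame:
    """Correlation of tau with average expression, with and without zeros.

    For each simulated matrix: per-gene group means, tau over those
    means, average expression over all entries (zeros included) and over
    nonzero entries only, then the Spearman correlation of tau with each
    average.  Genes unexpressed everywhere are dropped pairwise.
    Returns one row per matrix with columns ``corr_with_zeros`` and
    ``corr_excluding_zeros``.
    """
    rng = np.random.default_rng(params.seed)
    g, r = params.n_groups, params.reps_per_group
    rows = []
    for _ in range(params.n_matrices):
        x = simulate_zinb_matrix(params, rng)
        means = x.reshape(params.n_genes, g, r).mean(axis=2)
        mx = means.max(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.where(mx > 0, (1.0 - means / np.where(mx > 0, mx, 1.0)[:, None]).sum(axis=1) / (g - 1), np.nan)
        avg_incl = x.mean(axis=1)
        nz = (x > 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            avg_excl = np.where(nz > 0, x.sum(axis=1) / np.maximum(nz, 1), np.nan)
        rows.append(
            {
                "corr_with_zeros": _spearman_dropna(tau, avg_incl),
                "corr_excluding_zeros": _spearman_dropna(tau, avg_excl),
            }
        )
    return pd.DataFrame(rows)


def _spearman_dropna(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return float("nan")
    return float(stats.spearmanr(a[ok], b[ok]).statistic)


# ---------------------------------------------------------------------------
# expression study


@dataclass(frozen=True)
class ExpressionStudyConfig:
    """Treatment/study-structured expression study on a log2-TPM model.

    Per gene g and sample j (treatment t, study s):

        log2 TPM = baseline_g + log2 profile_{g,t} + beta_g * u_s + noise

    profile is 1 at the gene's preferred treatment and (1 - s_g)
    elsewhere, so the gene's true treatment specificity is s_g.  u_s is
    a per-study shift of scale batch_sd; beta_g is nonzero for a
    batch-affected gene subset.  ``incidence="balanced"`` samples every
    treatment in every study; ``"unbalanced"`` gives each study a
    rotating window of treatments (every treatment still appears in at
    least two studies), which confounds study with treatment the way
    heterogeneous public corpora do.
    """

    n_genes: int = 2000
    n_treatments: int = 5
    n_studies: int = 4
    reps: int = 1
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    specificity_beta: tuple[float, float] = (1.5, 3.0)
    noise_sd: float = 0.25
    batch_sd: float = 1.0
    affected_fraction: float = 0.3
    incidence: str = "balanced"
    tissue_label: str = "leaf"


@dataclass
class StudyTruth:
    """Planted ground truth serialized alongside each generated dataset."""

    gene_truth: pd.DataFrame | None = None
    sample_truth: pd.DataFrame | None = None
    site_truth: pd.DataFrame | None = None
    partial_correlations: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def to_files(self, prefix) -> None:
        from pathlib import Path
        import yaml

        prefix = Path(prefix)
        for name in ("gene_truth", "sample_truth", "site_truth", "partial_correlations"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(f"{prefix}.{name}.tsv", sep="\t", index=True, na_rep="NA")
        with open(f"{prefix}.params.yaml", "w") as fh:
            yaml.safe_dump(_plain(self.params), fh)

    @classmethod
    def from_files(cls, prefix) -> "StudyTruth":
        from pathlib import Path
        import yaml

        prefix = Path(prefix)
        kwargs = {}
        for name in ("gene_truth", "sample_truth", "site_truth", "partial_correlations"):
            p = Path(f"{prefix}.{name}.tsv")
            if p.exists():
                kwargs[name] = pd.read_csv(p, sep="\t", index_col=0, na_values=["NA"])
        p = Path(f"{prefix}.params.yaml")
        params = {}
        if p.exists():
            with open(p) as fh:
                params = yaml.safe_load(fh)
        return cls(params=params, **kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _study_incidence(cfg: ExpressionStudyConfig) -> list[tuple[int, int]]:
    """(treatment, study) cells that receive samples."""
    cells = []
    if cfg.incidence == "balanced":
        for t in range(cfg.n_treatments):
            for s in range(cfg.n_studies):
                cells.append((t, s))
    elif cfg.incidence == "unbalanced":
        width = max(2, (cfg.n_treatments + 1) // 2)
        for s in range(cfg.n_studies):
            for w in range(width):
                cells.append(((s + w) % cfg.n_treatments, s))
        covered = {}
        for t, s in cells:
            covered.setdefault(t, set()).add(s)
        for t in range(cfg.n_treatments):
            studies = covered.get(t, set())
            s = 0
            while len(studies) < 2:
                if s not in studies:
                    cells.append((t, s))
                    studies.add(s)
                s += 1
    else:
        raise ValueError(f"unknown incidence {cfg.incidence!r}")
    return sorted(set(cells))


def simulate_expression_study(
    cfg: ExpressionStudyConfig, seed: int
) -> tuple[ExpressionMatrix, StudyTruth]:
    rng = np.random.default_rng(seed)
    cells = _study_incidence(cfg)
    n_samples = len(cells) * cfg.reps
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    spec = rng.beta(*cfg.specificity_beta, cfg.n_genes)
    preferred = rng.integers(0, cfg.n_treatments, cfg.n_genes)
    profile = np.full((cfg.n_genes, cfg.n_treatments), 0.0)
    profile[:] = np.maximum(1.0 - spec[:, None], 1e-3)
    profile[np.arange(cfg.n_genes), preferred] = 1.0

    u = rng.normal(0.0, cfg.batch_sd, cfg.n_studies) if cfg.batch_sd > 0 else np.zeros(cfg.n_studies)
    affected = rng.random(cfg.n_genes) < cfg.affected_fraction
    beta = np.where(affected, rng.normal(1.0, 0.25, cfg.n_genes), 0.0)

    treat_idx = np.repeat([t for t, _ in cells], cfg.reps)
    study_idx = np.repeat([s for _, s in cells], cfg.reps)
    y = (
        baseline[:, None]
        + np.log2(profile[:, treat_idx])
        + beta[:, None] * u[study_idx][None, :]
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_samples))
    )
    tpm = np.exp2(y)

    sample_ids = [f"run{j:04d}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "run_id": sample_ids,
            "experiment_id": [f"exp{j:04d}" for j in range(n_samples)],
            "study_id": [f"study{s}" for s in study_idx],
            "tissue_label": cfg.tissue_label,
            "treatment_label": [f"treat{t}" for t in treat_idx],
        },
        index=sample_ids,
    )
    matrix = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=sample_ids), meta)
    truth = StudyTruth(
        gene_truth=pd.DataFrame(
            {
                "true_tau": spec,
                "preferred_treatment": [f"treat{t}" for t in preferred],
                "baseline_log2": baseline,
                "batch_loading": beta,
                "batch_affected": affected,
            },
            index=genes,
        ),
        sample_truth=pd.DataFrame(
            {"study_shift": u[study_idx], "treatment": [f"treat{t}" for t in treat_idx]},
            index=sample_ids,
        ),
        params=dataclasses.asdict(cfg) | {"seed": seed},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# genotypes


@dataclass(frozen=True)
class GenotypeConfig:
    """Neutral-SFS genotype simulation with planted per-site theta.

    Per gene and site class, the number of segregating sites is Poisson
    with mean theta * L * a_n (the neutral expectation); allele counts
    follow the neutral frequency spectrum P(count = i) proportional to
    1/i; each diploid call is missing independently with
    ``missing_rate``.  Non-segregating positions are emitted as
    invariant genotyped sites so diversity denominators are honest.
    """

    n_genes: int = 100
    n_chromosomes: int = 20  # diploid samples = n/2
    nonsyn_sites: int = 600
    syn_sites: int = 200
    theta_n: float = 0.002
    theta_s: float = 0.008
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_chromosomes % 2 != 0:
            raise ValueError("n_chromosomes must be even (diploid samples)")


def _neutral_sfs_counts(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    i = np.arange(1, n)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum())


def simulate_genotypes(
    cfg: GenotypeConfig, seed: int
) -> tuple[dict[str, list[VariantSite]], StudyTruth]:
    rng = np.random.default_rng(seed)
    n = cfg.n_chromosomes
    a_n = popgen_stats.harmonic_number(n)
    genes: dict[str, list[VariantSite]] = {}
    truth_rows = []
    for g in range(cfg.n_genes):
        gene_id = f"g{g:05d}"
        sites: list[VariantSite] = []
        pos = 1
        for cls, L, theta in (
            (SiteClass.MISSENSE, cfg.nonsyn_sites, cfg.theta_n),
            (SiteClass.SYNONYMOUS, cfg.syn_sites, cfg.theta_s),
        ):
            n_seg = min(rng.poisson(theta * L * a_n), L)
            seg_pos = set(rng.choice(L, size=n_seg, replace=False).tolist())
            alt_counts = _neutral_sfs_counts(n, n_seg, rng)
            it = iter(alt_counts)
            for j in range(L):
                n_called = n
                if cfg.missing_rate > 0:
                    n_called = 2 * int(
                        (rng.random(n // 2) >= cfg.missing_rate).sum()
                    )
                if j in seg_pos:
                    c_total = int(next(it))
                    if cfg.missing_rate > 0 and n_called < n:
                        c = int(rng.hypergeometric(c_total, n - c_total, n_called)) if n_called > 0 else 0
                    else:
                        c = c_total
                else:
                    c = 0
                if n_called < 2:
                    continue
                variant = c > 0 and c < n_called
                site_cls = cls if variant else SiteClass.INVARIANT
                # a planted allele fixed in the sampled chromosomes is
                # indistinguishable from an invariant site
                p_alt = c / n_called if variant else 0.0
                sites.append(
                    VariantSite(
                        chrom="chr1",
                        pos=pos,
                        gene_id=gene_id,
                        site_class=site_cls,
                        n_chromosomes=n_called,
                        p_ref=1.0 - p_alt,
                        p_alt=p_alt,
                    )
                )
                pos += 1
        genes[gene_id] = sites
        truth_rows.append(
            {"gene_id": gene_id, "theta_n": cfg.theta_n, "theta_s": cfg.theta_s}
        )
    truth = StudyTruth(
        gene_truth=pd.DataFrame(truth_rows).set_index("gene_id"),
        params=dataclasses.asdict(cfg) | {"seed": seed},
    )
    return genes, truth


def write_genotypes_vcf(
    genes: dict[str, list[VariantSite]], vcf_path, classes_path
) -> None:
    """Serialize simulated sites as a minimal VCF plus a class-interval TSV.

    Genotypes are reconstructed to match each site's allele counts
    (alt-carrying chromosomes first, then reference, then missing), so
    reading the VCF back recovers identical frequencies.
    """
    all_sites = [s for sites in genes.values() for s in sites]
    n_max = max(s.n_chromosomes for s in all_sites)
    n_samples = (n_max + 1) // 2
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr1>\n")
        cols = "\t".join(f"s{i}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        offset = 0
        for gene_id in genes:
            for s in genes[gene_id]:
                alt_count = round(s.p_alt * s.n_chromosomes)
                alleles = ["1"] * alt_count + ["0"] * (s.n_chromosomes - alt_count)
                alleles += ["."] * (2 * n_samples - len(alleles))
                gts = "\t".join(
                    f"{alleles[2*i]}/{alleles[2*i+1]}" for i in range(n_samples)
                )
                alt = "." if s.p_alt == 0 else "T"
                fh.write(
                    f"chr1\t{offset + s.pos}\t.\tA\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
                )
            offset += max(x.pos for x in genes[gene_id])
    with open(classes_path, "w") as fh:
        offset = 0
        for gene_id in genes:
            for s in genes[gene_id]:
                cls = s.site_class.value
                if cls == "invariant":
                    cls = "other"  # class of an invariant position is unobserved
                start = offset + s.pos - 1
                fh.write(f"chr1\t{start}\t{start + 1}\t{gene_id}\t{cls}\n")
            offset += max(x.pos for x in genes[gene_id])


# ---------------------------------------------------------------------------
# codon pairs


@dataclass(frozen=True)
class CodonPairConfig:
    """Divergence simulation along two lineages from a random ancestor.

    Substitution counts per lineage are Poisson with mean
    d/2 * (sites of that class); each substitution is a uniformly
    chosen single-base change accepted when its NG86 classification
    matches the requested class and it does not create a stop codon.
    """

    n_genes: int = 100
    n_codons: int = 300
    d_n: float = 0.1
    d_s: float = 0.2


_MUTANTS: dict[str, list[tuple[str, int, str, bool]]] = {}
# codon -> list of (new_codon, position, base, is_synonymous), stop-free


def _mutant_table(codon: str):
    if codon not in _MUTANTS:
        out = []
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut in STOP_CODONS:
                    continue
                out.append((mut, pos, b, AA[mut] == AA[codon]))
        _MUTANTS[codon] = out
    return _MUTANTS[codon]


def _random_ancestor(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), n_codons)
    return [SENSE_CODONS[i] for i in idx]


def _apply_substitutions(
    codons: list[str], n_subs: int, synonymous: bool, rng: np.random.Generator
) -> None:
    """Apply n single-base substitutions of one class, in place.

    Candidate mutations are uniform over all (codon, position, base)
    single-base changes in the sequence; changes creating stop codons or
    of the wrong class are rejected and redrawn, so every eligible
    change is equally likely.
    """
    applied = 0
    guard = 0
    limit = 2000 * max(n_subs, 1)
    n_codons = len(codons)
    while applied < n_subs:
        guard += 1
        if guard > limit:
            raise RuntimeError("substitution rejection sampling failed to converge")
        i = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        base = BASES[int(rng.integers(0, 4))]
        codon = codons[i]
        if base == codon[pos]:
            continue
        mut = codon[:pos] + base + codon[pos + 1 :]
        if mut in STOP_CODONS:
            continue
        if (AA[mut] == AA[codon]) != synonymous:
            continue
        codons[i] = mut
        applied += 1


def simulate_codon_pair_set(
    cfg: CodonPairConfig, seed: int
) -> tuple[list[CodonAlignmentPair], StudyTruth]:
    from .codon_evolution import count_sequence_sites

    rng = np.random.default_rng(seed)
    pairs = []
    rows = []
    for g in range(cfg.n_genes):
        gene_id = f"g{g:05d}"
        anc = _random_ancestor(cfg.n_codons, rng)
        counts = count_sequence_sites("".join(anc))
        for d in (cfg.d_n, cfg.d_s):
            # expected observed difference proportion under multiple hits
            p_expected = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            if p_expected >= 0.72:
                raise ValueError(
                    "planted divergence saturates by construction "
                    f"(d={d}: expected proportion {p_expected:.3f} at the "
                    "Jukes-Cantor domain boundary)"
                )
        lineages = []
        for _ in range(2):
            seq = list(anc)
            n_nonsyn = rng.poisson(cfg.d_n / 2.0 * counts.n_sites)
            n_syn = rng.poisson(cfg.d_s / 2.0 * counts.s_sites)
            _apply_substitutions(seq, n_nonsyn, synonymous=False, rng=rng)
            _apply_substitutions(seq, n_syn, synonymous=True, rng=rng)
            lineages.append("".join(seq))
        pairs.append(CodonAlignmentPair(gene_id, lineages[0], lineages[1]))
        rows.append(
            {"gene_id": gene_id, "true_d_n": cfg.d_n, "true_d_s": cfg.d_s,
             "anc_n_sites": counts.n_sites, "anc_s_sites": counts.s_sites}
        )
    truth = StudyTruth(
        gene_truth=pd.DataFrame(rows).set_index("gene_id"),
        params=dataclasses.asdict(cfg) | {"seed": seed},
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# joined study


@dataclass(frozen=True)
class JoinedStudyConfig:
    """End-to-end study generated from shared gene-level latent traits.

    Latent traits (tau, average expression, gene length, GC fraction,
    piN) are drawn from a Gaussian copula whose *partial*-correlation
    matrix is planted directly: the precision matrix is built with unit
    diagonal and off-diagonal -rho_partial, inverted, and standardized.
    Each latent maps monotonically to its observable; measurement is
    quasi-deterministic (expression replicates are noise-free and
    genotype diversity is planted by site-frequency construction, so
    only rank-quantization separates recovered from planted
    correlations).
    """

    n_genes: int = 2000
    n_treatments: int = 5
    reps: int = 2
    n_chromosomes: int = 100
    nonsyn_sites: int = 1200
    n_codons: int = 150
    tau_range: tuple[float, float] = (0.05, 0.85)
    avg_log10_range: tuple[float, float] = (np.log10(12.0), np.log10(400.0))
    theta_n_log10_range: tuple[float, float] = (-3.0, -2.0)
    gc_range: tuple[float, float] = (0.30, 0.60)
    include_codons: bool = True
    # planted partial correlations, variable order (tau, avg, length, gc, piN)
    partial_tau_pin: float = 0.10
    partial_avg_pin: float = -0.19
    partial_tau_avg: float = -0.15
    partial_length_pin: float = 0.0
    partial_gc_pin: float = 0.0


JOINED_VARIABLES = ("tau", "avg_expr", "length_bp", "gc_fraction", "pi_n")


def planted_partial_matrix(cfg: JoinedStudyConfig) -> np.ndarray:
    p = np.zeros((5, 5))
    idx = {v: i for i, v in enumerate(JOINED_VARIABLES)}
    pairs = {
        ("tau", "pi_n"): cfg.partial_tau_pin,
        ("avg_expr", "pi_n"): cfg.partial_avg_pin,
        ("tau", "avg_expr"): cfg.partial_tau_avg,
        ("length_bp", "pi_n"): cfg.partial_length_pin,
        ("gc_fraction", "pi_n"): cfg.partial_gc_pin,
    }
    for (a, b), r in pairs.items():
        p[idx[a], idx[b]] = p[idx[b], idx[a]] = r
    np.fill_diagonal(p, 1.0)
    return p


def _copula_covariance(partial: np.ndarray) -> np.ndarray:
    """Correlation matrix whose partial correlations equal ``partial``."""
    omega = -partial.copy()
    np.fill_diagonal(omega, 1.0)
    eig = np.linalg.eigvalsh(omega)
    if eig.min() <= 0:
        raise ValueError("planted partial-correlation matrix is not positive definite")
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _planted_pi_sites(
    theta: float, n_sites: int, n_chrom: int
) -> tuple[np.ndarray, np.ndarray]:
    """(n, alt_count) arrays realizing total diversity ~ theta * n_sites.

    Singleton sites each contribute pairwise diversity 2/n; the planted
    per-gene diversity is reached by the nearest achievable singleton
    count (quantization is the only measurement error).
    """
    per_singleton = 2.0 / n_chrom
    k = int(round(theta * n_sites / per_singleton))
    k = min(k, n_sites)
    n = np.full(n_sites, n_chrom)
    c = np.zeros(n_sites)
    c[:k] = 1
    return n, c


def simulate_joined_study(cfg: JoinedStudyConfig, seed: int) -> dict:
    """Generate the full bundle and measure it with the package's own tools.

    Returns a dict with the measured per-gene table (columns of
    :data:`JOINED_VARIABLES`), the planted truth, and (optionally) the
    codon-pair divergence estimates.
    """
    seeds = child_seeds(seed, 4)
    rng = np.random.default_rng(seeds[0])
    partial = planted_partial_matrix(cfg)
    sigma = _copula_covariance(partial)
    z = rng.multivariate_normal(np.zeros(5), sigma, size=cfg.n_genes)
    uni = stats.norm.cdf(z)  # per-variable uniforms, copula-linked

    lo, hi = cfg.tau_range
    tau_true = lo + (hi - lo) * uni[:, 0]
    avg_true = 10.0 ** (
        cfg.avg_log10_range[0]
        + (cfg.avg_log10_range[1] - cfg.avg_log10_range[0]) * uni[:, 1]
    )
    length = np.round(200.0 * np.exp(2.0 * z[:, 2])).astype(int) + 200
    gc = cfg.gc_range[0] + (cfg.gc_range[1] - cfg.gc_range[0]) * uni[:, 3]
    theta_n = 10.0 ** (
        cfg.theta_n_log10_range[0]
        + (cfg.theta_n_log10_range[1] - cfg.theta_n_log10_range[0]) * uni[:, 4]
    )

    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]

    # expression: per-treatment profile realizing tau exactly, scaled so the
    # plain mean equals avg_true and every value clears the TPM >= 5 cut
    t = cfg.n_treatments
    preferred = rng.integers(0, t, cfg.n_genes)
    profile = np.maximum(1.0 - tau_true[:, None], 1e-6) * np.ones((cfg.n_genes, t))
    profile[np.arange(cfg.n_genes), preferred] = 1.0
    profile /= profile.mean(axis=1)[:, None]
    group_tpm = avg_true[:, None] * profile

    tpm = np.repeat(group_tpm, cfg.reps, axis=1)
    sample_ids = [f"run{j:03d}" for j in range(t * cfg.reps)]
    meta = pd.DataFrame(
        {
            "run_id": sample_ids,
            "experiment_id": [f"exp{j:03d}" for j in range(t * cfg.reps)],
            "study_id": "study0",
            "tissue_label": "leaf",
            "treatment_label": [f"treat{j // cfg.reps}" for j in range(t * cfg.reps)],
        },
        index=sample_ids,
    )
    matrix = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=sample_ids), meta)

    from . import expression_metrics

    collapsed = expression_metrics.collapse_technical_replicates(matrix)
    gm = expression_metrics.group_means(collapsed, "treatment_label")
    tau_meas = expression_metrics.tau_frame(gm)
    avg_meas = expression_metrics.thresholded_average_expression(collapsed)

    # genotypes: planted realized diversity via singleton construction,
    # measured with the package's ratio-of-sums estimator
    pin_meas = np.empty(cfg.n_genes)
    for i in range(cfg.n_genes):
        n_arr, c_arr = _planted_pi_sites(theta_n[i], cfg.nonsyn_sites, cfg.n_chromosomes)
        per_site = popgen_stats.pi_ratio_of_sums(n_arr, c_arr)
        pin_meas[i] = per_site  # denominator = site count: diversity per site

    table = pd.DataFrame(
        {
            "tau": tau_meas.to_numpy(),
            "avg_expr": avg_meas.to_numpy(),
            "length_bp": length,
            "gc_fraction": gc,
            "pi_n": pin_meas,
        },
        index=genes,
    )

    divergence = None
    if cfg.include_codons:
        # constraint latent shared with piN: lower diversity, lower dN
        dn_true = np.clip(theta_n * 20.0, 0.005, 0.5)
        divergence = _joined_codon_divergence(dn_true, cfg, seeds[1])
        table["d_n"] = divergence["d_n"].to_numpy()

    truth = StudyTruth(
        gene_truth=pd.DataFrame(
            {
                "true_tau": tau_true,
                "true_avg": avg_true,
                "length_bp": length,
                "gc_fraction": gc,
                "true_theta_n": theta_n,
            }
            | ({"true_d_n": np.clip(theta_n * 20.0, 0.005, 0.5)} if cfg.include_codons else {}),
            index=genes,
        ),
        partial_correlations=pd.DataFrame(
            partial, index=list(JOINED_VARIABLES), columns=list(JOINED_VARIABLES)
        ),
        params=dataclasses.asdict(cfg) | {"seed": seed},
    )
    return {"table": table, "truth": truth, "matrix": matrix, "divergence": divergence}


def _joined_codon_divergence(
    dn_true: np.ndarray, cfg: JoinedStudyConfig, seed: int
) -> pd.DataFrame:
    from .codon_evolution import count_sequence_sites

    rng = np.random.default_rng(seed)
    rows = []
    for i, dn in enumerate(dn_true):
        anc = _random_ancestor(cfg.n_codons, rng)
        counts = count_sequence_sites("".join(anc))
        lineages = []
        for _ in range(2):
            seq = list(anc)
            _apply_substitutions(seq, rng.poisson(dn / 2.0 * counts.n_sites), False, rng)
            _apply_substitutions(seq, rng.poisson(0.05 * counts.s_sites), True, rng)
            lineages.append("".join(seq))
        est = pairwise_dnds(CodonAlignmentPair(f"g{i:05d}", lineages[0], lineages[1]))
        rows.append({"gene_id": f"g{i:05d}", "d_n": est.d_n, "d_s": est.d_s,
                     "saturated": est.saturated})
    return pd.DataFrame(rows).set_index("gene_id")


def recovered_partial_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """All-pairs partial Spearman over the joined-study variables."""
    from .correlation_analysis import correlation_heatmap

    return correlation_heatmap(table.reset_index(), list(JOINED_VARIABLES))
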