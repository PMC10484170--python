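import numpy as np
import pandas as pd
import pytest

from specsel.batch_correction import SurrogateVariableModel
from specsel.codon_evolution import pairwise_dnds
from specsel.expression_metrics import treatment_specificity
from specsel.io_formats import SiteClass, read_site_classes, read_sites_vcf
from specsel.popgen_stats import gene_pi
from specsel.synthetic_data import (
    CodonPairConfig,
    ExpressionStudyConfig,
    GenotypeConfig,
    JoinedStudyConfig,
    StudyTruth,
    ZINBParams,
    child_seeds,
    planted_partial_matrix,
    simulate_codon_pair_set,
    simulate_expression_study,
    simulate_genotypes,
    simulate_joined_study,
    simulate_zinb_matrix,
    write_genotypes_vcf,
    zinb_specificity_experiment,
)


class TestDeterminism:
    def test_all_generators_bit_reproducible(self):
        z1 = simulate_zinb_matrix(ZINBParams(n_genes=20, n_matrices=1, seed=5))
        z2 = simulate_zinb_matrix(ZINBParams(n_genes=20, n_matrices=1, seed=5))
        np.testing.assert_array_equal(z1, z2)

        cfg = ExpressionStudyConfig(n_genes=50)
        m1, _ = simulate_expression_study(cfg, 9)
        m2, _ = simulate_expression_study(cfg, 9)
        pd.testing.assert_frame_equal(m1.values, m2.values)

        g1, _ = simulate_genotypes(GenotypeConfig(n_genes=5), 9)
        g2, _ = simulate_genotypes(GenotypeConfig(n_genes=5), 9)
        assert g1 == g2

        p1, _ = simulate_codon_pair_set(CodonPairConfig(n_genes=3, n_codons=30), 9)
        p2, _ = simulate_codon_pair_set(CodonPairConfig(n_genes=3, n_codons=30), 9)
        assert [(p.seq_a, p.seq_b) for p in p1] == [(p.seq_a, p.seq_b) for p in p2]

    def test_child_seeds_below_31_bits(self):
        seeds = child_seeds(123456, 10)
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)


class TestZINB:
    def test_all_zero_when_never_expressed(self):
        params = ZINBParams(prob_nonzero=0.0, n_genes=10, seed=1)
        assert simulate_zinb_matrix(params).sum() == 0.0

    def test_moments_match_closed_form(self):
        # NB(size, p) mean = size (1-p)/p; ZINB scales by p2 and adds
        # the structural zero mass
        params = ZINBParams(n_genes=4000, seed=2)  # 10^5 entries
        draws = np.concatenate(
            [simulate_zinb_matrix(ZINBParams(n_genes=4000, seed=s)).ravel() for s in (2, 3)]
        )
        size, p, p2 = 100, 0.1, 0.4
        nb_mean = size * (1 - p) / p
        nb_var = size * (1 - p) / p**2
        mean = p2 * nb_mean
        var = p2 * (nb_var + nb_mean**2) - mean**2
        n = draws.size
        assert draws.mean() == pytest.approx(mean, abs=3 * np.sqrt(var / n))
        zero_frac = (1 - p2) + p2 * p**size
        assert (draws == 0).mean() == pytest.approx(
            zero_frac, abs=3 * np.sqrt(zero_frac * (1 - zero_frac) / n)
        )

    def test_experiment_output_shape_and_direction(self):
        params = ZINBParams(n_matrices=50, seed=3)
        df = zinb_specificity_experiment(params)
        assert list(df.columns) == ["corr_with_zeros", "corr_excluding_zeros"]
        assert len(df) == 50
        # zeros drive a strong negative coupling; excluding them removes it
        assert df["corr_with_zeros"].mean() < -0.2
        assert df["corr_excluding_zeros"].abs().mean() < df["corr_with_zeros"].abs().mean()


class TestExpressionStudy:
    def test_no_batch_gives_k_zero(self):
        cfg = ExpressionStudyConfig(n_genes=150, batch_sd=0.0)
        mat, _ = simulate_expression_study(cfg, 21)
        model = SurrogateVariableModel(k="auto", random_state=22).fit(mat)
        assert model.k_selected_ == 0

    def test_degenerate_specificity_gives_uniform_genes(self):
        cfg = ExpressionStudyConfig(
            n_genes=100, specificity_beta=(1e3, 1e9), batch_sd=0.0, noise_sd=0.05
        )
        mat, truth = simulate_expression_study(cfg, 4)
        assert truth.gene_truth["true_tau"].max() < 1e-3
        est = treatment_specificity(mat)["tau"]
        assert est.mean() < 0.1

    def test_tau_rank_recovery(self):
        cfg = ExpressionStudyConfig(n_genes=2000, batch_sd=0.0, noise_sd=0.25)
        mat, truth = simulate_expression_study(cfg, 8)
        est = treatment_specificity(mat)["tau"]
        rho = pd.Series(est.to_numpy()).corr(
            pd.Series(truth.gene_truth["true_tau"].to_numpy()), method="spearman"
        )
        assert rho > 0.8

    def test_metadata_contract(self):
        mat, truth = simulate_expression_study(ExpressionStudyConfig(n_genes=10), 1)
        assert set(mat.samples_meta.columns) >= {
            "run_id", "experiment_id", "study_id", "tissue_label", "treatment_label",
        }
        # validator ran at construction; truth aligned to genes
        assert list(truth.gene_truth.index) == mat.gene_ids


class TestGenotypes:
    def test_zero_theta_means_no_missense_variants(self):
        cfg = GenotypeConfig(n_genes=10, theta_n=0.0)
        genes, _ = simulate_genotypes(cfg, 3)
        for sites in genes.values():
            assert all(s.site_class is not SiteClass.MISSENSE for s in sites)

    def test_site_invariants_hold(self):
        genes, _ = simulate_genotypes(GenotypeConfig(n_genes=20), 4)
        for sites in genes.values():
            for s in sites:
                assert s.p_ref + s.p_alt == pytest.approx(1.0, abs=1e-12)
                assert s.n_chromosomes >= 2
                if s.site_class is SiteClass.INVARIANT:
                    assert s.p_alt == 0.0

    def test_pi_s_recovers_planted_theta(self):
        cfg = GenotypeConfig(n_genes=300, theta_s=0.008, missing_rate=0.1)
        genes, truth = simulate_genotypes(cfg, 6)
        ests = []
        for sites in genes.values():
            kept = [
                s for s in sites
                if s.site_class in (SiteClass.SYNONYMOUS, SiteClass.INVARIANT)
            ]
            pi = gene_pi(kept, None, len(kept), cfg.syn_sites)
            ests.append(pi)
        ests = np.array(ests, dtype=float)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert ests.mean() == pytest.approx(0.008, abs=2 * se)

    def test_vcf_round_trip_preserves_frequencies(self, tmp_path):
        genes, _ = simulate_genotypes(GenotypeConfig(n_genes=3), 7)
        write_genotypes_vcf(genes, tmp_path / "g.vcf", tmp_path / "c.tsv")
        table = read_site_classes(tmp_path / "c.tsv")
        back = read_sites_vcf(tmp_path / "g.vcf", table)
        for gene_id, sites in genes.items():
            got = back[gene_id]
            assert len(got) == len(sites)
            for s_in, s_out in zip(sites, got):
                assert s_out.n_chromosomes == s_in.n_chromosomes
                assert s_out.p_alt == pytest.approx(s_in.p_alt, abs=1e-12)
                assert (s_out.site_class is SiteClass.INVARIANT) == (
                    s_in.site_class is SiteClass.INVARIANT
                )


class TestCodonPairs:
    def test_zero_divergence_gives_identical_pairs(self):
        cfg = CodonPairConfig(n_genes=5, n_codons=50, d_n=0.0, d_s=0.0)
        pairs, _ = simulate_codon_pair_set(cfg, 5)
        for p in pairs:
            assert p.seq_a == p.seq_b

    def test_saturating_planted_ds_flags_majority(self):
        cfg = CodonPairConfig(n_genes=60, n_codons=300, d_n=0.05, d_s=1.2)
        pairs, _ = simulate_codon_pair_set(cfg, 6)
        flagged = np.mean([pairwise_dnds(p).saturated for p in pairs])
        assert flagged > 0.5

    def test_absurd_planted_rate_errors(self):
        with pytest.raises(ValueError, match="saturates by construction"):
            simulate_codon_pair_set(CodonPairConfig(n_genes=1, d_s=5.0), 1)


class TestJoinedStudy:
    def test_identity_copula_null_partials_near_zero(self):
        cfg = JoinedStudyConfig(
            n_genes=3000, include_codons=False,
            partial_tau_pin=0.0, partial_avg_pin=0.0, partial_tau_avg=0.0,
        )
        bundle = simulate_joined_study(cfg, 12)
        from specsel.synthetic_data import recovered_partial_correlations

        rec = recovered_partial_correlations(bundle["table"])
        assert rec["rho"].abs().max() < 0.05  # ~2.7 SE at n=3000

    def test_planted_partials_recovered_loosely(self):
        cfg = JoinedStudyConfig(n_genes=3000, include_codons=False)
        bundle = simulate_joined_study(cfg, 13)
        from specsel.correlation_analysis import spearman_partial

        t = bundle["table"]
        rho = spearman_partial(
            t["tau"].to_numpy(),
            t["pi_n"].to_numpy(),
            t[["avg_expr", "length_bp", "gc_fraction"]].to_numpy(),
        ).rho
        assert rho == pytest.approx(0.10, abs=0.05)

    def test_non_positive_definite_target_errors(self):
        cfg = JoinedStudyConfig(
            n_genes=10, partial_tau_pin=0.99, partial_avg_pin=-0.99, partial_tau_avg=-0.99
        )
        with pytest.raises(ValueError, match="positive definite"):
            simulate_joined_study(cfg, 1)

    def test_truth_round_trips_through_files(self, tmp_path):
        cfg = JoinedStudyConfig(n_genes=50, include_codons=False)
        bundle = simulate_joined_study(cfg, 14)
        truth = bundle["truth"]
        truth.to_files(tmp_path / "truth")
        back = StudyTruth.from_files(tmp_path / "truth")
        pd.testing.assert_frame_equal(
            back.gene_truth, truth.gene_truth, check_exact=False, rtol=1e-12
        )
        pd.testing.assert_frame_equal(
            back.partial_correlations, truth.partial_correlations, rtol=1e-12
        )
        assert back.params["n_genes"] == 50

    def test_planted_partial_matrix_layout(self):
        p = planted_partial_matrix(JoinedStudyConfig())
        assert p[0, 4] == 0.10 and p[1, 4] == -0.19
        np.testing.assert_array_equal(np.diag(p), 1.0)
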