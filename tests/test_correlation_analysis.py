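import numpy as np
import pandas as pd
import pytest
from scipy import stats

from specsel.correlation_analysis import (
    CollinearityError,
    assemble_gene_table,
    build_analysis_table,
    correlation_heatmap,
    spearman_partial,
    target_correlation,
)

import oracles


class TestSpearmanPartial:
    def test_zero_covariates_reduces_to_spearman(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 50)
            y = x * 0.5 + rng.normal(0, 1, 50)
            x[rng.integers(0, 50, 5)] = x[0]  # inject ties
            res = spearman_partial(x, y)
            expected = stats.spearmanr(x, y)
            assert res.rho == pytest.approx(expected.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(expected.pvalue, rel=1e-6)

    def test_identical_variables_give_unit_rho(self, rng):
        x = rng.normal(0, 1, 40)
        z = rng.normal(0, 1, (40, 2))
        res = spearman_partial(x, x.copy(), z)
        assert res.rho == pytest.approx(1.0)

    def test_matches_rank_residual_oracle(self, rng):
        for _ in range(50):
            n = 60
            k = int(rng.integers(0, 5))
            z = rng.normal(0, 1, (n, k))
            x = z.sum(axis=1) * 0.3 + rng.normal(0, 1, n)
            y = z.sum(axis=1) * 0.3 - 0.2 * x + rng.normal(0, 1, n)
            res = spearman_partial(x, y, z)
            assert res.rho == pytest.approx(
                oracles.partial_spearman_residual(x, y, z), abs=1e-10
            )

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 80
        z = rng.normal(0, 1, (n, 2))
        x = z[:, 0] * 0.4 + rng.normal(0, 1, n)
        y = z[:, 1] * 0.4 + 0.3 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        expected = pingouin.partial_corr(
            df, x="x", y="y", covar=["z1", "z2"], method="spearman"
        )
        res = spearman_partial(x, y, z)
        assert res.rho == pytest.approx(float(expected["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(expected["p_val"].iloc[0]), rel=1e-6)

    def test_rank_invariance_under_monotone_transforms(self, rng):
        n = 100
        z = rng.gamma(2, 1, (n, 2))
        x = rng.gamma(2, 1, n) + z[:, 0]
        y = rng.gamma(2, 1, n) + z[:, 1]
        base = spearman_partial(x, y, z).rho
        assert spearman_partial(np.log(x), y**3, np.column_stack([np.exp(z[:, 0] / 5), z[:, 1]])).rho == pytest.approx(base, abs=1e-12)

    def test_collinear_covariates_named(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        z1 = rng.normal(0, 1, 30)
        with pytest.raises(CollinearityError, match="z1.*z2|z2.*z1"):
            spearman_partial(
                x, y, np.column_stack([z1, 2 * z1]), covariate_names=("z1", "z2")
            )

    def test_sample_size_guard(self, rng):
        with pytest.raises(ValueError, match="n >"):
            spearman_partial(np.arange(4.0), np.arange(4.0), rng.normal(0, 1, (4, 2)))

    def test_nan_rejected(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="complete cases"):
            spearman_partial(x, x[::-1])


def _gene_table(n=40, rng=None):
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "tau_treatment": rng.random(n),
            "tau_tissue": rng.random(n),
            "avg_expr": rng.gamma(2, 50, n),
            "length_bp": rng.integers(300, 5000, n),
            "gc_fraction": rng.uniform(0.3, 0.6, n),
            "family_size": rng.integers(1, 6, n),
            "pi_n": rng.gamma(1, 0.002, n),
            "tajima_d": rng.normal(-0.5, 0.5, n),
            "dos": rng.uniform(-0.5, 0.5, n),
            "d_n": rng.gamma(1, 0.05, n),
            "saturated": [False] * n,
            "one_to_one": [True] * n,
        }
    )
    return df


class TestBuildAnalysisTable:
    def test_family_size_only_for_within_species_targets(self):
        table = _gene_table()
        _, covs_pin = build_analysis_table(table, "piN")
        _, covs_dn = build_analysis_table(table, "dN")
        assert "family_size" in covs_pin
        assert "family_size" not in covs_dn

    def test_saturated_genes_dropped_for_dn_only(self):
        table = _gene_table()
        table.loc[0, "saturated"] = True
        df_dn, _ = build_analysis_table(table, "dN")
        df_dos, _ = build_analysis_table(table, "DoS")
        assert "g0" not in set(df_dn["gene_id"])
        assert "g0" in set(df_dos["gene_id"])

    def test_one_to_one_restriction_for_divergence_targets(self):
        table = _gene_table()
        table.loc[1, "one_to_one"] = False
        df_dn, _ = build_analysis_table(table, "dN")
        df_pin, _ = build_analysis_table(table, "piN")
        assert "g1" not in set(df_dn["gene_id"])
        assert "g1" in set(df_pin["gene_id"])

    def test_complete_case_count(self):
        table = _gene_table(10)
        table.loc[2, "pi_n"] = np.nan
        table.loc [5, "avg_expr"] = np.nan
        df, _ = build_analysis_table(table, "piN")
        assert len(df) == 8

    def test_unknown_target_errors(self):
        with pytest.raises(ValueError, match="unknown target"):
            build_analysis_table(_gene_table(), "alpha")

    def test_target_correlation_runs(self):
        res = target_correlation(_gene_table(60), "piN")
        assert -1 <= res.rho <= 1
        assert res.n == 60
        assert "family_size" in res.covariates


class TestHeatmap:
    def test_pair_symmetry(self, rng):
        n = 50
        df = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["a", "b", "c"])
        fwd = spearman_partial(df["a"], df["b"], df[["c"]].to_numpy()).rho
        rev = spearman_partial(df["b"], df["a"], df[["c"]].to_numpy()).rho
        assert fwd == pytest.approx(rev, abs=1e-14)

    def test_independent_variables_near_zero(self, rng):
        n = 10000
        df = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["a", "b", "c"])
        out = correlation_heatmap(df, ["a", "b", "c"])
        assert (out["rho"].abs() < 0.05).all()
        assert len(out) == 3

    def test_planted_gaussian_copula_structure_recovered(self, rng):
        # partial-correlation matrix with one strong planted entry
        omega = np.eye(3)
        omega[0, 1] = omega[1, 0] = -0.4
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
        n = 4000
        z = rng.multivariate_normal(np.zeros(3), sigma, n)
        df = pd.DataFrame(z, columns=["a", "b", "c"])
        out = correlation_heatmap(df, ["a", "b", "c"]).set_index(["var_x", "var_y"])
        se = 2.0 / np.sqrt(n)
        assert out.loc[("a", "b"), "rho"] == pytest.approx(0.4, abs=2.5 * se + 0.01)
        assert abs(out.loc[("a", "c"), "rho"]) < 2.5 * se + 0.01

    def test_fixed_control_mode(self, rng):
        n = 200
        df = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=["a", "b", "c", "z"])
        out = correlation_heatmap(df, ["a", "b", "c"], control="fixed", fixed_covariates=["z"])
        assert len(out) == 3


class TestAssembleGeneTable:
    def test_outer_join_preserves_all_genes(self, rng):
        spec = pd.DataFrame({"tau": [0.1, 0.2]}, index=["g1", "g2"])
        avg = pd.Series([5.0], index=["g3"], name="avg")
        out = assemble_gene_table(specificity=spec, avg_expr=avg)
        assert set(out["gene_id"]) == {"g1", "g2", "g3"}
        assert out.set_index("gene_id").loc["g3", "tau_treatment"] != out.set_index("gene_id").loc["g3", "tau_treatment"]  # NaN
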