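"""Integration index: closed forms, bias correction, bootstrap, divergence."""

import numpy as np
import pytest

from floralint import (
    DegenerateTraitError,
    ValidationError,
    bootstrap_integration,
    correlation_matrix,
    divergence_pca,
    integration_index,
    trait_anova_tukey,
)

from .conftest import exact_correlation_data, make_trait_table


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_correlation(self):
        x = np.arange(1.0, 11.0)
        corr = correlation_matrix(np.column_stack([x, x]))
        assert corr[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        x = rng.standard_normal((10_000, 2))
        corr = correlation_matrix(x)
        assert abs(corr[0, 1]) < 0.05

    def test_constant_column_rejected(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 5.0)])
        with pytest.raises(DegenerateTraitError):
            correlation_matrix(x)

    def test_trace_conservation(self, rng):
        """Eigenvalues of any correlation matrix sum to the trait count."""
        for t in (2, 5, 8):
            x = rng.standard_normal((40, t)) @ rng.standard_normal((t, t))
            res = integration_index(x + 10)
            assert res.eigenvalues.sum() == pytest.approx(t, abs=1e-8)


class TestIntegrationIndex:
    def test_collinear_traits_reach_maximum(self):
        x = np.outer(np.arange(1.0, 31.0), np.ones(8))
        res = integration_index(x)
        assert res.raw_variance == pytest.approx(8.0, abs=1e-10)
        assert res.eigenvalues[0] == pytest.approx(8.0, abs=1e-10)
        assert np.all(np.abs(res.eigenvalues[1:]) < 1e-10)

    def test_exactly_independent_traits(self, rng):
        """Zero eigenvalue variance leaves only the negative bias correction."""
        x = exact_correlation_data(np.eye(4), 20, rng)
        res = integration_index(x)
        assert res.raw_variance == pytest.approx(0.0, abs=1e-12)
        assert res.corrected_int == pytest.approx(-(4 - 1) / 20, abs=1e-12)
        assert res.negative_corrected

    def test_equicorrelation_closed_form(self, rng):
        """r = 0.5, T = 3: eigenvalues {2, 0.5, 0.5}, sample variance 0.75."""
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        x = exact_correlation_data(R, 30, rng)
        res = integration_index(x)
        np.testing.assert_allclose(sorted(res.eigenvalues), [0.5, 0.5, 2.0], atol=1e-10)
        assert res.raw_variance == pytest.approx(0.75, abs=1e-10)

    def test_single_trait_rejected(self, rng):
        with pytest.raises(ValidationError):
            integration_index(rng.standard_normal((10, 1)))

    def test_bias_correction_removes_most_independence_bias(self, rng):
        """Under trait independence the sample variance of the eigenvalues
        has exact expectation T/(N-1) (each squared off-diagonal Pearson
        correlation has mean 1/(N-1)), so the (T-1)/N correction leaves a
        small positive remainder of (T+N-1)/(N(N-1)); the corrected index
        matches that value and removes over 80% of the raw bias."""
        t, n = 8, 30
        vals = [
            integration_index(rng.standard_normal((n, t))).corrected_int
            for _ in range(500)
        ]
        remainder = (t + n - 1) / (n * (n - 1))
        assert np.mean(vals) == pytest.approx(remainder, abs=0.02)
        assert abs(np.mean(vals)) < 0.2 * (t / (n - 1))

    def test_percent_int_monotone_in_correlation(self, rng):
        """Stronger equicorrelation never lowers the percent index."""
        means = []
        for r in (0.0, 0.2, 0.4, 0.6, 0.8):
            R = np.full((8, 8), r)
            np.fill_diagonal(R, 1.0)
            L = np.linalg.cholesky(R)
            vals = [
                integration_index(rng.standard_normal((500, 8)) @ L.T).percent_int
                for _ in range(50)
            ]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_bounds(self, rng):
        for _ in range(20):
            x = rng.standard_normal((15, 5)) @ rng.standard_normal((5, 5)) + 5
            res = integration_index(x)
            t, n = res.n_traits, res.n_individuals
            assert 0 <= res.raw_variance <= t + 1e-10
            assert res.percent_int <= 100 * (t - (t - 1) / n) / t + 1e-10


class TestBootstrap:
    def test_fixed_seed_reproducible(self, rng):
        x = rng.standard_normal((20, 4)) + 10
        a = bootstrap_integration(x, n_boot=100, seed=7)
        b = bootstrap_integration(x, n_boot=100, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_collinear_data_degenerate_ci(self):
        x = np.outer(np.arange(1.0, 21.0), np.ones(8))
        res = bootstrap_integration(x, n_boot=50, seed=0)
        max_pct = 100 * (8 - 7 / 20) / 8
        assert res.ci_low == pytest.approx(max_pct, abs=1e-8)
        assert res.ci_high == pytest.approx(max_pct, abs=1e-8)

    def test_invalid_replicate_count(self, rng):
        with pytest.raises(ValidationError):
            bootstrap_integration(rng.standard_normal((10, 3)), n_boot=0)

    def test_ci_covers_population_value(self):
        """95% percentile CI covers the analytic equicorrelation index in at
        least 90% of outer replicates (r = 0.6, T = 8, N = 30)."""
        r, t, n = 0.6, 8, 30
        target = 100 * (8 * r * r - (t - 1) / n) / t
        R = np.full((t, t), r)
        np.fill_diagonal(R, 1.0)
        L = np.linalg.cholesky(R)
        outer_rng = np.random.default_rng(2024)
        cover = 0
        for _ in range(100):
            x = outer_rng.standard_normal((n, t)) @ L.T
            res = bootstrap_integration(x, n_boot=2000, seed=outer_rng)
            cover += res.ci_low <= target <= res.ci_high
        assert cover >= 90


class TestDivergence:
    def test_perfectly_correlated_pair_pc1_total(self, rng):
        table = make_trait_table({"a": np.ones(8), "b": 2 * np.ones(8)}, 10, rng)
        # overwrite all traits with one latent axis => PC1 carries everything
        latent = rng.standard_normal(len(table.frame))
        for j, trait in enumerate(table.trait_names):
            table.frame[trait] = 5 + (j + 1) * latent
        res = divergence_pca(table)
        assert res.pca_proportions[0] == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_proportions(self, rng):
        table = make_trait_table({"a": np.ones(8), "b": np.ones(8)}, 5, rng)
        big = rng.standard_normal((10_000, 8))
        import pandas as pd

        frame = pd.DataFrame(big + 10, columns=table.trait_names)
        frame.insert(0, "individual_id", [f"i{k}" for k in range(len(frame))])
        frame.insert(0, "species_id", ["a"] * 5000 + ["b"] * 5000)
        from floralint import TraitTable

        res = divergence_pca(TraitTable(frame))
        np.testing.assert_allclose(res.pca_proportions, np.full(8, 1 / 8), atol=0.03)

    def test_proportions_sorted_and_sum_to_one(self, lonicera_bundle):
        res = divergence_pca(lonicera_bundle.traits)
        p = res.pca_proportions
        assert p.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(p) <= 1e-12)
        # sign convention: dominant loading of each component positive
        for col in res.pca_loadings.columns:
            v = res.pca_loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestAnovaTukey:
    def test_identical_groups_share_letter(self, rng):
        table = make_trait_table({"a": np.ones(8), "b": np.ones(8), "c": np.ones(8)}, 5, rng)
        for trait in table.trait_names:
            table.frame[trait] = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 3)
        res = trait_anova_tukey(table)
        assert (res.anova["F"] == 0).all()
        assert (res.tukey_letters == "a").all().all()

    def test_separated_groups_get_distinct_letters(self, rng):
        table = make_trait_table({"lo": np.ones(8), "hi": np.ones(8)}, 4, rng)
        jitter = 0.01 * rng.standard_normal(8)
        table.frame.loc[table.frame.species_id == "lo", "stigma_height"] = 1.0 + jitter[:4]
        table.frame.loc[table.frame.species_id == "hi", "stigma_height"] = 11.0 + jitter[4:]
        res = trait_anova_tukey(table)
        letters = res.tukey_letters["stigma_height"]
        assert letters["lo"] != letters["hi"]

    def test_bonferroni_adjustment(self, lonicera_bundle):
        res = trait_anova_tukey(lonicera_bundle.traits)
        t = len(lonicera_bundle.traits.trait_names)
        expected = np.minimum(1.0, res.anova["p_raw"] * t)
        np.testing.assert_allclose(res.anova["p_bonferroni"], expected, atol=1e-12)

    def test_single_individual_species_rejected(self, rng):
        from types import SimpleNamespace

        table = make_trait_table({"a": np.ones(8), "b": np.ones(8)}, 3, rng)
        frame = table.frame.drop(index=[4, 5]).reset_index(drop=True)  # "b" keeps 1 flower
        crippled = SimpleNamespace(
            frame=frame,
            trait_names=table.trait_names,
            species=lambda: sorted(frame["species_id"].unique()),
        )
        with pytest.raises(ValidationError, match="b"):
            trait_anova_tukey(crippled)
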