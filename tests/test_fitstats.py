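import numpy as np
import pytest

import mlcfa
from mlcfa.engine import LevelParams


class TestRmsea:
    def test_printed_cfa_misfit_value(self):
        # severe one-level misfit on N = 10,000
        assert mlcfa.rmsea(12699.87, 27, 10000) == pytest.approx(0.217, abs=5e-4)

    def test_chi2_below_df_gives_zero(self):
        assert mlcfa.rmsea(26.089, 27, 10000) == 0.0

    def test_algebraic_unit_value(self):
        N = 500
        df = 11
        assert mlcfa.rmsea(df + df * (N - 1), df, N) == pytest.approx(1.0)

    def test_df_zero_undefined(self):
        assert np.isnan(mlcfa.rmsea(3.0, 0, 100))

    def test_monotone_in_chi2(self):
        vals = [mlcfa.rmsea(c, 10, 200) for c in (5, 15, 40, 100)]
        assert vals == sorted(vals)


class TestCfi:
    def test_perfect_fit(self):
        assert mlcfa.cfi(5.0, 9, 500.0, 36) == 1.0

    def test_formula_arithmetic(self):
        assert mlcfa.cfi(110.0, 10, 1010.0, 10) == pytest.approx(0.9)

    def test_monotone_nonincreasing_in_chi2(self):
        vals = [mlcfa.cfi(c, 10, 1000.0, 45) for c in (5, 50, 200, 900)]
        assert vals == sorted(vals, reverse=True)

    def test_clamped_to_unit_interval(self):
        assert mlcfa.cfi(5000.0, 10, 100.0, 45) == 0.0


class TestSrmr:
    def test_exact_fit_zero(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert mlcfa.srmr(S, S) == 0.0

    def test_two_indicator_arithmetic(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        Sig = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert mlcfa.srmr(S, Sig) == pytest.approx(np.sqrt(0.01 / 3), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 4 * np.eye(4)
        Sig = S + 0.05 * np.eye(4)
        perm = [2, 0, 3, 1]
        assert mlcfa.srmr(S, Sig) == pytest.approx(
            mlcfa.srmr(S[np.ix_(perm, perm)], Sig[np.ix_(perm, perm)])
        )

    def test_zero_diagonal_rejected(self):
        S = np.array([[0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(mlcfa.ValidationError):
            mlcfa.srmr(S, np.eye(2))


class TestRSquared:
    @pytest.mark.parametrize(
        "lam, psi, theta, expected",
        [
            (0.800, 1.001, 0.357, 0.642),  # multilevel within-level solution
            (0.800, 1.985, 0.791, 0.616),  # conflated one-level solution
        ],
    )
    def test_single_factor_values(self, lam, psi, theta, expected):
        params = LevelParams(
            np.array([[lam]]), np.array([[psi]]), np.array([[theta]]),
            ("f",), ("V1",),
        )
        assert mlcfa.r_squared(params).iloc[0] == pytest.approx(expected, abs=5e-4)

    def test_zero_residual_gives_one(self):
        params = LevelParams(
            np.array([[0.5]]), np.array([[2.0]]), np.array([[0.0]]),
            ("f",), ("y",),
        )
        assert mlcfa.r_squared(params).iloc[0] == 1.0


class TestChiSquare:
    def test_exact_fit_saturated_zero(self, toy_decomposition):
        model = mlcfa.ModelDefinition(
            mlcfa.ModelKind.SATURATED, ("x",), within="saturated"
        )
        fit = mlcfa.minimize(
            model, (toy_decomposition.S_T, toy_decomposition.n_obs),
            compute_se=False,
        )
        chi2, df, p = mlcfa.chi_square(fit)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert df == 0
        assert np.isnan(p)

    def test_cfa_on_its_own_implied_matrix_is_zero_for_any_n(self):
        pat = mlcfa.pattern_from_dict({"f": ["a", "b", "c"]}, ["a", "b", "c"])
        model = mlcfa.build_model("CFA", within_spec=pat)
        Sigma = np.full((3, 3), 0.48)
        np.fill_diagonal(Sigma, 1.0)
        for N in (50, 5000):
            fit = mlcfa.minimize(model, (Sigma, N), compute_se=False)
            chi2, _, _ = mlcfa.chi_square(fit)
            assert chi2 == pytest.approx(0.0, abs=1e-6)


class TestLevelSpecificFit:
    def test_within_statistics_match_pooled_matrix_route(self, benchmark_fit_bundle):
        """Within-specific chi-square from the maximum model equals fitting
        the within model to S_PW alone with weight N - G."""
        d = benchmark_fit_bundle["decomp"]
        w = benchmark_fit_bundle["within"]
        fit, fs = mlcfa.level_specific_fit(w, d, "within_specific")
        cfa = mlcfa.build_model("CFA", within_spec=w)
        fpw = mlcfa.minimize(
            cfa, (d.S_PW, d.n_obs - d.n_clusters + 1), compute_se=False
        )
        assert fs.chi2 == pytest.approx(fpw.f_min, abs=1e-5)
        assert fs.df == 27

    def test_between_specific_df(self, benchmark_fit_bundle):
        d = benchmark_fit_bundle["decomp"]
        b = benchmark_fit_bundle["between"]
        _, fs = mlcfa.level_specific_fit(b, d, "between_specific")
        assert fs.df == 24
        assert fs.chi2 >= 0

    def test_family_design_between_specific_df_is_nine(self, family_patterns):
        _, b = family_patterns
        model = mlcfa.build_model("PS_BETWEEN", between_spec=b)
        assert mlcfa.degrees_of_freedom(model, "between_specific") == 9

    def test_saturated_both_levels_zero_chi2_zero_df(self, benchmark_fit_bundle):
        d = benchmark_fit_bundle["decomp"]
        model = mlcfa.ModelDefinition(
            mlcfa.ModelKind.MCFA, d.labels, within="saturated",
            between="saturated",
        )
        fit = mlcfa.minimize(model, d, compute_se=False)
        chi2, df, _ = mlcfa.chi_square(fit)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert df == 0

    def test_misfit_pattern_cfa_poor_max_good(self, benchmark_fit_bundle):
        """On clustered data the one-level CFA shows severe misfit while the
        maximum model's within-specific fit is excellent."""
        d = benchmark_fit_bundle["decomp"]
        cfa_stats = mlcfa.fit_statistics(
            benchmark_fit_bundle["fits"]["CFA"], d, "overall"
        )
        max_stats = mlcfa.fit_statistics(
            benchmark_fit_bundle["fits"]["MAX_MCFA"], d, "within_specific"
        )
        assert cfa_stats.cfi < 0.95
        assert max_stats.cfi > 0.99
        assert max_stats.rmsea < 0.01
        assert cfa_stats.rmsea > 0.1


class TestCalibration:
    def test_within_specific_chi2_rejection_rate_nominal(self):
        """Correctly specified within model: rejection rate of the
        within-specific chi-square at alpha = 0.05 stays near nominal."""
        from scipy import stats as sp_stats

        labels = ("a", "b", "c", "d")
        within = LevelParams(
            np.array([[1.0], [0.9], [1.1], [0.8]]), np.eye(1) * 0.8,
            np.diag([0.5, 0.6, 0.4, 0.5]), ("f",), labels,
        )
        between = LevelParams(
            np.array([[1.0], [1.0], [1.0], [1.0]]), np.eye(1) * 0.3,
            np.diag([0.2, 0.2, 0.2, 0.2]), ("f",), labels,
        )
        pop = mlcfa.TwoLevelPopulation(within, between, 20, 8, seed=0)
        pat = mlcfa.pattern_from_dict({"f": list(labels)}, labels)
        model = mlcfa.build_model("MAX_MCFA", within_spec=pat)
        df = mlcfa.degrees_of_freedom(model, "within_specific")
        assert df == 2
        crit = sp_stats.chi2.ppf(0.95, df)

        reps = 500
        seeds = np.random.SeedSequence(314).spawn(reps)
        rejections = 0
        used = 0
        for ss in seeds:
            ds = mlcfa.generate(pop, rng=np.random.default_rng(ss))
            d = mlcfa.compute_decomposition(ds)
            fit = mlcfa.minimize(model, d, compute_se=False)
            if not fit.converged:
                continue
            used += 1
            if fit.f_min > crit:
                rejections += 1
        rate = rejections / used
        se = np.sqrt(0.05 * 0.95 / used)
        assert abs(rate - 0.05) < 3 * se + 1e-9
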