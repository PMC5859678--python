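import numpy as np
import pytest
from scipy import optimize as sp_optimize

import mlcfa
from mlcfa.engine import LevelParams
from .conftest import make_random_dataset


class TestImpliedCovariance:
    def test_scalar(self):
        params = LevelParams(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[0.36]]),
            ("f",), ("y",),
        )
        assert mlcfa.implied_covariance(params)[0, 0] == pytest.approx(1.36)

    def test_zero_loadings_give_theta(self):
        theta = np.diag([0.5, 0.7])
        params = LevelParams(
            np.zeros((2, 1)), np.eye(1), theta, ("f",), ("a", "b")
        )
        np.testing.assert_allclose(mlcfa.implied_covariance(params), theta)

    def test_benchmark_within_population_moments(self):
        # lambda = 0.8, psi = 1, theta = 0.36: unit diagonal, 0.64 off-diagonal
        pop = mlcfa.benchmark_population()
        Sigma_W, Sigma_B, _ = mlcfa.population_moments(pop)
        np.testing.assert_allclose(np.diag(Sigma_W), 1.0)
        off = Sigma_W[~np.eye(9, dtype=bool)]
        np.testing.assert_allclose(off, 0.64)


class TestDiscrepancyFunctions:
    def test_fml_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        S = A @ A.T + 3 * np.eye(3)
        assert mlcfa.f_ml(S, S) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "s, sigma, expected",
        [
            (2.0, 1.0, 2 - np.log(2) - 1),
            (1.0, 2.0, np.log(2) + 0.5 - 1),
        ],
    )
    def test_fml_scalar_arithmetic(self, s, sigma, expected):
        got = mlcfa.f_ml(np.array([[s]]), np.array([[sigma]]))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_fml_non_pd_reports_eigenvalue(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(mlcfa.NotPositiveDefiniteError) as err:
            mlcfa.f_ml(S, np.eye(2))
        assert err.value.min_eigenvalue == pytest.approx(-1.0)

    def test_fmuml_exact_fit_is_zero(self, toy_decomposition):
        d = toy_decomposition
        sigma_w = d.S_PW
        sigma_b = (d.S_B - d.S_PW) / d.c
        assert mlcfa.f_muml(d, sigma_w, sigma_b) == pytest.approx(0.0, abs=1e-12)

    def test_fmuml_toy_arithmetic(self, toy_decomposition):
        got = mlcfa.f_muml(
            toy_decomposition, np.array([[2.0]]), np.array([[3.0]])
        )
        assert got == pytest.approx(2 * (1 - np.log(2)), rel=1e-12)

    def test_fmuml_identifies_failing_bracket(self, toy_decomposition):
        with pytest.raises(mlcfa.NotPositiveDefiniteError, match="within"):
            mlcfa.f_muml(
                toy_decomposition, np.array([[-1.0]]), np.array([[5.0]])
            )


def _two_group_oracle(decomp, model):
    """Independently coded weighted two-group ML minimisation.

    Treats the MUML problem as multi-group ML: group 1 is S_B with weight G
    and implied matrix Sigma_W + c Sigma_B, group 2 is S_PW with weight
    N - G and implied matrix Sigma_W. Matrices are assembled by explicit
    elementwise loops and minimised with a generic derivative-free check
    plus numerical-gradient BFGS.
    """
    from mlcfa.engine import _Objective  # only for start values / labels

    obj = _Objective(model, decomp)
    x0 = obj.start()
    nw = obj.within.n_params

    def build(level, x):
        params = level.unpack(np.asarray(x))
        p = len(params.indicators)
        sigma = np.zeros((p, p))
        m = params.Lambda.shape[1]
        for i in range(p):
            for j in range(p):
                acc = 0.0
                for r in range(m):
                    for s in range(m):
                        acc += params.Lambda[i, r] * params.Psi[r, s] * params.Lambda[j, s]
                sigma[i, j] = acc + params.Theta[i, j]
        return sigma

    def ml(S, Sigma):
        if np.linalg.eigvalsh(Sigma)[0] <= 0:
            return 1e8  # finite penalty keeps the line search sane
        return (
            np.linalg.slogdet(Sigma)[1]
            + np.trace(np.linalg.inv(Sigma) @ S)
            - np.linalg.slogdet(S)[1]
            - S.shape[0]
        )

    def f(x):
        sw = build(obj.within, x[:nw])
        sb = build(obj.between, x[nw:])
        g1 = ml(decomp.S_B, sw + decomp.c * sb)
        g2 = ml(decomp.S_PW, sw)
        return decomp.n_clusters * g1 + (decomp.n_obs - decomp.n_clusters) * g2

    from scipy.optimize._numdiff import approx_derivative

    def num_grad(x):
        return approx_derivative(f, x, method="3-point", rel_step=1e-6)

    res = sp_optimize.minimize(f, x0, jac=num_grad, method="BFGS",
                               options={"gtol": 1e-9, "maxiter": 5000})
    # Newton polish on numerical derivatives to pin down the optimum
    x, fx = res.x, res.fun
    for _ in range(20):
        g = num_grad(x)
        if np.abs(g).max() < 1e-8 * max(1.0, abs(fx)):
            break
        H = approx_derivative(num_grad, x, method="3-point", rel_step=1e-5)
        H = 0.5 * (H + H.T)
        ev = np.linalg.eigvalsh(H)[0]
        if ev <= 1e-10:
            H = H + (abs(ev) + 1e-8) * np.eye(x.size)
        step = -np.linalg.solve(H, g)
        alpha = 1.0
        while alpha > 1e-6:
            if f(x + alpha * step) < fx:
                x = x + alpha * step
                fx = f(x)
                break
            alpha /= 2
        else:
            break
    return fx, x


class TestMinimize:
    def test_just_identified_cfa_closed_form(self):
        # unit diagonal, all off-diagonals 0.48 -> lambda = 1, psi = 0.48,
        # theta = 0.52, perfect fit
        S = np.full((3, 3), 0.48)
        np.fill_diagonal(S, 1.0)
        pat = mlcfa.pattern_from_dict({"f": ["a", "b", "c"]}, ["a", "b", "c"])
        model = mlcfa.build_model("CFA", within_spec=pat)
        fit = mlcfa.minimize(model, (S, 100))
        assert fit.f_min == pytest.approx(0.0, abs=1e-8)
        assert fit.estimates["within.lambda[b~f]"] == pytest.approx(1.0, abs=1e-5)
        assert fit.estimates["within.lambda[c~f]"] == pytest.approx(1.0, abs=1e-5)
        assert fit.estimates["within.psi[f,f]"] == pytest.approx(0.48, abs=1e-5)
        for ind in "abc":
            assert fit.estimates[f"within.theta[{ind}]"] == pytest.approx(
                0.52, abs=1e-5
            )

    def test_saturated_two_level_exact_fit(self):
        rng = np.random.default_rng(8)
        ds = make_random_dataset(rng, n_clusters=8, size_range=(3, 6), p=3)
        d = mlcfa.compute_decomposition(ds)
        model = mlcfa.ModelDefinition(
            mlcfa.ModelKind.MCFA, d.labels, within="saturated", between="saturated"
        )
        fit = mlcfa.minimize(model, d, compute_se=False)
        assert fit.f_min == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(fit.implied_within, d.S_PW, atol=1e-5)
        np.testing.assert_allclose(
            fit.implied_between, (d.S_B - d.S_PW) / d.c, atol=1e-5
        )

    def test_fmin_invariant_to_indicator_permutation(self):
        rng = np.random.default_rng(21)
        pop = mlcfa.benchmark_population(n_clusters=30, cluster_size=15, seed=3)
        ds = mlcfa.generate(pop)
        labels = list(ds.labels)
        perm = list(rng.permutation(9))
        permuted = mlcfa.MultilevelDataset(
            ds.values[:, perm], ds.cluster_id, ds.case_id,
            tuple(labels[i] for i in perm),
        )

        def fit_for(dataset):
            items = list(dataset.labels)
            pat = mlcfa.pattern_from_dict({"W_f1": items}, items)
            model = mlcfa.build_model("MAX_MCFA", within_spec=pat)
            return mlcfa.minimize(
                model, mlcfa.compute_decomposition(dataset), compute_se=False
            )

        f1 = fit_for(ds)
        f2 = fit_for(permuted)
        # markers differ between orderings, so compare the fit value and a
        # marker-invariant quantity (residual variances)
        assert abs(f1.f_min - f2.f_min) < 1e-5
        t1 = {lab: f1.estimates[f"within.theta[{lab}]"] for lab in labels}
        t2 = {lab: f2.estimates[f"within.theta[{lab}]"] for lab in labels}
        for lab in labels:
            assert t1[lab] == pytest.approx(t2[lab], abs=1e-5)

    def test_max_equals_within_model_on_pooled_matrix(self, benchmark_fit_bundle):
        """Saturated between absorbs S_B: MAX estimates = within-only fit."""
        d = benchmark_fit_bundle["decomp"]
        w = benchmark_fit_bundle["within"]
        fmax = benchmark_fit_bundle["fits"]["MAX_MCFA"]
        cfa = mlcfa.build_model("CFA", within_spec=w)
        fpw = mlcfa.minimize(
            cfa, (d.S_PW, d.n_obs - d.n_clusters + 1), compute_se=False
        )
        assert fmax.f_min == pytest.approx(fpw.f_min, abs=1e-6)
        for lab in fpw.estimates.index:
            assert fmax.estimates[lab] == pytest.approx(
                fpw.estimates[lab], abs=1e-6
            )

    @pytest.mark.parametrize("seed", [101, 202])
    def test_muml_matches_independent_two_group_oracle(self, seed):
        """Two-level fits from populations with genuine factor structure at
        both levels agree with an independently coded weighted two-group ML
        minimisation to 1e-6 in the discrepancy and 1e-4 in estimates."""
        rng = np.random.default_rng(seed)
        labels = ("y0", "y1", "y2", "y3")
        within = mlcfa.LevelParams(
            rng.uniform(0.6, 1.1, size=(4, 1)), np.eye(1),
            np.diag(rng.uniform(0.3, 0.7, size=4)), ("f",), labels,
        )
        between = mlcfa.LevelParams(
            rng.uniform(0.5, 1.0, size=(4, 1)), np.eye(1) * 0.6,
            np.diag(rng.uniform(0.2, 0.5, size=4)), ("f",), labels,
        )
        pop = mlcfa.TwoLevelPopulation(within, between, 40, 12, seed=seed)
        d = mlcfa.compute_decomposition(mlcfa.generate(pop))
        pat = mlcfa.pattern_from_dict({"f": list(labels)}, labels)
        model = mlcfa.build_model("MCFA", within_spec=pat, between_spec=pat)
        fit = mlcfa.minimize(model, d, compute_se=False)
        assert fit.converged
        f_oracle, x_oracle = _two_group_oracle(d, model)
        assert fit.f_min == pytest.approx(f_oracle, abs=1e-6)
        np.testing.assert_allclose(
            fit.estimates.to_numpy(), x_oracle, atol=1e-4
        )

    def test_heywood_case_flagged_not_clamped(self):
        # forces a negative residual: y2 almost collinear with the factor
        S = np.array(
            [
                [1.0, 0.9, 0.54],
                [0.9, 1.0, 0.4],
                [0.54, 0.4, 1.0],
            ]
        )
        pat = mlcfa.pattern_from_dict({"f": ["a", "b", "c"]}, ["a", "b", "c"])
        model = mlcfa.build_model("CFA", within_spec=pat)
        fit = mlcfa.minimize(model, (S, 200), compute_se=False)
        negative = (fit.estimates.filter(like="theta") < 0).any()
        if negative:
            assert any("Heywood" in m for m in fit.messages)


class TestStandardErrors:
    def test_scalar_saturated_closed_form(self):
        # one-level saturated p=1: theta-hat = s^2, SE = sqrt(2 s^4 / (N-1))
        s2 = 2.5
        N = 73
        model = mlcfa.ModelDefinition(
            mlcfa.ModelKind.SATURATED, ("y",), within="saturated"
        )
        fit = mlcfa.minimize(model, (np.array([[s2]]), N))
        assert fit.estimates.iloc[0] == pytest.approx(s2, rel=1e-7)
        # closed-form Hessian of (N-1) f_ml at the optimum gives
        # SE = sqrt(2 s^4 / (N-1))
        assert fit.se.iloc[0] == pytest.approx(
            np.sqrt(2 * s2**2 / (N - 1)), rel=1e-4
        )

    def test_doubling_counts_halves_squared_se(self):
        pop = mlcfa.benchmark_population(n_clusters=40, cluster_size=25, seed=5)
        ds = mlcfa.generate(pop)
        d1 = mlcfa.compute_decomposition(ds)
        pat = mlcfa.benchmark_within_pattern()
        model = mlcfa.build_model("MAX_MCFA", within_spec=pat)
        fit1 = mlcfa.minimize(model, d1)

        double = mlcfa.CovDecomposition(
            S_T=d1.S_T, S_PW=d1.S_PW, S_B=d1.S_B, c=d1.c,
            n_obs=2 * d1.n_obs, n_clusters=2 * d1.n_clusters,
            n_g=np.repeat(d1.n_g, 2), grand_mean=d1.grand_mean,
            group_means=d1.group_means, labels=d1.labels,
        )
        fit2 = mlcfa.minimize(model, double)
        lam = fit1.estimates.filter(like="lambda").index
        ratio = (fit1.se[lam] ** 2 / fit2.se[lam] ** 2).to_numpy()
        np.testing.assert_allclose(ratio, 2.0, rtol=0.06)

    def test_standard_errors_function_matches_fit(self, benchmark_fit_bundle):
        d = benchmark_fit_bundle["decomp"]
        fit = benchmark_fit_bundle["fits"]["MAX_MCFA"]
        recomputed = mlcfa.standard_errors(fit, d)
        np.testing.assert_allclose(
            recomputed.to_numpy(), fit.se.to_numpy(), rtol=1e-4
        )
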