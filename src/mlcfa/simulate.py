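"""Two-level normal factor-model data generation and recovery experiments.

Data are drawn from the two-level factor model

    y_gi = mu + Lambda_B eta_g + eps_g + Lambda_W eta_gi + eps_gi

with eta_g ~ N(0, Psi_B), eps_g ~ N(0, Theta_B), eta_gi ~ N(0, Psi_W),
eps_gi ~ N(0, Theta_W), all independent, so the population level
covariances are Sigma_L = Lambda_L Psi_L Lambda_L' + Theta_L and the
population ICC of indicator j is Sigma_B,jj / (Sigma_B,jj + Sigma_W,jj).

The bundled reference population (:func:`benchmark_population`) mirrors a
balanced benchmark design: nine indicators, one within-level factor and
three between-level factors of three indicators each, all loadings 0.80,
all residual variances 0.36, unit factor variances, between-factor
covariances 0.30, 50 clusters of 200 cases. With these values every
indicator has unit variance at both levels and a population ICC of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MultilevelDataset
from .decompose import compute_decomposition
from .engine import LevelParams, minimize
from .exceptions import ConfigurationError, NotPositiveDefiniteError, ValidationError
from .fitstats import fit_statistics
from .modelspec import (
    SATURATED_LEVEL,
    FactorPattern,
    ModelDefinition,
    ModelKind,
    degrees_of_freedom,
    pattern_from_dict,
)


@dataclass(frozen=True)
class TwoLevelPopulation:
    """Population parameters for a balanced or unbalanced two-level design."""

    within: LevelParams
    between: LevelParams
    n_clusters: int
    cluster_size: int | list[int]
    mu: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.within.Lambda.shape[0] != self.between.Lambda.shape[0]:
            raise ConfigurationError("within/between indicator counts differ")
        if self.within.indicators != self.between.indicators:
            raise ConfigurationError("within/between indicator order differs")
        for lvl, params in (("within", self.within), ("between", self.between)):
            if params.Psi.size and np.linalg.eigvalsh(params.Psi)[0] <= 0:
                raise NotPositiveDefiniteError(f"{lvl} Psi is not positive definite")
            if (np.diag(params.Theta) < 0).any():
                raise ValidationError(f"{lvl} Theta has negative diagonal entries")
        if self.n_clusters < 2:
            raise ValidationError("need at least 2 clusters")
        mu = (
            np.zeros(self.p)
            if self.mu is None
            else np.asarray(self.mu, dtype=float)
        )
        object.__setattr__(self, "mu", mu)

    @property
    def p(self) -> int:
        return self.within.Lambda.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        if np.isscalar(self.cluster_size):
            return np.full(self.n_clusters, int(self.cluster_size))
        sizes = np.asarray(self.cluster_size, dtype=int)
        if sizes.size != self.n_clusters:
            raise ConfigurationError("cluster_size list length must equal n_clusters")
        return sizes


def unbalanced_sizes(n_clusters: int, low: int, high: int, seed: int) -> list[int]:
    """Draw cluster sizes uniformly from [low, high], reproducibly."""
    rng = np.random.default_rng(seed)
    return rng.integers(low, high + 1, size=n_clusters).tolist()


def population_moments(pop: TwoLevelPopulation):
    """Population Sigma_W, Sigma_B and per-indicator ICC."""
    Sigma_W = pop.within.implied()
    Sigma_B = pop.between.implied()
    icc = np.diag(Sigma_B) / (np.diag(Sigma_B) + np.diag(Sigma_W))
    return Sigma_W, Sigma_B, pd.Series(icc, index=list(pop.within.indicators),
                                       name="icc_pop")


def _sqrt_factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root used to colour standard-normal draws."""
    if cov.size == 0:
        return cov
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-10:
        raise NotPositiveDefiniteError(
            f"covariance not PSD (min eigenvalue {w.min():.3g})", float(w.min())
        )
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def generate(pop: TwoLevelPopulation, rng=None) -> MultilevelDataset:
    """Draw one dataset from the population; deterministic given the seed."""
    if rng is None:
        rng = np.random.default_rng(pop.seed)
    sizes = pop.sizes
    G = pop.n_clusters
    N = int(sizes.sum())
    p = pop.p

    def draw(Lambda, Psi, Theta, n):
        m = Lambda.shape[1]
        eta = rng.standard_normal((n, m)) @ _sqrt_factor(Psi).T if m else np.zeros((n, p))
        eps = rng.standard_normal((n, p)) @ _sqrt_factor(Theta).T
        return (eta @ Lambda.T if m else 0.0) + eps

    between_part = draw(pop.between.Lambda, pop.between.Psi, pop.between.Theta, G)
    within_part = draw(pop.within.Lambda, pop.within.Psi, pop.within.Theta, N)

    values = pop.mu + np.repeat(between_part, sizes, axis=0) + within_part
    width = len(str(G))
    cluster = np.repeat([f"g{g:0{width}d}" for g in range(G)], sizes)
    case = np.concatenate([np.arange(n) for n in sizes])
    case = np.array([f"c{i:06d}" for i in case])
    return MultilevelDataset(values, cluster, case, pop.within.indicators)


# ---------------------------------------------------------------------------
# reference population and model
# ---------------------------------------------------------------------------

def benchmark_population(
    n_clusters: int = 50,
    cluster_size: int | list[int] = 200,
    loading: float = 0.8,
    residual_var: float = 0.36,
    between_factor_cov: float = 0.30,
    seed: int = 0,
) -> TwoLevelPopulation:
    """Balanced benchmark population: 9 indicators, 1 within / 3 between factors."""
    labels = tuple(f"V{j}" for j in range(1, 10))
    Lw = np.full((9, 1), loading)
    within = LevelParams(
        Lw, np.eye(1), np.eye(9) * residual_var, ("W_f1",), labels
    )
    Lb = np.zeros((9, 3))
    for r in range(3):
        Lb[3 * r : 3 * r + 3, r] = loading
    Psi_B = np.full((3, 3), between_factor_cov)
    np.fill_diagonal(Psi_B, 1.0)
    between = LevelParams(
        Lb, Psi_B, np.eye(9) * residual_var, ("B_f1", "B_f2", "B_f3"), labels
    )
    return TwoLevelPopulation(within, between, n_clusters, cluster_size, seed=seed)


def family_iq_population(
    n_clusters: int = 60,
    size_range: tuple[int, int] = (4, 12),
    size_seed: int = 1,
    seed: int = 123,
) -> TwoLevelPopulation:
    """Synthetic unbalanced population emulating a family intelligence study.

    Six cognitive subtests on children nested within families: two
    correlated within-family ability factors (verbal-ish and
    performance-ish triplets) and one general family-level factor with a
    nontrivial shared variance component, giving indicator ICCs around
    0.35-0.5. Family sizes are drawn uniformly from ``size_range``.

    This is a synthetic stand-in calibrated to the scale of classic
    family-IQ analyses; it is used to exercise the qualitative contrasts
    between one-level and multilevel fits under high ICC (conflated CFA
    residual variances, incongruent loading estimates).
    """
    labels = ("wordst", "cards", "matrix", "figure", "animal", "occpat")
    Lw = np.zeros((6, 2))
    Lw[:3, 0] = [1.0, 1.001, 0.962]
    Lw[3:, 1] = [1.0, 1.026, 0.901]
    within = LevelParams(
        Lw,
        np.array([[9.918, 3.721], [3.721, 9.724]]),
        np.diag([6.228, 5.335, 6.414, 6.824, 4.859, 5.358]),
        ("f1", "f2"),
        labels,
    )
    between = LevelParams(
        np.array([[1.0], [0.985], [0.831], [0.878], [1.050], [1.091]]),
        np.array([[9.677]]),
        np.diag([1.024, 1.449, 1.947, 2.161, 0.495, 1.763]),
        ("B_f1",),
        labels,
    )
    sizes = unbalanced_sizes(n_clusters, size_range[0], size_range[1], size_seed)
    return TwoLevelPopulation(within, between, n_clusters, sizes, seed=seed)


def family_iq_within_pattern(marker_value: float = 1.0) -> FactorPattern:
    labels = ["wordst", "cards", "matrix", "figure", "animal", "occpat"]
    return pattern_from_dict(
        {"f1": labels[:3], "f2": labels[3:]}, labels, marker_value
    )


def family_iq_between_pattern(marker_value: float = 1.0) -> FactorPattern:
    labels = ["wordst", "cards", "matrix", "figure", "animal", "occpat"]
    return pattern_from_dict({"B_f1": labels}, labels, marker_value)


def benchmark_within_pattern(marker_value: float = 1.0) -> FactorPattern:
    labels = [f"V{j}" for j in range(1, 10)]
    return pattern_from_dict({"W_f1": labels}, labels, marker_value)


def benchmark_between_pattern(marker_value: float = 1.0) -> FactorPattern:
    labels = [f"V{j}" for j in range(1, 10)]
    return pattern_from_dict(
        {
            "B_f1": labels[0:3],
            "B_f2": labels[3:6],
            "B_f3": labels[6:9],
        },
        labels,
        marker_value,
    )


def true_parameter_values(
    pop: TwoLevelPopulation, model: ModelDefinition
) -> dict[str, float]:
    """Map fitted-parameter labels to population values where defined.

    Covers pattern levels whose factor layout matches the population level
    (free loadings, Psi elements, residual variances) and saturated between
    blocks (population Sigma_B elements). Labels with no population
    counterpart are omitted.
    """
    Sigma_W, Sigma_B, _ = population_moments(pop)
    out: dict[str, float] = {}

    def pattern_truth(pattern: FactorPattern, params: LevelParams, prefix: str):
        if pattern.m != params.Lambda.shape[1]:
            return
        for j, row in enumerate(pattern.loadings):
            for r, entry in enumerate(row):
                if entry == "free":
                    out[
                        f"{prefix}.lambda[{pattern.indicators[j]}~{pattern.factors[r]}]"
                    ] = float(params.Lambda[j, r])
        for r in range(pattern.m):
            out[f"{prefix}.psi[{pattern.factors[r]},{pattern.factors[r]}]"] = float(
                params.Psi[r, r]
            )
            if pattern.correlated:
                for s in range(r + 1, pattern.m):
                    out[
                        f"{prefix}.psi[{pattern.factors[r]},{pattern.factors[s]}]"
                    ] = float(params.Psi[r, s])
        for j, ind in enumerate(pattern.indicators):
            out[f"{prefix}.theta[{ind}]"] = float(params.Theta[j, j])

    if isinstance(model.within, FactorPattern):
        pattern_truth(model.within, pop.within, "within")
    if isinstance(model.between, FactorPattern):
        pattern_truth(model.between, pop.between, "between")
    elif model.between == SATURATED_LEVEL:
        labels = pop.within.indicators
        for i in range(pop.p):
            for j in range(i, pop.p):
                out[f"between.sigma[{labels[i]},{labels[j]}]"] = float(Sigma_B[i, j])
    return out


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    """Aggregated Monte-Carlo parameter-recovery summary."""

    summary: pd.DataFrame
    chi2: dict
    n_reps: int
    n_converged: int
    n_failed: int
    per_rep_estimates: pd.DataFrame = field(repr=False, default=None)


def recovery_experiment(
    pop: TwoLevelPopulation,
    model: ModelDefinition,
    reps: int,
    seed: int = 0,
    compute_se: bool = True,
) -> RecoveryResult:
    """Fit ``model`` to ``reps`` independent datasets drawn from ``pop``.

    Aggregates per-parameter mean estimate, empirical SE (SD across
    replications), mean reported SE, population value and bias, plus the
    mean model chi-square (within-specific for the maximum model, overall
    otherwise). Nonconvergent replications are excluded and counted.
    """
    if reps < 2:
        raise ConfigurationError("need at least 2 replications")
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    est_rows, se_rows, chi2_vals = [], [], []
    n_failed = 0
    scope = (
        "within_specific" if model.kind is ModelKind.MAX_MCFA else "overall"
    )
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        ds = generate(pop, rng=rng)
        decomp = compute_decomposition(ds)
        fit = minimize(model, decomp, compute_se=compute_se)
        if not fit.converged:
            n_failed += 1
            continue
        est_rows.append(fit.estimates)
        se_rows.append(fit.se)
        if model.kind in (ModelKind.MCFA, ModelKind.MAX_MCFA, ModelKind.PS_BETWEEN):
            stats_scope = scope
            fs = fit_statistics(fit, decomp, stats_scope)
            chi2_vals.append(fs.chi2)
        else:
            fs = fit_statistics(fit, decomp, "overall")
            chi2_vals.append(fs.chi2)

    if not est_rows:
        raise ValidationError("no replication converged")
    est = pd.DataFrame(est_rows).reset_index(drop=True)
    ses = pd.DataFrame(se_rows).reset_index(drop=True)
    truth = true_parameter_values(pop, model)
    summary = pd.DataFrame(
        {
            "mean_estimate": est.mean(),
            "empirical_se": est.std(ddof=1),
            "mean_reported_se": ses.mean(),
        }
    )
    summary["true_value"] = pd.Series(truth).reindex(summary.index)
    summary["bias"] = summary["mean_estimate"] - summary["true_value"]

    chi2_arr = np.asarray(chi2_vals)
    chi2_info = {
        "scope": scope,
        "mean": float(chi2_arr.mean()),
        "sd": float(chi2_arr.std(ddof=1)),
        "df": int(degrees_of_freedom(model, scope)),
        "n": len(chi2_arr),
    }
    return RecoveryResult(
        summary=summary,
        chi2=chi2_info,
        n_reps=reps,
        n_converged=len(est_rows),
        n_failed=n_failed,
        per_rep_estimates=est,
    )
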