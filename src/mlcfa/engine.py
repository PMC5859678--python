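"""Discrepancy functions and numerical estimation for one- and two-level CFA.

One-level models minimise the Wishart maximum-likelihood discrepancy

    F_ML(S, Sigma) = ln|Sigma| + tr(Sigma^{-1} S) - ln|S| - p

weighted by N - 1, so the minimised value is the likelihood-ratio chi-square.

Two-level models use Muthén's limited-information (MUML) discrepancy, a
weighted two-group ML function over the scaled between matrix S_B (with
G "cases") and the pooled within matrix S_PW (with N - G "cases"):

    F_MUML = G * F_ML(S_B, Sigma_W + c Sigma_B)
           + (N - G) * F_ML(S_PW, Sigma_W)

which is exact ML for balanced designs and a quasi-likelihood otherwise.
The minimised F_MUML is itself the model chi-square.

Free parameters are optimised without bounds (quasi-Newton with analytic
gradients, then a Newton-CG polish); admissibility — positive-definite
factor covariances, nonnegative residual variances — is diagnosed after
the fit, so Heywood cases surface as warnings rather than being clamped.
Standard errors come from the numerical Hessian H of the count-weighted
discrepancy at the optimum: SE = sqrt(diag(2 H^{-1})).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .decompose import CovDecomposition
from .exceptions import ConfigurationError, NotPositiveDefiniteError
from .modelspec import (
    FREE,
    INDEPENDENCE_LEVEL,
    SATURATED_LEVEL,
    TWO_LEVEL_KINDS,
    FactorPattern,
    ModelDefinition,
)

_PENALTY = 1e10


# ---------------------------------------------------------------------------
# discrepancy functions
# ---------------------------------------------------------------------------

def _check_pd(S: np.ndarray, name: str) -> None:
    ev = np.linalg.eigvalsh(S)
    if ev[0] <= 0:
        raise NotPositiveDefiniteError(
            f"{name} is not positive definite (smallest eigenvalue {ev[0]:.4g})",
            min_eigenvalue=float(ev[0]),
        )


def f_ml(S: np.ndarray, Sigma: np.ndarray, p: int | None = None) -> float:
    """ML discrepancy ln|Sigma| + tr(Sigma^{-1} S) - ln|S| - p (>= 0)."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if p is None:
        p = S.shape[0]
    _check_pd(S, "sample matrix S")
    _check_pd(Sigma, "implied matrix Sigma")
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    return float(logdet_m + np.trace(np.linalg.solve(Sigma, S)) - logdet_s - p)


def f_muml(
    decomp: CovDecomposition, Sigma_W: np.ndarray, Sigma_B: np.ndarray
) -> float:
    """MUML discrepancy for a two-level model on a covariance decomposition."""
    p = decomp.p
    G = decomp.n_clusters
    N = decomp.n_obs
    try:
        between = f_ml(decomp.S_B, Sigma_W + decomp.c * Sigma_B, p)
    except NotPositiveDefiniteError as err:
        raise NotPositiveDefiniteError(
            f"between bracket failed: {err}", err.min_eigenvalue
        ) from err
    try:
        within = f_ml(decomp.S_PW, Sigma_W, p)
    except NotPositiveDefiniteError as err:
        raise NotPositiveDefiniteError(
            f"within bracket failed: {err}", err.min_eigenvalue
        ) from err
    return G * between + (N - G) * within


# ---------------------------------------------------------------------------
# level parameterisations
# ---------------------------------------------------------------------------

@dataclass
class LevelParams:
    """Structured parameters of one level: Sigma = Lambda Psi Lambda' + Theta."""

    Lambda: np.ndarray
    Psi: np.ndarray
    Theta: np.ndarray  # p x p, diagonal for pattern levels
    factors: tuple[str, ...]
    indicators: tuple[str, ...]

    def implied(self) -> np.ndarray:
        return implied_covariance(self)

    @property
    def heywood(self) -> np.ndarray:
        return np.diag(self.Theta) < 0


def implied_covariance(params: LevelParams) -> np.ndarray:
    """Factor-analytic implied covariance Sigma = Lambda Psi Lambda' + Theta."""
    L, P = params.Lambda, params.Psi
    return L @ P @ L.T + params.Theta


class _PatternLevel:
    """Free-parameter bookkeeping for a FactorPattern level."""

    def __init__(self, pattern: FactorPattern, prefix: str):
        self.pattern = pattern
        self.prefix = prefix
        p, m = pattern.p, pattern.m
        self.p, self.m = p, m
        self.fixed_lambda = np.zeros((p, m))
        self.free_lambda_idx: list[tuple[int, int]] = []
        for j, row in enumerate(pattern.loadings):
            for r, entry in enumerate(row):
                if entry == FREE:
                    self.free_lambda_idx.append((j, r))
                elif entry != "zero":
                    self.fixed_lambda[j, r] = float(entry)
        self.psi_idx = [(r, r) for r in range(m)]
        if pattern.correlated:
            self.psi_idx += [(r, s) for r in range(m) for s in range(r + 1, m)]
        self.n_params = len(self.free_lambda_idx) + len(self.psi_idx) + p

    def labels(self) -> list[str]:
        pat = self.pattern
        out = [
            f"{self.prefix}.lambda[{pat.indicators[j]}~{pat.factors[r]}]"
            for j, r in self.free_lambda_idx
        ]
        out += [
            f"{self.prefix}.psi[{pat.factors[r]},{pat.factors[s]}]"
            for r, s in self.psi_idx
        ]
        out += [f"{self.prefix}.theta[{ind}]" for ind in pat.indicators]
        return out

    def start(self, S_level: np.ndarray) -> np.ndarray:
        pat = self.pattern
        svar = np.clip(np.diag(S_level), 1e-4, None)
        x = [0.7] * len(self.free_lambda_idx)
        for r, s in self.psi_idx:
            if r == s:
                # half the marker indicator's sample variance, on the
                # factor scale implied by the fixed marker loading
                marker_j, marker_v = self._marker(r)
                x.append(0.5 * svar[marker_j] / marker_v**2)
            else:
                x.append(0.0)
        x += list(0.5 * svar)
        return np.asarray(x, dtype=float)

    def _marker(self, r: int) -> tuple[int, float]:
        for j, row in enumerate(self.pattern.loadings):
            entry = row[r]
            if entry not in (FREE, "zero"):
                return j, float(entry)
        return 0, 1.0  # unreachable for validated patterns

    def unpack(self, x: np.ndarray) -> LevelParams:
        L = self.fixed_lambda.copy()
        k = 0
        for j, r in self.free_lambda_idx:
            L[j, r] = x[k]
            k += 1
        Psi = np.zeros((self.m, self.m))
        for r, s in self.psi_idx:
            Psi[r, s] = Psi[s, r] = x[k]
            k += 1
        Theta = np.diag(x[k : k + self.p])
        return LevelParams(
            L, Psi, Theta, self.pattern.factors, self.pattern.indicators
        )

    def implied(self, x: np.ndarray) -> np.ndarray:
        return implied_covariance(self.unpack(x))

    def dimplied(self, x: np.ndarray) -> list[np.ndarray]:
        """Derivative matrices dSigma/dtheta_k at the point x."""
        params = self.unpack(x)
        L, Psi = params.Lambda, params.Psi
        LP = L @ Psi
        p = self.p
        out = []
        for j, r in self.free_lambda_idx:
            d = np.zeros((p, p))
            d[j, :] += LP[:, r]
            d[:, j] += LP[:, r]
            out.append(d)
        for r, s in self.psi_idx:
            lr, ls = L[:, r], L[:, s]
            if r == s:
                out.append(np.outer(lr, lr))
            else:
                out.append(np.outer(lr, ls) + np.outer(ls, lr))
        for j in range(p):
            d = np.zeros((p, p))
            d[j, j] = 1.0
            out.append(d)
        return out


class _SaturatedLevel:
    """Direct symmetric parameterisation of a level covariance matrix."""

    def __init__(self, indicators: tuple[str, ...], prefix: str):
        self.indicators = indicators
        self.prefix = prefix
        self.p = len(indicators)
        self.idx = [(i, j) for i in range(self.p) for j in range(i, self.p)]
        self.n_params = len(self.idx)

    def labels(self) -> list[str]:
        return [
            f"{self.prefix}.sigma[{self.indicators[i]},{self.indicators[j]}]"
            for i, j in self.idx
        ]

    def start(self, S_level: np.ndarray) -> np.ndarray:
        S = S_level.copy()
        # ensure a PD starting matrix
        ev = np.linalg.eigvalsh(S)
        if ev[0] <= 1e-8:
            S = S + (1e-6 + abs(ev[0])) * np.eye(self.p)
        return np.array([S[i, j] for i, j in self.idx])

    def unpack(self, x: np.ndarray) -> LevelParams:
        S = np.zeros((self.p, self.p))
        for k, (i, j) in enumerate(self.idx):
            S[i, j] = S[j, i] = x[k]
        return LevelParams(
            np.zeros((self.p, 0)), np.zeros((0, 0)), S, (), self.indicators
        )

    def implied(self, x: np.ndarray) -> np.ndarray:
        return self.unpack(x).Theta

    def dimplied(self, x: np.ndarray) -> list[np.ndarray]:
        out = []
        for i, j in self.idx:
            d = np.zeros((self.p, self.p))
            d[i, j] = d[j, i] = 1.0
            out.append(d)
        return out


class _IndependenceLevel:
    """Diagonal covariance (zero loadings, free residual variances)."""

    def __init__(self, indicators: tuple[str, ...], prefix: str):
        self.indicators = indicators
        self.prefix = prefix
        self.p = len(indicators)
        self.n_params = self.p

    def labels(self) -> list[str]:
        return [f"{self.prefix}.theta[{ind}]" for ind in self.indicators]

    def start(self, S_level: np.ndarray) -> np.ndarray:
        return np.clip(np.diag(S_level).copy(), 1e-4, None)

    def unpack(self, x: np.ndarray) -> LevelParams:
        return LevelParams(
            np.zeros((self.p, 0)), np.zeros((0, 0)), np.diag(x), (), self.indicators
        )

    def implied(self, x: np.ndarray) -> np.ndarray:
        return np.diag(x)

    def dimplied(self, x: np.ndarray) -> list[np.ndarray]:
        out = []
        for j in range(self.p):
            d = np.zeros((self.p, self.p))
            d[j, j] = 1.0
            out.append(d)
        return out


def _make_level(struct, indicators: tuple[str, ...], prefix: str):
    if isinstance(struct, FactorPattern):
        return _PatternLevel(struct, prefix)
    if struct == SATURATED_LEVEL:
        return _SaturatedLevel(indicators, prefix)
    if struct == INDEPENDENCE_LEVEL:
        return _IndependenceLevel(indicators, prefix)
    raise ConfigurationError(f"cannot parameterise level structure {struct!r}")


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Raw optimisation outcome for one model on one dataset."""

    model: ModelDefinition
    estimates: pd.Series
    se: pd.Series
    f_min: float
    converged: bool
    n_iter: int
    gradient_norm: float
    n_obs: int
    n_clusters: int | None
    c: float | None
    implied_within: np.ndarray | None
    implied_between: np.ndarray | None
    implied_total: np.ndarray | None
    within_params: LevelParams | None
    between_params: LevelParams | None
    messages: list[str] = field(default_factory=list)
    se_condition_number: float | None = None

    @property
    def is_two_level(self) -> bool:
        return self.model.kind in TWO_LEVEL_KINDS

    @property
    def n_free(self) -> int:
        return len(self.estimates)


# ---------------------------------------------------------------------------
# objective assembly and minimisation
# ---------------------------------------------------------------------------

def _safe_fml_terms(S, Sigma):
    """Return (value, A) where A = Sigma^-1 - Sigma^-1 S Sigma^-1, or None."""
    try:
        cho = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return None, None
    logdet_m = 2.0 * np.log(np.diag(cho)).sum()
    Sigma_inv = np.linalg.inv(Sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    val = logdet_m + (Sigma_inv * S).sum() - logdet_s - S.shape[0]
    A = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    return val, A


class _Objective:
    """Count-weighted total discrepancy with analytic gradient."""

    def __init__(self, model: ModelDefinition, data, weight_convention="N-1"):
        self.model = model
        self.two_level = model.kind in TWO_LEVEL_KINDS
        if self.two_level:
            if not isinstance(data, CovDecomposition):
                raise ConfigurationError(
                    "two-level models require a CovDecomposition"
                )
            self.decomp = data
            _check_pd(data.S_PW, "pooled within matrix S_PW")
            _check_pd(data.S_B, "scaled between matrix S_B")
            self.within = _make_level(model.within, model.indicators, "within")
            self.between = _make_level(model.between, model.indicators, "between")
            self.n_params = self.within.n_params + self.between.n_params
        else:
            if isinstance(data, CovDecomposition):
                S, N = data.S_T, data.n_obs
            else:
                S, N = data
            _check_pd(np.asarray(S, float), "sample matrix")
            self.S = np.asarray(S, dtype=float)
            self.N = int(N)
            self.weight = self.N - 1 if weight_convention == "N-1" else self.N
            self.within = _make_level(model.within, model.indicators, "within")
            self.n_params = self.within.n_params

    def labels(self) -> list[str]:
        if self.two_level:
            return self.within.labels() + self.between.labels()
        return self.within.labels()

    def start(self) -> np.ndarray:
        if self.two_level:
            d = self.decomp
            sigma_b0 = d.sigma_b_moment()
            # floor the between diagonal so pattern starts stay sensible
            sigma_b0 = sigma_b0.copy()
            np.fill_diagonal(
                sigma_b0, np.maximum(np.diag(sigma_b0), 0.05)
            )
            return np.concatenate(
                [self.within.start(d.S_PW), self.between.start(sigma_b0)]
            )
        return self.within.start(self.S)

    def value_grad(self, x: np.ndarray):
        if not self.two_level:
            Sigma = self.within.implied(x)
            val, A = _safe_fml_terms(self.S, Sigma)
            if val is None:
                return _PENALTY, np.zeros_like(x)
            grad = np.array(
                [(A * d).sum() for d in self.within.dimplied(x)]
            )
            return self.weight * val, self.weight * grad

        d = self.decomp
        nw = self.within.n_params
        xw, xb = x[:nw], x[nw:]
        Sigma_W = self.within.implied(xw)
        Sigma_B = self.between.implied(xb)
        G, N, c = d.n_clusters, d.n_obs, d.c

        val_b, A_b = _safe_fml_terms(d.S_B, Sigma_W + c * Sigma_B)
        val_w, A_w = _safe_fml_terms(d.S_PW, Sigma_W)
        if val_b is None or val_w is None:
            return _PENALTY, np.zeros_like(x)

        f = G * val_b + (N - G) * val_w
        gw = np.array(
            [
                G * (A_b * dm).sum() + (N - G) * (A_w * dm).sum()
                for dm in self.within.dimplied(xw)
            ]
        )
        gb = np.array([G * c * (A_b * dm).sum() for dm in self.between.dimplied(xb)])
        return f, np.concatenate([gw, gb])


def minimize(
    model: ModelDefinition,
    data,
    weight_convention: str = "N-1",
    compute_se: bool = True,
    gtol: float = 1e-6,
) -> FitResult:
    """Fit a model by quasi-Newton minimisation of its discrepancy function.

    ``data`` is a :class:`CovDecomposition` (always valid; one-level kinds
    use its S_T and N) or, for one-level kinds, a ``(S, N)`` pair.

    The optimiser runs BFGS with analytic gradients followed by a
    Newton-CG polish. Convergence requires the gradient infinity-norm to
    drop below ``gtol`` (scaled by max(1, F)). Heywood cases (negative
    residual-variance estimates) are flagged in ``messages``.
    """
    obj = _Objective(model, data, weight_convention)
    x0 = obj.start()
    messages: list[str] = []

    res = optimize.minimize(
        obj.value_grad, x0, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": 2000},
    )
    n_iter = res.nit
    x = res.x
    f_val, grad = obj.value_grad(x)

    # Newton polish with the exact (numerically differenced) Hessian
    x, f_val, grad, hess, newton_steps, resolved = _newton_polish(
        obj, x, f_val, grad, gtol
    )
    n_iter += newton_steps
    gnorm = float(np.abs(grad).max()) if grad.size else 0.0

    converged = bool(
        resolved or gnorm <= max(gtol * max(1.0, abs(f_val)), gtol)
    )
    if not converged:
        messages.append(
            f"optimizer did not reach gradient tolerance (|g|_inf = {gnorm:.3g})"
        )

    labels = obj.labels()
    estimates = pd.Series(x, index=labels, name="estimate")

    se = pd.Series(np.nan, index=labels, name="se")
    cond = None
    if compute_se and converged and len(labels):
        hess = _num_hessian(obj, x)  # at the final iterate
        se_vals, cond, se_msg = _se_from_hessian(hess)
        se = pd.Series(se_vals, index=labels, name="se")
        if se_msg:
            messages.append(se_msg)

    if obj.two_level:
        nw = obj.within.n_params
        wp = obj.within.unpack(x[:nw])
        bp = obj.between.unpack(x[nw:])
        implied_w = obj.within.implied(x[:nw])
        implied_b = obj.between.implied(x[nw:])
        implied_t = None
        n_obs, n_clusters, c = obj.decomp.n_obs, obj.decomp.n_clusters, obj.decomp.c
    else:
        wp = obj.within.unpack(x)
        bp = None
        implied_w = None
        implied_b = None
        implied_t = obj.within.implied(x)
        n_obs, n_clusters, c = obj.N, None, None

    for params, lvl in ((wp, "within"), (bp, "between")):
        if params is not None and params.Lambda.shape[1] and params.heywood.any():
            bad = [
                params.indicators[j] for j in np.where(params.heywood)[0]
            ]
            messages.append(f"Heywood case: negative residual variance ({lvl}: {bad})")

    for lvl, mat in (("within", implied_w), ("between", implied_b), ("total", implied_t)):
        if mat is not None and mat.shape[0]:
            ev = np.linalg.eigvalsh(mat)
            if ev[0] < -1e-10:
                messages.append(
                    f"implied {lvl} covariance not positive semidefinite "
                    f"(min eigenvalue {ev[0]:.3g})"
                )

    return FitResult(
        model=model,
        estimates=estimates,
        se=se,
        f_min=float(max(f_val, 0.0)),
        converged=converged,
        n_iter=int(n_iter),
        gradient_norm=gnorm,
        n_obs=n_obs,
        n_clusters=n_clusters,
        c=c,
        implied_within=implied_w,
        implied_between=implied_b,
        implied_total=implied_t,
        within_params=wp,
        between_params=bp,
        messages=messages,
        se_condition_number=cond,
    )


def _num_hessian(obj: _Objective, x: np.ndarray) -> np.ndarray:
    """Numerical Hessian of the count-weighted discrepancy.

    Central differences of the analytic gradient, step 1e-5 * max(1, |x_i|).
    """
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        h = 1e-5 * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = obj.value_grad(xp)
        _, gm = obj.value_grad(xm)
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _newton_polish(obj, x, f_val, grad, gtol, max_steps: int = 10):
    """Full Newton steps with backtracking.

    Returns ``(x, f, grad, hessian, steps, resolved)``. ``resolved`` is set
    when the Newton-predicted remaining decrease 0.5 g' H^{-1} g falls
    below the numerical resolution of F — the point is an optimum to
    machine precision even if the raw gradient norm (whose floor scales
    like sqrt(eps * F * curvature) for count-weighted discrepancies)
    cannot reach an absolute tolerance.
    """
    hess = None
    steps = 0
    resolved = not grad.size
    for _ in range(max_steps):
        gnorm = float(np.abs(grad).max()) if grad.size else 0.0
        if not grad.size or gnorm <= 0.1 * gtol * max(1.0, abs(f_val)):
            resolved = True
            break
        hess = _num_hessian(obj, x)
        ev_min = np.linalg.eigvalsh(hess)[0]
        H = hess if ev_min > 1e-12 else hess + (abs(ev_min) + 1e-8) * np.eye(x.size)
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        predicted_decrease = -0.5 * float(grad @ step)
        if 0 <= predicted_decrease < 1e-12 * max(1.0, abs(f_val)):
            resolved = True
            break
        alpha = 1.0
        improved = False
        for _ in range(30):
            f_new, g_new = obj.value_grad(x + alpha * step)
            if f_new <= f_val + 1e-12 * max(1.0, abs(f_val)):
                x = x + alpha * step
                f_val, grad = f_new, g_new
                improved = True
                break
            alpha *= 0.5
        steps += 1
        if not improved:
            break
    return x, f_val, grad, hess, steps, resolved


def _se_from_hessian(H: np.ndarray):
    k = H.shape[0]
    ev = np.linalg.eigvalsh(H)
    cond = float(ev[-1] / ev[0]) if ev[0] != 0 else np.inf
    if ev[0] <= 0 or not np.isfinite(cond) or cond > 1e14:
        return (
            np.full(k, np.nan),
            cond,
            f"standard errors unavailable: Hessian not positive definite "
            f"(condition number {cond:.3g})",
        )
    cov = 2.0 * np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return se, cond, None


def standard_errors(fit: FitResult, data, weight_convention: str = "N-1") -> pd.Series:
    """Recompute standard errors for a converged fit (see :func:`minimize`)."""
    obj = _Objective(fit.model, data, weight_convention)
    H = _num_hessian(obj, fit.estimates.to_numpy())
    se_vals, cond, msg = _se_from_hessian(H)
    if msg:
        warnings.warn(msg, stacklevel=2)
    return pd.Series(se_vals, index=fit.estimates.index, name="se")
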