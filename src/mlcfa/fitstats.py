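"""Model fit statistics: chi-square, CFI, RMSEA, SRMR, level-specific fit, R².

Fit can be judged at three scopes. ``overall`` uses the model's full
discrepancy. ``within_specific`` statistics come from the maximum model
(hypothesised within structure, saturated between level): the saturated
block reproduces S_B exactly, so the remaining chi-square is attributable
to the within-level structure alone. ``between_specific`` statistics come
from the partially saturated model the other way round (saturated within,
hypothesised between).

Conventions (documented because the indices leave room for choice):

* The CFI baseline at each scope is the independence structure for the
  scoped level (zero loadings, free diagonal), with the other level
  saturated for two-level scopes.
* RMSEA uses the total sample size N at every scope:
  sqrt(max(chi2 - df, 0) / (df (N - 1))).
* SRMR standardises residuals by the sample matrix of the relevant block:
  S_T for the overall one-level scope, S_PW (vs Sigma_W) for the within
  scope and S_B (vs Sigma_W + c Sigma_B) for the between scope; the
  overall two-level scope pools both blocks' standardised residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import CovDecomposition
from .engine import FitResult, LevelParams, f_ml, minimize
from .exceptions import ConfigurationError, ValidationError
from .modelspec import (
    INDEPENDENCE_LEVEL,
    SATURATED_LEVEL,
    FactorPattern,
    ModelDefinition,
    ModelKind,
    build_model,
    degrees_of_freedom,
)


@dataclass(frozen=True)
class FitStatistics:
    """Chi-square and fit indices for one model at one scope."""

    scope: str
    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    srmr: float
    n_obs: int
    baseline_chi2: float
    baseline_df: int

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
        }


def chi_square(fit: FitResult, df: int | None = None):
    """Likelihood-ratio chi-square, df and p-value of a fitted model.

    ``fit.f_min`` is already count-weighted (by N-1 for one-level models
    and by the G / N-G MUML weights for two-level models), so the
    chi-square equals the minimised discrepancy.
    """
    if df is None:
        df = degrees_of_freedom(fit.model, "overall")
    chi2 = float(fit.f_min)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    return chi2, df, p


def cfi(chi2: float, df: float, chi2_baseline: float, df_baseline: float) -> float:
    """Comparative fit index against an independence baseline, clamped to [0, 1]."""
    excess = max(chi2 - df, 0.0)
    base_excess = max(chi2_baseline - df_baseline, 0.0)
    denom = max(base_excess, excess)
    if denom == 0.0:
        if excess > 0:  # pragma: no cover - excess>0 implies denom>0
            warnings.warn("CFI baseline no worse than target model", stacklevel=2)
        return 1.0
    return float(np.clip(1.0 - excess / denom, 0.0, 1.0))


def rmsea(chi2: float, df: float, n_obs: int) -> float:
    """Root mean square error of approximation; NaN when df = 0."""
    if df <= 0:
        return np.nan
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n_obs - 1))))


def srmr(S: np.ndarray, Sigma_hat: np.ndarray) -> float:
    """Standardised root mean square residual over unique elements."""
    S = np.asarray(S, float)
    Sigma_hat = np.asarray(Sigma_hat, float)
    if S.shape != Sigma_hat.shape:
        raise ConfigurationError("S and Sigma_hat dimensions differ")
    d = np.diag(S)
    if (d <= 0).any():
        raise ValidationError("sample matrix has a nonpositive diagonal entry")
    return float(np.sqrt(np.mean(_std_residuals(S, Sigma_hat) ** 2)))


def _std_residuals(S: np.ndarray, Sigma_hat: np.ndarray) -> np.ndarray:
    d = np.diag(S)
    scale = np.sqrt(np.outer(d, d))
    resid = (S - Sigma_hat) / scale
    iu = np.triu_indices(S.shape[0])
    return resid[iu]


def r_squared(params: LevelParams) -> pd.Series:
    """Per-indicator explained variance (Lambda Psi Lambda')_jj over total."""
    common = np.diag(params.Lambda @ params.Psi @ params.Lambda.T)
    total = common + np.diag(params.Theta)
    out = np.where(total > 0, common / np.where(total > 0, total, 1.0), np.nan)
    if (total <= 0).any():
        warnings.warn("zero total variance; R^2 undefined for some indicators",
                      stacklevel=2)
    return pd.Series(out, index=list(params.indicators), name="r_squared")


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def _baseline(decomp_or_sn, scope: str, indicators, weight_convention="N-1"):
    """Independence-baseline chi-square and df for a scope.

    The one-level and within-specific baselines have closed-form optima
    (free variances equal the sample variances; for the within scope the
    saturated between block absorbs S_B exactly). The between-specific and
    overall two-level baselines are optimised numerically.
    """
    p = len(indicators)
    pp = p * (p + 1) // 2
    if scope == "overall_onelevel":
        S, N = decomp_or_sn
        weight = N - 1 if weight_convention == "N-1" else N
        return weight * f_ml(S, np.diag(np.diag(S))), pp - p
    d: CovDecomposition = decomp_or_sn
    if scope == "within_specific":
        chi2_b = (d.n_obs - d.n_clusters) * f_ml(d.S_PW, np.diag(np.diag(d.S_PW)))
        return chi2_b, pp - p
    if scope == "between_specific":
        model = ModelDefinition(
            ModelKind.PS_BETWEEN, tuple(indicators),
            within=SATURATED_LEVEL, between=INDEPENDENCE_LEVEL,
        )
        fit = minimize(model, d, compute_se=False)
        return fit.f_min, pp - p
    if scope == "overall_twolevel":
        model = ModelDefinition(
            ModelKind.MCFA, tuple(indicators),
            within=INDEPENDENCE_LEVEL, between=INDEPENDENCE_LEVEL,
        )
        fit = minimize(model, d, compute_se=False)
        return fit.f_min, 2 * pp - 2 * p
    raise ConfigurationError(f"unknown baseline scope {scope!r}")


# ---------------------------------------------------------------------------
# statistics for a fitted model
# ---------------------------------------------------------------------------

def fit_statistics(
    fit: FitResult,
    data,
    scope: str = "overall",
    weight_convention: str = "N-1",
) -> FitStatistics:
    """Assemble chi-square and fit indices for a fitted model at a scope.

    For a one-level fit only ``overall`` is valid. For two-level fits,
    ``within_specific`` requires a hypothesised within pattern with a
    saturated between level (the maximum model) and ``between_specific``
    a hypothesised between pattern with a saturated within level; use
    :func:`level_specific_fit` to build and fit those directly.
    """
    model = fit.model
    two_level = fit.is_two_level

    if not two_level:
        if scope != "overall":
            raise ConfigurationError("one-level fits only have overall scope")
        if isinstance(data, CovDecomposition):
            S, N = data.S_T, data.n_obs
        else:
            S, N = data
        df = degrees_of_freedom(model, "overall")
        chi2_val, _, p_val = chi_square(fit, df)
        chi2_b, df_b = _baseline((S, N), "overall_onelevel", model.indicators,
                                 weight_convention)
        srmr_val = srmr(S, fit.implied_total)
        return FitStatistics(
            "overall", chi2_val, df, p_val,
            cfi(chi2_val, df, chi2_b, df_b),
            rmsea(chi2_val, df, N), srmr_val, N, chi2_b, df_b,
        )

    d: CovDecomposition = data
    N = d.n_obs
    if scope == "within_specific":
        if not isinstance(model.within, FactorPattern) or (
            model.between != SATURATED_LEVEL
        ):
            raise ConfigurationError(
                "within-specific statistics require the maximum model "
                "(hypothesised within, saturated between)"
            )
        df = degrees_of_freedom(model, "within_specific")
        chi2_b, df_b = _baseline(d, "within_specific", model.indicators)
        srmr_val = srmr(d.S_PW, fit.implied_within)
    elif scope == "between_specific":
        if not isinstance(model.between, FactorPattern) or (
            model.within != SATURATED_LEVEL
        ):
            raise ConfigurationError(
                "between-specific statistics require the partially saturated "
                "model (saturated within, hypothesised between)"
            )
        df = degrees_of_freedom(model, "between_specific")
        chi2_b, df_b = _baseline(d, "between_specific", model.indicators)
        srmr_val = srmr(d.S_B, fit.implied_within + d.c * fit.implied_between)
    elif scope == "overall":
        df = degrees_of_freedom(model, "overall")
        chi2_b, df_b = _baseline(d, "overall_twolevel", model.indicators)
        resid = np.concatenate([
            _std_residuals(d.S_PW, fit.implied_within),
            _std_residuals(d.S_B, fit.implied_within + d.c * fit.implied_between),
        ])
        srmr_val = float(np.sqrt(np.mean(resid**2)))
    else:
        raise ConfigurationError(f"unknown scope {scope!r}")

    chi2_val, _, p_val = chi_square(fit, df)
    return FitStatistics(
        scope, chi2_val, df, p_val,
        cfi(chi2_val, df, chi2_b, df_b),
        rmsea(chi2_val, df, N), srmr_val, N, chi2_b, df_b,
    )


def level_specific_fit(
    spec: FactorPattern,
    decomp: CovDecomposition,
    scope: str,
    compute_se: bool = False,
):
    """Fit the partially saturated model that isolates one level's misfit.

    ``scope='within_specific'`` fits the maximum model (``spec`` at the
    within level, saturated between); ``scope='between_specific'`` fits the
    saturated-within model with ``spec`` at the between level. Returns
    ``(FitResult, FitStatistics)``.
    """
    if scope == "within_specific":
        model = build_model(ModelKind.MAX_MCFA, within_spec=spec)
    elif scope == "between_specific":
        model = build_model(ModelKind.PS_BETWEEN, between_spec=spec)
    else:
        raise ConfigurationError(f"unknown scope {scope!r}")
    fit = minimize(model, decomp, compute_se=compute_se)
    return fit, fit_statistics(fit, decomp, scope)
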