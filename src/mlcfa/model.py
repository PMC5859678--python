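"""High-level modelling interface: Model objects built from data, whose
``fit()`` returns a Results object with estimates, standard errors,
fit statistics and a printable summary.

Example
-------
>>> from mlcfa import MultilevelFactorModel
>>> model = MultilevelFactorModel.from_dataframe(
...     df, cluster_col="school", case_col="pupil",
...     within={"f1": ["x1", "x2", "x3"]},
...     between={"b1": ["x1", "x2", "x3"]},
...     kind="MCFA",
... )
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fitstats
from .data import MultilevelDataset, from_dataframe, read_dataset
from .decompose import CovDecomposition, compute_decomposition, icc
from .engine import FitResult, minimize
from .exceptions import ConfigurationError
from .modelspec import (
    FactorPattern,
    ModelDefinition,
    ModelKind,
    build_model,
    degrees_of_freedom,
    pattern_from_dict,
)


def _as_pattern(spec, indicators, marker_value) -> FactorPattern | None:
    if spec is None or isinstance(spec, FactorPattern):
        return spec
    if isinstance(spec, dict):
        return pattern_from_dict(spec, indicators, marker_value)
    raise ConfigurationError(f"cannot interpret factor spec {spec!r}")


class MultilevelFactorModel:
    """One- or two-level confirmatory factor model for clustered data.

    Parameters
    ----------
    data : MultilevelDataset or CovDecomposition
        Clustered data (decomposed on construction) or a precomputed
        covariance decomposition.
    within, between : dict or FactorPattern, optional
        Factor specifications, e.g. ``{"f1": ["x1", "x2", "x3"]}``. The
        first indicator listed per factor is its marker (loading fixed at
        ``marker_value``).
    kind : str
        ``"CFA"``, ``"MCFA"``, ``"MAX_MCFA"`` or ``"PS_BETWEEN"``.
    marker_value : float
        Fixed value of each factor's marker loading (default 1.0).
    """

    def __init__(
        self,
        data: MultilevelDataset | CovDecomposition,
        within=None,
        between=None,
        kind: str | ModelKind = "MCFA",
        marker_value: float = 1.0,
    ):
        if isinstance(data, MultilevelDataset):
            self.dataset = data
            self.decomposition = compute_decomposition(data)
        elif isinstance(data, CovDecomposition):
            self.dataset = None
            self.decomposition = data
        else:
            raise ConfigurationError(
                "data must be a MultilevelDataset or CovDecomposition"
            )
        indicators = self.decomposition.labels
        kind = ModelKind(kind)
        within = _as_pattern(within, indicators, marker_value)
        between = _as_pattern(between, indicators, marker_value)
        self.definition: ModelDefinition = build_model(kind, within, between)
        if self.definition.indicators != tuple(indicators):
            # allow spec over a subset/ordering only when it matches the data
            raise ConfigurationError(
                "model indicators must match data indicators in order: "
                f"model={list(self.definition.indicators)} "
                f"data={list(indicators)}"
            )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cluster_col: str,
        case_col: str | None = None,
        missing_code: float = -999999.0,
        indicators: list[str] | None = None,
        **model_kw,
    ) -> "MultilevelFactorModel":
        ds = from_dataframe(df, cluster_col, case_col, missing_code, indicators)
        return cls(ds, **model_kw)

    @classmethod
    def from_file(
        cls,
        path,
        cluster_col: str,
        case_col: str | None = None,
        missing_code: float = -999999.0,
        indicators: list[str] | None = None,
        **model_kw,
    ) -> "MultilevelFactorModel":
        ds = read_dataset(path, cluster_col, case_col, missing_code, indicators)
        return cls(ds, **model_kw)

    # -- introspection ----------------------------------------------------
    @property
    def kind(self) -> ModelKind:
        return self.definition.kind

    def degrees_of_freedom(self, scope: str = "overall") -> int:
        return degrees_of_freedom(self.definition, scope)

    def icc(self) -> pd.DataFrame:
        return icc(self.decomposition)

    # -- estimation -------------------------------------------------------
    def fit(self, compute_se: bool = True, **kw) -> "MCFAResults":
        raw = minimize(self.definition, self.decomposition,
                       compute_se=compute_se, **kw)
        return MCFAResults(self, raw)


class MCFAResults:
    """Estimates, uncertainties and fit diagnostics of a fitted model."""

    def __init__(self, model: MultilevelFactorModel, raw: FitResult):
        self.model = model
        self._raw = raw
        self._stats_cache: dict[str, fitstats.FitStatistics] = {}

    # -- basic accessors --------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._raw.estimates

    @property
    def bse(self) -> pd.Series:
        return self._raw.se

    @property
    def tvalues(self) -> pd.Series:
        return self._raw.estimates / self._raw.se

    @property
    def converged(self) -> bool:
        return self._raw.converged

    @property
    def fit_min(self) -> float:
        return self._raw.f_min

    @property
    def raw(self) -> FitResult:
        return self._raw

    @property
    def default_scope(self) -> str:
        kind = self.model.kind
        if kind is ModelKind.MAX_MCFA:
            return "within_specific"
        if kind in (ModelKind.MCFA, ModelKind.PS_BETWEEN):
            # the conventional tabulation reports the between-level-specific
            # statistics for the hypothesised between structure; the overall
            # two-level statistics remain available via scope="overall"
            return "between_specific"
        return "overall"

    def fit_statistics(self, scope: str | None = None) -> fitstats.FitStatistics:
        """Fit statistics at a scope.

        For an MCFA, level-specific scopes are obtained from the matching
        partially saturated model (saturated at the other level) fitted to
        the same decomposition, so the chi-square isolates that level's
        misfit; the result is cached.
        """
        scope = scope or self.default_scope
        if scope in self._stats_cache:
            return self._stats_cache[scope]
        defn = self.model.definition
        direct = (
            scope == "overall"
            or (scope == "within_specific" and defn.kind is ModelKind.MAX_MCFA)
            or (scope == "between_specific" and defn.kind is ModelKind.PS_BETWEEN)
        )
        if direct:
            fs = fitstats.fit_statistics(self._raw, self.model.decomposition, scope)
        else:
            pattern = (
                defn.within if scope == "within_specific" else defn.between
            )
            if not isinstance(pattern, FactorPattern):
                raise ConfigurationError(
                    f"no hypothesised pattern for scope {scope!r}"
                )
            _, fs = fitstats.level_specific_fit(
                pattern, self.model.decomposition, scope
            )
        self._stats_cache[scope] = fs
        return fs

    def r_squared(self, level: str = "within") -> pd.Series:
        params = (
            self._raw.within_params if level == "within" else self._raw.between_params
        )
        if params is None or params.Lambda.shape[1] == 0:
            raise ConfigurationError(f"no factor structure at the {level} level")
        return fitstats.r_squared(params)

    # -- reporting --------------------------------------------------------
    def parameter_table(self) -> pd.DataFrame:
        table = pd.DataFrame({"estimate": self.params, "se": self.bse})
        table["t"] = table["estimate"] / table["se"]
        return table

    def summary(self, scope: str | None = None, digits: int = 3) -> str:
        d = self.model.decomposition
        lines = [
            f"{self.model.kind.value} fit "
            f"(N = {d.n_obs}, G = {d.n_clusters}, c = {d.c:.4g})",
            "=" * 60,
        ]
        scopes = [scope] if scope else self._available_scopes()
        for sc in scopes:
            try:
                fs = self.fit_statistics(sc)
            except ConfigurationError:
                continue
            rm = "" if np.isnan(fs.rmsea) else f"{fs.rmsea:.{digits}f}"
            lines.append(
                f"[{fs.scope}] chi2({fs.df}) = {fs.chi2:.{digits}f}, "
                f"CFI = {fs.cfi:.{digits}f}, RMSEA = {rm}, "
                f"SRMR = {fs.srmr:.{digits}f}"
            )
        lines.append("-" * 60)
        lines.append(self.parameter_table().round(digits).to_string(na_rep=""))
        if self._raw.messages:
            lines.append("-" * 60)
            lines.extend(f"note: {m}" for m in self._raw.messages)
        if not self.converged:
            lines.append("WARNING: optimizer did not converge")
        return "\n".join(lines) + "\n"

    def _available_scopes(self) -> list[str]:
        kind = self.model.kind
        if kind is ModelKind.MAX_MCFA:
            return ["within_specific"]
        if kind is ModelKind.PS_BETWEEN:
            return ["between_specific"]
        if kind is ModelKind.MCFA:
            return ["between_specific", "overall"]
        return ["overall"]
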