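"""Side-by-side model comparison and congruence diagnostics.

The three-step workflow for clustered data compares a conventional CFA
against the maximum model (MAX MCFA) and the full MCFA. Two descriptive
congruence indices quantify how far the CFA's within-level estimates drift
from the multilevel reference:

* the relative difference 100 * (est_CFA - est_ref) / est_CFA, and
* a Wald-type t contrast (est1 - est2) / sqrt(se1^2 + se2^2) with
  df = n1 + n2 - 2, treating the two fits as independent samples.

Both are congruence descriptions, not formal tests — the two models are
fitted to the same data. Large relative differences (> 10%) or |t| > 1.96
signal between-level variation and the need for a multilevel structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .engine import FitResult
from .exceptions import ConfigurationError, ValidationError
from .fitstats import FitStatistics

_LAMBDA_RE = re.compile(r"^within\.lambda\[(?P<ind>[^~]+)~(?P<fac>[^\]]+)\]$")


def relative_difference(est_cfa: float, est_ref: float) -> float:
    """Percent difference of a CFA estimate from its multilevel reference.

    The denominator is the CFA estimate (the one-level quantity being
    judged), so positive values mean the CFA overstates the parameter.
    """
    if est_cfa == 0:
        raise ValidationError("relative difference undefined: CFA estimate is 0")
    return 100.0 * (est_cfa - est_ref) / est_cfa


def wald_t(est1, se1, n1, est2, se2, n2):
    """Wald-type contrast of two estimates from fits of sizes n1 and n2.

    Returns ``(t, df, p)`` with t = (est1 - est2)/sqrt(se1^2 + se2^2),
    df = n1 + n2 - 2 and a two-sided p from the t distribution.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValidationError("standard errors must be positive")
    if n1 < 2 or n2 < 2:
        raise ValidationError("sample sizes must be at least 2")
    t = (est1 - est2) / np.hypot(se1, se2)
    df = int(n1 + n2 - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass
class ComparisonTable:
    """Aligned fit, parameter and diagnostics blocks for several models."""

    fit_block: pd.DataFrame
    parameter_block: pd.DataFrame
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary_extremes(self) -> dict:
        if self.diagnostics.empty:
            return {}
        rd = self.diagnostics["relative_difference_pct"]
        return {
            "min_relative_difference_pct": float(rd.min()),
            "max_relative_difference_pct": float(rd.max()),
            "n_significant_contrasts": int(
                (self.diagnostics["abs_t"] > 1.96).sum()
            ),
        }

    def to_text(self, digits: int = 3) -> str:
        lines = ["Model fit statistics", "=" * 20]
        lines.append(self.fit_block.round(digits).to_string())
        lines.append("")
        lines.append("Parameter estimates")
        lines.append("=" * 19)
        block = self.parameter_block.copy()
        lines.append(
            block.round(digits).to_string(na_rep="")
        )
        if not self.diagnostics.empty:
            lines.append("")
            lines.append("Congruence diagnostics (CFA vs multilevel reference)")
            lines.append("=" * 52)
            lines.append(self.diagnostics.round(digits).to_string())
            ext = self.summary_extremes()
            lines.append(
                f"relative differences range "
                f"{ext['min_relative_difference_pct']:.2f}% to "
                f"{ext['max_relative_difference_pct']:.2f}%; "
                f"{ext['n_significant_contrasts']} contrast(s) with |t| > 1.96"
            )
        return "\n".join(lines) + "\n"

    def to_json_dict(self) -> dict:
        flat = self.parameter_block.copy()
        flat.columns = [f"{model}.{col}" for model, col in flat.columns]
        flat = flat.astype(object).where(flat.notna(), None)
        return {
            "fit": self.fit_block.to_dict(orient="index"),
            "parameters": flat.to_dict(orient="index"),
            "diagnostics": self.diagnostics.to_dict(orient="index"),
            "summary": self.summary_extremes(),
        }


_FIT_ROWS = ["chi2", "df", "p_value", "cfi", "rmsea", "srmr"]


def build_comparison(
    fits: dict[str, tuple[FitResult, FitStatistics]],
    reference: str | None = None,
) -> ComparisonTable:
    """Tabulate several fitted models side by side.

    ``fits`` maps a display name (e.g. ``"CFA"``, ``"MAX MCFA"``,
    ``"MCFA"``) to a ``(FitResult, FitStatistics)`` pair. When both a CFA
    and a multilevel reference (``reference`` or, by default, the first of
    "MAX MCFA"/"MAX"/"MCFA" present) are given, congruence diagnostics are
    computed for every free within-level loading present in both.
    """
    if not fits:
        raise ConfigurationError("no fitted models supplied")
    indicator_sets = {tuple(fr.model.indicators) for fr, _ in fits.values()}
    if len(indicator_sets) > 1:
        raise ConfigurationError(
            f"models use inconsistent indicator sets: {indicator_sets}"
        )

    fit_block = pd.DataFrame(
        {
            name: {row: getattr(fs, row) for row in _FIT_ROWS}
            for name, (_, fs) in fits.items()
        }
    ).T[_FIT_ROWS]

    all_params: list[str] = []
    for fr, _ in fits.values():
        for lab in fr.estimates.index:
            if lab not in all_params:
                all_params.append(lab)
    cols = {}
    for name, (fr, _) in fits.items():
        cols[(name, "est")] = fr.estimates.reindex(all_params)
        cols[(name, "se")] = fr.se.reindex(all_params)
    parameter_block = pd.DataFrame(cols, index=all_params)
    parameter_block.columns = pd.MultiIndex.from_tuples(parameter_block.columns)

    diagnostics = pd.DataFrame()
    cfa_name = next((n for n in fits if n.upper() == "CFA"), None)
    if reference is None:
        reference = next(
            (n for n in fits if n.upper() in ("MAX MCFA", "MAX_MCFA", "MAX", "MCFA")),
            None,
        )
    if cfa_name and reference and reference != cfa_name:
        diagnostics = _loading_diagnostics(fits[cfa_name][0], fits[reference][0])

    return ComparisonTable(fit_block, parameter_block, diagnostics)


def _loading_diagnostics(cfa: FitResult, ref: FitResult) -> pd.DataFrame:
    rows = {}
    n1 = cfa.n_obs
    n2 = ref.n_obs
    for lab in cfa.estimates.index:
        if not _LAMBDA_RE.match(lab) or lab not in ref.estimates.index:
            continue
        e1, s1 = cfa.estimates[lab], cfa.se[lab]
        e2, s2 = ref.estimates[lab], ref.se[lab]
        row = {"cfa_est": e1, "ref_est": e2}
        row["relative_difference_pct"] = (
            relative_difference(e1, e2) if e1 != 0 else np.nan
        )
        if np.isfinite(s1) and np.isfinite(s2) and s1 > 0 and s2 > 0:
            t, df, p = wald_t(e1, s1, n1, e2, s2, n2)
            row.update(t=t, df=df, p=p, abs_t=abs(t))
        else:
            row.update(t=np.nan, df=np.nan, p=np.nan, abs_t=np.nan)
        rows[lab] = row
    return pd.DataFrame(rows).T
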