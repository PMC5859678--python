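"""Three-step analysis workflow and report writers.

The workflow codifies the recommended model-building sequence for clustered
survey data:

1. screen per-indicator ICCs (nontrivial ICC indicates between-cluster
   variation worth modelling) and fit the conventional CFA alongside the
   maximum model, comparing their within-level estimates (congruence
   diagnostics);
2. settle the within-level structure on the maximum model's
   within-specific fit statistics;
3. fit candidate between-level structures as MCFAs judged on
   between-specific fit statistics.

``run_workflow`` executes all requested fits, tabulates them, and writes
matrices, per-model JSON, a comparison table and a log with the step-1
congruence verdict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import ComparisonTable, build_comparison
from .data import apply_missing_policy, read_dataset
from .decompose import compute_decomposition, icc
from .exceptions import ConfigurationError
from .model import MCFAResults, MultilevelFactorModel
from .modelspec import ModelKind

logger = logging.getLogger("mlcfa")

_MODEL_ORDER = ["MCFA", "CFA", "MAX_MCFA"]  # tabulation order of the fit block


@dataclass
class RunConfig:
    """Declarative description of a full analysis run."""

    data: str
    cluster: str
    case: str | None = None
    missing: float = -999999.0
    na_policy: str = "listwise"
    within: dict = field(default_factory=dict)
    between: dict | None = None
    marker_value: float = 1.0
    models: list[str] = field(default_factory=lambda: ["CFA", "MAX_MCFA", "MCFA"])
    outdir: str = "mlcfa_out"
    seed: int = 0
    icc_threshold: float = 0.05
    congruence_rd_threshold: float = 10.0
    congruence_t_threshold: float = 1.96
    indicators: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def run_workflow(cfg: RunConfig) -> dict:
    """Execute decomposition, ICC screening, all requested fits and tabulation."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg):
        logger.info(msg)
        log_lines.append(msg)

    ds = read_dataset(cfg.data, cfg.cluster, cfg.case, cfg.missing, cfg.indicators)
    handled = apply_missing_policy(ds, cfg.na_policy)
    decomp = compute_decomposition(handled)
    log(
        f"decomposition: N = {decomp.n_obs}, G = {decomp.n_clusters}, "
        f"c = {decomp.c:.4f}"
    )

    icc_table = icc(decomp)
    max_icc = icc_table["icc"].max()
    if max_icc > cfg.icc_threshold:
        log(
            f"ICC screening: max ICC = {max_icc:.3f} > {cfg.icc_threshold} — "
            "multilevel modeling indicated"
        )
    else:
        log(
            f"ICC screening: max ICC = {max_icc:.3f} <= {cfg.icc_threshold} — "
            "multilevel modeling not indicated"
        )

    fits: dict[str, MCFAResults] = {}
    for name in cfg.models:
        kind = ModelKind(name)
        kw = dict(marker_value=cfg.marker_value)
        if kind is ModelKind.CFA or kind is ModelKind.MAX_MCFA:
            model = MultilevelFactorModel(decomp, within=cfg.within, kind=kind, **kw)
        elif kind is ModelKind.MCFA:
            if not cfg.between:
                raise ConfigurationError("MCFA requested but no between spec given")
            model = MultilevelFactorModel(
                decomp, within=cfg.within, between=cfg.between, kind=kind, **kw
            )
        elif kind is ModelKind.PS_BETWEEN:
            model = MultilevelFactorModel(decomp, between=cfg.between, kind=kind, **kw)
        else:
            raise ConfigurationError(f"cannot run model kind {name!r}")
        res = model.fit()
        log(
            f"{name}: converged = {res.converged}, "
            f"discrepancy = {res.fit_min:.6f}"
        )
        for m in res.raw.messages:
            log(f"{name}: {m}")
        fits[name] = res

    # classic tabulation order: MCFA, CFA, MAX MCFA, then any extras
    ordered = [n for n in _MODEL_ORDER if n in fits] + [
        n for n in fits if n not in _MODEL_ORDER
    ]
    table = build_comparison(
        {name: (fits[name].raw, fits[name].fit_statistics()) for name in ordered}
    )

    verdict = None
    ext = table.summary_extremes()
    if ext:
        flag = (
            max(
                abs(ext["min_relative_difference_pct"]),
                abs(ext["max_relative_difference_pct"]),
            )
            > cfg.congruence_rd_threshold
            or ext["n_significant_contrasts"] > 0
        )
        verdict = {
            "incongruence_flag": bool(flag),
            **ext,
        }
        log(
            "step-1 congruence verdict: "
            + (
                "INCONGRUENT — between-level variation likely; proceed with "
                "multilevel modeling"
                if flag
                else "congruent — one-level estimates agree with the maximum model"
            )
        )

    bundle = {
        "config": cfg.to_dict(),
        "decomposition": decomp,
        "icc": icc_table,
        "fits": fits,
        "comparison": table,
        "congruence": verdict,
        "log": log_lines,
    }
    export_report(bundle, "json", outdir)
    export_report(bundle, "text", outdir)
    export_report(bundle, "tsv", outdir)
    _write_matrices(decomp, outdir)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle


def _write_matrices(decomp, outdir: Path) -> None:
    labels = list(decomp.labels)
    for name, mat in (("S_T", decomp.S_T), ("S_PW", decomp.S_PW), ("S_B", decomp.S_B)):
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(
            outdir / f"{name}.csv"
        )
    summary = {
        "N": int(decomp.n_obs),
        "G": int(decomp.n_clusters),
        "c": float(decomp.c),
        "icc": {lab: float(v) for lab, v in icc(decomp)["icc"].items()},
    }
    (outdir / "decomposition.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )


def _stats_dict(res: MCFAResults) -> dict:
    out = {}
    for scope in res._available_scopes():
        try:
            out[scope] = res.fit_statistics(scope).to_dict()
        except ConfigurationError:  # pragma: no cover
            continue
    return out


def export_report(bundle: dict, format: str, outdir) -> list[Path]:
    """Write the report bundle in one format; deterministic given the bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table: ComparisonTable = bundle["comparison"]
    written: list[Path] = []
    if format == "json":
        payload = {
            "config": bundle["config"],
            "icc": bundle["icc"]["icc"].to_dict(),
            "models": {
                name: {
                    "estimates": res.params.to_dict(),
                    "se": {
                        k: (None if not np.isfinite(v) else v)
                        for k, v in res.bse.items()
                    },
                    "converged": res.converged,
                    "discrepancy": res.fit_min,
                    "fit_statistics": _stats_dict(res),
                }
                for name, res in bundle["fits"].items()
            },
            "comparison": table.to_json_dict(),
            "congruence": bundle["congruence"],
        }
        path = outdir / "report.json"
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n"
        )
        written.append(path)
    elif format == "text":
        path = outdir / "report.txt"
        path.write_text(table.to_text())
        written.append(path)
    elif format == "tsv":
        fit_path = outdir / "fit_block.tsv"
        table.fit_block.to_csv(fit_path, sep="\t")
        par_path = outdir / "parameters.tsv"
        flat = table.parameter_block.copy()
        flat.columns = [f"{m}_{c}" for m, c in flat.columns]
        flat.to_csv(par_path, sep="\t")
        written.extend([fit_path, par_path])
        if not table.diagnostics.empty:
            diag_path = outdir / "diagnostics.tsv"
            table.diagnostics.to_csv(diag_path, sep="\t")
            written.append(diag_path)
    else:
        raise ConfigurationError(f"unknown report format {format!r}")
    return written
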