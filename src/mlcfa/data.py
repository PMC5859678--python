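"""Long-format clustered datasets: reading, validation, missing-data policy.

A multilevel (two-level) dataset is a long-format table with one row per
lowest-level unit: a cluster identifier (the between-level sampling unit),
a case identifier unique within its cluster, and ``p`` continuous indicator
columns. Missing cells are marked with a numeric sentinel (default
``-999999``), the convention of classic SEM batch software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParseError, ValidationError

DEFAULT_MISSING_CODE = -999999.0


@dataclass(frozen=True)
class MultilevelDataset:
    """Validated, sorted long-format clustered indicator data.

    Attributes
    ----------
    values : (N, p) ndarray
        Continuous indicator scores; missing cells hold ``nan``.
    cluster_id : (N,) ndarray of str
        Between-level unit label per row. IDs are opaque strings
        ("01" and "1" are distinct labels).
    case_id : (N,) ndarray of str
        Within-cluster unit label, unique within each cluster.
    labels : tuple of str
        Indicator (column) names, unique and non-empty.
    missing_code : float
        Sentinel that marked missing cells in the source file.
    """

    values: np.ndarray
    cluster_id: np.ndarray
    case_id: np.ndarray
    labels: tuple[str, ...]
    missing_code: float = DEFAULT_MISSING_CODE

    # populated by __post_init__
    cluster_sizes: pd.Series = field(default=None, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        cluster = np.asarray(self.cluster_id, dtype=str)
        case = np.asarray(self.case_id, dtype=str)
        labels = tuple(str(x) for x in self.labels)

        if values.ndim != 2:
            raise ValidationError("values must be a 2-D (N, p) array")
        n, p = values.shape
        if len(labels) != p:
            raise ValidationError(f"{len(labels)} labels for {p} indicator columns")
        if len(set(labels)) != p or any(not lab for lab in labels):
            raise ValidationError("indicator labels must be unique and non-empty")
        if cluster.shape != (n,) or case.shape != (n,):
            raise ValidationError("cluster_id and case_id must have one entry per row")

        # sort ascending by cluster then case; stable so equal keys keep order
        order = np.lexsort((case, cluster))
        values = values[order]
        cluster = cluster[order]
        case = case[order]

        sizes = pd.Series(cluster).value_counts().sort_index()
        if len(sizes) < 2:
            raise ValidationError(
                f"need at least 2 clusters, found {len(sizes)}"
            )

        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cluster_id", cluster)
        object.__setattr__(self, "case_id", case)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "cluster_sizes", sizes)

    # -- basic shape accessors -------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n_g(self) -> np.ndarray:
        """Per-cluster sizes, in sorted cluster order."""
        return self.cluster_sizes.to_numpy()

    def to_frame(self, cluster_col: str = "cluster", case_col: str = "case") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.labels))
        df.insert(0, case_col, self.case_id)
        df.insert(0, cluster_col, self.cluster_id)
        return df

    def write(self, path, cluster_col: str = "cluster", case_col: str = "case") -> None:
        """Write as delimited text; missing cells rendered as the sentinel."""
        df = self.to_frame(cluster_col, case_col)
        for lab in self.labels:
            df[lab] = df[lab].fillna(self.missing_code)
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def from_dataframe(
    df: pd.DataFrame,
    cluster_col: str,
    case_col: str | None = None,
    missing_code: float = DEFAULT_MISSING_CODE,
    indicators: list[str] | None = None,
) -> MultilevelDataset:
    """Build a :class:`MultilevelDataset` from a long-format DataFrame.

    Non-indicator columns other than the two ID columns are dropped when
    ``indicators`` names the columns to keep; otherwise every remaining
    column is treated as an indicator and must be numeric.
    """
    if cluster_col not in df.columns:
        raise ConfigurationError(f"cluster column {cluster_col!r} not in data")
    if case_col is not None and case_col not in df.columns:
        raise ConfigurationError(f"case column {case_col!r} not in data")

    id_cols = [cluster_col] + ([case_col] if case_col else [])
    if indicators is None:
        indicators = [c for c in df.columns if c not in id_cols]
    else:
        missing_cols = [c for c in indicators if c not in df.columns]
        if missing_cols:
            raise ConfigurationError(f"indicator columns not in data: {missing_cols}")
    if not indicators:
        raise ConfigurationError("no indicator columns remain after removing IDs")

    vals = np.empty((len(df), len(indicators)), dtype=float)
    for j, col in enumerate(indicators):
        try:
            # numpy parses via float(), which round-trips %.17g exactly
            # (pandas' to_numeric fast path does not)
            vals[:, j] = df[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = list(df.index[bad.isna() & df[col].notna()][:5])
            raise ParseError(
                f"non-numeric value in indicator column {col!r} at rows {rows}"
            ) from None
    vals[vals == missing_code] = np.nan

    cluster = df[cluster_col].astype(str).to_numpy()
    if case_col is not None:
        case = df[case_col].astype(str).to_numpy()
    else:
        case = np.array(
            [str(i) for i in df.groupby(cluster_col, sort=False).cumcount()], dtype=str
        )
    return MultilevelDataset(vals, cluster, case, tuple(indicators), missing_code)


def read_dataset(
    path,
    cluster_col: str,
    case_col: str | None = None,
    missing_code: float = DEFAULT_MISSING_CODE,
    indicators: list[str] | None = None,
) -> MultilevelDataset:
    """Read a delimited-text clustered dataset (CSV, or TSV by extension).

    The file must have a header row naming ``cluster_col`` and (optionally)
    ``case_col``; all other retained columns are numeric indicators. Rows are
    sorted ascending by cluster then case during validation.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except FileNotFoundError:
        raise ConfigurationError(f"data file not found: {path}") from None
    return from_dataframe(df, cluster_col, case_col, missing_code, indicators)


@dataclass(frozen=True)
class PairwiseMask:
    """Per-pair complete-case bookkeeping for pairwise deletion.

    ``counts[j, k]`` is the number of rows on which indicators j and k are
    both observed. The effective sample size used downstream in likelihood
    weighting is the minimum pairwise count (a conservative choice).
    """

    dataset: MultilevelDataset
    counts: np.ndarray

    @property
    def effective_n(self) -> int:
        return int(self.counts.min())


def apply_missing_policy(ds: MultilevelDataset, policy: str = "listwise"):
    """Apply a missing-data policy.

    ``listwise`` drops every row with any missing indicator (clusters that
    lose all rows are removed with a warning). ``pairwise`` keeps all rows
    and returns a :class:`PairwiseMask` recording per-pair complete counts,
    matching the pairwise-deletion behaviour of classic multi-group MUML
    front ends.
    """
    if policy not in ("listwise", "pairwise"):
        raise ConfigurationError(f"unknown missing policy {policy!r}")

    nan_mask = np.isnan(ds.values)
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        bad = [ds.labels[j] for j in np.where(all_missing)[0]]
        raise ValidationError(f"indicator(s) entirely missing: {bad}")

    if not nan_mask.any():
        if policy == "listwise":
            return ds
        obs = (~nan_mask).astype(int)
        return PairwiseMask(ds, obs.T @ obs)

    if policy == "pairwise":
        obs = (~nan_mask).astype(int)
        return PairwiseMask(ds, obs.T @ obs)

    keep = ~nan_mask.any(axis=1)
    kept_clusters = set(ds.cluster_id[keep])
    lost = sorted(set(ds.cluster_id) - kept_clusters)
    if lost:
        warnings.warn(
            f"listwise deletion removed entire cluster(s): {lost}", stacklevel=2
        )
    if len(kept_clusters) < 2:
        raise ValidationError("fewer than 2 clusters remain after listwise deletion")
    return MultilevelDataset(
        ds.values[keep],
        ds.cluster_id[keep],
        ds.case_id[keep],
        ds.labels,
        ds.missing_code,
    )
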