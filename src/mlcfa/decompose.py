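"""Covariance decomposition for two-level data and ICC screening.

For clustered observations y_gi (case i in cluster g, N cases in G
clusters) the sample total covariance splits exactly into a pooled
within-cluster part and a size-weighted between-cluster part:

    S_T  = sum_g sum_i (y_gi - ybar)(y_gi - ybar)' / (N - 1)
    S_PW = sum_g sum_i (y_gi - ybar_g)(y_gi - ybar_g)' / (N - G)
    S_B  = sum_g n_g (ybar_g - ybar)(ybar_g - ybar)' / (G - 1)

so that (N-1) S_T = (N-G) S_PW + (G-1) S_B holds to machine precision.
Under a two-level normal model S_PW estimates the within-level population
covariance Sigma_W, and S_B estimates Sigma_W + c * Sigma_B, where

    c = (N^2 - sum_g n_g^2) / (N (G - 1))

is the MUML scaling constant (equal to the common cluster size in a
balanced design, and close to the average size otherwise).

Per-indicator intraclass correlations use moment estimates derived from
the same decomposition: sigma2_B,j = max((S_B,jj - S_PW,jj) / c, 0),
sigma2_W,j = S_PW,jj, icc_j = sigma2_B,j / (sigma2_B,j + sigma2_W,j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MultilevelDataset, PairwiseMask
from .exceptions import ValidationError


@dataclass(frozen=True)
class CovDecomposition:
    """Total / pooled-within / scaled-between sample covariance matrices."""

    S_T: np.ndarray
    S_PW: np.ndarray
    S_B: np.ndarray
    c: float
    n_obs: int
    n_clusters: int
    n_g: np.ndarray
    grand_mean: np.ndarray
    group_means: np.ndarray
    labels: tuple[str, ...]

    @property
    def p(self) -> int:
        return self.S_T.shape[0]

    def sigma_b_moment(self) -> np.ndarray:
        """Moment estimate of the between-level covariance, (S_B - S_PW)/c.

        Not truncated; may be indefinite in small samples.
        """
        return (self.S_B - self.S_PW) / self.c


def scaling_constant(n_g) -> float:
    """MUML common-group-size scalar c = (N^2 - sum n_g^2) / (N (G-1))."""
    n_g = np.asarray(n_g, dtype=float)
    G = n_g.size
    if G < 2:
        raise ValidationError("scaling constant requires at least 2 clusters")
    N = n_g.sum()
    return float((N**2 - (n_g**2).sum()) / (N * (G - 1)))


def compute_decomposition(ds: MultilevelDataset | PairwiseMask) -> CovDecomposition:
    """Compute S_T, S_PW, S_B, c, and the means from a validated dataset.

    Accepts a :class:`PairwiseMask` (from the pairwise missing policy), in
    which case every covariance element is computed on the rows where both
    of its indicators are observed, and the reported ``n_obs`` is the
    minimum pairwise complete count.
    """
    if isinstance(ds, PairwiseMask):
        return _pairwise_decomposition(ds)

    if np.isnan(ds.values).any():
        raise ValidationError(
            "dataset contains missing values; apply a missing policy first"
        )

    y = ds.values
    N, p = y.shape
    G = ds.n_clusters
    if N <= G:
        raise ValidationError(
            "within covariance undefined: every cluster is a singleton (N == G)"
        )

    zero_var = np.where(y.var(axis=0) == 0)[0]
    if zero_var.size:
        raise ValidationError(
            f"zero-variance indicator(s): {[ds.labels[j] for j in zero_var]}"
        )

    df = pd.DataFrame(y)
    groups = pd.Series(ds.cluster_id)
    group_means = df.groupby(groups, sort=True).mean().to_numpy()
    n_g = ds.n_g.astype(float)
    grand = y.mean(axis=0)

    dev_t = y - grand
    S_T = dev_t.T @ dev_t / (N - 1)

    expanded = np.repeat(group_means, ds.n_g, axis=0)  # rows already cluster-sorted
    dev_w = y - expanded
    S_PW = dev_w.T @ dev_w / (N - G)

    dev_b = group_means - grand
    S_B = (dev_b.T * n_g) @ dev_b / (G - 1)

    c = scaling_constant(n_g)
    return CovDecomposition(
        S_T=S_T,
        S_PW=S_PW,
        S_B=S_B,
        c=c,
        n_obs=N,
        n_clusters=G,
        n_g=ds.n_g.copy(),
        grand_mean=grand,
        group_means=group_means,
        labels=ds.labels,
    )


def _pairwise_decomposition(mask: PairwiseMask) -> CovDecomposition:
    ds = mask.dataset
    p = ds.n_indicators
    S_T = np.empty((p, p))
    S_PW = np.empty((p, p))
    S_B = np.empty((p, p))
    for j in range(p):
        for k in range(j, p):
            rows = ~np.isnan(ds.values[:, j]) & ~np.isnan(ds.values[:, k])
            sub = MultilevelDataset(
                ds.values[rows][:, [j, k]] if j != k else ds.values[rows][:, [j]],
                ds.cluster_id[rows],
                ds.case_id[rows],
                (ds.labels[j], ds.labels[k]) if j != k else (ds.labels[j],),
                ds.missing_code,
            )
            d = compute_decomposition(sub)
            idx = (0, 1) if j != k else (0, 0)
            S_T[j, k] = S_T[k, j] = d.S_T[idx]
            S_PW[j, k] = S_PW[k, j] = d.S_PW[idx]
            S_B[j, k] = S_B[k, j] = d.S_B[idx]

    for name, mat in (("S_T", S_T), ("S_PW", S_PW)):
        ev = np.linalg.eigvalsh(mat).min()
        if ev < -1e-10:
            warnings.warn(
                f"pairwise-deletion {name} is not positive semidefinite "
                f"(min eigenvalue {ev:.3g}); downstream fits will abort",
                stacklevel=3,
            )

    # counts/means from the complete-row subset for reporting; effective N
    # for likelihood weighting is the minimum pairwise count
    complete = ~np.isnan(ds.values).any(axis=1)
    base = compute_decomposition(
        MultilevelDataset(
            ds.values[complete], ds.cluster_id[complete], ds.case_id[complete],
            ds.labels, ds.missing_code,
        )
    )
    return CovDecomposition(
        S_T=S_T, S_PW=S_PW, S_B=S_B, c=base.c,
        n_obs=mask.effective_n, n_clusters=base.n_clusters, n_g=base.n_g,
        grand_mean=base.grand_mean, group_means=base.group_means,
        labels=ds.labels,
    )


def icc(decomp: CovDecomposition) -> pd.DataFrame:
    """Per-indicator between/within variance estimates and ICC.

    Negative raw between-variance estimates are truncated to zero for the
    ICC (variances cannot be negative); the raw value is kept in the
    ``sigma2_between_raw`` column for diagnostics.
    """
    raw_b = (np.diag(decomp.S_B) - np.diag(decomp.S_PW)) / decomp.c
    sigma_w = np.diag(decomp.S_PW)
    if (raw_b < 0).any():
        neg = [decomp.labels[j] for j in np.where(raw_b < 0)[0]]
        warnings.warn(
            f"negative between-variance estimate truncated to 0 for: {neg}",
            stacklevel=2,
        )
    sigma_b = np.maximum(raw_b, 0.0)
    table = pd.DataFrame(
        {
            "sigma2_between": sigma_b,
            "sigma2_within": sigma_w,
            "sigma2_between_raw": raw_b,
            "icc": sigma_b / (sigma_b + sigma_w),
        },
        index=list(decomp.labels),
    )
    return table
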