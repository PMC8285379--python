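"""Environmental-table curation: variable filtering, scaling, imputation.

The curation chain mirrors standard pre-modeling practice for mixed-type
oceanographic tables: drop near-zero-variance variables, drop one member of
every excessively correlated quantitative pair, center/scale the quantitative
variables, then impute remaining gaps from the k nearest samples (k = 5 by
default) in standardized environmental space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import nzv_flag
from .types import EnvironmentTable


@dataclass(frozen=True)
class PrepConfig:
    """Curation parameters.

    ``freq_cut`` is the most-common / second-most-common frequency ratio above
    which a variable is near-zero-variance (95/5 = 19); ``unique_cut`` the
    percent-distinct threshold below which it is; ``corr_cut`` the absolute
    Pearson correlation above which one of a quantitative pair is dropped;
    ``k_impute`` the neighbor count for imputation.
    """

    freq_cut: float = 95.0 / 5.0
    unique_cut: float = 10.0
    corr_cut: float = 0.90
    k_impute: int = 5

    def __post_init__(self) -> None:
        if not (self.freq_cut > 0 and 0 < self.unique_cut <= 100):
            raise ValueError("invalid nzv cuts")
        if not (0 < self.corr_cut <= 1 and self.k_impute >= 1):
            raise ValueError("invalid corr_cut or k_impute")


def filter_variables(
    env: EnvironmentTable, cfg: PrepConfig = PrepConfig()
) -> tuple[EnvironmentTable, pd.DataFrame]:
    """Drop near-zero-variance variables, then one member of each highly
    correlated quantitative pair.

    The correlation step is greedy on the most correlated remaining pair and
    removes the member with the larger mean absolute correlation to all other
    remaining quantitative variables.  Qualitative variables face only the
    near-zero-variance check.  Returns the reduced table and a removal report
    (variable, reason).
    """
    removed: list[dict] = []
    keep: list[str] = []
    for v in env.data.columns:
        col = env.data[v].dropna().to_numpy()
        if len(col) >= 2 and nzv_flag(col, cfg.freq_cut, cfg.unique_cut):
            removed.append({"variable": v, "reason": "nzv"})
        else:
            keep.append(v)

    quant = [v for v in env.quantitative if v in keep]
    if len(quant) >= 2:
        corr = env.data[quant].corr(method="pearson").abs()
        np.fill_diagonal(corr.values, 0.0)
        while True:
            if corr.shape[0] < 2:
                break
            max_r = corr.values.max()
            if max_r <= cfg.corr_cut:
                break
            i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
            a, b = corr.index[i], corr.columns[j]
            drop = a if corr[a].mean() >= corr[b].mean() else b
            removed.append({"variable": drop, "reason": "corr"})
            keep.remove(drop)
            corr = corr.drop(index=drop, columns=drop)

    report = pd.DataFrame(removed, columns=["variable", "reason"])
    return env.subset(keep), report


def scale_center(env: EnvironmentTable) -> EnvironmentTable:
    """Standardize each quantitative variable to mean 0, sd 1 (n-1
    denominator), computed over observed entries only."""
    out = env.copy()
    for v in out.quantitative:
        col = out.data[v]
        sd = col.std(ddof=1)  # pandas skips NaN
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {v!r}: zero variance at scaling stage")
        out.data[v] = (col - col.mean()) / sd
    return out


def knn_impute(env: EnvironmentTable, k: int = 5) -> EnvironmentTable:
    """Fill missing quantitative cells with the mean of the k nearest samples.

    Sample distance is Euclidean over quantitative variables observed in both
    samples, divided by the number of shared variables; neighbors must have
    the target variable observed.  Distance ties are broken by sample-ID
    order, so imputation is deterministic.
    """
    out = env.copy()
    quant = out.quantitative
    X = out.data[quant].to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n = X.shape[0]
    sample_order = np.argsort(np.asarray(out.data.index, dtype=object))
    rank_of = np.empty(n, dtype=int)
    rank_of[sample_order] = np.arange(n)

    for j, v in enumerate(quant):
        have = obs[:, j]
        if have.sum() < k:
            raise ValueError(f"variable {v!r} observed in fewer than k={k} samples")

    # pairwise distances, shared-variable normalized
    dist = np.full((n, n), np.inf)
    for a in range(n):
        shared = obs[a] & obs
        diff = X[a] - X
        diff[~shared] = 0.0
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(np.nansum(diff**2, axis=1)) / n_shared
        d[n_shared == 0] = np.inf
        dist[a] = d
    np.fill_diagonal(dist, np.inf)

    filled = X.copy()
    for a in range(n):
        for j in np.where(~obs[a, :])[0]:
            candidates = np.where(obs[:, j])[0]
            # sort by (distance, sample-ID order) for deterministic ties
            order = sorted(candidates, key=lambda b: (dist[a, b], rank_of[b]))
            nearest = order[:k]
            filled[a, j] = float(np.mean(X[nearest, j]))
    out.data[quant] = filled
    return out


def prepare_environment(
    env: EnvironmentTable, cfg: PrepConfig = PrepConfig()
) -> tuple[EnvironmentTable, pd.DataFrame]:
    """Full curation chain: filter -> scale/center -> impute."""
    reduced, report = filter_variables(env, cfg)
    scaled = scale_center(reduced)
    complete = knn_impute(scaled, cfg.k_impute)
    return complete, report
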