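"""Constrained correspondence analysis (CCA) of cluster abundances.

The response table Y (samples x clusters, non-negative) is converted to
chi-square-standardized residuals Q = (P - r c') / sqrt(r c') with P = Y /
grand total and r, c the row/column mass vectors.  The explanatory table X is
weighted-centered, row-weighted by sqrt(r), and Q is projected onto its
column space; the SVD of the fitted part yields the constrained axes.
Eigenvalues sum to the constrained inertia, which cannot exceed the total
inertia sum(Q^2).

Significance is assessed by permuting sample rows of X and comparing the
constrained-inertia fraction; explanatory variables can be chosen by a
bidirectional greedy search on an AIC analog
``n log(residual_inertia / n) + 2 (k + 1)`` with k the number of fitted
constraint columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .types import EnvironmentTable

_RANK_TOL = 1e-9


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray  # non-increasing, non-negative
    total_inertia: float
    constrained_inertia: float
    feature_scores: pd.DataFrame  # clusters x axes
    site_scores: pd.DataFrame  # samples x axes
    biplot_scores: pd.DataFrame  # design columns x axes
    dropped_columns: list[str] = field(default_factory=list)
    perm_p: float | None = None

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia


def build_design(env: EnvironmentTable) -> pd.DataFrame:
    """Explanatory design matrix: quantitative columns as-is, qualitative
    one-hot with the first (sorted) level dropped as reference."""
    blocks: list[pd.DataFrame] = []
    for v in env.quantitative:
        blocks.append(env.data[[v]].astype(float))
    for v in env.qualitative:
        dummies = pd.get_dummies(env.data[v], prefix=v, dtype=float)
        dummies = dummies[sorted(dummies.columns)[1:]]  # drop reference level
        blocks.append(dummies)
    if not blocks:
        return pd.DataFrame(index=env.data.index)
    return pd.concat(blocks, axis=1)


def _chi_square_setup(Y: pd.DataFrame):
    vals = Y.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("response table must be non-negative")
    row_sums = vals.sum(axis=1)
    col_sums = vals.sum(axis=0)
    if (row_sums <= 0).any():
        bad = Y.index[np.argmin(row_sums)]
        raise ValueError(f"zero-sum sample row {bad!r}")
    if (col_sums <= 0).any():
        bad = Y.columns[np.argmin(col_sums)]
        raise ValueError(f"zero-sum feature column {bad!r}")
    total = vals.sum()
    P = vals / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    return Q, r, c


def _independent_columns(Xw: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, list[int], list[str]]:
    """Greedy maximal independent column subset, preferring earlier columns
    (a later column collinear with earlier ones is the one dropped)."""
    if Xw.shape[1] == 0:
        return Xw, [], []
    norm = np.linalg.norm(Xw, axis=0)
    scale = norm.max() if norm.max() > 0 else 1.0
    keep: list[int] = []
    basis: list[np.ndarray] = []  # orthonormal basis of kept columns
    for j in range(Xw.shape[1]):
        v = Xw[:, j].copy()
        for b in basis:
            v -= (b @ Xw[:, j]) * b
        if np.linalg.norm(v) > scale * _RANK_TOL:
            basis.append(v / np.linalg.norm(v))
            keep.append(j)
    dropped = [names[i] for i in range(Xw.shape[1]) if i not in keep]
    return Xw[:, keep], keep, dropped


def fit_cca(
    Y: pd.DataFrame,
    X: EnvironmentTable | pd.DataFrame,
    n_axes: int | None = None,
) -> OrdinationResult:
    """Constrained correspondence analysis of Y (samples x clusters) on X.

    Scores are reported in species-focused scaling: feature scores carry the
    eigenvalue weight (V * d / sqrt(c)), site scores are the unit-inertia
    linear-combination scores (U / sqrt(r)), and biplot scores are the
    r-weighted correlations of design columns with the site scores.  Each
    axis is oriented so its largest-magnitude biplot score is positive.
    Linearly dependent design columns are dropped with a warning.
    """
    design = build_design(X) if isinstance(X, EnvironmentTable) else X.astype(float)
    design = design.loc[Y.index]
    Q, r, c = _chi_square_setup(Y)
    total_inertia = float((Q**2).sum())

    Xmat = design.to_numpy(dtype=float)
    names = list(design.columns)
    # r-weighted centering, then sqrt(r) row weighting
    Xc = Xmat - r @ Xmat
    Xw = np.sqrt(r)[:, None] * Xc
    Xw, keep, dropped = _independent_columns(Xw, names)
    kept_names = [names[i] for i in keep]
    if dropped:
        warnings.warn(f"dropping dependent design columns: {dropped}")
    if Xw.shape[1] == 0:
        raise ValueError("no usable explanatory columns")

    B, *_ = np.linalg.lstsq(Xw, Q, rcond=None)
    Q_fit = Xw @ B
    constrained_inertia = float((Q_fit**2).sum())

    U, d, Vt = np.linalg.svd(Q_fit, full_matrices=False)
    rank = int((d > (d[0] * _RANK_TOL if d.size and d[0] > 0 else 0)).sum())
    if n_axes is not None:
        rank = min(rank, n_axes)
    U, d, Vt = U[:, :rank], d[:rank], Vt[:rank]

    site = U / np.sqrt(r)[:, None]
    feat = (Vt.T / np.sqrt(c)[:, None]) * d

    # biplot scores: r-weighted correlation of design columns with site scores
    biplot = np.zeros((len(kept_names), rank))
    for j in range(Xw.shape[1]):
        x = Xc[:, keep[j]]
        xm = r @ x
        xsd = np.sqrt(r @ (x - xm) ** 2)
        for k in range(rank):
            z = site[:, k]
            zm = r @ z
            zsd = np.sqrt(r @ (z - zm) ** 2)
            if xsd > 0 and zsd > 0:
                biplot[j, k] = (r * (x - xm) * (z - zm)).sum() / (xsd * zsd)

    # orient each axis so its largest-|value| biplot score is positive
    for k in range(rank):
        if biplot.shape[0] and biplot[np.argmax(np.abs(biplot[:, k])), k] < 0:
            site[:, k] *= -1
            feat[:, k] *= -1
            biplot[:, k] *= -1

    axes = [f"CCA{k + 1}" for k in range(rank)]
    return OrdinationResult(
        eigenvalues=d**2,
        total_inertia=total_inertia,
        constrained_inertia=constrained_inertia,
        feature_scores=pd.DataFrame(feat, index=Y.columns, columns=axes),
        site_scores=pd.DataFrame(site, index=Y.index, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=kept_names, columns=axes),
        dropped_columns=dropped,
    )


def permutation_test(
    Y: pd.DataFrame,
    X: EnvironmentTable | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the constrained-inertia fraction.

    Sample rows of X are permuted; p = (1 + #{perm >= observed}) / (1 + n).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = build_design(X) if isinstance(X, EnvironmentTable) else X.astype(float)
    design = design.loc[Y.index]

    def stat(des: pd.DataFrame) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_cca(Y, des)
        return res.constrained_inertia / res.total_inertia

    observed = stat(design)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(design))
        permuted = pd.DataFrame(
            design.to_numpy()[perm], index=design.index, columns=design.columns
        )
        if stat(permuted) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def ordination_aic(Y: pd.DataFrame, env: EnvironmentTable, variables: Sequence[str]) -> float:
    """AIC analog: n log(residual_inertia / n) + 2 (k + 1), k = fitted
    constraint columns (0 for the empty model, whose residual is the total
    inertia)."""
    n = Y.shape[0]
    if not variables:
        Q, _, _ = _chi_square_setup(Y)
        residual = float((Q**2).sum())
        k = 0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_cca(Y, env.subset(variables))
        residual = res.total_inertia - res.constrained_inertia
        k = res.biplot_scores.shape[0]
    return n * np.log(max(residual, 1e-12) / n) + 2 * (k + 1)


def stepwise_select(
    Y: pd.DataFrame,
    env: EnvironmentTable,
    start: Sequence[str] = (),
    seed: int | None = None,
) -> list[str]:
    """Bidirectional greedy AIC selection of explanatory variables.

    Each sweep tries forward additions first, then backward drops, taking the
    single move that most improves the AIC; it stops at a fixed point.  Ties
    are broken by variable order, so the search is deterministic (``seed`` is
    accepted for interface uniformity and unused).
    """
    candidates = list(env.data.columns)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate variables")
    current = list(start)
    current_aic = ordination_aic(Y, env, current)
    while True:
        best_move: tuple[float, str, str] | None = None  # (aic, action, var)
        for v in candidates:
            if v in current:
                continue
            aic = ordination_aic(Y, env, current + [v])
            if aic < current_aic - 1e-10 and (best_move is None or aic < best_move[0] - 1e-10):
                best_move = (aic, "add", v)
        if best_move is None:
            for v in current:
                aic = ordination_aic(Y, env, [w for w in current if w != v])
                if aic < current_aic - 1e-10 and (
                    best_move is None or aic < best_move[0] - 1e-10
                ):
                    best_move = (aic, "drop", v)
        if best_move is None:
            return current
        current_aic, action, v = best_move
        if action == "add":
            current.append(v)
        else:
            current.remove(v)


@dataclass(frozen=True)
class GroupBarycenter:
    group_id: str
    n_members: int
    position: tuple[float, ...]  # per-axis mean of member feature scores
    spread: tuple[float, ...]  # per-axis sd (n-1), 0 for a single member
    below_min_size: bool


def group_barycenters(
    feature_scores: pd.DataFrame,
    membership: Mapping[str, Iterable[str]],
    min_size: int = 10,
) -> list[GroupBarycenter]:
    """Mean position and per-axis spread of each group of features.

    ``membership`` maps each feature to the groups it belongs to (a cluster
    may map to several pathways).  Groups smaller than ``min_size`` are
    flagged, never dropped.
    """
    unknown = set(membership) - set(feature_scores.index)
    if unknown:
        raise ValueError(f"unknown features in membership: {sorted(unknown)[:5]}")
    by_group: dict[str, list[str]] = {}
    for feature, groups in membership.items():
        for g in groups:
            by_group.setdefault(str(g), []).append(feature)
    out = []
    for gid in sorted(by_group):
        members = by_group[gid]
        scores = feature_scores.loc[members].to_numpy(dtype=float)
        mean = scores.mean(axis=0)
        sd = (
            scores.std(axis=0, ddof=1)
            if len(members) > 1
            else np.zeros(scores.shape[1])
        )
        out.append(
            GroupBarycenter(
                group_id=gid,
                n_members=len(members),
                position=tuple(float(v) for v in mean),
                spread=tuple(float(v) for v in sd),
                below_min_size=len(members) < min_size,
            )
        )
    return out
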