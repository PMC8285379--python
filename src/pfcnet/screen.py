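"""Repeated random-forest screen linking cluster abundance to environment.

For each cluster's abundance profile across samples, the screen repeats
``n_repeats`` times: draw a 75/25 train/test split, tune the forest's
``mtry`` (features tried per split) over a small grid by k-fold
cross-validation minimizing RMSE, refit the winner on the whole training set,
and record the out-of-fold R-squared, the test-set R-squared, and per-variable
permutation-importance ranks.  Averaged over repeats, the out-of-fold
R-squared classifies clusters: above 0.5 "highly linked to environment"
(hle), above 0.25 "linked".

R-squared here is the squared Pearson correlation between predictions and
observations, computed per held-out fold and averaged over folds — the
resample-averaged convention of caret-style training frameworks; a
1 - SSE/SST variant is available via ``r2_definition``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .types import EnvironmentTable


def nzv_flag(
    values: np.ndarray | Sequence,
    freq_cut: float = 95.0 / 5.0,
    unique_cut: float = 10.0,
    mode: str = "and",
) -> bool:
    """Near-zero-variance flag for an abundance (or variable) vector.

    Flags when the percent of distinct values is below ``unique_cut`` AND the
    most-common/second-most-common frequency ratio exceeds ``freq_cut``
    (``mode="or"`` flags on either condition alone).  A vector with a single
    distinct value is always flagged.
    """
    values = np.asarray(values)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    _, counts = np.unique(values, return_counts=True)
    if len(counts) == 1:
        return True
    unique_pct = 100.0 * len(counts) / values.size
    top2 = np.sort(counts)[::-1][:2]
    freq_ratio = top2[0] / top2[1]
    low_unique = unique_pct < unique_cut
    high_ratio = freq_ratio > freq_cut
    if mode == "and":
        return low_unique and high_ratio
    if mode == "or":
        return low_unique or high_ratio
    raise ValueError(f"unknown mode {mode!r}")


def train_size(n_samples: int, train_fraction: float = 0.75) -> int:
    """Training-set size: the train fraction of n, rounded up (93 -> 70)."""
    return math.ceil(n_samples * train_fraction)


def default_mtry(n_predictors: int) -> int:
    """Conventional forest default: floored square root of the predictor
    count (52 predictors -> 7)."""
    return math.floor(math.sqrt(n_predictors))


@dataclass(frozen=True)
class ScreenConfig:
    n_repeats: int = 10
    train_fraction: float = 0.75
    n_folds: int = 5
    mtry_grid: tuple[int, ...] = (5, 6, 7, 8, 9)
    n_trees: int = 500
    r2_link: float = 0.25
    r2_hle: float = 0.5
    r2_definition: str = "pearson"  # or "sse"
    n_importance_shuffles: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if min(self.mtry_grid) < 1:
            raise ValueError("mtry values must be positive")

    @classmethod
    def scaled(cls, **kwargs) -> "ScreenConfig":
        """Desk-scale profile: 3 repeats, 100 trees, same protocol."""
        base = dict(n_repeats=3, n_trees=100)
        base.update(kwargs)
        return cls(**base)


@dataclass
class ScreenResult:
    pfc_id: int | str
    mean_cv_r2: float
    mean_test_r2: float
    mean_rmse: float
    importance_rank: pd.Series  # per original variable, mean rank (1 = best)
    category: str  # none | linked | hle
    n_degenerate_repeats: int = 0
    encoding: str = "one-hot"
    best_mtry: tuple[int, ...] = ()


def classify_link(mean_cv_r2: float, cfg: ScreenConfig = ScreenConfig()) -> str:
    """Strictly-over thresholds: > r2_hle -> hle; > r2_link -> linked."""
    if mean_cv_r2 > cfg.r2_hle:
        return "hle"
    if mean_cv_r2 > cfg.r2_link:
        return "linked"
    return "none"


def encode_predictors(env: EnvironmentTable) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot encode qualitative variables (all levels kept; forests need no
    reference level).  Returns the design matrix and the variable -> columns
    map used to group importances back onto original variables."""
    blocks: list[pd.DataFrame] = []
    groups: dict[str, list[str]] = {}
    for v in env.quantitative:
        blocks.append(env.data[[v]].astype(float))
        groups[v] = [v]
    for v in env.qualitative:
        dummies = pd.get_dummies(env.data[v], prefix=v, dtype=float)
        dummies = dummies[sorted(dummies.columns)]
        blocks.append(dummies)
        groups[v] = list(dummies.columns)
    X = pd.concat(blocks, axis=1)
    return X, groups


def _r2(pred: np.ndarray, obs: np.ndarray, definition: str) -> tuple[float, bool]:
    """R-squared of predictions vs observations; flags degenerate inputs."""
    if np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0, True
    if definition == "pearson":
        r = np.corrcoef(pred, obs)[0, 1]
        return float(r * r), False
    if definition == "sse":
        sst = float(np.sum((obs - obs.mean()) ** 2))
        sse = float(np.sum((obs - pred) ** 2))
        return 1.0 - sse / sst, False
    raise ValueError(f"unknown r2 definition {definition!r}")


def _forest(n_trees: int, mtry: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
    )


def _grouped_permutation_ranks(
    model: RandomForestRegressor,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    groups: Mapping[str, list[str]],
    rng: np.random.Generator,
    n_shuffles: int,
) -> pd.Series:
    """Permutation importance per original variable (dummy blocks permuted
    jointly), converted to ranks 1..v; ties keep variable order."""
    base_mse = float(np.mean((model.predict(X_test) - y_test) ** 2))
    importances = {}
    for var, cols in groups.items():
        deltas = []
        for _ in range(n_shuffles):
            Xp = X_test.copy()
            perm = rng.permutation(len(Xp))
            Xp[cols] = Xp[cols].to_numpy()[perm]
            mse = float(np.mean((model.predict(Xp) - y_test) ** 2))
            deltas.append(mse - base_mse)
        importances[var] = float(np.mean(deltas))
    imp = pd.Series(importances)
    # rank 1 = most important; ties broken by variable (insertion) order
    order = sorted(range(len(imp)), key=lambda i: (-imp.iloc[i], i))
    ranks = pd.Series(index=imp.index, dtype=float)
    for rank, i in enumerate(order, start=1):
        ranks.iloc[i] = rank
    return ranks


def screen_pfc(
    y: pd.Series,
    env: EnvironmentTable,
    cfg: ScreenConfig = ScreenConfig(),
    pfc_id: int | str = 0,
    seed: int | None = None,
) -> ScreenResult:
    """Run the repeated train/tune/test protocol for one cluster profile."""
    X, groups = encode_predictors(env)
    X = X.loc[y.index]
    n = len(y)
    n_train = train_size(n, cfg.train_fraction)
    grid = [min(m, X.shape[1]) for m in cfg.mtry_grid]
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    cv_r2s, test_r2s, rmses, rank_rows, best_mtries = [], [], [], [], []
    n_degenerate = 0
    for _ in range(cfg.n_repeats):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        X_train, y_train = X.iloc[train_idx], y.iloc[train_idx].to_numpy()
        X_test, y_test = X.iloc[test_idx], y.iloc[test_idx].to_numpy()
        if np.std(y_train) == 0:
            n_degenerate += 1
            cv_r2s.append(0.0)
            test_r2s.append(0.0)
            rmses.append(float(np.sqrt(np.mean((y_test - y_train.mean()) ** 2))))
            rank_rows.append(
                pd.Series({v: (len(groups) + 1) / 2 for v in groups})
            )
            best_mtries.append(grid[0])
            continue

        fold_seed = int(rng.integers(2**31))
        kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=fold_seed)
        splits = list(kf.split(X_train))
        best = None
        for mtry in grid:
            fold_rmse, fold_r2, fold_deg = [], [], 0
            for k, (tr, va) in enumerate(splits):
                model = _forest(cfg.n_trees, mtry, fold_seed + k)
                model.fit(X_train.iloc[tr], y_train[tr])
                pred = model.predict(X_train.iloc[va])
                fold_rmse.append(float(np.sqrt(np.mean((pred - y_train[va]) ** 2))))
                r2_k, deg_k = _r2(pred, y_train[va], cfg.r2_definition)
                fold_r2.append(r2_k)
                fold_deg += deg_k
            # resample-averaged metrics (per-fold, then mean over folds)
            rmse = float(np.mean(fold_rmse))
            if best is None or rmse < best[0]:
                best = (rmse, mtry, float(np.mean(fold_r2)), fold_deg)
        rmse, mtry, cv_r2, fold_deg = best
        if fold_deg:
            n_degenerate += 1
        model = _forest(cfg.n_trees, mtry, fold_seed + cfg.n_folds)
        model.fit(X_train, y_train)
        test_r2, _ = _r2(model.predict(X_test), y_test, cfg.r2_definition)
        ranks = _grouped_permutation_ranks(
            model, X_test, y_test, groups, rng, cfg.n_importance_shuffles
        )
        cv_r2s.append(cv_r2)
        test_r2s.append(test_r2)
        rmses.append(rmse)
        rank_rows.append(ranks)
        best_mtries.append(mtry)

    mean_rank = pd.concat(rank_rows, axis=1).mean(axis=1)
    mean_cv_r2 = float(np.mean(cv_r2s))
    return ScreenResult(
        pfc_id=pfc_id,
        mean_cv_r2=mean_cv_r2,
        mean_test_r2=float(np.mean(test_r2s)),
        mean_rmse=float(np.mean(rmses)),
        importance_rank=mean_rank,
        category=classify_link(mean_cv_r2, cfg),
        n_degenerate_repeats=n_degenerate,
        best_mtry=tuple(best_mtries),
    )


def screen_many(
    abundance: pd.DataFrame,
    env: EnvironmentTable,
    cfg: ScreenConfig = ScreenConfig(),
    seed: int | None = None,
) -> tuple[list[ScreenResult], list]:
    """Screen every row of a clusters x samples abundance matrix.

    Rows failing the near-zero-variance check are skipped and returned
    separately.  Each cluster gets an independent seed derived from the
    master, so results do not depend on screening order.
    """
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    results, skipped = [], []
    for cid in abundance.index:
        y = abundance.loc[cid, :]
        cluster_seed = int(master.integers(2**31))
        if nzv_flag(y.to_numpy()):
            skipped.append(cid)
            continue
        results.append(screen_pfc(y, env, cfg, pfc_id=cid, seed=cluster_seed))
    return results, skipped


def aggregate_importance(results: Iterable[ScreenResult]) -> pd.DataFrame:
    """Cross-model importance summary per environmental variable.

    ``times_rank1`` / ``times_top3`` count models where the variable is the
    most important / within the top 3 (by mean rank over repeats);
    ``mean_r2_when_best`` averages mean CV R-squared over models whose best
    variable is the focal one.
    """
    results = list(results)
    if not results:
        raise ValueError("no screen results to aggregate")
    variables = list(results[0].importance_rank.index)
    rows = {
        v: {"times_rank1": 0, "times_top3": 0, "rank_sum": 0.0, "r2_best": []}
        for v in variables
    }
    for res in results:
        ranks = res.importance_rank
        if list(ranks.index) != variables:
            raise ValueError("screen results have differing variable sets")
        best = ranks.idxmin()
        rows[best]["times_rank1"] += 1
        rows[best]["r2_best"].append(res.mean_cv_r2)
        for v in ranks.nsmallest(3).index:
            rows[v]["times_top3"] += 1
        for v in variables:
            rows[v]["rank_sum"] += float(ranks[v])
    out = pd.DataFrame(
        {
            "times_rank1": [rows[v]["times_rank1"] for v in variables],
            "times_top3": [rows[v]["times_top3"] for v in variables],
            "mean_rank": [rows[v]["rank_sum"] / len(results) for v in variables],
            "mean_r2_when_best": [
                float(np.mean(rows[v]["r2_best"])) if rows[v]["r2_best"] else np.nan
                for v in variables
            ],
        },
        index=pd.Index(variables, name="variable"),
    )
    return out


def results_to_frame(results: Iterable[ScreenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "pfc_id": r.pfc_id,
                "mean_cv_r2": r.mean_cv_r2,
                "mean_test_r2": r.mean_test_r2,
                "mean_rmse": r.mean_rmse,
                "category": r.category,
                "n_degenerate_repeats": r.n_degenerate_repeats,
                "encoding": r.encoding,
            }
        )
    return pd.DataFrame(rows).set_index("pfc_id")
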