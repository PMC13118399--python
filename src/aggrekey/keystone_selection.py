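"""Keystone module / genus selection and importance ranking.

A *keystone module* is a major co-occurrence module whose per-sample
abundance profile correlates (Spearman, p < alpha) with at least one of the
four aggregate-carbon responses (the C share of each size class).  Within a
keystone module, *keystone genera* are the highest-abundance members whose
cumulative share of the module's total abundance exceeds a configured
fraction (default 75%) and whose abundance differs among treatments
(Duncan's test).

Genera are then ranked against each carbon response with a bagged ensemble
of regression trees: importance is the mean increase in out-of-bag MSE when
a predictor is permuted (the %IncMSE convention), expressed as a percentage
of the out-of-bag MSE, with significance from refitting the ensemble on
permuted responses.  Variance explained is 1 - OOB-MSE / Var(response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .cooccurrence_network import CoocNetwork
from .group_stats import anova_duncan, spearman


def keystone_modules(profiles: pd.DataFrame, responses: pd.DataFrame,
                     major: tuple[str, ...],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Correlate module abundance profiles with aggregate-C responses.

    ``profiles``: modules x samples (z-scored abundances);
    ``responses``: samples x response columns (C share per size class).
    Returns one row per module with rho / p per response and a keystone
    flag: a major module with any response p < alpha.
    """
    if list(profiles.columns) != list(responses.index):
        raise ValueError("samples misaligned between profiles and responses")
    rows = {}
    for mod in profiles.index:
        row: dict[str, float | bool] = {}
        any_sig = False
        for col in responses.columns:
            rho, p = spearman(profiles.loc[mod], responses[col])
            row[f"rho:{col}"] = rho
            row[f"p:{col}"] = p
            any_sig = any_sig or p < alpha
        row["major"] = mod in major
        row["keystone"] = bool(row["major"] and any_sig)
        rows[mod] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def keystone_genera(module_members, network: CoocNetwork, design,
                    fraction: float = 0.75, alpha: float = 0.05) -> list[str]:
    """High-abundance, treatment-responsive genera of one keystone module.

    Members are sorted by mean relative abundance (descending, ties broken
    by genus id for determinism) and the smallest prefix whose cumulative
    share of the module total *exceeds* ``fraction`` is taken; within that
    prefix only genera with a significant Duncan split (not all treatments
    sharing one letter) are kept.
    """
    members = list(module_members)
    if not members:
        raise ValueError("empty module")
    means = network.abundances.loc[members].mean(axis=1)
    order = sorted(members, key=lambda g: (-means[g], g))
    total = means[order].sum()
    if total <= 0:
        raise ValueError("module has zero total abundance")
    cum = 0.0
    prefix: list[str] = []
    for g in order:
        prefix.append(g)
        cum += means[g] / total
        if cum > fraction:
            break
    selected = []
    for g in prefix:
        letters = anova_duncan(network.abundances.loc[g], design, alpha=alpha)
        if not letters.all_share_letter():
            selected.append(g)
    return selected


@dataclass
class ImportanceResult:
    """Per-predictor %IncMSE importance with permutation p-values."""

    table: pd.DataFrame          # index genus; importance_pct, p_value
    variance_explained: float    # 1 - OOB-MSE / Var(y)
    n_trees: int
    n_permutations: int


def _fit_bagged(x: np.ndarray, y: np.ndarray, n_trees: int,
                rng: np.random.Generator, max_features: float = 1 / 3):
    """Bootstrap ensemble of regression trees; returns (trees, oob lists).

    ``max_features`` follows the regression-forest convention of drawing
    about a third of the predictors per split, which keeps importance from
    collapsing onto one member of a correlated predictor clique; leaves
    hold at least five samples (the classical regression node size), which
    matters at the small n of a field experiment.
    """
    n = len(y)
    trees, oob = [], []
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        tree = DecisionTreeRegressor(max_features=max_features,
                                     min_samples_leaf=5,
                                     random_state=int(rng.integers(2 ** 31)))
        tree.fit(x[idx], y[idx])
        trees.append(tree)
        oob.append(np.flatnonzero(mask))
    return trees, oob


def _oob_stats(trees, oob, x: np.ndarray, y: np.ndarray,
               rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Raw per-predictor mean OOB MSE increase and the ensemble OOB MSE.

    The ensemble OOB MSE averages, per sample, the predictions of the trees
    that did not see it.
    """
    n, p = x.shape
    inc = np.zeros(p)
    base_sum = 0.0
    used = 0
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for tree, ob in zip(trees, oob):
        if len(ob) == 0:
            continue
        used += 1
        # one batched predict call: original OOB rows + p permuted copies
        xs = [x[ob]]
        for j in range(p):
            xp = x[ob].copy()
            xp[:, j] = xp[rng.permutation(len(ob)), j]
            xs.append(xp)
        preds = tree.predict(np.vstack(xs)).reshape(p + 1, len(ob))
        pred_sum[ob] += preds[0]
        pred_cnt[ob] += 1
        base = np.mean((y[ob] - preds[0]) ** 2)
        base_sum += base
        inc += np.mean((y[ob] - preds[1:]) ** 2, axis=1) - base
    if used == 0:
        raise RuntimeError("no out-of-bag samples; increase tree count")
    seen = pred_cnt > 0
    oob_mse = float(np.mean(
        (y[seen] - pred_sum[seen] / pred_cnt[seen]) ** 2))
    return inc / used, oob_mse


def importance_ranking(network: CoocNetwork, candidates, response: pd.Series,
                       n_trees: int = 500, n_permutations: int = 999,
                       seed: int | np.random.Generator = 0) -> ImportanceResult:
    """Rank candidate genera against one carbon response.

    Importance is the mean OOB MSE increase under predictor permutation,
    as a percentage of the ensemble OOB MSE; its p-value is the proportion
    of ``n_permutations`` response-permutation refits with importance at
    least as large (add-one corrected).
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate genera")
    x = network.abundances.loc[candidates].to_numpy().T
    y = response.loc[network.abundances.columns].to_numpy(dtype=float)
    if len(y) < 10:
        raise ValueError("need >= 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    rng = np.random.default_rng(seed)

    trees, oob = _fit_bagged(x, y, n_trees, rng)
    inc, oob_mse = _oob_stats(trees, oob, x, y, rng)
    importance = 100.0 * inc / oob_mse
    var_explained = 1.0 - oob_mse / y.var()

    exceed = np.zeros(len(candidates))
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        t_p, o_p = _fit_bagged(x, y_perm, n_trees, rng)
        inc_p, mse_p = _oob_stats(t_p, o_p, x, y_perm, rng)
        exceed += (100.0 * inc_p / mse_p) >= importance
    p_values = (1.0 + exceed) / (1.0 + n_permutations)

    table = pd.DataFrame(
        {"importance_pct": importance, "p_value": p_values},
        index=pd.Index(candidates, name="genus"))
    table = table.sort_values("importance_pct", ascending=False)
    return ImportanceResult(table=table, variance_explained=float(var_explained),
                            n_trees=n_trees, n_permutations=n_permutations)


def crucial_genera(rankings: dict[str, ImportanceResult],
                   alpha: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Union of genera with significant importance for any response.

    Returns (union list, long-format membership table with one row per
    significant genus x response pair).
    """
    rows = []
    for response_name, result in rankings.items():
        sig = result.table[result.table["p_value"] < alpha]
        for genus, row in sig.iterrows():
            rows.append({"genus": genus, "response": response_name,
                         "importance_pct": row["importance_pct"],
                         "p_value": row["p_value"]})
    membership = pd.DataFrame(
        rows, columns=["genus", "response", "importance_pct", "p_value"])
    union = sorted(membership["genus"].unique())
    return union, membership
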