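"""Locus scoring for age prediction: the four screening metrics.

Univariate F-regression, continuous-target mutual information (Kraskov
nearest-neighbour family), and young-vs-aged delta of the mean or variance.
F-regression only sees linear association; MI also captures non-monotone
(e.g. parabolic) age trajectories, which is why the two rank such loci very
differently.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_regression, mutual_info_regression

METHODS = ("f_regression", "mutual_information", "delta_mean", "delta_variance")


def _check(matrix: pd.DataFrame, ages) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if len(ages) != matrix.shape[1]:
        raise ValueError("ages length does not match sample count")
    return ages


def f_regression_scores(matrix: pd.DataFrame, ages) -> pd.Series:
    """Per-locus univariate F statistic of beta on age: F = (n-2) r^2/(1-r^2)."""
    ages = _check(matrix, ages)
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant")
    x = matrix.to_numpy(dtype=float)
    constant = np.ptp(x, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_regression(x.T, ages)
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    f_stat[constant] = 0.0
    return pd.Series(f_stat, index=matrix.index, name="f_regression")


def mutual_information_scores(
    matrix: pd.DataFrame,
    ages,
    k_neighbors: int = 3,
    chunk_fraction: float = 0.25,
    seed: int = 0,
) -> pd.Series:
    """Nearest-neighbour MI estimate between each locus and age (nats).

    Loci are processed ``chunk_fraction`` at a time; chunking only bounds
    memory — each locus's estimate depends on that locus and age alone.
    """
    ages = _check(matrix, ages)
    n = matrix.shape[1]
    if n < 20:
        raise ValueError("need at least 20 samples for MI estimation")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n={n}")
    x = matrix.to_numpy(dtype=float).T  # samples x loci
    n_loci = matrix.shape[0]
    chunk = max(1, math.ceil(n_loci * chunk_fraction))
    out = np.empty(n_loci)
    for start in range(0, n_loci, chunk):
        out[start : start + chunk] = mutual_info_regression(
            x[:, start : start + chunk],
            ages,
            n_neighbors=k_neighbors,
            random_state=seed,
        )
    return pd.Series(out, index=matrix.index, name="mutual_information")


def delta_group_scores(
    matrix: pd.DataFrame,
    ages,
    stat: str = "mean",
    young: tuple[float, float] = (25.0, 35.0),
    aged: tuple[float, float] = (65.0, 100.0),
) -> pd.Series:
    """|stat(aged window) - stat(young window)| per locus, stat in {mean, variance}."""
    if stat not in ("mean", "variance"):
        raise ValueError(f"stat must be 'mean' or 'variance': {stat}")
    ages = _check(matrix, ages)
    young_mask = (ages >= young[0]) & (ages <= young[1])
    aged_mask = (ages >= aged[0]) & (ages <= aged[1])
    for name, mask, window in [("young", young_mask, young), ("aged", aged_mask, aged)]:
        if not mask.any():
            raise ValueError(f"{name} age window {window} contains no samples")
    x = matrix.to_numpy(dtype=float)
    if stat == "mean":
        score = np.abs(x[:, aged_mask].mean(axis=1) - x[:, young_mask].mean(axis=1))
    else:
        score = np.abs(
            x[:, aged_mask].var(axis=1, ddof=1) - x[:, young_mask].var(axis=1, ddof=1)
        )
    return pd.Series(score, index=matrix.index, name=f"delta_{stat}")


def top_fraction(scores: pd.Series, fraction: float = 0.20) -> list[str]:
    """The ceil(fraction * n) best-scoring loci; threshold ties break by locus id."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1]: {fraction}")
    n_keep = math.ceil(fraction * len(scores))
    order = scores.to_frame("score").reset_index()
    order.columns = ["locus_id", "score"]
    order = order.sort_values(
        ["score", "locus_id"], ascending=[False, True], kind="stable"
    )
    return order["locus_id"].head(n_keep).tolist()


def score_table(matrix: pd.DataFrame, ages, methods=METHODS, seed: int = 0) -> pd.DataFrame:
    """Long-format table (locus_id, method, score, rank) over the given methods."""
    parts = []
    for method in methods:
        if method == "f_regression":
            s = f_regression_scores(matrix, ages)
        elif method == "mutual_information":
            s = mutual_information_scores(matrix, ages, seed=seed)
        elif method == "delta_mean":
            s = delta_group_scores(matrix, ages, stat="mean")
        elif method == "delta_variance":
            s = delta_group_scores(matrix, ages, stat="variance")
        else:
            raise ValueError(f"unknown method {method!r}")
        df = s.rename("score").to_frame().reset_index(names="locus_id")
        df["method"] = method
        df["rank"] = df["score"].rank(ascending=False, method="min").astype(int)
        parts.append(df[["locus_id", "method", "score", "rank"]])
    return pd.concat(parts, ignore_index=True)
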