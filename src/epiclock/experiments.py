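"""Clock meta-experiments: iterative knockout, transfer matrices, concordance.

The knockout (depletion) experiment asks how many distinct predictive loci
the methylome contains: train several clocks, remove every locus any of
them used, retrain on the remainder, and repeat until prediction collapses.
Transfer matrices train a clock per group (tissue or age bin) and evaluate
every train/test pair, with the diagonal always on held-out samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .clock import ClockMetrics, ClockModel, TrainingConfig, evaluate, predict_ages, train_clock

DEFAULT_AGE_BINS = {"young": (25.0, 50.0), "middle": (50.0, 75.0), "aged": (75.0, 100.0)}


@dataclass
class DepletionCurve:
    rounds: pd.DataFrame  # round, removed_locus_count, cumulative_removed_fraction, r, rmse, mad
    removed_sets: list[set[str]]
    n_pool_initial: int


@dataclass
class CrossMatrix:
    grouping: str
    groups: list[str]
    metrics: dict[tuple[str, str], ClockMetrics]
    models: dict[str, ClockModel]

    def table(self, field: str = "pearson_r") -> pd.DataFrame:
        data = {
            test: {train: getattr(self.metrics[(train, test)], field) for train in self.groups}
            for test in self.groups
        }
        return pd.DataFrame(data).loc[self.groups, self.groups]


@dataclass
class ConcordanceMatrix:
    correlations: pd.DataFrame  # model x model, NaN where undefined
    shared_counts: pd.DataFrame
    loci_considered: list[str]


def _split_train_test(
    sample_ids: list[str], test_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    ids = np.array(sample_ids)
    rng.shuffle(ids)
    n_test = max(1, int(round(test_fraction * len(ids))))
    return list(ids[n_test:]), list(ids[:n_test])


def run_depletion(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    config: TrainingConfig,
    models_per_round: int = 5,
    test_fraction: float = 0.25,
    max_rounds: int | None = None,
    reduce: str = "mean",
) -> DepletionCurve:
    """Iteratively remove all clock-selected loci and retrain.

    Each round fits ``models_per_round`` clocks with distinct seeds on the
    surviving locus pool (train split fixed before round 1), records the
    mean (or best) test metrics, and removes the union of all nonzero loci.
    Stops when the pool empties, a round selects no loci, or ``max_rounds``.
    """
    if reduce not in ("mean", "best"):
        raise ValueError("reduce must be 'mean' or 'best'")
    pool = list(config.feature_pool) if config.feature_pool else list(matrix.index)
    if not pool:
        raise ValueError("initial locus pool is empty")
    rng = np.random.default_rng(config.seed)
    train_ids, test_ids = _split_train_test(list(matrix.columns), test_fraction, rng)
    assert not set(train_ids) & set(test_ids)
    n_pool0 = len(pool)
    test_matrix = matrix[test_ids]
    test_ages = samples.loc[test_ids, "age"].to_numpy(dtype=float)

    rows, removed_sets = [], []
    round_index = 0
    while pool:
        if max_rounds is not None and round_index >= max_rounds:
            break
        removed_this_round: set[str] = set()
        metrics_this_round = []
        for m in range(models_per_round):
            cfg = replace(
                config,
                seed=int(config.seed + 1000 * round_index + m + 1),
                feature_pool=pool,
            )
            model = train_clock(matrix[train_ids], samples.loc[train_ids], cfg)
            removed_this_round |= set(model.loci)
            pred = predict_ages(model, test_matrix)
            metrics_this_round.append(evaluate(pred.to_numpy(), test_ages))
        if reduce == "mean":
            r = float(np.mean([m.pearson_r for m in metrics_this_round]))
            rmse = float(np.mean([m.rmse for m in metrics_this_round]))
            mad = float(np.mean([m.mad for m in metrics_this_round]))
        else:
            best = max(metrics_this_round, key=lambda m: m.pearson_r)
            r, rmse, mad = best.pearson_r, best.rmse, best.mad
        removed_sets.append(removed_this_round)
        cum_removed = sum(len(s) for s in removed_sets)
        rows.append(
            {
                "round": round_index,
                "removed_locus_count": len(removed_this_round),
                "cumulative_removed_fraction": cum_removed / n_pool0,
                "pearson_r": r,
                "rmse": rmse,
                "mad": mad,
                "pool_remaining": len(pool) - len(removed_this_round),
            }
        )
        pool = [l for l in pool if l not in removed_this_round]
        round_index += 1
        if not removed_this_round:
            break
    return DepletionCurve(
        rounds=pd.DataFrame(rows), removed_sets=removed_sets, n_pool_initial=n_pool0
    )


def assign_age_bins(
    samples: pd.DataFrame, bins: dict[str, tuple[float, float]] = DEFAULT_AGE_BINS
) -> pd.Series:
    """Bin label per sample; right-open intervals except the last (by upper edge)."""
    ordered = sorted(bins.items(), key=lambda kv: kv[1][0])
    labels = pd.Series(index=samples.index, dtype=object)
    last = ordered[-1][0]
    for name, (lo, hi) in ordered:
        ages = samples["age"]
        mask = (ages >= lo) & ((ages <= hi) if name == last else (ages < hi))
        labels[mask] = name
    return labels


def cross_group_matrix(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    grouping: str,
    config: TrainingConfig,
    bins: dict[str, tuple[float, float]] = DEFAULT_AGE_BINS,
    test_fraction: float = 0.25,
    min_group_size: int | None = None,
) -> CrossMatrix:
    """Train one clock per group, test on every group (held-out on diagonal)."""
    if grouping == "tissue":
        labels = samples["tissue"].astype(str)
    elif grouping == "age_bin":
        labels = assign_age_bins(samples, bins)
    else:
        raise ValueError(f"grouping must be 'tissue' or 'age_bin': {grouping}")
    min_size = min_group_size if min_group_size is not None else 2 * config.cv_folds
    groups = []
    for g in sorted(labels.dropna().unique()):
        n_g = int((labels == g).sum())
        if n_g < min_size:
            import warnings

            warnings.warn(f"group {g!r} has {n_g} samples (< {min_size}); excluded")
            continue
        groups.append(g)
    if not groups:
        raise ValueError("no group meets the minimum size")

    split: dict[str, tuple[list[str], list[str]]] = {}
    for g in groups:
        # per-group seed derived from the label, so results do not depend on
        # group processing order or on which other groups are present
        g_digest = int.from_bytes(hashlib.sha256(str(g).encode()).digest()[:4], "little")
        rng = np.random.default_rng([config.seed, g_digest])
        ids = sorted(samples.index[labels == g])
        split[g] = _split_train_test(ids, test_fraction, rng)

    models: dict[str, ClockModel] = {}
    metrics: dict[tuple[str, str], ClockMetrics] = {}
    for g in groups:
        train_ids, _ = split[g]
        models[g] = train_clock(matrix[train_ids], samples.loc[train_ids], config)
    for train_g in groups:
        for test_g in groups:
            if train_g == test_g:
                test_ids = split[test_g][1]
            else:
                test_ids = split[test_g][0] + split[test_g][1]
            pred = predict_ages(models[train_g], matrix[test_ids])
            actual = samples.loc[test_ids, "age"].to_numpy(dtype=float)
            metrics[(train_g, test_g)] = evaluate(pred.to_numpy(), actual)
    return CrossMatrix(grouping=grouping, groups=groups, metrics=metrics, models=models)


def coefficient_concordance(
    models: list[ClockModel], min_models_shared: int = 3, min_shared_loci: int = 3
) -> ConcordanceMatrix:
    """Pairwise Pearson correlation of coefficients over recurrent clock loci.

    Only loci nonzero in >= ``min_models_shared`` models are considered;
    each pair correlates over its mutually nonzero subset of those loci.
    Cells with fewer than ``min_shared_loci`` shared loci are NaN-flagged.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    names = [f"model_{i}" for i in range(len(models))]
    counts: dict[str, int] = {}
    for m in models:
        for l in m.loci:
            counts[l] = counts.get(l, 0) + 1
    considered = sorted(l for l, c in counts.items() if c >= min_models_shared)

    corr = pd.DataFrame(np.nan, index=names, columns=names)
    shared = pd.DataFrame(0, index=names, columns=names)
    for i, j in combinations(range(len(models)), 2):
        common = [
            l
            for l in considered
            if l in models[i].coefficients and l in models[j].coefficients
        ]
        shared.iloc[i, j] = shared.iloc[j, i] = len(common)
        if len(common) >= min_shared_loci:
            wi = np.array([models[i].coefficients[l] for l in common])
            wj = np.array([models[j].coefficients[l] for l in common])
            if np.ptp(wi) > 0 and np.ptp(wj) > 0:
                r = float(pearsonr(wi, wj).statistic)
                corr.iloc[i, j] = corr.iloc[j, i] = r
    for i in range(len(models)):
        own = [l for l in considered if l in models[i].coefficients]
        shared.iloc[i, i] = len(own)
        if len(own) >= min_shared_loci:
            corr.iloc[i, i] = 1.0
    return ConcordanceMatrix(
        correlations=corr, shared_counts=shared, loci_considered=considered
    )


def overlap_counts(models: list[ClockModel]) -> pd.DataFrame:
    """Exclusive intersection sizes over every subset of models (UpSet counts)."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    union = set()
    for m in models:
        union |= set(m.loci)
    rows = []
    membership = {l: tuple(l in m.coefficients for m in models) for l in union}
    n = len(models)
    from itertools import product

    for pattern in product([False, True], repeat=n):
        if not any(pattern):
            continue
        count = sum(1 for v in membership.values() if v == pattern)
        rows.append(
            {
                "models": ",".join(str(i) for i, p in enumerate(pattern) if p),
                "degree": sum(pattern),
                "count": count,
            }
        )
    df = pd.DataFrame(rows)
    assert df["count"].sum() == len(union)
    return df
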