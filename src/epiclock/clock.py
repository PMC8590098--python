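"""Elastic-net epigenetic clock training, prediction and evaluation.

A clock is a sparse linear model of transformed age on beta values:
minimise ||y - Xw||^2/(2n) + alpha * (l1_ratio * ||w||_1
+ (1 - l1_ratio)/2 * ||w||_2^2), with alpha chosen by k-fold
cross-validation over a log-spaced penalty path and l1_ratio fixed at 0.5.
Predictions are inverse-transformed back to years before evaluation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, StratifiedKFold

from .preprocess import AgeTransform, inverse_transform_age, transform_age


@dataclass
class TrainingConfig:
    l1_ratio: float = 0.5
    cv_folds: int = 10
    n_alphas: int = 20
    alpha_eps: float = 1e-3  # alpha_min / alpha_max of the log-spaced path
    selection_rule: str = "1se"  # "1se" (glmnet lambda.1se style) or "min"
    seed: int = 0
    feature_pool: list[str] | None = None
    adult_age: float = 20.0
    transform: bool = True  # fit on transformed age (raw-age fitting for ablation)
    max_iter: int = 3000

    def __post_init__(self):
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError(f"l1_ratio must be in [0, 1]: {self.l1_ratio}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2: {self.cv_folds}")


@dataclass
class ClockModel:
    """Sparse linear age predictor on the transformed-age scale."""

    intercept: float
    coefficients: dict[str, float]  # locus_id -> weight, nonzero only
    age_transform: AgeTransform
    transform: bool = True
    provenance: dict = field(default_factory=dict)

    @property
    def loci(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "age_transform": {"adult_age": self.age_transform.adult_age},
                "transform": self.transform,
                "provenance": self.provenance,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClockModel":
        d = json.loads(text)
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            age_transform=AgeTransform(d["age_transform"]["adult_age"]),
            transform=bool(d.get("transform", True)),
            provenance=d.get("provenance", {}),
        )


@dataclass
class ClockMetrics:
    pearson_r: float
    rmse: float
    mad: float  # median absolute error, years
    n: int
    constant_prediction: bool = False


def _age_strata(ages: np.ndarray, n_folds: int) -> np.ndarray:
    """Age-quartile labels for stratified CV folds (degrades to fewer bins)."""
    qs = np.quantile(ages, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, ages)


def train_clock(
    matrix: pd.DataFrame, samples: pd.DataFrame, config: TrainingConfig
) -> ClockModel:
    """Fit an elastic-net clock; deterministic given the config seed."""
    pool = config.feature_pool
    if pool is not None:
        missing = set(pool) - set(matrix.index)
        if missing:
            raise ValueError(f"feature_pool loci absent from matrix: {sorted(missing)[:5]}")
        matrix = matrix.loc[list(pool)]
    if len(samples) < config.cv_folds:
        raise ValueError(
            f"need >= cv_folds={config.cv_folds} samples, got {len(samples)}"
        )
    x = matrix.to_numpy(dtype=float).T  # samples x loci
    if np.all(np.ptp(x, axis=0) == 0):
        raise ValueError("all features are constant")
    ages = samples.loc[matrix.columns, "age"].to_numpy(dtype=float)
    t = AgeTransform(config.adult_age)
    y = transform_age(ages, t) if config.transform else ages

    strata = _age_strata(ages, config.cv_folds)
    if np.bincount(strata).min() >= config.cv_folds:
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**31)
        )
        splits = list(skf.split(x, strata))
    else:  # too few samples per age quartile to stratify
        kf = KFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**31)
        )
        splits = list(kf.split(x))

    if config.selection_rule not in ("1se", "min"):
        raise ValueError(f"unknown selection_rule {config.selection_rule!r}")
    cv_model = ElasticNetCV(
        l1_ratio=config.l1_ratio,
        alphas=config.n_alphas,  # int: length of the log-spaced path
        eps=config.alpha_eps,
        cv=splits,
        max_iter=config.max_iter,
        random_state=config.seed % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv_model.fit(x, y)
        if config.selection_rule == "1se":
            # largest penalty whose CV error is within one standard error of
            # the minimum: a sparser model statistically tied with the best
            mse = cv_model.mse_path_.mean(axis=-1)
            se = cv_model.mse_path_.std(axis=-1, ddof=1) / np.sqrt(
                cv_model.mse_path_.shape[-1]
            )
            best = int(np.argmin(mse))
            threshold = mse[best] + se[best]
            eligible = np.where(mse <= threshold)[0]
            # alphas_ is decreasing: the smallest index is the largest alpha
            alpha = float(cv_model.alphas_[int(eligible.min())])
        else:
            alpha = float(cv_model.alpha_)
        model = ElasticNet(
            alpha=alpha, l1_ratio=config.l1_ratio, max_iter=config.max_iter
        )
        model.fit(x, y)

    coefs = {
        locus: float(w)
        for locus, w in zip(matrix.index, model.coef_)
        if w != 0.0
    }
    sample_hash = hashlib.sha256(
        ",".join(map(str, matrix.columns)).encode()
    ).hexdigest()[:16]
    return ClockModel(
        intercept=float(model.intercept_),
        coefficients=coefs,
        age_transform=t,
        transform=config.transform,
        provenance={
            "seed": config.seed,
            "alpha": alpha,
            "selection_rule": config.selection_rule,
            "n_samples": len(samples),
            "sample_hash": sample_hash,
            "tissues": sorted(samples["tissue"].unique().tolist())
            if "tissue" in samples
            else [],
            "age_range": [float(ages.min()), float(ages.max())],
        },
    )


def predict_ages(model: ClockModel, matrix: pd.DataFrame) -> pd.Series:
    """Apply a clock to a beta matrix, returning predicted age in years."""
    missing = [l for l in model.loci if l not in matrix.index]
    if missing:
        raise ValueError(f"matrix lacks {len(missing)} model loci: {missing[:5]}")
    vals = matrix.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("beta values outside [0, 1]")
    score = np.full(matrix.shape[1], model.intercept)
    if model.loci:
        sub = matrix.loc[model.loci].to_numpy(dtype=float)
        w = np.array([model.coefficients[l] for l in model.loci])
        score = score + w @ sub
    years = (
        inverse_transform_age(score, model.age_transform)
        if model.transform
        else score
    )
    return pd.Series(np.atleast_1d(years), index=matrix.columns, name="predicted_age")


def evaluate(pred, actual) -> ClockMetrics:
    """Pearson r, RMSE (years) and median absolute error (years)."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.size < 3:
        raise ValueError("pred and actual must be equal-length with n >= 3")
    err = pred - actual
    rmse = float(np.sqrt(np.mean(err**2)))
    mad = float(np.median(np.abs(err)))
    constant = np.ptp(pred) == 0 or np.ptp(actual) == 0
    r = 0.0 if constant else float(pearsonr(pred, actual).statistic)
    return ClockMetrics(
        pearson_r=r, rmse=rmse, mad=mad, n=pred.size, constant_prediction=constant
    )
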