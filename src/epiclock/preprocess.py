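"""Sample filtering, age transformation, imputation and batch correction.

The age transform is the standard piecewise log/linear map used for clock
fitting: logarithmic below ``adult_age`` (compressing development) and
linear above it, continuous and differentiable at the knot, with an exact
inverse.  KNN imputation works locus-wise in chunks (large arrays cannot be
held as all-pairs distance matrices).  Batch correction is the parametric
empirical-Bayes location/scale model (ComBat) applied on the logit scale,
protecting listed covariates such as age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import ks_2samp
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Age transformation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeTransform:
    """Piecewise log/linear age map with knot at ``adult_age`` (years).

    forward(a) = log(a + 1) - log(adult_age + 1)        for a <= adult_age
               = (a - adult_age) / (adult_age + 1)      for a >  adult_age
    """

    adult_age: float = 20.0

    def __post_init__(self):
        if self.adult_age <= 0:
            raise ValueError(f"adult_age must be positive: {self.adult_age}")


def transform_age(age, t: AgeTransform = AgeTransform()):
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be nonnegative")
    a0 = t.adult_age
    out = np.where(
        age <= a0,
        np.log1p(age) - np.log1p(a0),
        (age - a0) / (a0 + 1.0),
    )
    return float(out) if out.ndim == 0 else out


def inverse_transform_age(x, t: AgeTransform = AgeTransform()):
    x = np.asarray(x, dtype=float)
    a0 = t.adult_age
    out = np.where(
        x <= 0,
        np.expm1(x + np.log1p(a0)),
        x * (a0 + 1.0) + a0,
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Sample filtering
# ---------------------------------------------------------------------------


def filter_adults(samples: pd.DataFrame, min_age: float = 25.0) -> pd.DataFrame:
    """Keep samples with age >= min_age (development excluded), order preserved."""
    if "age" not in samples.columns:
        raise ValueError("sample table has no age column")
    kept = samples[samples["age"] >= min_age]
    if kept.empty:
        raise ValueError(
            f"no samples remain after age >= {min_age} filter "
            f"(started with {len(samples)})"
        )
    logger.info("filter_adults: kept %d of %d samples", len(kept), len(samples))
    return kept.copy()


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------


def knn_impute(
    matrix: pd.DataFrame, k: int = 10, chunk_size: int = 120_000
) -> pd.DataFrame:
    """Impute missing betas from the k nearest loci, in chunks of loci.

    Distances are NaN-aware Euclidean over samples (pairwise-complete,
    rescaled to the full sample count); donor loci are the k nearest rows
    with an observed value in the target sample, averaged uniformly.
    Chunking changes only which loci are co-considered.  Rows that cannot
    be imputed (e.g. all-missing) fall back to the per-sample chunk mean.
    """
    if not matrix.isna().any().any():
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    out = np.empty_like(values)
    for start in range(0, len(values), chunk_size):
        chunk = values[start : start + chunk_size].copy()
        # samples with no observed value anywhere in the chunk would be
        # dropped by the imputer; pre-fill them from locus means
        dead_cols = np.all(np.isnan(chunk), axis=0)
        if dead_cols.any():
            logger.warning(
                "knn_impute: %d samples all-missing in a chunk; locus-mean filled",
                int(dead_cols.sum()),
            )
            row_mean = np.nanmean(chunk, axis=1)
            chunk[:, dead_cols] = row_mean[:, None]
        dead_rows = np.all(np.isnan(chunk), axis=1)
        if dead_rows.any():
            logger.warning(
                "knn_impute: %d all-missing loci fell back to chunk means",
                int(dead_rows.sum()),
            )
        # rows are loci: each missing entry is imputed from the k nearest
        # loci (NaN-aware Euclidean over samples) observed in that sample
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        out[start : start + chunk_size] = imputer.fit_transform(chunk)
    out = np.clip(out, 0.0, 1.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# ComBat batch correction (parametric empirical Bayes), on the logit scale
# ---------------------------------------------------------------------------

_LOGIT_EPS = 1e-4


def _combat_parametric(
    data: np.ndarray, batch: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """Parametric EB location/scale adjustment (features x samples)."""
    batches, batch_idx = np.unique(batch, return_inverse=True)
    n_batch = len(batches)
    n_features, n_samples = data.shape
    counts = np.bincount(batch_idx)

    design_cols = [np.eye(n_batch)[batch_idx]]
    if covariates is not None and covariates.size:
        design_cols.append(covariates)
    design = np.column_stack(design_cols)

    beta_hat, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    grand_mean = (counts / n_samples) @ beta_hat[:n_batch]
    fitted = design @ beta_hat
    var_pooled = np.mean((data.T - fitted) ** 2, axis=0)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = np.tile(grand_mean, (n_samples, 1))
    if covariates is not None and covariates.size:
        stand_mean = stand_mean + covariates @ beta_hat[n_batch:]
    z = (data.T - stand_mean) / np.sqrt(var_pooled)
    z = z.T  # features x samples

    gamma_hat = np.vstack(
        [z[:, batch_idx == i].mean(axis=1) for i in range(n_batch)]
    )
    delta_hat = np.vstack(
        [z[:, batch_idx == i].var(axis=1, ddof=1) for i in range(n_batch)]
    )

    # method-of-moments hyperpriors
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    v = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * s2 + v**2) / np.maximum(s2, 1e-12)
    b_prior = (v * s2 + v**3) / np.maximum(s2, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i in range(n_batch):
        n_i = counts[i]
        g_new = gamma_hat[i].copy()
        d_new = delta_hat[i].copy()
        zi = z[:, batch_idx == i]
        for _ in range(100):
            g_old, d_old = g_new, d_new
            g_new = (tau2[i] * n_i * gamma_hat[i] + d_old * gamma_bar[i]) / (
                tau2[i] * n_i + d_old
            )
            sum2 = ((zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior[i]) / (n_i / 2.0 + a_prior[i] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            if change < 1e-4:
                break
        gamma_star[i] = g_new
        delta_star[i] = d_new

    adjusted = z.copy()
    for i in range(n_batch):
        cols = batch_idx == i
        adjusted[:, cols] = (z[:, cols] - gamma_star[i][:, None]) / np.sqrt(
            np.maximum(delta_star[i][:, None], 1e-12)
        )
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean.T
    return adjusted


def correct_batches(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Remove per-batch location/scale effects while protecting covariates.

    Betas are logit-transformed, adjusted with the parametric
    empirical-Bayes model, and back-transformed; listed numeric covariates
    (default ``["age"]``) enter the standardisation design so their signal
    survives correction.
    """
    covariates = ["age"] if covariates is None else covariates
    if matrix.isna().any().any():
        raise ValueError("correct_batches requires a complete (imputed) matrix")
    batch = samples.loc[matrix.columns, "batch"].to_numpy()
    uniq, counts = np.unique(batch, return_counts=True)
    if len(uniq) < 2:
        warnings.warn("single batch: returning matrix unchanged")
        return matrix.copy()
    if counts.min() < 2:
        raise ValueError("every batch needs at least 2 samples")

    cov = None
    if covariates:
        cov = samples.loc[matrix.columns, covariates].to_numpy(dtype=float)
        for j, name in enumerate(covariates):
            within = [np.var(cov[batch == b, j]) for b in uniq]
            if max(within) == 0.0:
                raise ValueError(
                    f"covariate {name!r} is constant within every batch "
                    "(confounded 1:1 with batch); cannot protect it"
                )
        cov = cov - cov.mean(axis=0)

    y = logit(np.clip(matrix.to_numpy(dtype=float), _LOGIT_EPS, 1 - _LOGIT_EPS))
    adjusted = _combat_parametric(y, batch, cov)
    out = expit(adjusted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Beta-distribution outlier flagging
# ---------------------------------------------------------------------------


def flag_distribution_outliers(
    matrix: pd.DataFrame, threshold: float | None = None
) -> pd.Series:
    """Flag samples whose beta distribution departs from the cohort's.

    The per-sample statistic is the two-sample Kolmogorov-Smirnov distance
    between the sample's beta values and the cohort's per-locus median
    profile.  With ``threshold=None`` the cut is cohort-relative: median
    distance + 10 x IQR, so a homogeneous cohort yields no flags while a
    sample from a different distribution stands far outside the spread.
    Samples are flagged, never dropped.
    """
    if matrix.isna().any().any():
        raise ValueError("flag_distribution_outliers requires a complete matrix")
    reference = matrix.median(axis=1).to_numpy()
    stats = {}
    for sample in matrix.columns:
        stats[sample] = ks_2samp(matrix[sample].to_numpy(), reference).statistic
    s = pd.Series(stats, name="ks_distance")
    if threshold is None:
        q1, q3 = np.percentile(s, [25, 75])
        threshold = float(np.median(s) + 10 * max(q3 - q1, 1e-6))
    flags = s > threshold
    if flags.any():
        logger.info(
            "flag_distribution_outliers: flagged %d of %d samples",
            int(flags.sum()),
            len(flags),
        )
    return flags
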