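"""Per-locus age x tissue association and trajectory shape analysis.

Each locus is fit with the OLS model ``methylation ~ age + tissue +
age:tissue`` (tissue categorical, full interaction).  Term-level p-values
come from partial F-tests of nested models (type-II sums of squares with
the full-model residual as denominator), so a locus can be classed as
tissue-only, age-only, both with/without interaction, or null after
per-term Benjamini-Hochberg correction.  Because every locus shares one
design matrix, all loci are fit simultaneously with one QR decomposition
per nested design.

Trajectory analysis smooths each locus with lowess and counts qualifying
turning points (direction changes whose flanking amplitude exceeds a noise
tolerance), classifying trajectories as linear, non-monotone, or flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import f as f_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

TERMS = ("age", "tissue", "age:tissue")
CLASSES = ("tissue_only", "age_only", "both_interaction", "both_no_interaction", "none")


def _rss(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of y on the design (QR)."""
    q, _ = np.linalg.qr(design)
    resid = y - q @ (q.T @ y)
    return np.sum(resid**2, axis=0)


def fit_locus_models(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Vectorised OLS ``beta ~ age + tissue + age:tissue`` for every locus.

    Returns a table indexed by locus with per-term p-values
    (``p_age``, ``p_tissue``, ``p_interaction``) and per-tissue Pearson
    correlations of beta with age (``r_<tissue>``).
    """
    samples = samples.loc[matrix.columns]
    counts = samples["tissue"].value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        import warnings

        warnings.warn(f"dropping single-sample tissues: {singletons}")
        keep = ~samples["tissue"].isin(singletons)
        samples = samples[keep]
        matrix = matrix.loc[:, samples.index]
    tissues = sorted(samples["tissue"].unique())
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues with >= 2 samples")
    age = samples["age"].to_numpy(dtype=float)
    for t in tissues:
        if np.ptp(age[(samples["tissue"] == t).to_numpy()]) == 0:
            raise ValueError(f"tissue {t!r} has a degenerate age range")

    n = len(samples)
    dummies = np.column_stack(
        [(samples["tissue"] == t).to_numpy(float) for t in tissues[1:]]
    )
    ones = np.ones((n, 1))
    x_age = age[:, None]
    x_inter = dummies * age[:, None]

    d_full = np.column_stack([ones, x_age, dummies, x_inter])
    d_main = np.column_stack([ones, x_age, dummies])
    d_tissue = np.column_stack([ones, dummies])
    d_age = np.column_stack([ones, x_age])

    y = matrix.to_numpy(dtype=float).T  # samples x loci
    rss_full = _rss(d_full, y)
    rss_main = _rss(d_main, y)
    rss_tissue = _rss(d_tissue, y)
    rss_age = _rss(d_age, y)

    p_full = d_full.shape[1]
    if np.linalg.matrix_rank(d_full) < p_full:
        raise ValueError("rank-deficient design (tissue confounded with age?)")
    df_resid = n - p_full
    mse_full = rss_full / df_resid

    df_t = len(tissues) - 1

    def term_p(ss_term: np.ndarray, df_term: int) -> np.ndarray:
        f_stat = (ss_term / df_term) / np.maximum(mse_full, 1e-300)
        return f_dist.sf(f_stat, df_term, df_resid)

    p_age = term_p(np.maximum(rss_tissue - rss_main, 0), 1)
    p_tis = term_p(np.maximum(rss_age - rss_main, 0), df_t)
    p_int = term_p(np.maximum(rss_main - rss_full, 0), df_t)

    out = pd.DataFrame(
        {"p_age": p_age, "p_tissue": p_tis, "p_interaction": p_int},
        index=matrix.index,
    )
    for t in tissues:
        mask = (samples["tissue"] == t).to_numpy()
        yt = y[mask]
        at = age[mask]
        yc = yt - yt.mean(axis=0)
        ac = at - at.mean()
        denom = np.sqrt(np.sum(yc**2, axis=0) * np.sum(ac**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"r_{t}"] = np.where(denom > 0, (ac @ yc) / denom, np.nan)
    return out


def adjust_fdr(pvals, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if p.size == 0:
        return p
    return multipletests(p, alpha=q, method="fdr_bh")[1]


def classify_loci(assoc: pd.DataFrame, alpha_q: float = 0.05) -> pd.DataFrame:
    """Assign each locus one class from its per-term BH q-values.

    Each term (age, tissue, interaction) forms its own BH family, and the
    BH decision rule is q <= alpha.  A significant interaction implies age
    and tissue are jointly involved (hierarchical principle), so such loci
    class as both_interaction; otherwise both significant main effects give
    both_no_interaction, a single one age_only / tissue_only, else none.
    """
    out = assoc.copy()
    out["q_age"] = adjust_fdr(assoc["p_age"].to_numpy(), alpha_q)
    out["q_tissue"] = adjust_fdr(assoc["p_tissue"].to_numpy(), alpha_q)
    out["q_interaction"] = adjust_fdr(assoc["p_interaction"].to_numpy(), alpha_q)
    sig_a = out["q_age"] <= alpha_q
    sig_t = out["q_tissue"] <= alpha_q
    sig_i = out["q_interaction"] <= alpha_q
    cls = np.full(len(out), "none", dtype=object)
    cls[sig_a & ~sig_t] = "age_only"
    cls[~sig_a & sig_t] = "tissue_only"
    cls[sig_a & sig_t] = "both_no_interaction"
    cls[sig_i] = "both_interaction"
    out["class"] = cls
    return out


@dataclass
class TrajectoryFit:
    locus_id: str
    slope: float  # beta-units per year, linear fit
    intercept: float
    grid: np.ndarray
    smoothed: np.ndarray
    turning_ages: list[float]
    shape: str  # linear | non_monotone | flat
    noise_tolerance: float

    @property
    def turning_point_count(self) -> int:
        return len(self.turning_ages)


def fit_trajectory(
    values,
    ages,
    span: float = 0.5,
    noise_tolerance: float | None = None,
    locus_id: str = "",
    grid_step: float = 1.0,
) -> TrajectoryFit:
    """Lowess-smooth one locus over age and classify its trajectory shape.

    Turning points are extrema of the smoothed curve with prominence above
    ``noise_tolerance``.  The default tolerance scales with the noise floor
    of the *smoothed* curve, not the per-sample scatter: 6 x resid_sd /
    sqrt(span x n), where resid_sd is the residual sd of the linear fit —
    a lowess window averages about span*n points, so its standard error is
    resid_sd / sqrt(span*n).  flat: total smoothed range below tolerance;
    linear: no qualifying turning point; non_monotone: otherwise.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.size < 20:
        raise ValueError("need >= 20 samples")
    if np.ptp(ages) < 30:
        raise ValueError("need an age span of >= 30 years")
    slope, intercept = np.polyfit(ages, values, 1)
    resid_sd = float(np.std(values - (slope * ages + intercept)))
    if noise_tolerance is None:
        tol = 6.0 * resid_sd / np.sqrt(span * values.size)
    else:
        tol = float(noise_tolerance)

    grid = np.arange(ages.min(), ages.max() + grid_step / 2, grid_step)
    smoothed = lowess(values, ages, frac=span, xvals=grid)

    peaks_hi, _ = find_peaks(smoothed, prominence=tol)
    peaks_lo, _ = find_peaks(-smoothed, prominence=tol)
    turning = sorted(np.concatenate([grid[peaks_hi], grid[peaks_lo]]).tolist())

    if float(np.ptp(smoothed)) < tol:
        shape = "flat"
    elif not turning:
        shape = "linear"
    else:
        shape = "non_monotone"
    return TrajectoryFit(
        locus_id=locus_id,
        slope=float(slope),
        intercept=float(intercept),
        grid=grid,
        smoothed=smoothed,
        turning_ages=turning,
        shape=shape,
        noise_tolerance=tol,
    )


def trajectory_table(
    matrix: pd.DataFrame, samples: pd.DataFrame, span: float = 0.5, **kwargs
) -> pd.DataFrame:
    ages = samples.loc[matrix.columns, "age"].to_numpy(dtype=float)
    rows = []
    for locus in matrix.index:
        fit = fit_trajectory(
            matrix.loc[locus].to_numpy(), ages, span=span, locus_id=locus, **kwargs
        )
        rows.append(
            {
                "locus_id": locus,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "turning_points": fit.turning_point_count,
                "first_turning_age": fit.turning_ages[0] if fit.turning_ages else np.nan,
                "shape": fit.shape,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")
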