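"""Age acceleration: computation, external clocks, and group comparisons.

"Age acceleration" is the discrepancy between clock-predicted and
chronological age, either as the plain difference (predicted - actual) or
as the residual of regressing predicted on actual age (mean zero by
construction).  Externally published clocks are applied from a
user-supplied coefficient file; their output calibration (e.g. a
mortality-score-to-years map) is treated as an opaque, supplied transform.
Group differences vs pooled controls use per-group two-sample t tests
after a one-way linear model, with Holm step-down adjustment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .preprocess import AgeTransform, inverse_transform_age

logger = logging.getLogger(__name__)


def compute_acceleration(pred_years, actual_years, mode: str = "difference") -> np.ndarray:
    """Per-sample age acceleration in years.

    difference: predicted - actual.  residual: residual of the OLS
    regression of predicted on actual age.
    """
    pred = np.asarray(pred_years, dtype=float)
    actual = np.asarray(actual_years, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    if mode == "difference":
        return pred - actual
    if mode == "residual":
        if np.ptp(actual) == 0:
            raise ValueError("residual mode undefined for constant actual ages")
        slope, intercept = np.polyfit(actual, pred, 1)
        return pred - (slope * actual + intercept)
    raise ValueError(f"mode must be 'difference' or 'residual': {mode}")


@dataclass
class ExternalClockSpec:
    """A published clock loaded from file: coefficients plus calibration."""

    intercept: float
    coefficients: dict[str, float]
    calibration: dict = field(default_factory=lambda: {"type": "identity"})

    @classmethod
    def from_json(cls, text: str) -> "ExternalClockSpec":
        d = json.loads(text)
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            calibration=d.get("calibration", {"type": "identity"}),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "calibration": self.calibration,
            },
            indent=1,
            sort_keys=True,
        )


def _calibrate(score: np.ndarray, calibration: dict) -> np.ndarray:
    kind = calibration.get("type", "identity")
    if kind == "identity":
        return score
    if kind == "linear":
        a = float(calibration["params"]["a"])
        b = float(calibration["params"]["b"])
        return a * score + b
    if kind == "inverse_age_transform":
        adult_age = float(calibration.get("params", {}).get("adult_age", 20.0))
        return inverse_transform_age(score, AgeTransform(adult_age))
    raise ValueError(f"unknown calibration type {kind!r}")


def apply_external_clock(
    spec: ExternalClockSpec, matrix: pd.DataFrame, max_missing: float = 0.10
) -> pd.Series:
    """Apply a supplied clock to a beta matrix, returning predicted years.

    Spec loci absent from the matrix (up to ``max_missing`` of them) are
    imputed at the per-sample background mean beta; more is a hard error.
    """
    loci = list(spec.coefficients)
    missing = [l for l in loci if l not in matrix.index]
    if loci and len(missing) / len(loci) > max_missing:
        raise ValueError(
            f"{len(missing)}/{len(loci)} clock loci missing from matrix "
            f"(> {max_missing:.0%} allowed)"
        )
    if missing:
        logger.warning(
            "apply_external_clock: %d of %d loci missing; background-mean imputed",
            len(missing),
            len(loci),
        )
    present = [l for l in loci if l not in set(missing)]
    score = np.full(matrix.shape[1], spec.intercept, dtype=float)
    if present:
        w = np.array([spec.coefficients[l] for l in present])
        score = score + w @ matrix.loc[present].to_numpy(dtype=float)
    if missing:
        bg_mean = matrix.mean(axis=0).to_numpy(dtype=float)
        w_missing = sum(spec.coefficients[l] for l in missing)
        score = score + w_missing * bg_mean
    years = _calibrate(score, spec.calibration)
    return pd.Series(years, index=matrix.columns, name="predicted_age")


@dataclass
class AccelerationResult:
    per_sample: pd.Series  # acceleration, years
    group_stats: pd.DataFrame  # n, mean, sd per group
    comparisons: pd.DataFrame  # group vs pooled controls: t, p, p_holm, significant
    anova_p: float


def group_comparison(
    accel: pd.Series,
    samples: pd.DataFrame,
    control_labels: list[str] | None = None,
    alpha: float = 0.05,
) -> AccelerationResult:
    """Compare each condition group's acceleration to pooled controls.

    One-way linear model (ANOVA F) over groups, then per-group two-sample
    t tests vs the pooled control samples with Holm step-down adjustment.
    Groups of size 1 are excluded with a warning.
    """
    control_labels = control_labels or ["control"]
    cond = samples.loc[accel.index, "condition"].astype(str)
    is_control = cond.isin(control_labels)
    controls = accel[is_control].to_numpy()
    if controls.size == 0:
        raise ValueError(f"no samples match control labels {control_labels}")
    group_names = [g for g in cond.unique() if g not in control_labels]
    kept = []
    for g in sorted(group_names):
        n_g = int((cond == g).sum())
        if n_g < 2:
            import warnings

            warnings.warn(f"group {g!r} has {n_g} sample(s); excluded")
            continue
        kept.append(g)
    if not kept:
        raise ValueError("need at least one non-control group with >= 2 samples")

    groups_all = [("control", controls)] + [
        (g, accel[cond == g].to_numpy()) for g in kept
    ]
    stats_rows = [
        {"group": g, "n": len(v), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
        for g, v in groups_all
    ]
    from scipy.stats import f_oneway

    anova_p = float(f_oneway(*[v for _, v in groups_all]).pvalue)

    t_stats, raw_p = [], []
    for g in kept:
        res = ttest_ind(accel[cond == g].to_numpy(), controls, equal_var=True)
        t_stats.append(float(res.statistic))
        raw_p.append(float(res.pvalue))
    p_holm = multipletests(raw_p, alpha=alpha, method="holm")[1]
    comparisons = pd.DataFrame(
        {
            "group": kept,
            "t": t_stats,
            "p": raw_p,
            "p_holm": p_holm,
            "significant": p_holm < alpha,
        }
    ).set_index("group")
    return AccelerationResult(
        per_sample=accel,
        group_stats=pd.DataFrame(stats_rows).set_index("group"),
        comparisons=comparisons,
        anova_p=anova_p,
    )
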