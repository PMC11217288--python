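"""Evaluation statistics, score normalization, and confounder screening."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class MetricSet:
    """Observed-vs-predicted agreement metrics.

    ``r2_sq`` is the squared Pearson correlation; ``r2_ss`` the
    sum-of-squares coefficient of determination 1 - SSres/SStot. The two
    coincide only for a perfectly calibrated linear predictor, so both
    are reported.
    """

    r: float
    p: float
    mae: float
    r2_sq: float
    r2_ss: float

    def to_dict(self) -> dict[str, float]:
        return {"r": self.r, "p": self.p, "mae": self.mae,
                "r2_sq": self.r2_sq, "r2_ss": self.r2_ss}


@dataclass
class ConfounderReport:
    """One screening row per covariate: method, coefficient, p value."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["variable", "method", "coefficient", "p"])


def _check_vector(x: np.ndarray, name: str, min_len: int = 4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if x.size < min_len:
        raise ValueError(f"{name} needs at least {min_len} values")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with the two-sided parametric p value.

    The p value comes from the exact t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of
    freedom (scipy's beta-distribution form is algebraically identical).
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def point_biserial(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Point-biserial correlation of a binary grouping with a continuous score.

    Identical to Pearson correlation on the 0/1 coding of ``g``.
    """
    g = np.asarray(g)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"grouping variable must take exactly two values, "
                         f"got {levels.size}")
    coded = (g == levels[1]).astype(float)
    y = _check_vector(y, "y")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; correlation undefined")
    res = stats.pointbiserialr(coded, y)
    return float(res.correlation), float(res.pvalue)


def regression_metrics(observed: np.ndarray,
                       predicted: np.ndarray) -> MetricSet:
    """r, parametric p, MAE, and both R-squared conventions."""
    observed = _check_vector(observed, "observed")
    predicted = _check_vector(predicted, "predicted")
    if observed.size != predicted.size:
        raise ValueError("observed and predicted must have equal length")
    r, p = pearson_with_p(observed, predicted)
    mae = float(np.mean(np.abs(observed - predicted)))
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return MetricSet(r=r, p=p, mae=mae, r2_sq=r * r,
                     r2_ss=1.0 - ss_res / ss_tot)


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Scale scores to [0, 1] by dividing by the within-dataset maximum."""
    scores = np.asarray(scores, dtype=float)
    mx = scores.max()
    if not mx > 0:
        raise ValueError("maximum score must be positive for normalization")
    return scores / mx


def confounder_screen(behavior: pd.DataFrame,
                      score_column: str = "c_total") -> ConfounderReport:
    """Correlate each covariate with the creativity score.

    Age and education use Pearson correlation; gender (binary) uses the
    point-biserial correlation. Education must be an ordinal 0-5.
    """
    for col in ("age", "gender", "education", score_column):
        if col not in behavior.columns:
            raise ValueError(f"behavior table is missing column {col!r}")
    edu = behavior["education"].to_numpy()
    if not np.all(np.isin(edu, np.arange(6))):
        raise ValueError("education values must lie in {0, ..., 5}")
    score = behavior[score_column].to_numpy(dtype=float)

    report = ConfounderReport()
    for var in ("age", "education"):
        coef, p = pearson_with_p(behavior[var].to_numpy(dtype=float), score)
        report.rows.append({"variable": var, "method": "pearson",
                            "coefficient": coef, "p": p})
    coef, p = point_biserial(behavior["gender"].to_numpy(), score)
    report.rows.append({"variable": "gender", "method": "point-biserial",
                        "coefficient": coef, "p": p})
    return report
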