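"""Repeated-measures inference across dark-adaptation timestamps.

One-way repeated-measures ANOVA compares a measure across the seven
acquisition time points, followed by Bonferroni-corrected paired t-tests of
each dark timestamp against the light-adapted baseline.  Pearson correlation
quantifies linear association between time courses.  No sphericity correction
is applied to the primary F-test; the Greenhouse-Geisser epsilon is reported
alongside as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import DegenerateVarianceError, InferenceError, InvalidParameterError

__all__ = [
    "RepeatedMeasuresTable",
    "AnovaResult",
    "PosthocResult",
    "rm_anova",
    "bonferroni_vs_baseline",
    "pearson",
    "fisher_ci",
]


@dataclass
class RepeatedMeasuresTable:
    """Complete subject x timestamp measurement matrix."""

    data: np.ndarray
    timestamps: tuple
    measure: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("table must be 2-D (subjects x timestamps)")
        if np.isnan(self.data).any():
            raise InvalidParameterError("table has missing cells")
        n, k = self.data.shape
        if n < 2 or k < 2:
            raise InferenceError("need >= 2 subjects and >= 2 timestamps")
        if len(self.timestamps) != k:
            raise InvalidParameterError("timestamp labels do not match columns")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timestamps(self) -> int:
        return self.data.shape[1]

    def to_long(self) -> pd.DataFrame:
        n, k = self.data.shape
        return pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "time": np.tile(np.asarray(self.timestamps, dtype=float), n),
            "value": self.data.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value: str, *,
                   subject: str = "subject", time: str = "timestamp_min",
                   measure: str = "", units: str = "") -> "RepeatedMeasuresTable":
        wide = df.pivot(index=subject, columns=time, values=value).sort_index(axis=1)
        if wide.isna().any().any():
            raise InvalidParameterError(f"measure {value!r} has missing cells")
        return cls(wide.to_numpy(), tuple(wide.columns), measure or value, units)


@dataclass
class AnovaResult:
    f_statistic: float
    df_effect: int
    df_error: int
    p_value: float
    means: np.ndarray
    ci95: np.ndarray  # (k, 2) per-timestamp mean confidence intervals
    gg_epsilon: float


@dataclass
class PosthocResult:
    """Bonferroni-adjusted paired comparisons against the baseline column."""

    timestamps: tuple
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    bonferroni_factor: int
    earliest_significant: float | None


def _sums_of_squares(x: np.ndarray) -> tuple[float, float, float]:
    grand = x.mean()
    ss_subject = x.shape[1] * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_time = x.shape[0] * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    return ss_subject, ss_time, ss_total - ss_subject - ss_time


def rm_anova(table: RepeatedMeasuresTable) -> AnovaResult:
    """One-way repeated-measures ANOVA over the timestamps.

    The univariate F = MS_time / MS_error with df = (k-1, (k-1)(n-1)), subject
    variance removed.  A table with no between-timestamp variation returns
    F = 0, p = 1; zero error variance with non-zero timestamp variation is
    degenerate and raises.
    """
    x = table.data
    n, k = x.shape
    ss_s, ss_t, ss_e = _sums_of_squares(x)
    scale = max(ss_s + ss_t + ss_e, 1.0)
    if ss_t <= 1e-12 * scale:
        f, p, eps = 0.0, 1.0, 1.0
    elif ss_e <= 1e-12 * scale:
        raise DegenerateVarianceError(
            "zero within-subject error variance; the F statistic is undefined"
        )
    else:
        aov = pg.rm_anova(
            data=table.to_long(), dv="value", within="time", subject="subject",
            detailed=True, correction=False, effsize="np2",
        )
        row = aov.loc[aov["Source"] == "time"].iloc[0]
        f, p = float(row["F"]), float(row["p_unc"])
        eps = float(row["eps"])
    means = x.mean(axis=0)
    sem = x.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    ci = np.stack([means - tcrit * sem, means + tcrit * sem], axis=1)
    return AnovaResult(
        f_statistic=f, df_effect=k - 1, df_error=(k - 1) * (n - 1),
        p_value=p, means=means, ci95=ci, gg_epsilon=eps,
    )


def bonferroni_vs_baseline(
    table: RepeatedMeasuresTable, baseline_index: int = 0, alpha: float = 0.05
) -> PosthocResult:
    """Paired two-sided t-tests of each timestamp against the baseline column
    with Bonferroni adjustment (factor = number of comparisons, 6 for the
    seven-timestamp design); adjusted p = min(1, factor * raw p)."""
    x = table.data
    if x.shape[0] < 2:
        raise InferenceError("paired t-tests need >= 2 subjects")
    base = x[:, baseline_index]
    others = [j for j in range(x.shape[1]) if j != baseline_index]
    factor = len(others)
    raw = np.empty(factor)
    for i, j in enumerate(others):
        d = x[:, j] - base
        if np.allclose(d.std(ddof=1), 0.0):
            raw[i] = 1.0 if np.allclose(d.mean(), 0.0) else 0.0
        else:
            raw[i] = sps.ttest_rel(x[:, j], base).pvalue
    adjusted = np.minimum(1.0, factor * raw)
    earliest = None
    for i, j in enumerate(others):
        if adjusted[i] < alpha:
            earliest = table.timestamps[j]
            break
    return PosthocResult(
        timestamps=tuple(table.timestamps[j] for j in others),
        raw_p=raw,
        adjusted_p=adjusted,
        bonferroni_factor=factor,
        earliest_significant=earliest,
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("series must be equal-length 1-D arrays")
    if x.size < 3:
        raise InferenceError("Pearson correlation needs >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateVarianceError("a series has zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval for a correlation coefficient."""
    if n <= 3:
        raise InferenceError("Fisher interval needs n > 3")
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))
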