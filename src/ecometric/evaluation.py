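"""Estimator evaluation: anomaly fields, correlations, ANOVA.

An anomaly is observed minus estimated log precipitation (the modern-data
convention; the fossil-site comparison reverses it).  Smaller anomalies mean
a less biased method.  Methods are compared by a lower-triangular Pearson
correlation matrix of observed plus the four estimate series, and by a
one-way fixed-effects ANOVA of anomaly by method.  Missing estimates (the
binned maximum-likelihood method declines nonanalog queries) propagate as
NaN, are excluded pairwise from correlations and groupwise from the ANOVA,
and are counted — never imputed.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

OBSERVED_LABEL = "observed"


@dataclass
class AnomalyField:
    """Per-point anomalies for one method, with a recomputable summary."""

    method: str
    values: pd.Series  # indexed by point_id; NaN where the estimate is missing
    direction: str = "observed_minus_estimated"

    @property
    def summary(self) -> dict:
        v = self.values.dropna()
        return {
            "min": float(v.min()) if len(v) else float("nan"),
            "max": float(v.max()) if len(v) else float("nan"),
            "mean": float(v.mean()) if len(v) else float("nan"),
            "n": int(len(v)),
            "n_missing": int(self.values.isna().sum()),
        }


def _as_series(data, name: str) -> pd.Series:
    if isinstance(data, pd.Series):
        return data.astype(float)
    if isinstance(data, Mapping):
        return pd.Series(data, dtype=float)
    raise ValidationError(f"{name} must be a mapping or Series of point values")


def compute_anomalies(
    observed,
    estimated,
    direction: str = "observed_minus_estimated",
    method: str = "",
) -> AnomalyField:
    """Signed difference between observed and estimated values per point.

    Missing estimates yield NaN anomalies and are counted in the summary.
    """
    obs = _as_series(observed, "observed")
    est = _as_series(estimated, "estimated")
    shared = obs.index.intersection(est.index)
    if len(shared) == 0:
        raise ValidationError("observed and estimated share no point_ids")
    if direction == "observed_minus_estimated":
        diff = obs.loc[shared] - est.loc[shared]
    elif direction == "estimated_minus_observed":
        diff = est.loc[shared] - obs.loc[shared]
    else:
        raise ValidationError(f"unknown anomaly direction '{direction}'")
    return AnomalyField(method=method, values=diff, direction=direction)


@dataclass
class CorrelationMatrix:
    """Lower-triangular Pearson r (and p) for observed + estimate series."""

    labels: list[str]
    r: pd.DataFrame  # NaN above the diagonal; 1.0 on it
    p: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sample sizes

    def to_dict(self) -> dict:
        def tidy(df):
            return {
                row: {col: (None if pd.isna(v) else float(v)) for col, v in s.items()}
                for row, s in df.iterrows()
            }

        return {"labels": self.labels, "r": tidy(self.r), "p": tidy(self.p),
                "n": tidy(self.n.astype(float))}


def correlation_matrix(observed, estimates: Mapping[str, object]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations of observed + estimate series.

    Each pair drops points where either member is missing; a pair left with
    fewer than 3 complete records, or with a constant series, is an error
    (r undefined) rather than a silent NaN.
    """
    series = {OBSERVED_LABEL: _as_series(observed, "observed")}
    for name, est in estimates.items():
        series[name] = _as_series(est, name)
    frame = pd.DataFrame(series)
    labels = list(frame.columns)
    k = len(labels)
    r = pd.DataFrame(np.full((k, k), np.nan), index=labels, columns=labels)
    p = r.copy()
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=labels, columns=labels)
    for i, a in enumerate(labels):
        r.loc[a, a], p.loc[a, a], n.loc[a, a] = 1.0, 0.0, int(frame[a].notna().sum())
        for b in labels[:i]:
            pair = frame[[a, b]].dropna()
            if len(pair) < 3:
                raise ValidationError(
                    f"fewer than 3 pairwise-complete records for ({a}, {b})"
                )
            xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                raise ValidationError(f"constant series in pair ({a}, {b}): r undefined")
            res = stats.pearsonr(xa, xb)
            r.loc[a, b] = float(res.statistic)
            p.loc[a, b] = float(res.pvalue)
            n.loc[a, b] = len(pair)
    return CorrelationMatrix(labels=labels, r=r, p=p, n=n)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float

    def to_dict(self) -> dict:
        return {"f": self.f, "df_between": self.df_between,
                "df_within": self.df_within, "p": self.p}


def anova_anomalies(fields: list[AnomalyField]) -> AnovaResult:
    """One-way fixed-effects ANOVA of anomaly value by method.

    Missing anomalies are excluded per group.  Sums of squares are formed
    explicitly so the degenerate zero-within-variance case yields F = inf
    (p = 0) deterministically; four identical groups yield F = 0.
    """
    groups = []
    for f in fields:
        g = f.values.dropna().to_numpy(float)
        if g.size < 2:
            raise ValidationError(
                f"method '{f.method}' has {g.size} non-missing anomalies (need >= 2)"
            )
        groups.append(g)
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two methods")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)
    ms_between = ss_between / df_between
    if ms_between == 0.0:
        return AnovaResult(f=0.0, df_between=df_between, df_within=df_within, p=1.0)
    if ss_within == 0.0:
        return AnovaResult(f=float("inf"), df_between=df_between,
                           df_within=df_within, p=0.0)
    f_stat = ms_between / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(f=float(f_stat), df_between=df_between,
                       df_within=df_within, p=p)


@dataclass
class ComparisonReport:
    correlation: CorrelationMatrix
    anova: AnovaResult
    anomaly_summaries: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "correlation": self.correlation.to_dict(),
            "anova": self.anova.to_dict(),
            "anomaly_summaries": self.anomaly_summaries,
        }


def compare_methods(
    observed, estimates: Mapping[str, object],
    direction: str = "observed_minus_estimated",
) -> tuple[list[AnomalyField], ComparisonReport]:
    """Full modern-data evaluation: anomaly fields, correlations, ANOVA."""
    fields = [
        compute_anomalies(observed, est, direction=direction, method=name)
        for name, est in estimates.items()
    ]
    corr = correlation_matrix(observed, estimates)
    anova = anova_anomalies(fields)
    report = ComparisonReport(
        correlation=corr,
        anova=anova,
        anomaly_summaries={f.method: f.summary for f in fields},
    )
    return fields, report
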