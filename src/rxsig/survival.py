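"""Score-based cohort stratification and survival statistics.

Patients are stratified by polygenic score either by quartiles (bottom
quartile = LOW, top quartile = HIGH, middle half excluded — the default for
large cohorts) or by the median (two groups, used for small cohorts and as
the Cox indicator cutoff).  Group differences use the Kaplan–Meier estimator
with the two-sided Mantel log-rank test; adjusted effects come from Cox
proportional-hazards regression with Efron tie handling (the lifelines
implementation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)

LOW, HIGH, EXCLUDED = "LOW", "HIGH", "EXCLUDED"


@dataclass
class StrataLabels:
    labels: pd.Series            # sample_id -> LOW / HIGH / EXCLUDED
    method: str                  # QUARTILE or MEDIAN
    thresholds: tuple            # (q1, q3) or (median,)

    def samples(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


def _as_series(scores) -> pd.Series:
    if hasattr(scores, "scores"):
        scores = scores.scores
    s = pd.Series(scores, dtype=float)
    if s.isna().any():
        raise ValueError("scores contain missing values")
    return s


def stratify_by_score(scores, method: str = "QUARTILE") -> StrataLabels:
    """Label samples LOW/HIGH(/EXCLUDED) by score quartiles or the median.

    Quartile rule: LOW iff score <= Q1, HIGH iff score >= Q3 (linearly
    interpolated percentiles; boundary samples join the extreme groups),
    everything strictly between excluded.  Median rule: HIGH iff score >
    median, no exclusions.
    """
    s = _as_series(scores)
    method = method.upper()
    if s.nunique() < 2:
        raise ValueError("all scores identical: stratification impossible")
    if method == "QUARTILE":
        if len(s) < 8:
            raise ValueError("quartile stratification needs at least 8 samples")
        q1, q3 = np.percentile(s.to_numpy(), [25, 75])
        if q1 == q3:
            raise ValueError("degenerate score distribution: Q1 equals Q3")
        lab = pd.Series(EXCLUDED, index=s.index, dtype=object)
        lab[s <= q1] = LOW
        lab[s >= q3] = HIGH
        return StrataLabels(lab, "QUARTILE", (float(q1), float(q3)))
    if method == "MEDIAN":
        if len(s) < 2:
            raise ValueError("median stratification needs at least 2 samples")
        med = float(np.median(s.to_numpy()))
        lab = pd.Series(LOW, index=s.index, dtype=object)
        lab[s > med] = HIGH
        return StrataLabels(lab, "MEDIAN", (med,))
    raise ValueError(f"unknown stratification method {method!r}")


def km_curve(times, events) -> KaplanMeierFitter:
    """Product-limit survival estimate (right-continuous, starts at 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return KaplanMeierFitter().fit(times, events)


def logrank_test(group_low: pd.DataFrame, group_high: pd.DataFrame) -> tuple[float, float]:
    """Two-sided Mantel log-rank test between two groups.

    Each group is a frame with ``time`` and ``event`` columns.  Returns the
    1-df chi-square statistic and its p-value.
    """
    if len(group_low) == 0 or len(group_high) == 0:
        raise ValueError("both groups must be non-empty")
    total_events = int(group_low["event"].sum() + group_high["event"].sum())
    if total_events == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(
        group_low["time"], group_high["time"],
        event_observed_A=group_low["event"], event_observed_B=group_high["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-variable hazard ratios with Wald CIs and p-values."""

    summary: pd.DataFrame   # variable, coef, hazard_ratio, ci_low, ci_high, p_value
    kind: str               # UNIVARIATE or MULTIVARIATE
    n: int
    events: int

    def hazard_ratio(self, variable: str) -> float:
        row = self.summary.set_index("variable").loc[variable]
        return float(row["hazard_ratio"])

    def p_value(self, variable: str) -> float:
        row = self.summary.set_index("variable").loc[variable]
        return float(row["p_value"])

    def coef(self, variable: str) -> float:
        row = self.summary.set_index("variable").loc[variable]
        return float(row["coef"])


def cox_fit(records: pd.DataFrame, covariates, kind: str | None = None) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Newton iteration).

    ``records`` must carry ``time`` and ``event`` columns plus every
    covariate; rows with a missing covariate are dropped with a warning.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("cox_fit needs at least one covariate")
    missing_cols = [c for c in ["time", "event", *covariates] if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing column(s): {missing_cols}")
    df = records[["time", "event", *covariates]].dropna()
    if len(df) < len(records):
        logger.warning("cox_fit: dropped %d row(s) with missing covariates",
                       len(records) - len(df))
    events = int(df["event"].sum())
    if events < 10 * len(covariates):
        logger.warning("cox_fit: only %d events for %d coefficient(s)", events, len(covariates))
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="time", event_col="event")
    summ = fitter.summary
    out = pd.DataFrame(
        {"variable": summ.index,
         "coef": summ["coef"].to_numpy(),
         "hazard_ratio": summ["exp(coef)"].to_numpy(),
         "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
         "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
         "p_value": summ["p"].to_numpy()}
    ).reset_index(drop=True)
    if kind is None:
        kind = "UNIVARIATE" if len(covariates) == 1 else "MULTIVARIATE"
    return CoxResult(summary=out, kind=kind, n=len(df), events=events)


def score_group_cox(
    clinical: pd.DataFrame,
    scores,
    covariates=(),
    stratify: str = "MEDIAN",
) -> CoxResult:
    """Cox fit with a HIGH-vs-LOW score indicator (HIGH = 1) plus optional
    clinical covariates, using the median cut by default."""
    s = _as_series(scores)
    shared = clinical.index.intersection(s.index)
    if len(shared) == 0:
        raise ValueError("no overlap between clinical records and scores")
    strata = stratify_by_score(s.loc[shared], method=stratify)
    keep = strata.labels[strata.labels != EXCLUDED].index
    df = clinical.loc[keep].copy()
    df["score_high"] = (strata.labels.loc[keep] == HIGH).astype(float)
    return cox_fit(df, ["score_high", *covariates])
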