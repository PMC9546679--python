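"""Survival analysis: Kaplan-Meier curves, log-rank tests, Cox PH models.

Estimation is delegated to lifelines (product-limit estimator, chi-square
log-rank, Cox partial likelihood with Efron tie handling); this module fixes
the cohort-level conventions: overall and pairwise subtype log-rank tests
(pairwise p-values reported unadjusted, with a BH column alongside),
one-vs-rest subtype contrasts for Cox models, and the risk-factor flag
(p < 0.05 and the whole 95% CI of the HR above 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .diffexpr import bh_adjust
from .io import ClinicalTable

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "cox_fit",
    "code_binary",
    "subtype_onehot",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray  # sorted distinct observed times (event or censor)
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # risk-set size just before each time

    def at(self, t: float) -> float:
        """S(t): step-function value at time t."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events differ in length")
    if (t <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of S(t)."""
    t, e = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    # drop the t=0 anchor row lifelines prepends
    surv = kmf.survival_function_["KM_estimate"]
    surv = surv[surv.index > 0]
    ts = surv.index.to_numpy(dtype=float)
    ev = kmf.event_table.loc[kmf.event_table.index > 0]
    return KMCurve(
        times=ts,
        survival=surv.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=float),
    )


def logrank_test(times, events, group_labels) -> LogRankResult:
    """k-group log-rank test (observed - expected chi-square, df = k-1)."""
    t, e = _check_times_events(times, events)
    groups = pd.Series(group_labels).astype(str).to_numpy()
    if groups.shape[0] != t.shape[0]:
        raise ValueError("group labels differ in length from times")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValueError("log-rank needs >= 2 non-empty groups")
    if e.sum() == 0:
        raise ValueError("log-rank undefined with no events")
    res = multivariate_logrank_test(t, groups, e)
    return LogRankResult(
        statistic=float(res.test_statistic), df=int(uniq.size - 1), p=float(res.p_value)
    )


def pairwise_logrank(times, events, group_labels) -> pd.DataFrame:
    """All pairwise two-group log-rank tests between subtype labels.

    p-values are reported unadjusted (matching how pairwise subtype survival
    contrasts are conventionally printed) with a BH-adjusted column for
    transparency.
    """
    t, e = _check_times_events(times, events)
    groups = pd.Series(group_labels).astype(str).to_numpy()
    rows = []
    for a, b in combinations(sorted(np.unique(groups)), 2):
        mask = (groups == a) | (groups == b)
        if e[mask].sum() == 0:
            rows.append({"group1": a, "group2": b, "statistic": np.nan, "p": np.nan})
            continue
        r = logrank_test(t[mask], e[mask], groups[mask])
        rows.append({"group1": a, "group2": b, "statistic": r.statistic, "p": r.p})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["p_bh"] = np.nan
    if ok.any():
        df.loc[ok, "p_bh"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    return df


def code_binary(series: pd.Series, positive_levels: list[str]) -> pd.Series:
    """0/1 indicator for membership in ``positive_levels`` (NaN preserved)."""
    s = series.astype("object")
    out = s.isin(positive_levels).astype(float)
    out[s.isna()] = np.nan
    return out


def subtype_onehot(calls: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest 0/1 indicators for each subtype ('Other' is the reference)."""
    sub = calls["subtype"].astype(str)
    return pd.DataFrame({s: (sub == s).astype(float) for s in sub.unique()})


def cox_fit(
    c: ClinicalTable,
    covariates: list[str],
    model: str = "univariate",
) -> pd.DataFrame:
    """Cox proportional-hazards regression with Efron tie handling.

    ``covariates`` name numeric (typically 0/1 contrast) columns of the
    clinical table. ``model='univariate'`` fits each covariate alone;
    ``'multivariate'`` fits them jointly. Rows with missing values in the
    fitted columns are dropped per fit.

    Returns one row per covariate: coef, hr, ci_low, ci_high, p, n, model,
    and ``risk_factor`` (p < 0.05 and ci_low > 1).
    """
    if model not in ("univariate", "multivariate"):
        raise ValueError(f"unknown model type {model!r}")
    if not covariates:
        raise ValueError("no covariates given")
    missing = [v for v in covariates if v not in c.data.columns]
    if missing:
        raise KeyError(f"covariate(s) not in clinical table: {missing}")

    def fit_one(cols: list[str]) -> pd.DataFrame:
        df = c.data[["os_time_days", "os_event", *cols]].dropna()
        if df["os_event"].sum() < 1:
            raise ValueError("no events among complete cases")
        for v in cols:
            if df[v].nunique() < 2:
                raise ValueError(f"covariate {v!r} is constant among complete cases")
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="os_time_days", event_col="os_event")
        except Exception as exc:  # convergence / separation
            raise RuntimeError(f"Cox fit failed for {cols}: {exc}") from exc
        s = cph.summary
        out = pd.DataFrame(
            {
                "variable": s.index,
                "coef": s["coef"].to_numpy(),
                "hr": s["exp(coef)"].to_numpy(),
                "ci_low": s["exp(coef) lower 95%"].to_numpy(),
                "ci_high": s["exp(coef) upper 95%"].to_numpy(),
                "p": s["p"].to_numpy(),
            }
        )
        out["n"] = len(df)
        return out

    if model == "univariate":
        parts = [fit_one([v]) for v in covariates]
        res = pd.concat(parts, ignore_index=True)
    else:
        res = fit_one(list(covariates)).reset_index(drop=True)
    res["model"] = model
    res["risk_factor"] = (res["p"] < 0.05) & (res["ci_low"] > 1.0)
    return res
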