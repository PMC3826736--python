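"""Downstream statistics for AD-PS scores.

Two-sample Kolmogorov-Smirnov comparisons of score distributions across
cognitive-status / age / functional strata, and proportional-hazards
association of each metric with MCI-to-AD conversion time, reported as the
hazard ratio per 1 SD of the score. No multiple-testing adjustment is
applied to the stratified tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import special
from scipy import stats as sps

__all__ = [
    "KSResult",
    "SurvivalRecords",
    "CoxResult",
    "ks_two_sample",
    "cox_fit",
    "stratified_table",
]


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(a, b, method: str = "asymp") -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    The statistic is the sup-difference of the two empirical CDFs over all
    pooled points. With ``method="asymp"`` (default) the p-value comes from
    the asymptotic Kolmogorov distribution with effective size
    n1*n2/(n1+n2); ``method="exact"`` uses small-sample enumeration and is
    available as a cross-check for n1*n2 <= 400.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "exact":
        if a.size * b.size > 400:
            raise ValueError("exact enumeration is limited to n1*n2 <= 400")
        res = sps.ks_2samp(a, b, alternative="two-sided", method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "asymp":
        stat = float(sps.ks_2samp(a, b, alternative="two-sided", method="asymp").statistic)
        en = a.size * b.size / (a.size + b.size)
        p = float(special.kolmogorov(np.sqrt(en) * stat))
    else:
        raise ValueError("method must be 'asymp' or 'exact'")
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return KSResult(stat, p, a.size, b.size)


@dataclass(frozen=True)
class SurvivalRecords:
    """Per-subject follow-up: months to conversion or last observation."""

    subject_id: tuple
    time_months: np.ndarray
    event: np.ndarray  # 1 = converted to AD, 0 = censored

    def __post_init__(self):
        t = np.asarray(self.time_months, dtype=float)
        e = np.asarray(self.event, dtype=int)
        if np.any(t <= 0):
            raise ValueError("time_months must be positive")
        if not set(np.unique(e)) <= {0, 1}:
            raise ValueError("event must be 0/1")
        if not len(self.subject_id) == len(t) == len(e):
            raise ValueError("survival record fields differ in length")
        object.__setattr__(self, "time_months", t)
        object.__setattr__(self, "event", e)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalRecords":
        return cls(
            tuple(df["subject_id"]),
            df["time_months"].to_numpy(float),
            df["event"].to_numpy(int),
        )


@dataclass(frozen=True)
class CoxResult:
    coefficient: float        # log hazard per 1 SD of the covariate
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    z_statistic: float
    p_value: float
    n: int
    n_events: int
    covariate_mean: float
    covariate_sd: float


def cox_fit(covariate, records: SurvivalRecords) -> CoxResult:
    """Univariate proportional-hazards fit; hazard ratio per 1 SD of the score.

    The covariate is standardized internally (sample SD, ddof=1) so the
    reported coefficient is the log hazard per 1 SD unit; the partial
    likelihood is maximized with Efron handling of tied event times (ties do
    not arise for continuous conversion times, where Efron and Breslow
    coincide). ci95 = exp(coefficient +/- 1.96 * SE).
    """
    x = np.asarray(covariate, dtype=float).ravel()
    if x.size != len(records.time_months):
        raise ValueError("covariate and survival records differ in length")
    n_events = int(records.event.sum())
    if n_events < 1:
        raise ValueError("at least one event is required")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd <= 0:
        raise ValueError("covariate SD must be positive")
    z = (x - mu) / sd
    df = pd.DataFrame({"score": z, "time": records.time_months, "event": records.event})
    cph = CoxPHFitter()
    try:
        # tight Newton precision: the default leaves ~1e-4 slack on flat
        # partial likelihoods at very small n
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-10})
    except Exception as err:  # monotone likelihood / separation
        raise RuntimeError(f"proportional-hazards fit diverged: {err}") from err
    coef = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    zstat = coef / se
    return CoxResult(
        coefficient=coef,
        hazard_ratio=float(np.exp(coef)),
        ci95_low=float(np.exp(coef - 1.96 * se)),
        ci95_high=float(np.exp(coef + 1.96 * se)),
        z_statistic=zstat,
        p_value=float(2.0 * sps.norm.sf(abs(zstat))),
        n=x.size,
        n_events=n_events,
        covariate_mean=mu,
        covariate_sd=sd,
    )


def stratified_table(
    scores: pd.DataFrame,
    strata,
    strata_order: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-stratum medians and pairwise KS p-values for each score column.

    ``scores`` holds one column per metric; ``strata`` labels each row.
    Strata listed in ``strata_order`` but absent from the data are reported
    as missing (NaN) rather than dropped. P-values are unadjusted.
    """
    strata = pd.Series(np.asarray(strata, dtype=object), index=scores.index)
    levels = list(strata_order) if strata_order is not None else list(pd.unique(strata))
    rows = []
    for metric in scores.columns:
        row = {"metric": metric}
        groups = {}
        for lev in levels:
            vals = scores.loc[strata == lev, metric].dropna().to_numpy(float)
            groups[lev] = vals
            row[f"median[{lev}]"] = float(np.median(vals)) if vals.size else float("nan")
            row[f"n[{lev}]"] = int(vals.size)
        for a, b in combinations(levels, 2):
            key = f"p[{a} vs {b}]"
            if groups[a].size and groups[b].size:
                row[key] = ks_two_sample(groups[a], groups[b]).p_value
            else:
                row[key] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
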