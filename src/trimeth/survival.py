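"""Recurrence-free and overall-survival analytics.

Endpoints are built from inclusion/recurrence/death dates with
administrative censoring at the data cutoff.  Recurrence-free survival
(RFS) counts radiological or clinical recurrence and cancer-attributed
death as events; a non-cancer death without prior recurrence censors RFS
at the death date.  Overall survival (OS) counts death of any cause.
Times are in months (days / 30.4375).

Kaplan-Meier curves come with plain Greenwood 95% confidence intervals and
landmark queries; the two-group log-rank test is computed directly from
the risk tables; Cox proportional-hazards models (Efron tie handling, Wald
intervals) support the univariable screen -> multivariable workflow; ROC
analysis scores markers and calls against recurrence status.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "DAYS_PER_MONTH",
    "DeathCause",
    "Endpoint",
    "PatientRecord",
    "SurvivalEndpoint",
    "HazardEstimate",
    "KaplanMeierResult",
    "LogrankResult",
    "build_endpoints",
    "km_estimate",
    "logrank_test",
    "cox_univariable",
    "cox_multivariable",
    "roc_analysis",
    "covariate_association",
]

DAYS_PER_MONTH = 30.4375
DEFAULT_DATA_CUTOFF = _dt.date(2023, 7, 1)
LANDMARK_MONTHS = 24.0


class DeathCause(str, Enum):
    cancer = "cancer"
    other = "other"
    unknown = "unknown"


class Endpoint(str, Enum):
    RFS = "RFS"
    OS = "OS"


@dataclass(frozen=True)
class PatientRecord:
    """Clinical record for one patient."""

    patient_id: str
    inclusion_date: _dt.date
    covariates: Mapping[str, str] = field(default_factory=dict)
    recurrence_date: _dt.date | None = None
    death_date: _dt.date | None = None
    death_cause: DeathCause = DeathCause.unknown
    data_cutoff: _dt.date = DEFAULT_DATA_CUTOFF


@dataclass(frozen=True)
class SurvivalEndpoint:
    patient_id: str
    time: float  # months
    event: bool
    endpoint: Endpoint

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: non-positive follow-up time")


@dataclass(frozen=True)
class HazardEstimate:
    """Hazard ratio with Wald 95% CI and p-value for one contrast."""

    variable: str
    level: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int = 0
    diagnostic: str = ""

    @property
    def flagged(self) -> bool:
        return bool(self.diagnostic)


def _months(a: _dt.date, b: _dt.date) -> float:
    return (b - a).days / DAYS_PER_MONTH


def build_endpoints(record: PatientRecord) -> tuple[SurvivalEndpoint, SurvivalEndpoint]:
    """Derive the (RFS, OS) endpoints for one patient.

    Deaths of unknown cause are attributed to the cancer for RFS; an
    explicit non-cancer death without prior recurrence censors RFS at
    death.
    """
    inc, cutoff = record.inclusion_date, record.data_cutoff
    for label, d in (("recurrence", record.recurrence_date), ("death", record.death_date)):
        if d is not None:
            if d < inc:
                raise ValueError(f"{record.patient_id}: {label} date precedes inclusion")
            if d > cutoff:
                raise ValueError(f"{record.patient_id}: {label} date after data cutoff")

    cancer_death = record.death_date is not None and record.death_cause in (
        DeathCause.cancer,
        DeathCause.unknown,
    )
    if record.recurrence_date is not None:
        rfs = SurvivalEndpoint(record.patient_id, _months(inc, record.recurrence_date), True, Endpoint.RFS)
    elif cancer_death:
        rfs = SurvivalEndpoint(record.patient_id, _months(inc, record.death_date), True, Endpoint.RFS)
    elif record.death_date is not None:  # non-cancer death censors RFS
        rfs = SurvivalEndpoint(record.patient_id, _months(inc, record.death_date), False, Endpoint.RFS)
    else:
        rfs = SurvivalEndpoint(record.patient_id, _months(inc, cutoff), False, Endpoint.RFS)

    if record.death_date is not None:
        os_ = SurvivalEndpoint(record.patient_id, _months(inc, record.death_date), True, Endpoint.OS)
    else:
        os_ = SurvivalEndpoint(record.patient_id, _months(inc, cutoff), False, Endpoint.OS)
    return rfs, os_


def _to_arrays(endpoints: Iterable[SurvivalEndpoint]) -> tuple[np.ndarray, np.ndarray]:
    eps = list(endpoints)
    if not eps:
        raise ValueError("no subjects")
    t = np.array([e.time for e in eps], dtype=float)
    d = np.array([bool(e.event) for e in eps], dtype=bool)
    return t, d


@dataclass
class KaplanMeierResult:
    """Product-limit estimate with plain Greenwood 95% intervals."""

    timeline: np.ndarray       # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    ci_low: np.ndarray
    ci_high: np.ndarray
    event_table: pd.DataFrame  # time, at_risk, events, censored

    def survival_at(self, t: float) -> tuple[float, float, float]:
        """Landmark survival and its Greenwood 95% CI at time ``t``."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0, 1.0
        return float(self.survival[idx]), float(self.ci_low[idx]), float(self.ci_high[idx])


def km_estimate(endpoints: Iterable[SurvivalEndpoint]) -> KaplanMeierResult:
    """Kaplan-Meier product-limit estimator.

    S(0) = 1 and the curve is non-increasing; the 95% interval uses the
    plain Greenwood variance ``S(t)^2 * sum d_i / (n_i (n_i - d_i))``,
    clipped to [0, 1].
    """
    t, d = _to_arrays(endpoints)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=d)
    tbl = kmf.event_table  # index: event/censor times
    at_risk = tbl["at_risk"].to_numpy(dtype=float)
    events = tbl["observed"].to_numpy(dtype=float)
    times = tbl.index.to_numpy(dtype=float)

    mask = events > 0
    ev_times = times[mask]
    n_i, d_i = at_risk[mask], events[mask]
    surv = np.cumprod(1.0 - d_i / n_i)
    # Greenwood: terms are infinite when d_i == n_i (curve hits zero)
    with np.errstate(divide="ignore"):
        terms = np.where(n_i > d_i, d_i / (n_i * (n_i - d_i)), np.inf)
    var = surv**2 * np.cumsum(terms)
    half = 1.959963984540054 * np.sqrt(var)
    lo = np.clip(np.where(np.isfinite(half), surv - half, 0.0), 0.0, 1.0)
    hi = np.clip(np.where(np.isfinite(half), surv + half, surv), 0.0, 1.0)

    table = pd.DataFrame(
        {
            "time": times,
            "at_risk": at_risk.astype(int),
            "events": events.astype(int),
            "censored": tbl["censored"].to_numpy(dtype=int),
        }
    )
    return KaplanMeierResult(
        timeline=ev_times, survival=surv, ci_low=lo, ci_high=hi, event_table=table
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p_value: float
    observed_a: float
    expected_a: float


def logrank_test(
    group_a: Iterable[SurvivalEndpoint] | np.ndarray,
    group_b: Iterable[SurvivalEndpoint] | np.ndarray,
    events_a: np.ndarray | None = None,
    events_b: np.ndarray | None = None,
) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df, two-sided).

    Accepts either two lists of SurvivalEndpoint or raw (times, events)
    arrays.  Symmetric in the group labels.  A degenerate instance with no
    events, or no variance, returns statistic 0 and p = 1.
    """
    if events_a is not None:
        ta = np.asarray(group_a, dtype=float)
        da = np.asarray(events_a, dtype=bool)
        tb = np.asarray(group_b, dtype=float)
        db = np.asarray(events_b, dtype=bool)
        if ta.size == 0 or tb.size == 0:
            raise ValueError("both groups must be non-empty")
    else:
        ta, da = _to_arrays(group_a)
        tb, db = _to_arrays(group_b)

    times = np.concatenate([ta, tb])
    events = np.concatenate([da, db])
    in_a = np.zeros(times.size, dtype=bool)
    in_a[: ta.size] = True

    ev_times = np.unique(times[events])
    if ev_times.size == 0:
        return LogrankResult(0.0, 1.0, 0.0, 0.0)

    # risk sets and event counts at each distinct event time
    n_tot = (times[None, :] >= ev_times[:, None]).sum(axis=1).astype(float)
    n_a = ((times[None, :] >= ev_times[:, None]) & in_a[None, :]).sum(axis=1).astype(float)
    at_t = times[None, :] == ev_times[:, None]
    d_tot = (at_t & events[None, :]).sum(axis=1).astype(float)
    d_a = (at_t & events[None, :] & in_a[None, :]).sum(axis=1).astype(float)

    expected = d_tot * n_a / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    var = np.nan_to_num(var, nan=0.0)
    o_minus_e = float(np.sum(d_a - expected))
    v = float(np.sum(var))
    if v <= 0:
        return LogrankResult(0.0, 1.0, float(d_a.sum()), float(expected.sum()))
    chi2 = o_minus_e**2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, float(d_a.sum()), float(expected.sum()))


def _levels(values: pd.Series) -> list:
    if isinstance(values.dtype, pd.CategoricalDtype):
        return [l for l in values.cat.categories if (values == l).any()]
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def _fit_cox(df: pd.DataFrame, design_cols: list[str]) -> tuple[CoxPHFitter, str]:
    """Fit Cox PH (Efron ties); on convergence failure retry ridged."""
    cph = CoxPHFitter()
    diagnostic = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df[["time", "event", *design_cols]], duration_col="time", event_col="event")
        except ConvergenceError:
            diagnostic = "monotone likelihood suspected; ridge-stabilized fit"
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df[["time", "event", *design_cols]], duration_col="time", event_col="event")
    return cph, diagnostic


def _estimates_from_fit(
    cph: CoxPHFitter,
    df: pd.DataFrame,
    contrasts: list[tuple[str, str, str]],  # (column, variable, level)
    diagnostic: str,
) -> list[HazardEstimate]:
    out = []
    summ = cph.summary
    for col, var, level in contrasts:
        row = summ.loc[col]
        n_ev = int(df.loc[df[col] == 1, "event"].sum())
        diag = diagnostic
        if n_ev == 0 or int(df.loc[df[col] == 0, "event"].sum()) == 0:
            diag = (diag + "; " if diag else "") + "no events in one level (monotone likelihood)"
        out.append(
            HazardEstimate(
                variable=var,
                level=str(level),
                hr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
                n_events=n_ev,
                diagnostic=diag,
            )
        )
    return out


def _cox_frame(
    endpoints: Iterable[SurvivalEndpoint],
    covariates: Mapping[str, Mapping[str, object]],
    levels_map: Mapping[str, Sequence] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Build the design frame: dummy columns for each non-reference level.

    The reference level of each covariate is its first category (or the
    first entry of ``levels_map[var]`` when given).
    """
    eps = list(endpoints)
    df = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in eps],
            "time": [e.time for e in eps],
            "event": [bool(e.event) for e in eps],
        }
    )
    contrasts: list[tuple[str, str, str]] = []
    for var, mapping in covariates.items():
        vals = pd.Series([mapping[pid] for pid in df["patient_id"]], index=df.index)
        if levels_map and var in levels_map:
            levels = [l for l in levels_map[var] if (vals == l).any()]
        else:
            levels = _levels(vals)
        if len(levels) < 2:
            raise ValueError(f"covariate {var!r} has no contrast (single level)")
        for level in levels[1:]:
            col = f"{var}::{level}"
            df[col] = (vals == level).astype(float)
            contrasts.append((col, var, str(level)))
    return df, contrasts


def cox_univariable(
    endpoints: Iterable[SurvivalEndpoint],
    covariate: Mapping[str, object],
    name: str = "covariate",
    levels: Sequence | None = None,
) -> list[HazardEstimate]:
    """Univariable Cox PH fit of one categorical covariate.

    Returns one hazard estimate per non-reference level (reference = first
    category, or the first entry of ``levels``); for the usual binary
    covariate the list has one entry.
    """
    df, contrasts = _cox_frame(
        endpoints, {name: covariate}, {name: levels} if levels is not None else None
    )
    if int(df["event"].sum()) == 0:
        raise ValueError("no events observed; Cox model undefined")
    cph, diag = _fit_cox(df, [c for c, _, _ in contrasts])
    return _estimates_from_fit(cph, df, contrasts, diag)


def cox_multivariable(
    endpoints: Iterable[SurvivalEndpoint],
    covariates: Mapping[str, Mapping[str, object]],
    entry_p: float = 0.05,
    levels_map: Mapping[str, Sequence] | None = None,
) -> tuple[list[HazardEstimate], list[str], dict[str, float]]:
    """Univariable screen at ``entry_p``, then a joint Cox model.

    Each candidate is first fitted alone; candidates whose smallest
    contrast p-value is < ``entry_p`` enter the joint model.  Returns
    (adjusted estimates, entered variables, screen p-values).
    """
    eps = list(endpoints)
    screen: dict[str, float] = {}
    for var, mapping in covariates.items():
        lv = levels_map.get(var) if levels_map else None
        ests = cox_univariable(eps, mapping, name=var, levels=lv)
        screen[var] = min(e.p_value for e in ests)
    entered = [v for v, p in screen.items() if p < entry_p]
    if not entered:
        raise ValueError(f"no candidate passed the univariable screen at p < {entry_p}")
    df, contrasts = _cox_frame(eps, {v: covariates[v] for v in entered}, levels_map)
    cph, diag = _fit_cox(df, [c for c, _, _ in contrasts])
    return _estimates_from_fit(cph, df, contrasts, diag), entered, screen


def roc_analysis(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve and AUC of a marker score against the outcome label.

    The label is recurrence status at end of follow-up.  Returns
    (fpr, tpr, thresholds, auc); AUC is the trapezoidal area, equivalently
    the Mann-Whitney concordance with ties at half weight.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, auc


def covariate_association(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction.  Returns (statistic, two-sided p).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or (tab < 0).any() or tab.sum() <= 0:
        raise ValueError("need a nonnegative 2-d contingency table with positive total")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero row or column margin")
    res = stats.chi2_contingency(tab, correction=False)
    return float(res.statistic), float(res.pvalue)
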