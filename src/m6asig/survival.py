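"""Kaplan-Meier estimation and k-group log-rank comparison.

KM curves come from lifelines' product-limit estimator. The log-rank test
is computed directly from the aggregated risk tables (all deaths at a tied
time processed together; subjects censored at t count as at risk at t) so
that per-group observed and expected event counts can be reported alongside
the chi-square statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from ._errors import ValidationError
from .stratification import StrataAssignment


@dataclass
class KMCurve:
    """Product-limit survival estimate over the observed event times."""

    times: np.ndarray      # sorted distinct event times
    n_risk: np.ndarray     # at-risk count just before each event time
    n_event: np.ndarray    # deaths at each event time
    survival: np.ndarray   # S(t) just after each event time
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "n_risk": self.n_risk,
            "n_event": self.n_event, "survival": self.survival,
        })


def km_estimate(os_months, os_event, label: str = "") -> KMCurve:
    """Kaplan-Meier estimate; censored-only data give S identically 1."""
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(os_event, dtype=int)
    if t.size == 0:
        raise ValidationError("survival estimate requires >=1 sample")
    if (t < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    if len(ev) == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]),
                       np.array([]), label)
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(times, ev["at_risk"].to_numpy(), ev["observed"].to_numpy(),
                   surv, label)


@dataclass
class LogRankResult:
    """k-group log-rank test with per-group observed/expected events."""

    groups: list[str]
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float


def logrank(os_months, os_event, groups) -> LogRankResult:
    """Standard k-group log-rank test on aggregated event-time tables."""
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(os_event, dtype=int)
    g = np.asarray(groups)
    if (t < 0).any():
        raise ValidationError("negative survival time")
    labels = sorted(pd.unique(g).tolist())
    k = len(labels)
    if k < 2:
        raise ValidationError("log-rank requires >=2 groups")
    sizes = {lab: int((g == lab).sum()) for lab in labels}
    empty = [lab for lab, n in sizes.items() if n == 0]
    if empty:
        raise ValidationError(f"empty group(s): {empty}")
    small = [lab for lab, n in sizes.items() if n < 5]
    if small:
        warnings.warn(f"group(s) with <5 samples: {small}")

    gidx = np.searchsorted(labels, g)
    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for tj in event_times:
        at_risk = t >= tj
        nj = at_risk.sum()
        n_ij = np.bincount(gidx[at_risk], minlength=k).astype(float)
        death = at_risk & (e == 1) & (t == tj)
        dj = death.sum()
        d_ij = np.bincount(gidx[death], minlength=k).astype(float)
        observed += d_ij
        p = n_ij / nj
        expected += dj * p
        if nj > 1:
            scale = dj * (nj - dj) / (nj - 1)
            cov += scale * (np.diag(p) - np.outer(p, p))
    if observed.sum() == 0:
        return LogRankResult(labels, observed, expected, 0.0, k - 1, 1.0)
    z = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    stat = float(z @ np.linalg.pinv(v) @ z)
    p_value = float(stats.chi2.sf(stat, k - 1))
    return LogRankResult(labels, observed, expected, stat, k - 1, p_value)


def compare_strata_survival(
    clinical,
    assignment: StrataAssignment,
    pair: tuple[str, str] | None = None,
) -> tuple[LogRankResult, dict[str, KMCurve]]:
    """Log-rank across stratification groups, plus a KM curve per group.

    With ``pair`` given (e.g. the two most diverse WRE corners), the test is
    restricted to those two labels; otherwise it is the omnibus k-group test.
    """
    os_months, os_event = clinical.survival()
    labels = assignment.labels.reindex(os_months.index).dropna()
    os_months = os_months.loc[labels.index]
    os_event = os_event.loc[labels.index]
    if pair is not None:
        a, b = pair
        if a == b:
            raise ValidationError("pair must be two distinct labels")
        present = set(labels)
        missing = [x for x in (a, b) if x not in present]
        if missing:
            raise ValidationError(f"pair label(s) absent from assignment: {missing}")
        keep = labels.isin([a, b])
        labels, os_months, os_event = labels[keep], os_months[keep], os_event[keep]
    result = logrank(os_months, os_event, labels)
    curves = {
        lab: km_estimate(os_months[labels == lab], os_event[labels == lab], lab)
        for lab in result.groups
    }
    return result, curves
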