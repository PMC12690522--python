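"""Cohort-level statistics: survival, rank tests, growth-curve alignment.

Implemented from first principles so every estimator here is independently
checkable: the Kaplan-Meier product-limit estimator with median survival,
the unpaired two-sided Mann-Whitney U test (exact by enumeration for small
tie-free samples, otherwise normal approximation with tie-corrected variance
and continuity correction), induction-aligned tumor-growth summaries
(mean +/- SD per group and day), and median/IQR box summaries.

Survival tables are DataFrames with columns animal_id, group, time_days,
event (True = endpoint reached, False = censored); growth tables carry
animal_id, group, day, induction_day, size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["KMCurve", "GroupComparison", "km_estimate", "mann_whitney",
           "align_growth", "box_summary"]


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve over the distinct event times.

    ``survival[i]`` is S(t) just after ``times[i]``; ``at_risk[i]`` and
    ``n_events[i]`` are the risk-set size and event count at that time.
    ``median`` is the earliest event time with S <= 0.5, or None when the
    curve never reaches 0.5 (flagged, not silently zero).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int
    median: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "n_events": self.n_events})

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(table: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier estimate from (time, event) records.

    At each distinct event time t_i with d_i events among n_i at risk,
    S <- S * (1 - d_i / n_i); censored animals leave the risk set after
    their censoring time (a record censored exactly at t_i still counts as
    at risk there, the standard convention).
    """
    if len(table) == 0:
        raise ValueError("empty survival table")
    times = table["time_days"].to_numpy(dtype=np.float64)
    events = table["event"].to_numpy(dtype=bool)
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    n = len(times)
    event_times = np.unique(times[events])
    surv = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    d = np.empty(len(event_times), dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(times >= t))
        d[i] = int(np.sum(events & (times == t)))
        s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    below = surv <= 0.5
    median = float(event_times[np.argmax(below)]) if below.any() else None
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk,
                   n_events=d, n_total=n, median=median)


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Two-sided Mann-Whitney comparison of two independent samples."""

    n1: int
    n2: int
    u: float          # U statistic of the first sample
    p: float
    method: str       # 'exact' or 'normal'
    alpha: float
    significant: bool


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments giving each U value, U = 0 .. n1*n2.

    Standard recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u):
    the largest rank goes to sample 1 (adding n2 to U) or to sample 2.
    """
    table = {(0, 0): np.array([1.0])}

    def counts(a: int, b: int) -> np.ndarray:
        if (a, b) in table:
            return table[(a, b)]
        if a == 0 or b == 0:
            c = np.array([1.0])
        else:
            c = np.zeros(a * b + 1)
            left = counts(a - 1, b)
            c[b:b + len(left)] += left
            right = counts(a, b - 1)
            c[: len(right)] += right
        table[(a, b)] = c
        return c

    return counts(n1, n2)


def mann_whitney(x, y, alpha: float = 0.05,
                 max_exact: int = 12) -> GroupComparison:
    """Unpaired two-sided Mann-Whitney rank test.

    U is computed from midranks of the pooled sample. When the pooled size
    is at most ``max_exact`` and there are no ties, the two-sided p-value is
    exact: p = min(1, 2 * min(P(U <= u), P(U >= u))) under full enumeration
    of rank assignments. Otherwise the normal approximation is used, with
    tie-corrected variance and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n1 + n2 <= max_exact and not has_ties:
        c = _exact_u_counts(n1, n2)
        total = c.sum()
        k = int(round(u))
        p = min(1.0, 2.0 * min(c[: k + 1].sum(), c[k:].sum()) / total)
        method = "exact"
    else:
        nn = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
        if var <= 0:  # all observations identical
            p = 1.0
        else:
            diff = u - mu
            z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var) if diff != 0 else 0.0
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    return GroupComparison(n1=n1, n2=n2, u=float(u), p=float(p), method=method,
                           alpha=alpha, significant=bool(p < alpha))


# --------------------------------------------------------------------------
# growth alignment
# --------------------------------------------------------------------------

def align_growth(growth: pd.DataFrame, bin_width: float = 1.0,
                 ) -> tuple[pd.DataFrame, list[str]]:
    """Align growth series to induction day 0 and summarize per group.

    Each animal's time axis is shifted so its induction day is 0; aligned
    days are snapped to the nearest multiple of ``bin_width`` (i.e. within
    half a bin). Per group and grid day the summary reports n, mean size and
    sample SD; days with n < 2 carry SD = NaN. Animals with no measurement
    at or after induction are excluded and returned in the second element.

    Returns (summary frame with columns group, day, n, mean, sd,
    excluded animal ids).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    required = {"animal_id", "group", "day", "induction_day", "size"}
    missing = required - set(growth.columns)
    if missing:
        raise ValueError(f"growth table missing columns {sorted(missing)}")
    df = growth.copy()
    df["aligned"] = df["day"] - df["induction_day"]
    post_max = df.groupby("animal_id")["aligned"].max()
    excluded = sorted(post_max.index[post_max < 0])
    df = df[~df["animal_id"].isin(excluded)]
    df["grid_day"] = np.round(df["aligned"] / bin_width) * bin_width
    summary = (df.groupby(["group", "grid_day"], sort=True)["size"]
               .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
               .reset_index()
               .rename(columns={"grid_day": "day"}))
    summary.loc[summary["n"] < 2, "sd"] = np.nan
    return summary, excluded


def box_summary(values) -> tuple[float, float, float]:
    """(median, q25, q75) with linear-interpolation quantiles."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("box_summary requires at least one value")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return float(med), float(q25), float(q75)
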