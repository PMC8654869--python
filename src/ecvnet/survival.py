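"""Kaplan-Meier estimation and M-sample log-rank tests for subtype evaluation.

The log-rank statistic uses the standard discrete-time construction: at each
distinct event time, observed events per group are compared with expected
counts proportional to the at-risk sizes, with the hypergeometric variance
(tie-corrected).  The statistic is the quadratic form over M-1 groups and is
referred to a chi-square distribution with M-1 degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core_io import SurvivalData
from .ecv import GroupAssignment

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
]


@dataclass
class KMCurve:
    """Product-limit survival curve for one group (steps at event times only)."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        if np.any(self.survival > 1 + 1e-12) or np.any(self.survival < -1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival curve must be non-increasing")

    def at(self, t: float) -> float:
        """Survival probability at time t (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk,
             "group": self.group}
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    groups: list[str]
    observed: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")
        if abs(self.observed.sum() - self.expected.sum()) > 1e-9:
            raise ValueError("observed and expected event totals must match")


def km_estimate(records: Sequence[SurvivalData], group: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator with right censoring."""
    if not records:
        raise ValueError("cannot estimate a survival curve from an empty group")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events == 1])
    surv, risks, s = [], [], 1.0
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        risks.append(n_at_risk)
    return KMCurve(
        times=event_times.astype(float),
        survival=np.array(surv),
        at_risk=np.array(risks, dtype=int),
        group=group,
    )


def _group_arrays(
    records: Sequence[SurvivalData], groups: GroupAssignment | Mapping[str, object]
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, int]:
    labels = groups.labels if isinstance(groups, GroupAssignment) else {
        str(k): str(v) for k, v in groups.items()
    }
    kept = [r for r in records if r.sample_id in labels]
    n_dropped = len(records) - len(kept)
    names = sorted({labels[r.sample_id] for r in kept})
    if len(names) < 2:
        raise ValueError("log-rank test needs at least two groups with records")
    gidx = {g: i for i, g in enumerate(names)}
    times = np.array([r.time for r in kept])
    events = np.array([r.event for r in kept])
    memb = np.array([gidx[labels[r.sample_id]] for r in kept])
    return names, times, events, memb, n_dropped


def logrank_test(
    records: Sequence[SurvivalData], groups: GroupAssignment | Mapping[str, object]
) -> LogRankResult:
    """M-sample log-rank test; chi-square with M-1 df under the null.

    Records without a group label are dropped.  Raises if any group present
    in the assignment has no records, or if no events are observed at all.
    """
    names, times, events, memb, _ = _group_arrays(records, groups)
    if isinstance(groups, GroupAssignment):
        missing = [g for g in groups.group_names if g not in names]
        if missing:
            raise ValueError(f"groups with no survival records: {missing}")
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank statistic undefined")

    M = len(names)
    observed = np.zeros(M)
    expected = np.zeros(M)
    var = np.zeros((M, M))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int(((times == t) & (events == 1)).sum())
        n_g = np.array([(at_risk & (memb == g)).sum() for g in range(M)], dtype=float)
        d_g = np.array(
            [((times == t) & (events == 1) & (memb == g)).sum() for g in range(M)],
            dtype=float,
        )
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            # multivariate hypergeometric covariance with tie correction
            var += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))

    z = (observed - expected)[:-1]
    V = var[:-1, :-1]
    stat = float(z @ np.linalg.pinv(V) @ z) if z.size else 0.0
    stat = max(stat, 0.0)
    df = M - 1
    p = float(chi2.sf(stat, df))
    return LogRankResult(stat, df, p, names, observed, expected)


def pairwise_logrank(
    records: Sequence[SurvivalData],
    groups: GroupAssignment | Mapping[str, object],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Two-sample log-rank test for every unordered group pair.

    p-values are raw by default; ``bonferroni=True`` adds an adjusted column
    (multiplied by the number of pairs, capped at 1).
    """
    labels = groups.labels if isinstance(groups, GroupAssignment) else {
        str(k): str(v) for k, v in groups.items()
    }
    names = sorted(set(labels.values()))
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        sub_labels = {s: g for s, g in labels.items() if g in (a, b)}
        sub_records = [r for r in records if r.sample_id in sub_labels]
        res = logrank_test(sub_records, sub_labels)
        rows.append(
            {"group_a": a, "group_b": b, "statistic": res.statistic, "p_value": res.p_value}
        )
    df = pd.DataFrame(rows)
    if bonferroni:
        df["p_adjusted"] = np.minimum(df["p_value"] * len(pairs), 1.0)
    return df


def write_km_curves(curves: Sequence[KMCurve], path: str | Path) -> None:
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
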