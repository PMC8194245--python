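"""Expression-stratified prognosis: median split, Kaplan-Meier, log-rank.

Subjects are split at the median of a marker's expression (ties go to
the low group), survival in each stratum is summarised by the
product-limit estimator, and the strata are compared with the standard
one-degree-of-freedom log-rank test.  Estimation and testing are
delegated to lifelines.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .datatypes import SurvivalRecord


def split_by_median(expression: Mapping[str, float] | pd.Series) -> dict[str, str]:
    """Label each subject ``high`` (value > median) or ``low`` (<= median).

    Requires n >= 4 and at least two distinct values.
    """
    series = pd.Series(dict(expression), dtype=float)
    if series.size < 4:
        raise ValueError(f"median split needs n >= 4, got {series.size}")
    if series.nunique() < 2:
        raise ValueError("degenerate split: all expression values are equal")
    med = float(series.median())
    return {subject: ("high" if v > med else "low") for subject, v in series.items()}


def kaplan_meier(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival curve S(t) at the distinct event times.

    Returns a DataFrame with columns ``time`` and ``survival``, starting
    at (0, 1.0) and stepping down only at times where events occurred.
    """
    if not records:
        raise ValueError("kaplan_meier needs at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events == 1])
    points = [(0.0, 1.0)]
    for t in event_times:
        points.append((float(t), float(kmf.predict(t))))
    return pd.DataFrame(points, columns=["time", "survival"])


def logrank(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two strata.

    Returns ``(chi_square, p_value)``.  Requires both groups non-empty
    and at least one observed event overall.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        raise ValueError("log-rank test undefined with zero observed events")
    result = logrank_test(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(result.test_statistic), float(result.p_value)


def stratified_survival(
    survival: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Median-split a (subject, time, event, expression) table and test.

    Convenience wrapper: returns per-group KM curves plus the log-rank
    ``(chi_square, p_value)``.
    """
    required = {"subject", "time", "event", "expression"}
    missing = required - set(survival.columns)
    if missing:
        raise ValueError(f"survival table missing column(s) {sorted(missing)}")
    groups = split_by_median(
        dict(zip(survival["subject"].astype(str), survival["expression"]))
    )
    records = {
        "high": [], "low": [],
    }
    for _, row in survival.iterrows():
        g = groups[str(row["subject"])]
        records[g].append(
            SurvivalRecord(str(row["subject"]), float(row["time"]), int(row["event"]), g)
        )
    curves = {g: kaplan_meier(rs) for g, rs in records.items() if rs}
    chi2, p = logrank(records["high"], records["low"])
    return curves, chi2, p
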