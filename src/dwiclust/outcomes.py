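"""Postoperative outcome statistics.

Outcome is the ILAE class (1-6) recorded at yearly follow-ups; a subject is
seizure-free at a given year iff the class is 1 or 2 (no disabling seizures).
For survival analysis, the event is the first yearly follow-up with
ILAE >= 3; subjects never observed to relapse are censored at their last
follow-up.  Follow-up is yearly, so event times are integers 1..5.

Group comparisons follow the conventions that reproduce the clinical
reporting: Kaplan-Meier curves with two-sided log-rank tests (lifelines),
Pearson chi-squared with Yates continuity correction for 2x2 tables (the
uncorrected statistic does not match the reported values), Wilcoxon rank-sum
with tie-corrected normal approximation, and Wilson score intervals at 90%
coverage for seizure-freedom proportions.  No multiple-testing correction is
applied anywhere; p-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

MAX_FOLLOWUP_YEARS = 5


@dataclass
class SubjectOutcome:
    """Yearly ILAE classes plus covariates for one subject.

    ``ilae_by_year[k]`` is the class at follow-up year k+1, or None once
    follow-up stops; at least year 1 must be present.
    """

    subject_id: str
    ilae_by_year: list[int | None]
    onset_age: float | None = None
    sex: str | None = None
    epilepsy_type: str | None = None  # temporal / extratemporal
    side: str | None = None  # left / right
    mri_lesional: bool | None = None

    def __post_init__(self) -> None:
        if not self.ilae_by_year or self.ilae_by_year[0] is None:
            raise ValueError("year-1 follow-up is required")
        for v in self.ilae_by_year:
            if v is not None and not 1 <= int(v) <= 6:
                raise ValueError(f"ILAE class must be in 1..6, got {v}")


@dataclass
class SurvivalRecord:
    """Time-to-first-relapse encoding of one subject's outcome."""

    subject_id: str
    time_years: int
    event: bool  # True = relapse (ILAE >= 3) observed at time_years


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n: int | None = None


def seizure_free_at(outcome: SubjectOutcome, year: int) -> bool | None:
    """True iff ILAE is 1 or 2 at that follow-up year; None if not followed."""
    if not 1 <= year <= MAX_FOLLOWUP_YEARS:
        raise ValueError("year must be in 1..5")
    if year > len(outcome.ilae_by_year):
        return None
    ilae = outcome.ilae_by_year[year - 1]
    if ilae is None:
        return None
    return ilae <= 2


def to_survival(outcome: SubjectOutcome) -> SurvivalRecord:
    """Event at the first year with ILAE >= 3; censored at last follow-up.

    A subject who relapses and later remits still counts as an event at first
    relapse ("sustained" seizure freedom).
    """
    last_seen = 0
    for year, ilae in enumerate(outcome.ilae_by_year, start=1):
        if ilae is None:
            break
        last_seen = year
        if ilae >= 3:
            return SurvivalRecord(outcome.subject_id, year, True)
    return SurvivalRecord(outcome.subject_id, last_seen, False)


def km_logrank(
    groups: dict[str, list[SurvivalRecord]],
) -> tuple[pd.DataFrame, TestResult]:
    """Kaplan-Meier curves per group plus a two-sided log-rank test.

    Returns a long-format frame (group, time, survival) with the
    product-limit estimate at each integer year, and the log-rank TestResult
    (chi-squared statistic, df = n_groups - 1).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, recs in groups.items():
        if not recs:
            raise ValueError(f"group {name!r} has no records")
    rows = []
    curves = []
    for name, recs in groups.items():
        t = np.array([r.time_years for r in recs])
        e = np.array([r.event for r in recs], dtype=bool)
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e, label=name)
        for year in range(0, MAX_FOLLOWUP_YEARS + 1):
            curves.append(
                {
                    "group": name,
                    "time_years": year,
                    "survival": float(kmf.predict(year)),
                    "n": len(recs),
                }
            )
        rows.extend({"group": name, "time": ti, "event": ei} for ti, ei in zip(t, e))
    df = pd.DataFrame(rows)
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    test = TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        method="log-rank",
        df=len(groups) - 1,
        n=len(df),
    )
    return pd.DataFrame(curves), test


def chisq_yates(table: np.ndarray | list[list[int]]) -> TestResult:
    """Pearson chi-squared on a 2x2 table with Yates continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = stats.chi2_contingency(t, correction=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="chi-squared (Yates)",
        df=1,
        n=int(t.sum()),
    )


def wilcoxon_ranksum(x, y) -> TestResult:
    """Wilcoxon rank-sum: W plus two-sided tie-corrected normal p.

    W is the rank sum of the first sample.  The normal approximation uses the
    tie-corrected variance and no continuity correction, so identical samples
    give z = 0, p = 1 exactly; degenerate all-tied data also give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (w - mu) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return TestResult(statistic=w, p_value=min(p, 1.0), method="Wilcoxon rank-sum", n=n)


def proportion_ci90(successes: int, n: int) -> tuple[float, float, float]:
    """Point estimate and 90% Wilson score interval for a proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=0.10, method="wilson")
    return successes / n, float(lo), float(hi)


def compare_counts(group_a, group_b) -> TestResult:
    """Two-sided rank-based comparison of per-subject counts or volumes."""
    return wilcoxon_ranksum(group_a, group_b)
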