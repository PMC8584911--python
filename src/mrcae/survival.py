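"""Median-split prognostic screening: Kaplan-Meier, log-rank, hazard ratio.

For each candidate feature the cohort is dichotomized at the median of its
expression — group A holds samples at or below the median (low expression),
group B holds the rest — and the two groups' survival is compared with the
two-group log-rank test. The hazard ratio is estimated from the log-rank
internals as (O_A / E_A) / (O_B / E_B), so HR > 1 means the low-expression
group dies faster. A feature is called prognostic when the log-rank p-value
is at or below alpha and the hazard ratio differs from 1.

The log-rank chi-square uses the standard Mantel-Haenszel form
(O_A - E_A)^2 / V with the hypergeometric variance V accumulated over distinct
event times, the same statistic reported by the established survival packages.
Censored subjects tied with an event time remain at risk at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .data_io import ClinicalTable, ExpressionMatrix


@dataclass
class GroupAssignment:
    """Median dichotomy of a cohort for one feature (ties at the median -> A)."""

    group_a: list[str]
    group_b: list[str]
    median: float


@dataclass
class KMCurve:
    """Product-limit survival estimate, defined at each distinct event time."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def probability_at(self, t: float) -> float:
        """S(t): survival probability just after time t (1 before any event)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class LogRankResult:
    """Two-group log-rank test with O/E-based hazard ratio."""

    observed_a: int
    observed_b: int
    expected_a: float
    expected_b: float
    chi_square: float
    p_value: float
    hazard_ratio: float
    prognostic: bool = False
    feature_id: str | None = None
    n_samples: int | None = None
    median: float | None = None


class DegenerateSplitError(ValueError):
    """All expression values equal; the median split produces an empty group."""


def filter_expressed(expr: np.ndarray, max_zero_fraction: float = 0.5) -> bool:
    """True when the feature is expressed in enough samples to analyse.

    A feature is dropped when the fraction of exact-zero values exceeds
    ``max_zero_fraction`` (default: strict majority of zeros excludes).
    """
    if not 0 < max_zero_fraction < 1:
        raise ValueError("max_zero_fraction must lie in (0, 1)")
    expr = np.asarray(expr, dtype=float)
    if expr.size == 0:
        raise ValueError("empty cohort")
    return float(np.mean(expr == 0.0)) <= max_zero_fraction


def median_split(expr: np.ndarray, sample_ids: list[str] | None = None) -> GroupAssignment:
    """Dichotomize a cohort at the sample median of one feature's expression.

    Group A: value <= median (low expression); group B: value > median.
    Uses the standard sample median (mean of the middle two for even n), so
    ties at the median fall into group A.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.size < 4:
        raise ValueError("median split needs at least 4 samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(expr.size)]
    med = float(np.median(expr))
    low = expr <= med
    if low.all():
        raise DegenerateSplitError("all values at or below the median; group B empty")
    return GroupAssignment(
        group_a=[s for s, m in zip(sample_ids, low) if m],
        group_b=[s for s, m in zip(sample_ids, low) if not m],
        median=med,
    )


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i / n_i).

    ``d_i`` events at each distinct event time ``t_i`` with ``n_i`` subjects
    still at risk; censored subjects leave the risk set after their censoring
    time (and remain at risk for events tied with it).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no survival records")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = time.size

    event_times = []
    surv = []
    at_risk = []
    s = 1.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        d = 0
        while j < n and time[j] == t:
            d += event[j]
            j += 1
        n_at_risk = n - i
        if d > 0:
            s *= 1.0 - d / n_at_risk
            event_times.append(t)
            surv.append(s)
            at_risk.append(n_at_risk)
        i = j
    return KMCurve(
        event_times=np.asarray(event_times),
        survival_prob=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
    )


def logrank_test(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the expected events per group are proportional
    to the groups' at-risk counts; the chi-square statistic is
    (O_A - E_A)^2 / V with the hypergeometric variance V summed over event
    times, referred to chi-square with 1 df. The hazard ratio is the relative
    death-rate estimate (O_A / E_A) / (O_B / E_B); when group B has no events
    the ratio is reported as +infinity.
    """
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be non-empty")
    o_a, o_b = int(event_a.sum()), int(event_b.sum())
    if o_a + o_b == 0:
        raise ValueError("log-rank test undefined with zero events")

    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b])
    group_a = np.concatenate(
        [np.ones(time_a.size, dtype=bool), np.zeros(time_b.size, dtype=bool)]
    )
    event_times = np.unique(times[events == 1])

    e_a = 0.0
    e_b = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        d_t = int(events[(times == t)].sum())
        d_a = int(events[(times == t) & group_a].sum())
        exp_a = d_t * n_a / n_t
        e_a += exp_a
        e_b += d_t - exp_a
        if n_t > 1:
            var += d_t * (n_a / n_t) * (1 - n_a / n_t) * (n_t - d_t) / (n_t - 1)
        del d_a  # observed totals already accumulated in o_a / o_b

    if var > 0:
        chi_sq = (o_a - e_a) ** 2 / var
    else:
        chi_sq = 0.0
    p = float(chi2.sf(chi_sq, df=1)) if chi_sq > 0 else 1.0

    rate_a = o_a / e_a if e_a > 0 else np.inf
    rate_b = o_b / e_b if e_b > 0 else np.inf
    if rate_b == 0:
        hr = np.inf
    elif np.isinf(rate_a) and np.isinf(rate_b):
        hr = np.nan
    else:
        hr = rate_a / rate_b

    return LogRankResult(
        observed_a=o_a,
        observed_b=o_b,
        expected_a=float(e_a),
        expected_b=float(e_b),
        chi_square=float(chi_sq),
        p_value=min(p, 1.0),
        hazard_ratio=float(hr),
    )


def is_prognostic(result: LogRankResult, alpha: float = 0.05) -> bool:
    """Prognostic call: p <= alpha and hazard ratio different from 1."""
    hr_not_one = np.isinf(result.hazard_ratio) or abs(result.hazard_ratio - 1.0) > 1e-9
    return bool(result.p_value <= alpha and hr_not_one)


def prognostic_screen(
    m: ExpressionMatrix,
    clinical: ClinicalTable,
    features: set[str] | list[str],
    alpha: float = 0.05,
    max_zero_fraction: float = 0.5,
) -> list[LogRankResult]:
    """Median-split log-rank screen of a feature list against survival.

    Expression samples without clinical records are dropped (not an error).
    Features failing the zero-expression filter or producing a degenerate
    median split are skipped. Each returned result carries the feature ID,
    cohort size, split median, log-rank internals, HR and the prognostic flag
    (p <= alpha and HR != 1; no multiple-testing correction).
    """
    clin = {s: i for i, s in enumerate(clinical.sample_ids)}
    keep = [i for i, s in enumerate(m.sample_ids) if s in clin]
    if not keep:
        raise ValueError("no overlap between expression and clinical samples")
    rows = np.asarray(keep, dtype=int)
    sample_ids = [m.sample_ids[i] for i in rows]
    clin_idx = np.asarray([clin[s] for s in sample_ids], dtype=int)
    time = clinical.time[clin_idx]
    event = clinical.event[clin_idx]

    results: list[LogRankResult] = []
    for fid in sorted(set(features)):
        col = m.values[rows, m.feature_index([fid])[0]]
        if not filter_expressed(col, max_zero_fraction):
            continue
        try:
            split = median_split(col, sample_ids)
        except DegenerateSplitError:
            continue
        in_a = np.asarray([s in set(split.group_a) for s in sample_ids])
        try:
            res = logrank_test(time[in_a], event[in_a], time[~in_a], event[~in_a])
        except ValueError:
            continue
        res.feature_id = fid
        res.n_samples = len(sample_ids)
        res.median = split.median
        res.prognostic = is_prognostic(res, alpha)
        results.append(res)
    return results
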