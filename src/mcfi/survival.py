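"""Nonparametric survival analysis: Kaplan-Meier and log-rank, first principles.

Implements the product-limit survival estimator and the k-sample log-rank
test directly from their defining sums (hypergeometric event expectations
and variances at each distinct event time), plus the frailty-stratified
"days post assessment" survival construction: each mouse's clock starts at
its frailty assessment, its stratum is low/high FI at the clinical 0.21
cutoff, and mice whose vital status is unknown are excluded.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fi_core import (
    FI_CUTOFF,
    FrailtyStratum,
    ItemCatalog,
    ValidationError,
    compute_fi,
    default_catalog,
    stratify_fi,
)
from .cohort_sim import CohortRecord, VitalStatus

__all__ = [
    "Clock",
    "SurvivalCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "survival_post_fi",
    "survival_on_age_clock",
]

logger = logging.getLogger("mcfi")


class Clock(str, enum.Enum):
    AGE = "age"  # time = age at death/censoring (origin at birth)
    POST_FI = "post-fi"  # time = days from frailty assessment


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate for one group.

    ``times`` are the distinct event (death) times in ascending order;
    ``survival[i]`` is S(times[i]); ``at_risk[i]`` and ``events[i]`` are the
    risk-set size and death count at that time.  S = 1 before the first
    event.  Subjects censored at an event time are still at risk for it
    (deaths are processed before censorings at ties).
    """

    group: str
    n: int
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """S(t) as a right-continuous step function."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    """k-sample log-rank test summary."""

    chi2: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    p_permutation: Optional[float] = None
    n_permutations: Optional[int] = None


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValidationError("times and events must have equal length")
    if times.size == 0:
        raise ValidationError("need at least one subject")
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("event flags must be 0 (censored) or 1 (died)")
    return times, events


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    group: str = "",
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i), where d_i
    deaths occur among n_i subjects at risk at t_i.
    """
    times, events = _check_times_events(times, events)
    n = times.size
    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    event_times = np.unique(ts[es == 1])
    at_risk = np.empty(event_times.size, dtype=int)
    deaths = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int((ts >= t).sum())  # censored at t still at risk
        deaths[i] = int(((ts == t) & (es == 1)).sum())
    with np.errstate(divide="ignore"):
        surv = np.cumprod(1.0 - deaths / at_risk)
    return SurvivalCurve(
        group=group,
        n=n,
        times=event_times,
        survival=surv,
        at_risk=at_risk,
        events=deaths,
    )


def _logrank_statistic(
    times: np.ndarray, events: np.ndarray, codes: np.ndarray, k: int
) -> float:
    """Log-rank chi-square from per-event-time hypergeometric moments."""
    event_times = np.unique(times[events == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    var = np.zeros((k, k))
    for t in event_times:
        at_risk_mask = times >= t
        n_t = int(at_risk_mask.sum())
        d_t = int((events[times == t] == 1).sum())
        n_g = np.bincount(codes[at_risk_mask], minlength=k).astype(float)
        d_g = np.bincount(
            codes[(times == t) & (events == 1)], minlength=k
        ).astype(float)
        obs += d_g
        exp += d_t * n_g / n_t
        if n_t > 1:
            # multivariate hypergeometric covariance of deaths per group
            frac = n_g / n_t
            c = d_t * (n_t - d_t) / (n_t - 1.0)
            var += c * (np.diag(frac) - np.outer(frac, frac))
    z = (obs - exp)[: k - 1]
    v = var[: k - 1, : k - 1]
    if z.size == 0:
        return 0.0
    try:
        chi2 = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(v) @ z)
    return max(chi2, 0.0)


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
    permutation: bool = False,
    max_exhaustive: int = 200_000,
    n_permutations: int = 20_000,
    rng: Optional[np.random.Generator] = None,
) -> LogRankResult:
    """k-sample log-rank test.

    At each distinct death time the observed deaths per group are compared
    with their hypergeometric expectation given the risk sets; the quadratic
    form of the observed-minus-expected vector in its covariance is
    chi-square with k-1 df under the null.  With ``permutation=True``, a
    permutation p-value is added by recomputing the statistic over
    reassignments of group labels (exhaustively when the number of distinct
    label arrangements is at most ``max_exhaustive``, otherwise Monte Carlo).
    """
    times, events = _check_times_events(times, events)
    groups = np.asarray([str(g) for g in groups])
    if groups.shape != times.shape:
        raise ValidationError("groups must have one label per subject")
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValidationError("need >= 2 groups for a log-rank test")
    if events.sum() == 0:
        raise ValidationError("log-rank test undefined with zero events")
    k = len(labels)
    code_of = {g: i for i, g in enumerate(labels)}
    codes = np.array([code_of[g] for g in groups])

    chi2 = _logrank_statistic(times, events, codes, k)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))

    event_times = np.unique(times[events == 1])
    obs = {g: 0.0 for g in labels}
    exp = {g: 0.0 for g in labels}
    for t in event_times:
        n_t = int((times >= t).sum())
        d_t = int((events[times == t] == 1).sum())
        for g in labels:
            gmask = codes == code_of[g]
            obs[g] += int((events[(times == t) & gmask] == 1).sum())
            exp[g] += d_t * int((times >= t)[gmask].sum()) / n_t

    p_perm = None
    n_perm = None
    if permutation:
        p_perm, n_perm = _permutation_p(
            times, events, codes, k, chi2, max_exhaustive, n_permutations, rng
        )
    return LogRankResult(
        chi2=chi2,
        df=df,
        p_value=p,
        observed=obs,
        expected=exp,
        p_permutation=p_perm,
        n_permutations=n_perm,
    )


def _permutation_p(
    times, events, codes, k, chi2_obs, max_exhaustive, n_permutations, rng
) -> tuple[float, int]:
    n = codes.size
    counts = np.bincount(codes, minlength=k)
    n_arrangements = math.factorial(n)
    for c in counts:
        n_arrangements //= math.factorial(int(c))
    tol = 1e-9
    if n_arrangements <= max_exhaustive:
        total = 0
        hits = 0
        for perm in _multiset_permutations(counts):
            total += 1
            if _logrank_statistic(times, events, np.array(perm), k) >= chi2_obs - tol:
                hits += 1
        return hits / total, total
    if rng is None:
        rng = np.random.default_rng(0)
    hits = 0
    work = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(work)
        if _logrank_statistic(times, events, work, k) >= chi2_obs - tol:
            hits += 1
    # add-one rule keeps the Monte-Carlo p valid
    return (hits + 1) / (n_permutations + 1), n_permutations


def _multiset_permutations(counts: np.ndarray):
    symbols = [g for g, c in enumerate(counts) for _ in range(int(c))]
    seen = set()
    for perm in itertools.permutations(symbols):
        if perm not in seen:
            seen.add(perm)
            yield perm


def pairwise_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> pd.DataFrame:
    """All pairwise two-group log-rank tests, raw and Bonferroni-adjusted p."""
    times, events = _check_times_events(times, events)
    groups = np.asarray([str(g) for g in groups])
    labels = sorted(set(groups.tolist()))
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        mask = np.isin(groups, (a, b))
        if events[mask].sum() == 0:
            rows.append((a, b, np.nan, np.nan, np.nan))
            logger.warning("pairwise log-rank %s vs %s: zero events, skipped", a, b)
            continue
        res = logrank_test(times[mask], events[mask], groups[mask])
        rows.append((a, b, res.chi2, res.p_value, min(1.0, res.p_value * len(pairs))))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "chi2", "p_raw", "p_bonferroni"]
    )


def _record_fi(rec: CohortRecord, catalog: ItemCatalog) -> float:
    return compute_fi(rec.assessment, catalog).fi


def survival_post_fi(
    records: Sequence[CohortRecord],
    catalog: Optional[ItemCatalog] = None,
    cutoff: float = FI_CUTOFF,
) -> pd.DataFrame:
    """Frailty-stratified survival input on the days-post-assessment clock.

    time = (death or censor day) - assessment age; stratum low/high by the
    FI cutoff; unknown-vital-status mice are excluded (and counted in the
    log).  Returns a tidy frame: mouse_id, time, event, stratum, fi.
    """
    if catalog is None:
        catalog = default_catalog()
    rows = []
    n_unknown = 0
    for rec in records:
        if rec.status is VitalStatus.UNKNOWN:
            n_unknown += 1
            continue
        end = rec.death_day if rec.status is VitalStatus.DIED else rec.censor_day
        time = end - rec.age_at_fi
        if time < 0:
            raise ValidationError(
                f"mouse {rec.mouse_id!r}: follow-up ends {time} days before "
                f"its assessment"
            )
        fi = _record_fi(rec, catalog)
        rows.append(
            {
                "mouse_id": rec.mouse_id,
                "time": float(max(time, 0.5)),  # same-day end: half-day credit
                "event": 1 if rec.status is VitalStatus.DIED else 0,
                "stratum": stratify_fi(fi, cutoff).value,
                "fi": fi,
            }
        )
    if n_unknown:
        logger.info(
            "survival_post_fi: excluded %d mice with unknown vital status",
            n_unknown,
        )
    return pd.DataFrame(rows)


def survival_on_age_clock(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Survival input on the age clock (origin at birth), grouped by sex x genotype.

    No delayed entry is applied: each mouse is treated as at risk from birth,
    matching the conventional whole-lifespan reading of group survival
    curves.  Unknown-vital-status mice are excluded.
    """
    rows = []
    n_unknown = 0
    for rec in records:
        if rec.status is VitalStatus.UNKNOWN:
            n_unknown += 1
            continue
        end = rec.death_day if rec.status is VitalStatus.DIED else rec.censor_day
        sex = "male" if rec.sex.value == "M" else "female"
        rows.append(
            {
                "mouse_id": rec.mouse_id,
                "time": float(end),
                "event": 1 if rec.status is VitalStatus.DIED else 0,
                "group": f"{sex}_{rec.genotype.value.lower()}",
            }
        )
    if n_unknown:
        logger.info(
            "survival_on_age_clock: excluded %d mice with unknown vital status",
            n_unknown,
        )
    return pd.DataFrame(rows)
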