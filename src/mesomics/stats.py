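"""Outcome-association statistics.

The association layer used throughout the pipeline: exact tests and
confidence intervals on response counts, group comparisons of continuous
biomarkers, Kaplan-Meier / log-rank / Cox survival analysis, tertile
binarization of continuous features, and the exponential trial-design
helper (hazard rate = ln 2 / median).

Conventions
-----------
* Fisher's exact test is two-sided by the probability-mass rule (sum of
  hypergeometric probabilities no larger than the observed table's), the
  default of standard statistical software.
* Binomial confidence intervals are Clopper-Pearson ("exact").
* The Mann-Whitney test is exact for small samples without ties, exact by
  full permutation for small samples with ties, and normal-approximate with
  tie correction otherwise.
* Wherever a false-discovery rate is reported it is Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})


@dataclass(frozen=True)
class PatientOutcome:
    """Clinical outcome record for one patient."""

    patient_id: str
    best_overall_response: str  # CR / PR / SD / PD / NE
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    histology: str
    germline_carrier: bool = False

    def __post_init__(self) -> None:
        if self.best_overall_response not in RESPONSE_CATEGORIES:
            raise ValueError(
                f"unknown best_overall_response {self.best_overall_response!r}"
            )
        if self.pfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be non-negative")

    @property
    def responder(self) -> bool:
        return self.best_overall_response in RESPONDER_CATEGORIES


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


@dataclass(frozen=True)
class BinomialCI:
    k: int
    n: int
    level: float
    point: float
    low: float
    high: float


@dataclass
class SurvivalFit:
    """Kaplan-Meier fit, optionally with a two-group comparison."""

    median: float  # nan if the curve never crosses 0.5
    km_times: np.ndarray
    km_survival: np.ndarray
    n: int
    hr: float = math.nan
    hr_ci: tuple[float, float] = (math.nan, math.nan)
    logrank_p: float = math.nan
    group_medians: dict = field(default_factory=dict)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_two_sided(table) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return ContingencyResult(
        table=((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
        odds_ratio=float(odds),
        p_two_sided=float(p),
    )


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Clopper-Pearson exact binomial confidence interval for k successes of n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ci = sps.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return BinomialCI(
        k=int(k), n=int(n), level=float(level),
        point=k / n, low=float(ci.low), high=float(ci.high),
    )


def response_rate(outcomes, level: float = 0.95) -> BinomialCI:
    """Objective response rate (CR+PR over all enrolled, NE in the denominator)."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes supplied")
    k = sum(1 for o in outcomes if o.best_overall_response in RESPONDER_CATEGORIES)
    return exact_binomial_ci(k, len(outcomes), level)


@dataclass(frozen=True)
class GroupComparison:
    test: str
    p: float
    statistic: float
    effect: float  # difference of group medians (mann_whitney) or odds ratio (fisher)
    n_a: int
    n_b: int


def compare_groups(values_a, values_b, test: str = "mann_whitney") -> GroupComparison:
    """Two-sided comparison of two groups of a continuous or binary feature.

    ``mann_whitney``: exact for combined n <= 20 (full-permutation when ties
    are present), normal approximation with tie correction otherwise.
    ``fisher``: values are truthy/falsy; a 2x2 table is formed.
    """
    a = list(values_a)
    b = list(values_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if test == "fisher":
        table = [
            [sum(bool(v) for v in a), sum(not v for v in a)],
            [sum(bool(v) for v in b), sum(not v for v in b)],
        ]
        res = fisher_exact_two_sided(table)
        return GroupComparison(
            test="fisher", p=res.p_two_sided, statistic=res.odds_ratio,
            effect=res.odds_ratio, n_a=len(a), n_b=len(b),
        )
    if test != "mann_whitney":
        raise ValueError(f"unknown test {test!r}")
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    n = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a_arr, b_arr]))) < n
    if n <= 20 and not has_ties:
        method = "exact"
    elif n <= 20:
        # exhaustive permutation handles ties exactly at this size
        method = sps.PermutationMethod(n_resamples=200_000, rng=0)
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a_arr, b_arr, alternative="two-sided", method=method)
    return GroupComparison(
        test="mann_whitney",
        p=float(min(1.0, res.pvalue)),
        statistic=float(res.statistic),
        effect=float(np.median(a_arr) - np.median(b_arr)),
        n_a=len(a), n_b=len(b),
    )


def _km(times: np.ndarray, events: np.ndarray):
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    median = kmf.median_survival_time_
    return (
        float(median) if np.isfinite(median) else math.nan,
        sf.index.to_numpy(dtype=float),
        sf.iloc[:, 0].to_numpy(dtype=float),
    )


def survival_analysis(
    outcomes, endpoint: str = "os", group_by=None
) -> SurvivalFit:
    """Kaplan-Meier estimate; log-rank and Cox HR when ``group_by`` is given.

    Parameters
    ----------
    outcomes
        Iterable of :class:`PatientOutcome`.
    endpoint
        ``"os"`` or ``"pfs"``.
    group_by
        Optional callable PatientOutcome -> bool/str splitting the cohort in
        two groups; the hazard ratio is for group True (or the second label
        in sorted order) versus the other.
    """
    outcomes = list(outcomes)
    if len(outcomes) < 2:
        raise ValueError("need at least two subjects")
    if endpoint == "os":
        times = np.array([o.os_months for o in outcomes], dtype=float)
        events = np.array([o.os_event for o in outcomes], dtype=bool)
    elif endpoint == "pfs":
        times = np.array([o.pfs_months for o in outcomes], dtype=float)
        events = np.array([o.pfs_event for o in outcomes], dtype=bool)
    else:
        raise ValueError("endpoint must be 'os' or 'pfs'")

    median, km_t, km_s = _km(times, events)
    fit = SurvivalFit(median=median, km_times=km_t, km_survival=km_s, n=len(outcomes))
    if group_by is None:
        return fit

    labels = np.array([group_by(o) for o in outcomes])
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"group_by must split cohort in exactly 2 groups, got {uniq}")
    g = (labels == uniq[1]).astype(int)

    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    lr = logrank_test(times[g == 1], times[g == 0], events[g == 1], events[g == 0])
    fit.logrank_p = float(lr.p_value)
    for lab in uniq:
        m, _, _ = _km(times[labels == lab], events[labels == lab])
        fit.group_medians[lab] = m
    df = pd.DataFrame({"t": times, "e": events.astype(int), "g": g})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="t", event_col="e")
        fit.hr = float(np.exp(cph.params_["g"]))
        ci = cph.confidence_intervals_
        fit.hr_ci = (
            float(np.exp(ci.iloc[0, 0])),
            float(np.exp(ci.iloc[0, 1])),
        )
    except Exception:
        # monotone likelihood (no events in one group etc.); HR stays nan
        pass
    return fit


def tertile_binarize(values) -> np.ndarray:
    """Label values "low" (<= second-tertile cutpoint) or "high".

    The cutpoint is the empirical 2/3 quantile with linear interpolation;
    ties go to "low".
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for tertile binarization")
    cut = float(np.quantile(v, 2.0 / 3.0))
    return np.where(v <= cut, "low", "high")


def exponential_design(median_months: float) -> float:
    """Hazard rate of an exponential survival model with the given median."""
    if median_months <= 0:
        raise ValueError("median must be positive")
    return math.log(2.0) / median_months


def exponential_rate_wald_test(
    times, events, null_median_months: float
) -> tuple[float, float]:
    """One-sided Wald test on the log failure rate of an exponential model.

    Returns (observed hazard rate, one-sided p for rate < null rate). The
    MLE of the exponential rate is events / total follow-up; the Wald
    statistic is on log(rate) with variance 1/events.
    """
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=bool)
    d = int(e.sum())
    if d == 0:
        raise ValueError("no events observed")
    rate = d / float(t.sum())
    null_rate = exponential_design(null_median_months)
    z = (math.log(rate) - math.log(null_rate)) * math.sqrt(d)
    return rate, float(sps.norm.cdf(z))
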