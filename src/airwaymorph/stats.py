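"""Cohort statistics for paired pre/post airway studies.

Small paired cohorts with outliers call for nonparametric tools throughout:
median (Q1-Q3) summaries, Wilcoxon signed-rank tests for T1 vs T2, and
Spearman rank correlations between airway change and OSA-18 quality-of-life
change.  Exact null distributions are used wherever the sample is small
enough to enumerate — the signed-rank distribution by subset-sum counting
over all 2^n sign assignments (handling ties in the ranks), the Spearman
null by full permutation — falling back to the usual large-sample
approximations above those sizes.

OSA-18 totals range over [18, 126] (18 items, 7-point scale) and are banded
by impact on quality of life: < 60 low, 60-80 moderate, > 80 severe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats as sps

OSA18_MIN, OSA18_MAX = 18.0, 126.0
OSA18_SUBDOMAINS = (
    "sleep_disturbance",
    "physical_suffering",
    "emotional_distress",
    "daytime_problems",
    "caregiver_concern",
)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def median_quartiles(values, rule: str = "tukey") -> tuple[float, float, float]:
    """Median with lower/upper quartiles: "median (Q1-Q3)".

    ``rule='tukey'`` uses inclusive hinges (each half includes the median
    element at odd n); ``rule='linear'`` uses linear interpolation of order
    statistics.  The two differ at the small n of clinical pilots, which is
    why the rule is explicit.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise StatsError("median_quartiles needs at least one finite value")
    med = float(np.median(v))
    if rule == "linear":
        q1, q3 = (float(q) for q in np.percentile(v, [25, 75]))
    elif rule == "tukey":
        n = len(v)
        half = (n + 1) // 2  # inclusive: odd n keeps the median in both halves
        q1 = float(np.median(v[:half]))
        q3 = float(np.median(v[n - half:]))
    else:
        raise ValueError(f"unknown quartile rule {rule!r}")
    return med, q1, q3


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    n: int            # pairs used after zero handling
    mode: str         # 'exact' or 'normal-approx'


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p for W+ by subset-sum counting over sign assignments.

    Equivalent to enumerating all 2^n assignments but polynomial-time:
    counts[w] = number of rank subsets summing to w (ranks doubled so
    tied average ranks become integers).
    """
    r2 = np.round(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    w2 = int(round(w_obs * 2))
    denom = 2.0 ** len(ranks)
    cdf = counts[: w2 + 1].sum() / denom
    sf = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(
    t1_values,
    t2_values,
    mode: str = "auto",
    zero_method: str = "wilcox",
    exact_limit: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (T2 - T1).

    ``mode`` is ``exact`` (enumerated null, default up to n = ``exact_limit``
    pairs), ``normal-approx`` (tie-corrected normal with continuity
    correction), or ``auto``.  ``zero_method='wilcox'`` drops zero
    differences before ranking; ``'pratt'`` ranks them but discards their
    contribution.  All differences equal to zero is an error: the test is
    undefined.
    """
    t1 = np.asarray(t1_values, dtype=np.float64)
    t2 = np.asarray(t2_values, dtype=np.float64)
    if t1.shape != t2.shape:
        raise StatsError("paired samples must have equal length")
    d = t2 - t1
    if np.all(d == 0):
        raise StatsError("all paired differences are zero; test undefined")
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = len(d)
    w_plus = float(ranks[d > 0].sum())

    if mode == "auto":
        mode = "exact" if n <= exact_limit else "normal-approx"
    if mode == "exact":
        p = _signed_rank_exact_p(ranks, w_plus)
    elif mode == "normal-approx":
        mu = ranks.sum() / 2.0
        var = np.square(ranks).sum() / 4.0  # tie-aware: sum r^2 / 4
        if var == 0:
            raise StatsError("zero variance in signed ranks")
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return WilcoxonResult(w_plus, p, n, mode)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    mode: str  # 'permutation' or 't-approx'


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_rho(x, y, permutation_limit: int = 10) -> SpearmanResult:
    """Spearman rank correlation with average-rank tie handling.

    The two-sided p-value is exact (full permutation enumeration of one
    margin) for n <= ``permutation_limit``, otherwise the usual
    t-approximation.  Constant input is undefined: raises.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D with equal length")
    n = len(x)
    if n < 3:
        raise StatsError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant input: Spearman correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_of_ranks(rx, ry)

    if n <= permutation_limit:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        # enumerate all n! orderings of y's ranks
        import math

        perms = np.fromiter(
            itertools.chain.from_iterable(itertools.permutations(range(n))),
            dtype=np.int8,  # n <= 10, keeps the n! x n table small
            count=math.factorial(n) * n,
        ).reshape(-1, n)
        rhos = (ryc[perms] @ rxc) / denom
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
        return SpearmanResult(rho, p, n, "permutation")
    t = rho * np.sqrt((n - 2) / max(1e-15, 1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, p, n, "t-approx")


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in all reports).

    Pilot tables conventionally report raw p-values across subdomains; the
    adjustment is provided for callers who want family-wise control.
    """
    p = np.asarray(p_values, dtype=np.float64)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


# ---------------------------------------------------------------------------
# Change scores and severity banding
# ---------------------------------------------------------------------------

@dataclass
class PercentChange:
    value: float
    is_percent: bool  # False when t1 == 0: value is the absolute difference


def percent_change(t1: float, t2: float, direction: str = "t2_minus_t1") -> PercentChange:
    """Relative change 100 * (difference) / t1 with the t1 = 0 case flagged absolute."""
    if direction == "t2_minus_t1":
        diff = t2 - t1
    elif direction == "t1_minus_t2":
        diff = t1 - t2
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if t1 == 0:
        return PercentChange(float(diff), False)
    return PercentChange(float(100.0 * diff / t1), True)


def osa18_severity(total: float) -> str:
    """Impact-on-quality-of-life band for an OSA-18 total score.

    < 60 low, 60-80 (closed interval) moderate, > 80 severe.
    """
    if not OSA18_MIN <= total <= OSA18_MAX:
        raise ValueError(
            f"OSA-18 total must lie in [{OSA18_MIN:g}, {OSA18_MAX:g}], got {total}"
        )
    if total < 60:
        return "low"
    if total <= 80:
        return "moderate"
    return "severe"


# ---------------------------------------------------------------------------
# Subject records and cohort-level analysis
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One subject's paired questionnaire scores and airway measures.

    ``measures`` maps a measure name (e.g. ``volume_cm3``, ``patency_pct``)
    to its (T1, T2) values for the surgical segment.
    """

    subject_id: str
    osa18_t1: float
    osa18_t2: float
    measures: dict[str, tuple[float, float]] = field(default_factory=dict)
    subdomains_t1: dict[str, float] = field(default_factory=dict)
    subdomains_t2: dict[str, float] = field(default_factory=dict)
    surgery: str = ""
    recall_months: float = np.nan

    def __post_init__(self):
        for v in (self.osa18_t1, self.osa18_t2):
            if not OSA18_MIN <= v <= OSA18_MAX:
                raise ValueError(f"OSA-18 total {v} outside [{OSA18_MIN}, {OSA18_MAX}]")

    @property
    def osa18_improvement_pct(self) -> float:
        return percent_change(self.osa18_t1, self.osa18_t2, "t1_minus_t2").value


@dataclass
class CohortSummary:
    """Per-variable medians/quartiles, paired tests, and correlations."""

    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    severity_transitions: pd.DataFrame


def paired_variable_summary(
    name: str, t1, t2, rule: str = "tukey"
) -> dict[str, float | str]:
    """One Table-row worth of summary: medians at both timepoints, change, p."""
    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    m1, q1a, q3a = median_quartiles(t1, rule)
    m2, q1b, q3b = median_quartiles(t2, rule)
    per_subject_pct = [
        percent_change(a, b, "t1_minus_t2").value for a, b in zip(t1, t2) if a != 0
    ]
    try:
        test = wilcoxon_signed_rank(t1, t2)
        p = test.p_value
    except StatsError:
        p = np.nan
    row: dict[str, float | str] = {
        "variable": name,
        "t1_median": m1, "t1_q1": q1a, "t1_q3": q3a,
        "t2_median": m2, "t2_q1": q1b, "t2_q3": q3b,
        "p_value": p,
        # two estimands for the percent change, labelled: the median of
        # per-subject changes and the change of medians
        "pct_change_median_of_changes": (
            float(np.median(per_subject_pct)) if per_subject_pct else np.nan
        ),
        "pct_change_of_medians": (
            100.0 * (m1 - m2) / m1 if m1 != 0 else np.nan
        ),
    }
    return row


def correlate_airway_with_osa18(
    records: list[SubjectRecord],
    improvement_direction: dict[str, str] | None = None,
) -> CohortSummary:
    """Correlate OSA-18 improvement with the change in each airway measure.

    For every measure present in the records, the per-subject change
    (T2 - T1, or T1 - T2 where ``improvement_direction`` says improvement is
    a decrease, e.g. constriction) is correlated (Spearman) with the
    per-subject OSA-18 improvement.  Requires at least five complete
    subjects per measure.
    """
    if len(records) < 5:
        raise StatsError(f"need >= 5 complete subjects, got {len(records)}")
    improvement_direction = improvement_direction or {}
    osa_change = np.array([r.osa18_improvement_pct for r in records])

    measure_names: list[str] = sorted({m for r in records for m in r.measures})
    corr_rows = []
    for name in measure_names:
        deltas, osa = [], []
        for r, oc in zip(records, osa_change):
            if name not in r.measures:
                continue
            t1v, t2v = r.measures[name]
            if improvement_direction.get(name) == "decrease":
                deltas.append(t1v - t2v)
            else:
                deltas.append(t2v - t1v)
            osa.append(oc)
        if len(deltas) < 5:
            raise StatsError(f"measure {name!r} has only {len(deltas)} complete subjects")
        res = spearman_rho(np.asarray(deltas), np.asarray(osa), permutation_limit=8)
        corr_rows.append(
            {"measure": name, "n": res.n, "rho": res.rho, "p_value": res.p_value}
        )
    correlations = pd.DataFrame(corr_rows)

    desc_rows = [
        paired_variable_summary(
            "osa18_total",
            [r.osa18_t1 for r in records],
            [r.osa18_t2 for r in records],
        )
    ]
    for name in measure_names:
        rs = [r for r in records if name in r.measures]
        desc_rows.append(
            paired_variable_summary(
                name,
                [r.measures[name][0] for r in rs],
                [r.measures[name][1] for r in rs],
            )
        )
    descriptives = pd.DataFrame(desc_rows)

    trans = pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "severity_t1": [osa18_severity(r.osa18_t1) for r in records],
            "severity_t2": [osa18_severity(r.osa18_t2) for r in records],
        }
    )
    return CohortSummary(descriptives, correlations, trans)
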