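"""Nonparametric statistics against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from airwaymorph import stats as ams


# ---------------------------------------------------------------------------
# median / quartiles
# ---------------------------------------------------------------------------

def tukey_oracle(values):
    """Sort-based inclusive-hinge quartiles."""
    v = np.sort(values)
    n = len(v)
    half = (n + 1) // 2
    return float(np.median(v)), float(np.median(v[:half])), float(np.median(v[n - half:]))


def test_median_quartiles_small_example():
    assert ams.median_quartiles([1, 2, 3, 4, 5]) == (3, 2, 4)
    assert ams.median_quartiles([7.0]) == (7, 7, 7)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=100))
def test_median_quartiles_matches_sort_oracle(values):
    med, q1, q3 = ams.median_quartiles(values, rule="tukey")
    om, o1, o3 = tukey_oracle(np.asarray(values))
    assert (med, q1, q3) == (om, o1, o3)
    assert q1 <= med <= q3


def test_linear_rule_matches_percentile():
    rng = np.random.default_rng(3)
    v = rng.normal(size=37)
    med, q1, q3 = ams.median_quartiles(v, rule="linear")
    assert q1 == pytest.approx(np.percentile(v, 25))
    assert q3 == pytest.approx(np.percentile(v, 75))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_bruteforce_p(diffs):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.asarray(ws)
    denom = len(ws)
    cdf = (ws <= w_obs + 1e-9).sum() / denom
    sf = (ws >= w_obs - 1e-9).sum() / denom
    return min(1.0, 2.0 * min(cdf, sf))


def test_all_positive_n6_exact_p():
    """Six positive differences: most extreme assignment, p = 2/2^6."""
    t1 = np.zeros(6)
    t2 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    res = ams.wilcoxon_signed_rank(t1, t2, mode="exact")
    assert res.p_value == pytest.approx(2.0 / 64.0)


def test_all_zero_differences_rejected():
    with pytest.raises(ams.StatsError):
        ams.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


@pytest.mark.parametrize("seed", range(8))
def test_exact_p_matches_full_enumeration(seed):
    """Exact p equals brute-force 2^n enumeration, n <= 12, ties included."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    t1 = rng.integers(0, 6, size=n).astype(float)  # integers force ties
    t2 = t1 + rng.integers(-4, 5, size=n)
    if np.all(t2 == t1):
        t2[0] += 1.0
    res = ams.wilcoxon_signed_rank(t1, t2, mode="exact")
    assert res.p_value == pytest.approx(wilcoxon_bruteforce_p(t2 - t1))


def test_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(11)
    t1 = rng.normal(size=10)
    t2 = t1 + rng.normal(size=10)
    ours = ams.wilcoxon_signed_rank(t1, t2, mode="exact")
    ref = sps.wilcoxon(t2, t1, alternative="two-sided", method="exact")
    assert ours.p_value == pytest.approx(ref.pvalue)


def test_normal_approx_mode_reasonable():
    rng = np.random.default_rng(2)
    t1 = rng.normal(size=40)
    t2 = t1 + 0.8 + rng.normal(size=40)
    res = ams.wilcoxon_signed_rank(t1, t2, mode="normal-approx")
    assert res.mode == "normal-approx"
    assert res.p_value < 0.01


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman_rank_oracle(x, y):
    """Pearson on explicit average ranks."""
    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        sv = np.asarray(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def test_perfect_monotone():
    x = np.arange(8, dtype=float)
    assert ams.spearman_rho(x, x**3).rho == pytest.approx(1.0)
    assert ams.spearman_rho(x, -np.exp(x)).rho == pytest.approx(-1.0)


def test_ties_match_average_rank_oracle():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
    y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 5.0, 5.0, 6.0])
    res = ams.spearman_rho(x, y)
    assert res.rho == pytest.approx(spearman_rank_oracle(x, y))
    assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic)


def test_invariant_under_strictly_monotone_transform():
    rng = np.random.default_rng(9)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    base = ams.spearman_rho(x, y).rho
    assert ams.spearman_rho(np.exp(x), y).rho == pytest.approx(base)
    assert ams.spearman_rho(x, 3 * y - 7).rho == pytest.approx(base)


def test_permutation_p_matches_exact_enumeration_small_n():
    """n = 5: compare against direct enumeration of all 5! orderings."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    res = ams.spearman_rho(x, y)
    rho_obs = spearman_rank_oracle(x, y)
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rank_oracle(x, np.array(perm))) >= abs(rho_obs) - 1e-12:
            count += 1
    assert res.p_value == pytest.approx(count / total)


def test_constant_input_rejected():
    with pytest.raises(ams.StatsError):
        ams.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_holm_correction_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    p = rng.uniform(0, 0.2, size=6)
    ours = ams.holm_correction(p)
    _, ref, _, _ = multipletests(p, method="holm")
    np.testing.assert_allclose(ours, ref)


# ---------------------------------------------------------------------------
# percent change + severity bands
# ---------------------------------------------------------------------------

def test_percent_change_directions():
    assert ams.percent_change(100.0, 50.0, "t1_minus_t2").value == pytest.approx(50.0)
    assert ams.percent_change(64.2, 37.6, "t1_minus_t2").value == pytest.approx(
        41.4, abs=0.05
    )
    flagged = ams.percent_change(0.0, 8.0)
    assert not flagged.is_percent and flagged.value == 8.0


@pytest.mark.parametrize(
    "score,band",
    [(64.2, "moderate"), (37.6, "low"), (59.9, "low"), (60.0, "moderate"),
     (80.0, "moderate"), (80.1, "severe"), (126.0, "severe"), (18.0, "low")],
)
def test_osa18_severity_bands(score, band):
    assert ams.osa18_severity(score) == band


def test_osa18_severity_range_check():
    with pytest.raises(ValueError):
        ams.osa18_severity(10.0)


# ---------------------------------------------------------------------------
# cohort correlation
# ---------------------------------------------------------------------------

def _records(n, rng, coupled=True):
    recs = []
    gains = rng.uniform(0, 30, n)
    noise = rng.normal(0, 8, n)
    for i in range(n):
        imp = 30 + gains[i] * (1.5 if coupled else 0.0) + noise[i]
        t1 = 70.0
        t2 = float(np.clip(t1 * (1 - imp / 100.0), 18, 126))
        recs.append(
            ams.SubjectRecord(
                subject_id=f"s{i}",
                osa18_t1=t1,
                osa18_t2=t2,
                measures={
                    "patency_pct": (3.0, 3.0 + gains[i]),
                    "volume_cm3": (5.0, 5.0 + rng.normal(0, 1)),
                },
            )
        )
    return recs


def test_cohort_correlation_recovers_coupling():
    rng = np.random.default_rng(1)
    summary = ams.correlate_airway_with_osa18(_records(60, rng))
    corr = summary.correlations.set_index("measure")
    assert corr.loc["patency_pct", "rho"] > 0.5
    assert abs(corr.loc["volume_cm3", "rho"]) < 0.35
    assert set(summary.severity_transitions.columns) == {
        "subject", "severity_t1", "severity_t2"
    }


def test_cohort_refuses_insufficient_subjects():
    rng = np.random.default_rng(2)
    with pytest.raises(ams.StatsError):
        ams.correlate_airway_with_osa18(_records(3, rng))
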