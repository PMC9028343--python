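"""Group summaries and hypothesis tests for the tile and endpoint statistics.

The tile statistics (N_G, N_PC per 250×250 tile) are compared between
vaseline-treated (VAS) and imiquimod-treated (IMQ) arms with the two-sided
Mann–Whitney U test; profile-level endpoints (AUC, functional parameters)
use two-way fixed-effects ANOVA with Bonferroni-corrected pairwise post-hoc
t tests, or Student's t for plain two-group calls.  All test statistics are
computed from first principles here; SciPy supplies only distribution tail
probabilities (normal, t, F), and serves as an independent cross-check in
the test suite.

Conventions, fixed across the package:

* all tests are two-sided; significance threshold α = 0.05;
* Mann–Whitney uses mid-ranks for ties and reports U = min(U1, U2); the
  exact null distribution is used for combined n ≤ 12 with no ties
  (dynamic-programming recurrence), otherwise a tie-corrected normal
  approximation with continuity correction;
* quartiles use linear interpolation between order statistics (the numpy
  default), which determines where box edges fall;
* standard deviations use the n−1 denominator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

ALPHA = 0.05

#: Combined sample size at or below which the exact U distribution is used.
EXACT_N_LIMIT = 12


@dataclass(frozen=True)
class FiveNumber:
    """Five-number boxplot summary plus mean and sample sd."""

    min: float
    q1: float
    median: float
    q3: float
    max: float
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class TestResult:
    statistic_name: str  # "U" | "F" | "t"
    statistic_value: float
    p_value: float
    n1: int
    n2: int
    method: str
    alternative: str = "two-sided"


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with tied values sharing the average of their positions."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    n = len(pooled)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of arrangements giving each U1 value, by the standard recurrence.

    Uses the classical recurrence
    ``N(u; i, j) = N(u - j; i - 1, j) + N(u; i, j - 1)``
    (the last pooled observation is either an x, contributing j inversions,
    or a y, contributing none).  Entry ``u`` of the result is the number of
    the C(n1+n2, n1) arrangements with U1 = u.
    """
    max_u = n1 * n2
    # table[j] holds the distribution for (i, j) as i advances
    table = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        table[j][0] = 1.0  # i = 0: U is always 0
    for _i in range(1, n1 + 1):
        new = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
        new[0][0] = 1.0  # j = 0: U is always 0
        for j in range(1, n2 + 1):
            shifted = np.zeros(max_u + 1)
            shifted[j:] = table[j][: max_u + 1 - j]
            new[j] = shifted + new[j - 1]
        table = new
    return table[n2]


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test with mid-ranks.

    ``method`` is ``"auto"`` (exact when combined n ≤ 12 and no ties, else
    normal), ``"exact"`` (full-enumeration permutation test, valid with
    ties), or ``"normal"`` (tie-corrected normal approximation with
    continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if method == "auto":
        method = "exact" if (n1 + n2 <= EXACT_N_LIMIT and not has_ties) else "normal"
    if method not in ("exact", "normal"):
        raise ValueError(f"unknown method {method!r}")

    if method == "exact" and not has_ties:
        dist = _exact_u_distribution(n1, n2)
        total = dist.sum()
        us = np.arange(len(dist), dtype=float)
        extreme = np.minimum(us, n1 * n2 - us) <= u + 1e-9
        p = float(dist[extreme].sum() / total)
        return TestResult("U", u, min(p, 1.0), n1, n2, "exact-enumeration")
    if method == "exact":
        # Ties: enumerate group assignments of the fixed mid-ranks directly.
        n = n1 + n2
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            r1p = float(ranks[list(combo)].sum())
            u1p = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1p
            if min(u1p, n1 * n2 - u1p) <= u + 1e-9:
                count += 1
            total += 1
        return TestResult("U", u, count / total, n1, n2, "exact-enumeration")

    mean = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations tied: no evidence either way
        return TestResult("U", u, 1.0, n1, n2, "normal-approximation-tie-corrected")
    z = (u - mean + 0.5) / math.sqrt(var)  # u <= mean, continuity correction
    p = min(1.0, float(math.erfc(-z / math.sqrt(2.0))))
    return TestResult("U", u, p, n1, n2, "normal-approximation-tie-corrected")


# ---------------------------------------------------------------------------
# Boxplot summary
# ---------------------------------------------------------------------------

def boxplot_summary(values) -> FiveNumber:
    """Five-number summary with linearly interpolated quartiles, mean and sd."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_summary requires a non-empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return FiveNumber(
        min=float(v.min()), q1=float(q1), median=float(med), q3=float(q3),
        max=float(v.max()), n=int(v.size), mean=float(v.mean()), sd=sd,
    )


# ---------------------------------------------------------------------------
# VAS-vs-IMQ comparison table over the tile statistics
# ---------------------------------------------------------------------------

def condition_table(
    stats: pd.DataFrame, alpha: float = ALPHA, method: str = "auto"
) -> pd.DataFrame:
    """Mann–Whitney VAS-vs-IMQ p-values for N_G and N_PC per (strain, timepoint).

    ``stats`` must carry columns ``strain, treatment, timepoint, n_g, n_pc``
    with treatment labels ``"VAS"`` and ``"IMQ"``.  Returns one row per
    (strain, timepoint) cell with the two p-values and significance flags at
    ``alpha``.
    """
    required = {"strain", "treatment", "timepoint", "n_g", "n_pc"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    rows = []
    for (strain, timepoint), cell in stats.groupby(["strain", "timepoint"], sort=True):
        arms = {t: g for t, g in cell.groupby("treatment")}
        for arm in ("VAS", "IMQ"):
            if arm not in arms or len(arms[arm]) == 0:
                raise ValueError(
                    f"missing {arm} arm for strain={strain!r}, timepoint={timepoint!r}"
                )
        res_ng = mann_whitney(arms["VAS"]["n_g"], arms["IMQ"]["n_g"], method=method)
        res_npc = mann_whitney(arms["VAS"]["n_pc"], arms["IMQ"]["n_pc"], method=method)
        rows.append(
            {
                "strain": strain,
                "timepoint": timepoint,
                "p_n_g": res_ng.p_value,
                "p_n_pc": res_npc.p_value,
                "significant_n_g": res_ng.p_value < alpha,
                "significant_n_pc": res_npc.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-way ANOVA + Bonferroni post-hoc, Student's t
# ---------------------------------------------------------------------------

def _dummies(levels: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level as reference)."""
    cats = sorted(levels.unique())
    return np.column_stack([(levels == c).to_numpy(float) for c in cats[1:]]) if len(cats) > 1 else np.empty((len(levels), 0))


def _rss(xmat: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
    resid = y - xmat @ beta
    return float(resid @ resid)


def two_way_anova_bonferroni(
    data: pd.DataFrame, response: str, factor_a: str, factor_b: str
):
    """Two-way fixed-effects ANOVA (sequential SS) with Bonferroni post-hoc.

    Sums of squares are sequential (A, then B given A, then the interaction),
    which reduces to the textbook mean decomposition for balanced layouts and
    remains well defined for unbalanced ones.  The post-hoc compares the
    levels of ``factor_a`` pairwise within each level of ``factor_b`` with t
    tests on the pooled error variance; raw p-values are multiplied by the
    number of comparisons and capped at 1.

    Returns ``(anova, posthoc)``: a dict of :class:`TestResult` keyed by
    ``factor_a``, ``factor_b`` and ``"interaction"``, and a DataFrame of the
    pairwise comparisons.  Degenerate data with zero error variance reports
    F = 0, p = 1 when the effect SS is also zero, and F = inf with the
    smallest positive p otherwise.
    """
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    for fac in (factor_a, factor_b):
        if data[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} has fewer than 2 levels")
    y = data[response].to_numpy(float)
    n = len(y)
    a = _dummies(data[factor_a])
    b = _dummies(data[factor_b])
    ab = np.column_stack(
        [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
    ) if a.shape[1] and b.shape[1] else np.empty((n, 0))
    ones = np.ones((n, 1))
    x0 = ones
    x1 = np.hstack([ones, a])
    x2 = np.hstack([ones, a, b])
    x3 = np.hstack([ones, a, b, ab])
    rss0, rss1, rss2, rss3 = (_rss(m, y) for m in (x0, x1, x2, x3))
    df_a, df_b, df_ab = a.shape[1], b.shape[1], ab.shape[1]
    df_e = n - x3.shape[1]
    if df_e <= 0:
        raise ValueError("no residual degrees of freedom (need replication)")
    sse = rss3
    mse = sse / df_e
    tiny = float(np.finfo(float).tiny)
    # least-squares residual noise on an exactly-fitting model shows up as
    # SS of order eps^2 * scale; anything below this is structurally zero
    sst = float(((y - y.mean()) ** 2).sum())
    tol = 1e-10 * max(sst, 1.0)

    def f_result(ss: float, df_num: int) -> TestResult:
        ss = max(ss, 0.0)
        if ss < tol:
            return TestResult("F", 0.0, 1.0, df_num, df_e, "parametric")
        if sse < tol:
            return TestResult("F", math.inf, tiny, df_num, df_e, "parametric")
        f = (ss / df_num) / mse
        return TestResult(
            "F", f, float(_sps.f.sf(f, df_num, df_e)) or tiny, df_num, df_e, "parametric"
        )

    anova = {
        factor_a: f_result(rss0 - rss1, df_a),
        factor_b: f_result(rss1 - rss2, df_b),
        "interaction": f_result(rss2 - rss3, df_ab),
    }

    # Bonferroni post-hoc: factor_a levels pairwise within each factor_b level.
    comparisons = []
    a_levels = sorted(data[factor_a].unique())
    b_levels = sorted(data[factor_b].unique())
    pairs = [
        (bl, a1, a2)
        for bl in b_levels
        for a1, a2 in itertools.combinations(a_levels, 2)
    ]
    m = len(pairs)
    for bl, a1, a2 in pairs:
        g1 = y[(data[factor_a] == a1) & (data[factor_b] == bl)]
        g2 = y[(data[factor_a] == a2) & (data[factor_b] == bl)]
        if len(g1) == 0 or len(g2) == 0:
            continue
        diff = float(g1.mean() - g2.mean())
        se = math.sqrt(mse * (1.0 / len(g1) + 1.0 / len(g2))) if mse >= tol else 0.0
        if se == 0.0:
            t_val, p_raw = (0.0, 1.0) if abs(diff) < math.sqrt(tol) else (math.inf, tiny)
        else:
            t_val = diff / se
            p_raw = float(2.0 * _sps.t.sf(abs(t_val), df_e)) or tiny
        comparisons.append(
            {
                factor_b: bl, "level_1": a1, "level_2": a2,
                "mean_diff": diff, "t": t_val, "df": df_e,
                "p_raw": min(p_raw, 1.0), "p_bonferroni": min(1.0, m * p_raw),
            }
        )
    return anova, pd.DataFrame(comparisons)


def student_t(x, y) -> TestResult:
    """Two-sided pooled-variance Student's t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("student_t requires at least 2 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = float(x.mean() - y.mean())
    tiny = float(np.finfo(float).tiny)
    if sp2 <= 0:
        if diff == 0.0:
            return TestResult("t", 0.0, 1.0, n1, n2, "parametric")
        return TestResult("t", math.inf, tiny, n1, n2, "parametric")
    t_val = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = min(1.0, float(2.0 * _sps.t.sf(abs(t_val), df))) or tiny
    return TestResult("t", t_val, p, n1, n2, "parametric")
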