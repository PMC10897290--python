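"""Group-comparison statistics policy.

The policy mirrors how the morphometric tables are compared across cell
lines: each group is tested against a designated reference (wild type) with
a two-sided Mann-Whitney U test unless *both* samples pass a Shapiro-Wilk
normality check, in which case Welch's unequal-variance t test is used.
No multiple-testing correction is applied to the pairwise comparisons by
default (a Holm adjustment is available as an option).

The exact Mann-Whitney branch enumerates all C(n_a + n_b, n_a) relabelings
of the pooled sample (midranks, so ties are handled naturally) and is used
whenever both samples are small; larger samples use the tie- and
continuity-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupTable",
    "choose_test",
    "mann_whitney",
    "welch_t",
    "summarize",
    "compare_to_reference",
    "holm_adjust",
]


@dataclass
class TestResult:
    """One two-sample comparison with its gate bookkeeping."""

    metric: str
    group_a: str
    group_b: str
    test_name: str  # mann_whitney | welch_t
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    normality_p_a: float | None = None
    normality_p_b: float | None = None
    exact: bool | None = None  # which Mann-Whitney branch produced p

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GroupTable:
    """Long-format measurement table: (group, unit id, metric, value)."""

    data: pd.DataFrame  # columns: group, unit_id, metric, value
    reference: str = "WT"
    units: dict[str, str] | None = None

    def __post_init__(self) -> None:
        required = {"group", "unit_id", "metric", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"group table lacks columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.data["value"].to_numpy(dtype=float))):
            raise ValueError("group table contains non-finite values")

    def sample(self, group: str, metric: str) -> np.ndarray:
        sel = (self.data["group"] == group) & (self.data["metric"] == metric)
        return self.data.loc[sel, "value"].to_numpy(dtype=float)


def choose_test(sample_a, sample_b, alpha_normality: float = 0.05) -> str:
    """Welch's t iff both samples pass Shapiro-Wilk at ``alpha_normality``,
    otherwise Mann-Whitney.  Requires n >= 3 per sample (Shapiro's minimum)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("normality gating needs at least 3 observations per sample")
    p_a = _shapiro_p(a)
    p_b = _shapiro_p(b)
    return "welch_t" if (p_a > alpha_normality and p_b > alpha_normality) else "mann_whitney"


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:  # constant sample: certainly not Gaussian noise
        return 0.0
    return float(sps.shapiro(x).pvalue)


def _u_statistic(ranks_a_sum: float, n_a: int) -> float:
    return ranks_a_sum - n_a * (n_a + 1) / 2.0


def mann_whitney(sample_a, sample_b, exact_threshold: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact branch (both n <= ``exact_threshold``): the p-value is the fraction
    of all C(n_a+n_b, n_a) relabelings of the pooled observations whose U is
    at least as far from the null centre n_a*n_b/2 as the observed U; midranks
    make this valid under ties.  Otherwise the normal approximation with tie
    correction and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be nonempty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(float(ranks[:n_a].sum()), n_a)
    center = n_a * n_b / 2.0

    exact = n_a <= exact_threshold and n_b <= exact_threshold
    if exact:
        dev_obs = abs(u_obs - center)
        hits = 0
        total = comb(n_a + n_b, n_a)
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(float(ranks[list(idx)].sum()), n_a)
            if abs(u - center) >= dev_obs - 1e-9:
                hits += 1
        p = hits / total
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        u_obs = float(res.statistic)
    return TestResult(
        metric="",
        group_a="a",
        group_b="b",
        test_name="mann_whitney",
        statistic=float(u_obs),
        p_value=float(min(p, 1.0)),
        n_a=n_a,
        n_b=n_b,
        exact=exact,
    )


def welch_t(sample_a, sample_b) -> TestResult:
    """Two-sided unpaired t test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t needs at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult(
                metric="", group_a="a", group_b="b", test_name="welch_t",
                statistic=0.0, p_value=1.0, n_a=len(a), n_b=len(b),
            )
        raise ValueError("both samples are constant with different means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        metric="", group_a="a", group_b="b", test_name="welch_t",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=len(a), n_b=len(b),
    )


def summarize(table: GroupTable) -> pd.DataFrame:
    """Per-group mean, SD (ddof=1) and n for every metric (the ``mean +/- SD``
    convention of the figure legends)."""
    g = table.data.groupby(["metric", "group"])["value"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    return out


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (optional; off by default in reports)."""
    order = np.argsort(p_values)
    m = len(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adj[i] = min(running, 1.0)
    return adj.tolist()


def compare_to_reference(
    table: GroupTable,
    alpha_normality: float = 0.05,
    exact_threshold: int = 8,
    holm: bool = False,
) -> list[TestResult]:
    """Test every non-reference group against the reference, per metric,
    choosing Mann-Whitney or Welch's t by the normality gate."""
    results: list[TestResult] = []
    metrics = sorted(table.data["metric"].unique())
    groups = [g for g in sorted(table.data["group"].unique()) if g != table.reference]
    for metric in metrics:
        ref = table.sample(table.reference, metric)
        for group in groups:
            other = table.sample(group, metric)
            if len(ref) == 0 or len(other) == 0:
                continue
            name = choose_test(ref, other, alpha_normality)
            if name == "welch_t":
                res = welch_t(ref, other)
            else:
                res = mann_whitney(ref, other, exact_threshold)
            res.metric = metric
            res.group_a = table.reference
            res.group_b = group
            res.normality_p_a = _shapiro_p(np.asarray(ref, float))
            res.normality_p_b = _shapiro_p(np.asarray(other, float))
            results.append(res)
    if holm and results:
        adjusted = holm_adjust([r.p_value for r in results])
        for r, p in zip(results, adjusted):
            r.p_value = p
    return results


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
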