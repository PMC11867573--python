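"""Volume-agreement statistics: ICC(2,1), Wilcoxon rank-sum, mean ± SD tables.

ICC(2,1) is the intraclass correlation for a two-way random-effects model
with absolute agreement and single measures (Shrout & Fleiss).  With n
subjects and k raters, from the two-way ANOVA mean squares (MSR between
subjects, MSC between raters, MSE residual):

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1)·MSE + (k/n)·(MSC - MSE))

Under the variance-components model v_ij = mu + p_i + r_j + e_ij this
estimates sigma_p^2 / (sigma_p^2 + sigma_r^2 + sigma_e^2): rater bias counts
against agreement, which is what "absolute agreement" means.  Values above
0.75 are conventionally read as good agreement.

The Wilcoxon rank-sum test compares two independent samples via the sum of
midranks of the first sample in the pooled ordering.  The exact two-sided
p-value is the permutation probability P(|W - E[W]| >= |w_obs - E[W]|),
computed by dynamic programming over the permutation distribution of the
(doubled) midranks; large or tied samples fall back to the normal
approximation with tie and continuity corrections.  Significance is read at
p < 0.05 throughout, with no multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ICCResult",
    "TestResult",
    "icc_2_1",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "summarize_mean_sd",
]

#: agreement threshold for the ICC `good` flag
ICC_GOOD_THRESHOLD = 0.75
#: two-sided significance level for the `significant` flag
ALPHA = 0.05


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) estimate with the ANOVA mean squares behind it."""

    icc: float
    n_subjects: int
    n_raters: int
    ms_rows: float
    ms_cols: float
    ms_error: float

    @property
    def good(self) -> bool:
        """True iff the estimate exceeds the conventional 0.75 threshold."""
        return self.icc > ICC_GOOD_THRESHOLD


@dataclass(frozen=True)
class TestResult:
    """A two-sided hypothesis-test outcome."""

    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def icc_2_1(data: np.ndarray | Sequence[Sequence[float]]) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Parameters
    ----------
    data : array-like, shape (n_subjects, n_raters)
        One measurement per subject per rater; no missing cells.

    Notes
    -----
    Negative estimates are reported as computed (not clipped at zero);
    the ``good`` flag handles interpretation.  The estimate is invariant
    to adding a constant to all cells and to positive rescaling.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"data must be 2D (subjects x raters), got shape {x.shape}")
    n, k = x.shape
    if n < 2:
        raise ValueError(f"need >= 2 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need >= 2 raters, got {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data contains missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_error / ((n - 1) * (k - 1)), 0.0)  # clamp fp negatives

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom > 0 else 1.0 if msr > 0 else 0.0
    return ICCResult(
        icc=float(icc), n_subjects=n, n_raters=k,
        ms_rows=msr, ms_cols=msc, ms_error=mse,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

#: auto rule: exact path when min(n, m) <= this and the pooled data has no ties
EXACT_MAX_MIN_N = 10


def _rank_sum_exact_p(ranks2: np.ndarray, n_x: int, w2_obs: int) -> float:
    """Exact two-sided p for the rank-sum via the permutation distribution.

    ``ranks2`` are the pooled midranks doubled (hence integers even with
    ties); the DP counts, for every achievable doubled rank-sum s, the
    number of n_x-subsets of the pooled ranks with sum s.  Two-sided p is
    the symmetric-deviation tail P(|S - E[S]| >= |w2_obs - E[S]|).
    """
    total = int(ranks2.sum())
    n = len(ranks2)
    # counts[j, s] = number of j-subsets of the ranks processed so far summing to s
    max_sum = int(np.sort(ranks2)[-n_x:].sum())
    counts = np.zeros((n_x + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        # iterate j downwards so each rank is used at most once
        for j in range(min(n_x, n), 0, -1):
            counts[j, r:] += counts[j - 1, : max_sum + 1 - r]
    dist = counts[n_x]
    n_total = dist.sum()  # == C(n, n_x)
    mean2 = n_x * total / n
    dev_obs = abs(w2_obs - mean2)
    sums = np.arange(max_sum + 1, dtype=float)
    tail = dist[np.abs(sums - mean2) >= dev_obs - 1e-9].sum()
    return float(tail / n_total)


def wilcoxon_rank_sum(
    x: Iterable[float], y: Iterable[float], method: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test for two independent samples.

    The statistic is the sum of midranks of *x* in the pooled sample.
    ``method`` is ``"auto"`` (exact when min(n, m) <= 10 and there are no
    ties, else normal approximation), ``"exact"``, or ``"approx"``.  The
    normal path applies the tie correction to the variance and a 0.5
    continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks for ties
    w = float(ranks[:n].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if method == "exact" or (method == "auto" and min(n, m) <= EXACT_MAX_MIN_N and not has_ties):
        ranks2 = np.rint(2 * ranks).astype(np.int64)  # doubled midranks are integral
        p = _rank_sum_exact_p(ranks2, n, int(round(2 * w)))
        return TestResult(statistic=w, p_value=min(p, 1.0), method="exact")

    big_n = n + m
    mu = n * (big_n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:  # all pooled values identical
        return TestResult(statistic=w, p_value=1.0, method="normal_approx")
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * float(sps.norm.sf(z))
    return TestResult(statistic=w, p_value=min(p, 1.0), method="normal_approx")


def wilcoxon_signed_rank(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Paired signed-rank alternative for per-patient volume comparisons.

    The cohort pipeline compares paired per-patient measurements; the
    rank-sum test treats them as independent samples.  This variant is the
    matched-pairs analogue, exposed for users who prefer it.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("paired samples must be non-empty and equal length")
    diffs = x - y
    if np.all(diffs == 0):
        return TestResult(statistic=0.0, p_value=1.0, method="exact")
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True)
    method = "exact" if x.size <= 25 and np.unique(np.abs(diffs[diffs != 0])).size == np.count_nonzero(diffs) else "normal_approx"
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method=method)


# ---------------------------------------------------------------------------
# mean ± SD summaries
# ---------------------------------------------------------------------------

def _format_mean_sd(mean: float, sd: float, decimals: int) -> str:
    if np.isnan(sd):
        return f"{mean:.{decimals}f}"
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def summarize_mean_sd(
    records: pd.DataFrame | Iterable,
    group_keys: Sequence[str],
    value_col: str = "value",
    decimals: int = 3,
) -> pd.DataFrame:
    """Per-group count, mean, sample SD (ddof=1) and a "m ± s" string.

    ``records`` is a long-format DataFrame (or an iterable of dataclass
    records with matching attributes).  Rows whose value is missing
    ("not available" cells) are dropped before aggregation; groups with a
    single record get their SD marked absent rather than zero.  Empty
    input yields an empty table with the expected header.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records])
    cols = [*group_keys, "n", "mean", "sd", "formatted"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    df = records.dropna(subset=[value_col])
    if df.empty:
        return pd.DataFrame(columns=cols)
    grouped = df.groupby(list(group_keys), sort=True, observed=True)[value_col]
    out = grouped.agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    out["formatted"] = [
        _format_mean_sd(m, s, decimals) for m, s in zip(out["mean"], out["sd"])
    ]
    return out
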