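"""Statistical comparison of repeated ONEST runs.

Re-running an ONEST analysis with fresh random permutations shifts the
minimum curve and the read-off ONEST value a little.  Two rank-based
tests quantify whether repeated runs (or runs with and without divergent
raters) differ:

* Kruskal–Wallis on the minimum curves, treating each curve's n - 1 OPA
  values as one group.  Note the values within a curve are prefix OPAs
  and hence not independent; the test is the conventional screening
  procedure for comparing repeated runs, not a calibrated inference.
* Two-sample Wilcoxon rank sum on two sets of ONEST values (e.g. three
  runs with all raters vs three runs without the divergent ones).  For
  tiny groups the exact distribution is enumerated — its two-sided
  p-values are multiples of ``1 / C(n1 + n2, n1)``, so with 3-vs-3 the
  smallest attainable p is 0.1; the tie-corrected normal approximation is
  available for larger groups or to mirror approximate software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CurveComparisonResult",
    "RankSumResult",
    "kruskal_wallis_min_curves",
    "wilcoxon_rank_sum",
]

#: Largest number of group assignments the exact Wilcoxon test enumerates.
MAX_EXACT_ASSIGNMENTS = 200_000


@dataclass(frozen=True)
class CurveComparisonResult:
    """Kruskal–Wallis comparison of minimum-curve groups."""

    h_statistic: float
    p_value: float
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class RankSumResult:
    """Two-sample Wilcoxon rank sum result (rank sum of the first group)."""

    rank_sum: float
    p_value: float
    method: Literal["exact", "normal_approximation"]


def kruskal_wallis_min_curves(curves: Sequence[Sequence[float]]) -> CurveComparisonResult:
    """Tie-corrected Kruskal–Wallis H test across minimum OPA curves.

    Each curve's values form one group; H uses midranks with the standard
    tie correction and p comes from the chi-square distribution with
    ``len(curves) - 1`` degrees of freedom.  Identical pooled values give
    H = 0, p = 1 (complete ties carry no evidence).
    """
    groups = [np.asarray(c, dtype=float).ravel() for c in curves]
    if len(groups) < 2:
        raise ValueError(f"need at least two curves to compare, got {len(groups)}")
    if any(g.size < 2 for g in groups):
        raise ValueError("every curve must contain at least two values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return CurveComparisonResult(0.0, 1.0, tuple(g.size for g in groups))
    h, p = stats.kruskal(*groups)
    return CurveComparisonResult(float(h), float(p), tuple(g.size for g in groups))


def _exact_rank_sum_p(pooled_ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p by enumerating all C(N, n1) group assignments."""
    n = pooled_ranks.size
    mean_w = n1 * (n + 1) / 2.0  # midranks preserve the total N(N+1)/2
    obs_dev = abs(w_obs - mean_w)
    extreme = 0
    total = 0
    for subset in combinations(range(n), n1):
        w = pooled_ranks[list(subset)].sum()
        if abs(w - mean_w) >= obs_dev - 1e-9:
            extreme += 1
        total += 1
    return extreme / total


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    method: Literal["auto", "exact", "normal_approximation"] = "auto",
) -> RankSumResult:
    """Two-sided two-sample Wilcoxon rank sum test with midrank ties.

    ``method="exact"`` enumerates every assignment of the pooled midranks
    into groups of sizes ``(len(a), len(b))`` — feasible for the small
    replicate designs this package targets (guarded at 200000
    assignments).  ``"normal_approximation"`` uses the tie-corrected z
    statistic without continuity correction.  ``"auto"`` picks exact when
    the enumeration is small (min group size <= 8 and within the guard).
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w_obs = float(ranks[:n1].sum())

    if method == "auto":
        feasible = min(n1, n2) <= 8 and math.comb(n, n1) <= MAX_EXACT_ASSIGNMENTS
        method = "exact" if feasible else "normal_approximation"

    if method == "exact":
        if math.comb(n, n1) > MAX_EXACT_ASSIGNMENTS:
            raise ValueError(
                f"C({n}, {n1}) assignments exceed the exact-enumeration guard; "
                "use method='normal_approximation'"
            )
        p = _exact_rank_sum_p(ranks, n1, w_obs)
        return RankSumResult(w_obs, float(p), "exact")

    if method != "normal_approximation":
        raise ValueError(f"unknown method {method!r}")
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return RankSumResult(w_obs, 1.0, "normal_approximation")
    z = (w_obs - mean_w) / math.sqrt(var_w)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return RankSumResult(w_obs, p, "normal_approximation")
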