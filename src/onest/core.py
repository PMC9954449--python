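"""ONEST: Observers Needed to Evaluate Subjective Tests.

Given a cases x observers matrix of ordinal categories, the overall
percent agreement (OPA) of a set of observers is the fraction of cases on
which *all* of them assign the identical category.  For one ordering
(permutation) of the observers, the OPA curve (OPAC) is the sequence of
OPA values of the growing prefix, for k = 2..n observers; adding an
observer can only shrink the all-agree case set, so every OPAC is
non-increasing.

An ONEST analysis samples random observer permutations (classically 100),
plots all their OPACs, and summarises them by the pointwise minimum,
median and maximum curves.  Three scalar readings characterise
reproducibility:

* ``OPA(n)`` — agreement of the full panel (all curves end there);
* bandwidth — max minus min OPA at k = 2, the widest between-pair gap;
* the ONEST value — the observer count at which the worst-case (minimum)
  curve plateaus, i.e. the panel size beyond which adding observers no
  longer erodes worst-case agreement.

The plateau is formalised here with an explicit tolerance ``eps``: the
ONEST value is the smallest k such that the minimum curve drops by less
than ``eps`` anywhere beyond k.  The default ``eps = 1/C`` (one case's
worth of agreement) reflects OPA's resolution on C cases.

:class:`ONEST` is a scikit-learn style estimator; the module-level
functions (:func:`compute_opa`, :func:`run_onest`, ...) are thin wrappers
usable on bare arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from itertools import combinations, permutations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_random_state

__all__ = [
    "count_permutations",
    "sample_permutations",
    "compute_opa",
    "opac_for_permutation",
    "prefix_opa_curves",
    "summarize_curves",
    "exact_extrema",
    "onest_value",
    "OnestResult",
    "ONEST",
    "run_onest",
]

#: Largest number of observer subsets `exact_extrema` will enumerate.
MAX_EXACT_SUBSETS = 200_000

_EPS_GUARD = 1e-9  # strict "<" on OPA differences, robust to float noise


def count_permutations(n: int) -> int:
    """Exact size n! of the observer-permutation space (arbitrary precision)."""
    if n < 1:
        raise ValueError(f"need at least one observer, got n={n}")
    return math.factorial(n)


def sample_permutations(
    n: int, count: int, random_state=None
) -> np.ndarray:
    """Draw distinct observer permutations, or all of them if few enough.

    If ``n! <= count`` the full permutation space is returned in
    lexicographic order (exhaustive mode, exact small-n results).
    Otherwise ``count`` *distinct* permutations are drawn uniformly at
    random, reproducibly from ``random_state``.

    Returns an array of shape ``(P, n)`` of observer indices.
    """
    if n < 2:
        raise ValueError(f"need at least two observers, got n={n}")
    if count < 1:
        raise ValueError(f"need at least one permutation, got count={count}")
    total = math.factorial(n)
    if total <= count:
        return np.array(list(permutations(range(n))), dtype=np.intp)
    rng = check_random_state(random_state)
    seen: set[bytes] = set()
    out = np.empty((count, n), dtype=np.intp)
    filled = 0
    # duplicates are practically nil for n >= 9; the loop guarantees
    # distinctness at small n too
    while filled < count:
        perm = rng.permutation(n).astype(np.intp)
        key = perm.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out[filled] = perm
        filled += 1
    return out


def _as_category_array(categories) -> np.ndarray:
    arr = np.asarray(
        categories.to_numpy() if isinstance(categories, pd.DataFrame) else categories
    )
    if arr.ndim != 2:
        raise ValueError("categorical matrix must be 2-D (cases x observers)")
    if arr.shape[0] < 1 or arr.shape[1] < 2:
        raise ValueError(
            f"categorical matrix must have >=1 case and >=2 observers, got {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        as_float = arr.astype(float)
        if not np.isfinite(as_float).all():
            raise ValueError(
                "categorical matrix contains missing values; impute the ratings "
                "(onest.io.impute_missing) before categorising"
            )
        if not np.array_equal(as_float, np.rint(as_float)):
            raise ValueError("categories must be integers; binning comes first")
        arr = as_float.astype(np.int64)
    return arr


def compute_opa(categories, observers: Sequence[int]) -> float:
    """Overall percent agreement of a set of observers.

    The fraction of cases on which all selected observers assigned the
    identical category; always a multiple of ``1 / n_cases``.
    """
    arr = _as_category_array(categories)
    idx = np.asarray(list(observers), dtype=np.intp)
    if idx.size < 2:
        raise ValueError(f"OPA needs at least two observers, got {idx.size}")
    sub = arr[:, idx]
    agree = (sub == sub[:, [0]]).all(axis=1)
    return float(agree.mean())


def prefix_opa_curves(categories, perms: np.ndarray) -> np.ndarray:
    """OPA curves for the growing prefix of each permutation.

    Returns shape ``(P, n - 1)``: row ``p``, column ``k - 2`` holds the
    OPA of the first ``k`` observers of permutation ``p``, k = 2..n.
    """
    arr = _as_category_array(categories)
    perms = np.atleast_2d(np.asarray(perms, dtype=np.intp))
    n = arr.shape[1]
    if perms.shape[1] != n:
        raise ValueError(f"permutation length {perms.shape[1]} != n observers {n}")
    # (C, P, n): categories re-ordered per permutation
    reordered = arr[:, perms]
    ref = reordered[:, :, 0]
    agree = np.ones(ref.shape, dtype=bool)
    curves = np.empty((perms.shape[0], n - 1))
    for k in range(1, n):
        agree &= reordered[:, :, k] == ref
        curves[:, k - 1] = agree.mean(axis=0)
    return curves


def opac_for_permutation(categories, perm: Sequence[int]) -> np.ndarray:
    """The OPA curve (k = 2..n) of one observer ordering."""
    perm = np.asarray(perm, dtype=np.intp)
    n = _as_category_array(categories).shape[1]
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError(f"{perm.tolist()} is not a permutation of 0..{n - 1}")
    return prefix_opa_curves(categories, perm[None, :])[0]


def summarize_curves(curves) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise (min, max, median) summary of a bundle of OPA curves.

    The median of an even number of curves is the midpoint of the two
    middle values.
    """
    arr = np.atleast_2d(np.asarray(curves, dtype=float))
    if arr.size == 0:
        raise ValueError("need at least one curve to summarise")
    return arr.min(axis=0), arr.max(axis=0), np.median(arr, axis=0)


def exact_extrema(categories, k: int) -> tuple[float, float]:
    """Exact min and max OPA over *all* k-subsets of observers.

    Prefix OPA depends only on the observer set, not its order, so the
    exhaustive extrema over ``C(n, k)`` subsets bound any sampled minimum
    and maximum curve at that k.  Guarded to ``C(n, k) <= 200000``
    subsets; beyond that, sample permutations instead.
    """
    arr = _as_category_array(categories)
    n = arr.shape[1]
    if not 2 <= k <= n:
        raise ValueError(f"subset size k={k} outside [2, n={n}]")
    n_subsets = math.comb(n, k)
    if n_subsets > MAX_EXACT_SUBSETS:
        raise ValueError(
            f"C({n}, {k}) = {n_subsets} subsets exceeds the exhaustive guard "
            f"({MAX_EXACT_SUBSETS}); use sampled permutations"
        )
    lo, hi = 1.0, 0.0
    for subset in combinations(range(n), k):
        sub = arr[:, subset]
        opa = float((sub == sub[:, [0]]).all(axis=1).mean())
        lo = min(lo, opa)
        hi = max(hi, opa)
    return lo, hi


def onest_value(min_curve, n_cases: int, tolerance: float | str = "auto") -> int:
    """Observer count at which the minimum OPA curve plateaus.

    With tolerance ``eps`` (``"auto"`` = ``1 / n_cases``), returns the
    smallest k in 2..n such that ``min_curve(k) - min_curve(j) < eps`` for
    every later j; k = n always qualifies, so the value exists.
    """
    curve = np.asarray(min_curve, dtype=float)
    if curve.ndim != 1 or curve.size < 1:
        raise ValueError("min_curve must be a non-empty 1-D sequence (k = 2..n)")
    if tolerance == "auto":
        eps = 1.0 / n_cases
    else:
        eps = float(tolerance)
    if eps <= 0:
        raise ValueError(f"plateau tolerance must be positive, got {eps}")
    suffix_min = np.minimum.accumulate(curve[::-1])[::-1]
    ok = (curve - suffix_min) < eps - _EPS_GUARD
    return int(np.argmax(ok)) + 2


@dataclass
class OnestResult:
    """Complete output of one ONEST analysis.

    ``curves`` has one row per sampled permutation (k = 2..n along
    columns); the summary curves, the three scalar readings and the
    sampling provenance (seed, permutation count, exhaustive flag) are
    stored alongside.
    """

    ks: list[int]
    curves: np.ndarray
    permutations: np.ndarray
    min_curve: np.ndarray
    max_curve: np.ndarray
    median_curve: np.ndarray
    opa_n: float
    bandwidth: float
    onest_value: int
    n_cases: int
    n_observers: int
    n_permutations: int
    exhaustive: bool
    plateau_tolerance: float
    seed: int | None
    observer_ids: list[str]

    def curves_frame(self) -> pd.DataFrame:
        """All sampled OPACs as a DataFrame (index k, one column per permutation)."""
        return pd.DataFrame(
            self.curves.T,
            index=pd.Index(self.ks, name="k"),
            columns=[f"perm_{i + 1}" for i in range(self.curves.shape[0])],
        )

    def summary_frame(self) -> pd.DataFrame:
        """Min/median/max curves as a DataFrame indexed by k."""
        return pd.DataFrame(
            {"min": self.min_curve, "median": self.median_curve, "max": self.max_curve},
            index=pd.Index(self.ks, name="k"),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("curves", "permutations", "min_curve", "max_curve", "median_curve"):
            d[key] = d[key].tolist() if hasattr(d[key], "tolist") else d[key]
        return d

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "OnestResult":
        d = dict(d)
        for key in ("curves", "permutations", "min_curve", "max_curve", "median_curve"):
            d[key] = np.asarray(d[key])
        d["permutations"] = d["permutations"].astype(np.intp)
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "OnestResult":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


class ONEST(BaseEstimator):
    """Permutation-sampled observers-needed analysis of a categorical matrix.

    Fit on a cases x observers matrix of ordinal categories (the output of
    :class:`~onest.preprocessing.CutoffBinner`); the fitted attributes
    hold the sampled OPA curves, their min/median/max summaries and the
    three scalar readings.

    Parameters
    ----------
    n_permutations : int, default 100
        Number of distinct observer permutations to sample.  If
        ``n! <= n_permutations`` all permutations are used and the
        analysis is exact (``exhaustive_`` is set).
    plateau_tolerance : float or "auto", default "auto"
        Plateau tolerance ``eps`` for the ONEST value; ``"auto"`` uses
        ``1 / n_cases`` — one case's worth of agreement.
    exact_bandwidth : bool, default False
        Compute the bandwidth over all ``C(n, 2)`` observer pairs instead
        of the sampled summary curves at k = 2.
    random_state : int, RandomState or None
        Seed for permutation sampling; fixed seeds give identical results.

    Attributes
    ----------
    curves_ : ndarray of shape (P, n - 1)
        Sampled OPA curves, k = 2..n along columns.
    min_curve_, max_curve_, median_curve_ : ndarray of shape (n - 1,)
        Pointwise summaries of ``curves_``.
    opa_n_ : float
        Agreement of the full panel.
    bandwidth_ : float
        max - min OPA at k = 2.
    onest_value_ : int
        Plateau point of the minimum curve, in [2, n].
    result_ : OnestResult
        All of the above bundled with provenance.

    Examples
    --------
    >>> import numpy as np
    >>> from onest import ONEST
    >>> cats = np.array([[0, 0, 0], [0, 1, 0], [1, 1, 1], [0, 0, 1]])
    >>> est = ONEST(n_permutations=100, random_state=0).fit(cats)
    >>> est.opa_n_
    0.5
    """

    def __init__(
        self,
        n_permutations: int = 100,
        plateau_tolerance: float | str = "auto",
        exact_bandwidth: bool = False,
        random_state=None,
    ):
        self.n_permutations = n_permutations
        self.plateau_tolerance = plateau_tolerance
        self.exact_bandwidth = exact_bandwidth
        self.random_state = random_state

    def fit(self, X, y=None):
        """Run the analysis on a cases x observers categorical matrix."""
        observer_ids = (
            [str(c) for c in X.columns]
            if isinstance(X, pd.DataFrame)
            else None
        )
        arr = _as_category_array(X)
        n_cases, n_obs = arr.shape
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        perms = sample_permutations(n_obs, self.n_permutations, self.random_state)
        exhaustive = perms.shape[0] == math.factorial(n_obs)
        curves = prefix_opa_curves(arr, perms)
        lo, hi, med = summarize_curves(curves)
        opa_n = float(lo[-1])
        if self.exact_bandwidth:
            blo, bhi = exact_extrema(arr, 2)
            bandwidth = bhi - blo
        else:
            bandwidth = float(hi[0] - lo[0])
        tol = 1.0 / n_cases if self.plateau_tolerance == "auto" else float(self.plateau_tolerance)
        value = onest_value(lo, n_cases, tol)

        self.n_cases_ = n_cases
        self.n_observers_ = n_obs
        self.ks_ = list(range(2, n_obs + 1))
        self.permutations_ = perms
        self.curves_ = curves
        self.min_curve_, self.max_curve_, self.median_curve_ = lo, hi, med
        self.opa_n_ = opa_n
        self.bandwidth_ = float(bandwidth)
        self.onest_value_ = value
        self.exhaustive_ = exhaustive
        self.result_ = OnestResult(
            ks=self.ks_,
            curves=curves,
            permutations=perms,
            min_curve=lo,
            max_curve=hi,
            median_curve=med,
            opa_n=opa_n,
            bandwidth=float(bandwidth),
            onest_value=value,
            n_cases=n_cases,
            n_observers=n_obs,
            n_permutations=self.n_permutations,
            exhaustive=exhaustive,
            plateau_tolerance=tol,
            seed=self.random_state if isinstance(self.random_state, (int, np.integer)) else None,
            observer_ids=observer_ids or [str(j) for j in range(n_obs)],
        )
        return self

    def score(self, X=None, y=None) -> float:
        """Full-panel agreement OPA(n) of the fitted analysis."""
        check_is_fitted(self)
        return self.opa_n_


def run_onest(
    categories,
    n_permutations: int = 100,
    random_state=None,
    plateau_tolerance: float | str = "auto",
    exact_bandwidth: bool = False,
) -> OnestResult:
    """One-call ONEST analysis; see :class:`ONEST` for the parameters."""
    est = ONEST(
        n_permutations=n_permutations,
        plateau_tolerance=plateau_tolerance,
        exact_bandwidth=exact_bandwidth,
        random_state=random_state,
    )
    return est.fit(categories).result_
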