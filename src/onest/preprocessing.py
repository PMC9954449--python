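"""Cut-off schemes and scikit-learn transformers for rating matrices.

Two transformers cover the preprocessing stages of an agreement study:

* :class:`CaseMeanImputer` fills missing ratings with the case mean
  (rounded half-up), operating row-wise because a case's difficulty — not
  an observer's habit — is the best predictor of its missing score.
* :class:`CutoffBinner` maps continuous percentage scores to ordinal
  categories under a cut-off scheme, e.g. the two-tier
  lymphocyte-predominant thresholds (>=50% or >=60%), the prognostic
  >=30% threshold, or the three-tier 0-20 / 21-49 / >=50 classification.

Both compose with :class:`~sklearn.pipeline.Pipeline`, so a full analysis
is ``Pipeline([imputer, binner, ONEST(...)])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import impute_missing, validate_ratings

__all__ = [
    "CategoryScheme",
    "BUILTIN_SCHEMES",
    "get_scheme",
    "categorize",
    "CaseMeanImputer",
    "CutoffBinner",
]


@dataclass(frozen=True)
class CategoryScheme:
    """An ordered set of lower-bound cut-offs defining ordinal categories.

    Cut-offs ``t1 < t2 < ... < tm`` in ``(0, 100]`` induce the ``m + 1``
    half-open bins ``[0, t1), [t1, t2), ..., [tm, 100]`` labelled
    ``0 .. m``.  A score ``v`` falls in the largest category ``i`` with
    ``v >= t_i`` (category 0 if ``v < t1``), so a two-tier scheme ``{t}``
    partitions exactly as ``v < t`` versus ``v >= t``.
    """

    name: str
    lower_bounds: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        bounds = tuple(float(b) for b in self.lower_bounds)
        if len(bounds) < 1:
            raise ValueError("a category scheme needs at least one cut-off")
        if any(not (0.0 < b <= 100.0) for b in bounds):
            raise ValueError(f"cut-offs must lie in (0, 100], got {bounds}")
        if any(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"cut-offs must be strictly increasing, got {bounds}")
        object.__setattr__(self, "lower_bounds", bounds)

    @property
    def n_categories(self) -> int:
        return len(self.lower_bounds) + 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Vectorised category assignment (``v >= t_i`` is inclusive)."""
        return np.digitize(values, self.lower_bounds, right=False)


#: Named schemes used in sTIL reproducibility studies.
BUILTIN_SCHEMES: dict[str, CategoryScheme] = {
    # lymphocyte-predominant breast cancer definitions
    "lpbc60": CategoryScheme("lpbc60", (60,)),
    "lpbc50": CategoryScheme("lpbc50", (50,)),
    # prognostic cut-off in the adjuvant setting
    "prog30": CategoryScheme("prog30", (30,)),
    # three-tier 0-20 / 21-49 / >=50 working-group classification
    "iiobwg3": CategoryScheme("iiobwg3", (21, 50)),
}


def get_scheme(spec: str | Sequence[float] | CategoryScheme) -> CategoryScheme:
    """Resolve a scheme name, a cut-off sequence, or a scheme object."""
    if isinstance(spec, CategoryScheme):
        return spec
    if isinstance(spec, str):
        try:
            return BUILTIN_SCHEMES[spec]
        except KeyError:
            raise KeyError(
                f"unknown scheme {spec!r}; built-ins: {sorted(BUILTIN_SCHEMES)}"
            ) from None
    bounds = tuple(float(b) for b in spec)
    return CategoryScheme("custom" + "-".join(f"{b:g}" for b in bounds), bounds)


def categorize(
    ratings: pd.DataFrame, scheme: str | Sequence[float] | CategoryScheme
) -> pd.DataFrame:
    """Map a (fully observed) rating matrix to ordinal categories.

    Raises if the matrix still contains missing values, pointing the
    caller to :func:`onest.io.impute_missing`.
    """
    scheme = get_scheme(scheme)
    values = validate_ratings(ratings, allow_missing=False)
    cats = scheme.assign(values.to_numpy())
    return pd.DataFrame(cats.astype(np.int64), index=values.index, columns=values.columns)


class CaseMeanImputer(BaseEstimator, TransformerMixin):
    """Impute missing ratings with the per-case mean, rounded half-up.

    Stateless row-wise imputation: each missing cell is replaced by the
    mean of the same case's observed ratings, rounded to the closest
    integer (ties round up).  ``fit`` only validates; the transform is
    idempotent.
    """

    def fit(self, X, y=None):
        X = self._as_frame(X)
        validate_ratings(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        return impute_missing(self._as_frame(X))

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = check_array(X, ensure_all_finite=False, dtype=float, ensure_min_features=2)
        return pd.DataFrame(arr)


class CutoffBinner(BaseEstimator, TransformerMixin):
    """Discretise percentage scores into ordinal categories by cut-offs.

    Parameters
    ----------
    cutoffs : sequence of float, str or CategoryScheme, default (50,)
        Strictly increasing lower bounds in (0, 100], a built-in scheme
        name (``lpbc60``, ``lpbc50``, ``prog30``, ``iiobwg3``), or a
        :class:`CategoryScheme`.
    """

    def __init__(self, cutoffs: str | Sequence[float] | CategoryScheme = (50,)):
        self.cutoffs = cutoffs

    def fit(self, X, y=None):
        self.scheme_ = get_scheme(self.cutoffs)
        X = self._validated(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        frame = X if isinstance(X, pd.DataFrame) else None
        arr = self._validated(X)
        cats = self.scheme_.assign(arr).astype(np.int64)
        if frame is not None:
            return pd.DataFrame(cats, index=frame.index, columns=frame.columns)
        return cats

    def _validated(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return validate_ratings(X, allow_missing=False).to_numpy()
        arr = check_array(X, dtype=float, ensure_min_features=2)
        if ((arr < 0) | (arr > 100)).any():
            raise ValueError("scores must lie in [0, 100]")
        return arr
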