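"""Reading, writing and imputation of rating matrices.

A rating matrix holds continuous percentage scores (e.g. stromal
tumour-infiltrating lymphocyte percentages) with rows = cases and
columns = observers.  The canonical in-memory container is a pandas
``DataFrame`` whose index carries the case ids, whose columns carry the
observer ids, and whose cells are floats in ``[0, 100]`` with ``NaN``
marking a missing rating.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MISSING_TOKENS",
    "read_ratings",
    "write_ratings",
    "validate_ratings",
    "impute_missing",
]

#: Cell contents treated as a missing rating when reading delimited text.
DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "NA", "NaN"})


class RatingsError(ValueError):
    """Raised for malformed or out-of-contract rating matrices."""


def validate_ratings(ratings: pd.DataFrame, *, allow_missing: bool = True) -> pd.DataFrame:
    """Validate a cases x observers rating matrix.

    Checks shape (>= 1 case, >= 2 observers), id uniqueness and that every
    non-missing value lies in ``[0, 100]``.  Returns the (float-coerced)
    matrix unchanged otherwise.
    """
    if ratings.shape[0] < 1:
        raise RatingsError("rating matrix needs at least one case (row)")
    if ratings.shape[1] < 2:
        raise RatingsError(
            f"rating matrix needs at least two observers (columns), got {ratings.shape[1]}"
        )
    if ratings.index.has_duplicates:
        dupes = ratings.index[ratings.index.duplicated()].unique().tolist()
        raise RatingsError(f"duplicate case ids: {dupes}")
    if ratings.columns.has_duplicates:
        dupes = ratings.columns[ratings.columns.duplicated()].unique().tolist()
        raise RatingsError(f"duplicate observer ids: {dupes}")
    try:
        values = ratings.astype(float)
    except (TypeError, ValueError) as exc:
        raise RatingsError(f"non-numeric cell in rating matrix: {exc}") from exc
    arr = values.to_numpy()
    finite = np.isfinite(arr)
    if not allow_missing and not finite.all():
        r, c = np.argwhere(~finite)[0]
        raise RatingsError(
            f"missing value at case {values.index[r]!r}, observer {values.columns[c]!r}; "
            "impute first (see impute_missing)"
        )
    bad = finite & ((arr < 0) | (arr > 100))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise RatingsError(
            f"value {arr[r, c]} out of range [0, 100] at case {values.index[r]!r}, "
            f"observer {values.columns[c]!r}"
        )
    return values


def read_ratings(
    path: str | Path,
    delimiter: str = ",",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> pd.DataFrame:
    """Read a delimited cases x observers rating matrix.

    The first row is a header of observer ids; the first column holds case
    ids.  Cells matching a ``missing_tokens`` entry (after stripping
    whitespace) become ``NaN``.  Any other non-numeric cell raises a
    :class:`RatingsError` naming the offending case and observer.
    """
    path = Path(path)
    missing = {t.strip() for t in missing_tokens}
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise RatingsError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    observer_ids = header[1:]
    case_ids: list[str] = []
    data: list[list[float]] = []
    for row in rows[1:]:
        if not row or all(not cell.strip() for cell in row):
            continue
        case_id = row[0].strip()
        case_ids.append(case_id)
        parsed: list[float] = []
        for j, cell in enumerate(row[1:]):
            token = cell.strip()
            if token in missing:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(token))
            except ValueError:
                raise RatingsError(
                    f"{path}: non-numeric cell {token!r} at case {case_id!r}, "
                    f"observer {observer_ids[j] if j < len(observer_ids) else j!r}"
                ) from None
        if len(parsed) != len(observer_ids):
            raise RatingsError(
                f"{path}: case {case_id!r} has {len(parsed)} values, "
                f"expected {len(observer_ids)}"
            )
        data.append(parsed)
    frame = pd.DataFrame(data, index=pd.Index(case_ids, name="case"), columns=observer_ids)
    return validate_ratings(frame)


def write_ratings(ratings: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a rating matrix as delimited text (missing cells left empty)."""
    ratings.to_csv(path, sep=delimiter, index=True, index_label="case", na_rep="")


def impute_missing(ratings: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing rating by the case's mean score, rounded half-up.

    The replacement for a missing cell is the arithmetic mean of the same
    case's non-missing ratings across the other observers, rounded to the
    closest integer with ties (.5) rounding up.  Non-missing cells are
    unchanged.  A matrix with no missing cells is returned as an identical
    copy, so the operation is idempotent.

    Raises
    ------
    RatingsError
        If some case has no observed rating at all.
    """
    values = validate_ratings(ratings)
    arr = values.to_numpy(copy=True)
    missing = ~np.isfinite(arr)
    if not missing.any():
        return values
    observed_per_case = (~missing).sum(axis=1)
    if (observed_per_case == 0).any():
        row = int(np.argmax(observed_per_case == 0))
        raise RatingsError(
            f"case {values.index[row]!r} has no observed ratings; cannot impute"
        )
    with np.errstate(invalid="ignore"):
        case_means = np.nanmean(arr, axis=1)
    fill = np.floor(case_means + 0.5)  # round half up
    rows, cols = np.nonzero(missing)
    arr[rows, cols] = fill[rows]
    return pd.DataFrame(arr, index=values.index, columns=values.columns)
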