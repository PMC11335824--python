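"""Coding of confidence ratings into source decisions and tallying against ground truth.

An observer compares trace evidence against a reference sample and rates, on a
bounded confidence scale (default 1 = "sure different" to 12 = "sure same"),
how likely the two are to share a source. Ratings at or above the scale
midpoint are coded as "same-source" decisions, ratings below as
"different-source" decisions; an optional inconclusive window around the
midpoint yields a ternary coding. Decisions are then tallied against ground
truth into the familiar 2x2 (hits / misses / false alarms / correct
rejections) or 2x3 table (adding inconclusive counts per ground-truth state).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd

SAME = "same"
DIFFERENT = "different"
INCONCLUSIVE = "inconclusive"

#: Default confidence scale: 1 ("sure different") .. 12 ("sure same").
DEFAULT_SCALE: Tuple[float, float] = (1.0, 12.0)

#: Columns every trial-level rating table must carry.
RATING_COLUMNS = ("participant_id", "group", "trial_id", "truth", "rating")


def scale_midpoint(scale: Tuple[float, float] = DEFAULT_SCALE) -> float:
    """Midpoint of the rating scale (6.5 on the default 1-12 scale)."""
    lo, hi = scale
    return 0.5 * (lo + hi)


def _check_scale(scale: Tuple[float, float]) -> None:
    lo, hi = scale
    if not lo < hi:
        raise ValueError(f"invalid scale {scale!r}: scale_min must be < scale_max")


def _check_rating(rating: float, scale: Tuple[float, float]) -> None:
    lo, hi = scale
    if not (lo <= rating <= hi):
        raise ValueError(f"rating {rating!r} outside scale bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class RatingRecord:
    """One participant x trial observation: ground truth plus confidence rating."""

    participant_id: str
    group: str
    trial_id: str
    truth: str  # SAME or DIFFERENT
    rating: float

    def __post_init__(self) -> None:
        if self.truth not in (SAME, DIFFERENT):
            raise ValueError(
                f"truth must be {SAME!r} or {DIFFERENT!r}, got {self.truth!r}"
            )


@dataclass(frozen=True)
class BinaryTable:
    """2x2 classification counts of source decisions against ground truth."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"count {name} must be >= 0, got {v}")

    @property
    def n_same(self) -> int:
        return self.hits + self.misses

    @property
    def n_diff(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def total(self) -> int:
        return self.n_same + self.n_diff


@dataclass(frozen=True)
class TernaryTable:
    """2x3 classification counts with inconclusive decisions per ground-truth state."""

    hits: int
    misses: int
    inconclusive_same: int
    false_alarms: int
    correct_rejections: int
    inconclusive_different: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"count {name} must be >= 0, got {v}")

    @property
    def n_same(self) -> int:
        return self.hits + self.misses + self.inconclusive_same

    @property
    def n_diff(self) -> int:
        return self.false_alarms + self.correct_rejections + self.inconclusive_different

    @property
    def n_inconclusive(self) -> int:
        return self.inconclusive_same + self.inconclusive_different

    @property
    def total(self) -> int:
        return self.n_same + self.n_diff

    def collapse(self) -> BinaryTable:
        """Drop the inconclusive counts, leaving the conclusive 2x2 table."""
        return BinaryTable(
            self.hits, self.misses, self.false_alarms, self.correct_rejections
        )


def code_binary(
    rating: float,
    midpoint: Optional[float] = None,
    scale: Tuple[float, float] = DEFAULT_SCALE,
) -> str:
    """Code a rating as a binary source decision.

    Ratings below the midpoint code as "different", ratings at or above it as
    "same" (on the 1-12 scale: 1-6 -> different, 7-12 -> same). The boundary
    value codes as "same" by convention; the integer scale never produces it
    but continuous simulated ratings can.
    """
    _check_scale(scale)
    _check_rating(rating, scale)
    if midpoint is None:
        midpoint = scale_midpoint(scale)
    return SAME if rating >= midpoint else DIFFERENT


def code_ternary(
    rating: float,
    window: Optional[Tuple[float, float]] = None,
    midpoint: Optional[float] = None,
    scale: Tuple[float, float] = DEFAULT_SCALE,
) -> str:
    """Code a rating as same / different / inconclusive.

    Ratings inside the closed ``window`` [lo, hi] code as inconclusive;
    otherwise the binary rule applies. ``window=None`` disables the
    inconclusive option and reduces exactly to :func:`code_binary`.
    """
    if window is None:
        return code_binary(rating, midpoint=midpoint, scale=scale)
    lo, hi = window
    if lo > hi:
        raise ValueError(f"inverted inconclusive window [{lo}, {hi}]")
    if lo < scale[0] or hi > scale[1]:
        raise ValueError(f"window [{lo}, {hi}] not contained in scale {scale!r}")
    _check_scale(scale)
    _check_rating(rating, scale)
    if lo <= rating <= hi:
        return INCONCLUSIVE
    return code_binary(rating, midpoint=midpoint, scale=scale)


RecordsLike = Union[pd.DataFrame, Iterable[RatingRecord]]


def records_to_frame(records: RecordsLike) -> pd.DataFrame:
    """Coerce a record iterable (or pass through a DataFrame) to trial-level form."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        df = pd.DataFrame(
            [(r.participant_id, r.group, r.trial_id, r.truth, r.rating) for r in rows],
            columns=list(RATING_COLUMNS),
        )
    missing = [c for c in ("truth", "rating") if c not in df.columns]
    if missing:
        raise ValueError(f"rating table missing required columns: {missing}")
    return df


def tabulate(
    records: RecordsLike,
    window: Optional[Tuple[float, float]] = None,
    midpoint: Optional[float] = None,
    scale: Tuple[float, float] = DEFAULT_SCALE,
) -> Union[BinaryTable, TernaryTable]:
    """Tally coded decisions against ground truth.

    With ``window=None`` every rating is coded binary and a
    :class:`BinaryTable` is returned; with an inconclusive window a
    :class:`TernaryTable` is returned. The counts always partition the input
    records.
    """
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("cannot tabulate an empty record list")
    _check_scale(scale)
    if midpoint is None:
        midpoint = scale_midpoint(scale)

    rating = df["rating"].to_numpy(dtype=float)
    lo, hi = scale
    if np.any((rating < lo) | (rating > hi)):
        bad = np.flatnonzero((rating < lo) | (rating > hi))[:5]
        raise ValueError(
            f"ratings outside scale bounds [{lo}, {hi}] at rows {bad.tolist()}"
        )
    truth = df["truth"].to_numpy()
    is_same = truth == SAME
    if not np.all(is_same | (truth == DIFFERENT)):
        bad_labels = sorted(set(truth) - {SAME, DIFFERENT})
        raise ValueError(f"unknown truth labels: {bad_labels}")

    says_same = rating >= midpoint
    if window is None:
        return BinaryTable(
            hits=int(np.sum(is_same & says_same)),
            misses=int(np.sum(is_same & ~says_same)),
            false_alarms=int(np.sum(~is_same & says_same)),
            correct_rejections=int(np.sum(~is_same & ~says_same)),
        )

    wlo, whi = window
    if wlo > whi:
        raise ValueError(f"inverted inconclusive window [{wlo}, {whi}]")
    inconclusive = (rating >= wlo) & (rating <= whi)
    return TernaryTable(
        hits=int(np.sum(is_same & says_same & ~inconclusive)),
        misses=int(np.sum(is_same & ~says_same & ~inconclusive)),
        inconclusive_same=int(np.sum(is_same & inconclusive)),
        false_alarms=int(np.sum(~is_same & says_same & ~inconclusive)),
        correct_rejections=int(np.sum(~is_same & ~says_same & ~inconclusive)),
        inconclusive_different=int(np.sum(~is_same & inconclusive)),
    )
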