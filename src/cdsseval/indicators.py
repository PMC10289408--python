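"""Concordance / conformity classification and indicator rates.

Three matching schemes are implemented:

* five-way physician-vs-CDSS concordance (Level I match, Level II match,
  not available, both not recommended, recommend dispute),
* four-way concordance with a designated high-level physician,
* five-way guideline conformity, applied to a physician decision or to the
  CDSS's full Level-I recommendation set.

Under the strict rule used throughout, only a Level-I match (respectively an
identical recommendation, for the high-level scheme) or an agreed
"not recommended" counts as concordant/conforming; a Level-II match is
discordant.  Rates are numerator/denominator percentages reported at one
decimal, rounded half-up.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Hashable, Sequence, TypeVar, Union

from .model import Decision, StudyValidationError, TieredRecommendation

__all__ = [
    "ConcordanceCategory",
    "HLConcordanceCategory",
    "IndicatorResult",
    "classify_concordance",
    "is_concordant",
    "classify_hl_concordance",
    "is_hl_concordant",
    "classify_guideline_conformity",
    "is_conforming",
    "indicator_rate",
    "round_half_up",
    "OVERALL",
]

T = TypeVar("T")

#: Key under which the pooled computation is reported by :func:`indicator_rate`.
OVERALL = "Overall"


class ConcordanceCategory(str, Enum):
    """Five-way match between a decision and a tiered reference."""

    LEVEL_I_MATCH = "level_i_match"
    LEVEL_II_MATCH = "level_ii_match"
    NOT_AVAILABLE = "not_available"
    NOT_RECOMMENDED_MATCH = "not_recommended_match"
    RECOMMEND_DISPUTE = "recommend_dispute"


class HLConcordanceCategory(str, Enum):
    """Four-way match against a high-level physician's single decision."""

    RECOMMENDED_MATCH = "recommended_match"
    NOT_AVAILABLE = "not_available"
    NOT_RECOMMENDED_MATCH = "not_recommended_match"
    RECOMMEND_DISPUTE = "recommend_dispute"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the convention used for all printed percentages)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class IndicatorResult:
    """A numerator/denominator/rate triple for one indicator on one group."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise StudyValidationError("indicator denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise StudyValidationError(
                f"numerator {self.numerator} outside [0, {self.denominator}]"
            )

    @property
    def rate(self) -> float:
        """Percentage at one decimal, rounded half-up."""
        return round_half_up(100.0 * self.numerator / self.denominator, 1)

    @property
    def exact_rate(self) -> float:
        """Unrounded percentage (used when a rate feeds further arithmetic)."""
        return 100.0 * self.numerator / self.denominator

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.rate}% ({self.numerator}/{self.denominator})"


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def classify_concordance(
    phys: Decision, ref: TieredRecommendation
) -> ConcordanceCategory:
    """Five-way physician-vs-reference classification (total over all inputs).

    Guideline references may carry a Level-III tier; a Level-III match is not
    one of the five defined situations and is classified NOT_AVAILABLE (the
    physician's regimen is outside the tiers the scheme recognises).
    """
    if phys.recommended and ref.recommended:
        if phys.regimen in ref.level1:
            return ConcordanceCategory.LEVEL_I_MATCH
        if phys.regimen in ref.level2:
            return ConcordanceCategory.LEVEL_II_MATCH
        return ConcordanceCategory.NOT_AVAILABLE
    if not phys.recommended and not ref.recommended:
        return ConcordanceCategory.NOT_RECOMMENDED_MATCH
    return ConcordanceCategory.RECOMMEND_DISPUTE


def is_concordant(cat: ConcordanceCategory) -> bool:
    """Strict rule: only a Level-I match or an agreed 'not recommended' is concordant."""
    return cat in (
        ConcordanceCategory.LEVEL_I_MATCH,
        ConcordanceCategory.NOT_RECOMMENDED_MATCH,
    )


Subject = Union[Decision, TieredRecommendation]


def _subject_parts(subject: Subject) -> tuple[bool, frozenset[str]]:
    """(recommended flag, comparison set) for a physician decision or a CDSS Level-I set."""
    if isinstance(subject, Decision):
        return subject.recommended, (
            frozenset({subject.regimen}) if subject.recommended else frozenset()
        )
    if subject.recommended and not subject.level1:
        raise StudyValidationError("recommending CDSS subject has empty Level-I set")
    return subject.recommended, subject.level1


def classify_hl_concordance(subject: Subject, hl: Decision) -> HLConcordanceCategory:
    """Four-way match of a physician decision or CDSS Level-I set against a
    high-level physician's decision.

    A match requires the high-level regimen to equal the physician's regimen,
    or to lie in the CDSS's Level-I set.
    """
    recommended, options = _subject_parts(subject)
    if recommended and hl.recommended:
        if hl.regimen in options:
            return HLConcordanceCategory.RECOMMENDED_MATCH
        return HLConcordanceCategory.NOT_AVAILABLE
    if not recommended and not hl.recommended:
        return HLConcordanceCategory.NOT_RECOMMENDED_MATCH
    return HLConcordanceCategory.RECOMMEND_DISPUTE


def is_hl_concordant(cat: HLConcordanceCategory) -> bool:
    return cat in (
        HLConcordanceCategory.RECOMMENDED_MATCH,
        HLConcordanceCategory.NOT_RECOMMENDED_MATCH,
    )


def classify_guideline_conformity(
    subject: Subject, guide: TieredRecommendation
) -> ConcordanceCategory:
    """Five-way conformity of a physician decision or CDSS Level-I set vs the guideline.

    For a CDSS subject the unit of comparison is its whole Level-I set:
    a Level-I (II) match requires non-empty intersection with the guideline's
    Level-I (II) tier, Level-I taking precedence.
    """
    recommended, options = _subject_parts(subject)
    if recommended and guide.recommended:
        if options & guide.level1:
            return ConcordanceCategory.LEVEL_I_MATCH
        if options & guide.level2:
            return ConcordanceCategory.LEVEL_II_MATCH
        return ConcordanceCategory.NOT_AVAILABLE
    if not recommended and not guide.recommended:
        return ConcordanceCategory.NOT_RECOMMENDED_MATCH
    return ConcordanceCategory.RECOMMEND_DISPUTE


#: Conformity uses the same strict concordant set as the five-way scheme.
is_conforming = is_concordant


# ---------------------------------------------------------------------------
# Rates over arbitrary groupings
# ---------------------------------------------------------------------------

def indicator_rate(
    records: Sequence[T],
    predicate: Callable[[T], bool],
    grouping: Callable[[T], Hashable] | None = None,
) -> dict[Hashable, IndicatorResult]:
    """Per-group numerator/denominator/rate, plus the pooled ``"Overall"`` entry.

    ``predicate`` flags the records counted in the numerator; ``grouping``
    maps a record to its subgroup key (``None`` = overall only).  Groups are
    formed from the records themselves, so no group is empty; an empty record
    list yields an empty result with a warning rather than a zero division.
    """
    records = list(records)
    if not records:
        warnings.warn("indicator_rate: no records; returning empty result", stacklevel=2)
        return {}
    out: dict[Hashable, IndicatorResult] = {}
    flags = [bool(predicate(r)) for r in records]
    out[OVERALL] = IndicatorResult(sum(flags), len(records))
    if grouping is not None:
        groups: dict[Hashable, list[bool]] = {}
        for r, f in zip(records, flags):
            groups.setdefault(grouping(r), []).append(f)
        for key in sorted(groups, key=str):
            out[key] = IndicatorResult(sum(groups[key]), len(groups[key]))
    return out
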