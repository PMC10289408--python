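"""Decision stability and panel consensus.

Stability is defined on the subgroup of decisions whose *initial* version is
discordant with the CDSS reference: a decision is stable when the final
decision equals the initial one (the physician resisted the external
opinion).  Consensus is unanimity of the three panel physicians on one
decision point (case x treatment stage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Sequence

from .indicators import IndicatorResult, classify_concordance, indicator_rate, is_concordant
from .model import (
    Decision,
    DecisionRecord,
    StudyBundle,
    StudyValidationError,
    TieredRecommendation,
    TreatmentStage,
)

__all__ = [
    "PanelDecisionPoint",
    "is_stable",
    "discordant_records",
    "stability_rate",
    "has_consensus",
    "consensus_rate",
    "panel_decision_points",
]


def _require_discordant(record: DecisionRecord, ai: TieredRecommendation) -> None:
    if is_concordant(classify_concordance(record.initial, ai)):
        raise StudyValidationError(
            f"record ({record.case_id}, {record.stage.value}, {record.reviewer.code}) "
            "is AI-concordant; stability is defined on the discordance subgroup"
        )


def is_stable(record: DecisionRecord, ai: TieredRecommendation) -> bool:
    """True iff the final decision equals the initial one (flag and regimen).

    The record must belong to the discordance subgroup w.r.t. the CDSS
    reference ``ai``; otherwise a contract violation is raised.
    """
    _require_discordant(record, ai)
    return record.final == record.initial


def discordant_records(
    records: Iterable[DecisionRecord],
    ai_reference: dict[tuple[str, TreatmentStage], TieredRecommendation],
) -> list[DecisionRecord]:
    """The stability denominator: records whose initial decision is AI-discordant."""
    return [
        r
        for r in records
        if not is_concordant(classify_concordance(r.initial, ai_reference[(r.case_id, r.stage)]))
    ]


def stability_rate(
    records: Sequence[DecisionRecord],
    ai_reference: dict[tuple[str, TreatmentStage], TieredRecommendation],
    grouping: Callable[[DecisionRecord], Hashable] | None = None,
) -> dict[Hashable, IndicatorResult]:
    """Per-group decision stability over an (optionally matched) discordant record set."""
    for r in records:
        _require_discordant(r, ai_reference[(r.case_id, r.stage)])
    return indicator_rate(records, lambda r: r.final == r.initial, grouping)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelDecisionPoint:
    """The three panel physicians' decisions for one (case, stage)."""

    case_id: str
    stage: TreatmentStage
    decisions: tuple[Decision, ...]

    def __post_init__(self) -> None:
        if len(self.decisions) != 3:
            raise StudyValidationError(
                f"decision point ({self.case_id}, {self.stage.value}) has "
                f"{len(self.decisions)} decisions, expected 3"
            )


def has_consensus(point: PanelDecisionPoint) -> bool:
    """True iff the three decisions are in complete agreement."""
    return point.decisions[0] == point.decisions[1] == point.decisions[2]


def consensus_rate(
    points: Sequence[PanelDecisionPoint],
    grouping: Callable[[PanelDecisionPoint], Hashable] | None = None,
) -> dict[Hashable, IndicatorResult]:
    """Per-group consensus percentage over decision points."""
    return indicator_rate(points, has_consensus, grouping)


def panel_decision_points(
    bundle: StudyBundle, use: str = "initial"
) -> list[PanelDecisionPoint]:
    """Assemble one PanelDecisionPoint per (case, stage) from a bundle.

    ``use`` selects which pass feeds the consensus computation; the default is
    the initial (pre-CDSS) decisions, the physicians' unaided judgments.
    """
    if use not in ("initial", "final"):
        raise ValueError("use must be 'initial' or 'final'")
    by_point: dict[tuple[str, TreatmentStage], list[Decision]] = {}
    for r in sorted(bundle.records, key=lambda r: (r.case_id, r.stage.value, r.reviewer.code)):
        by_point.setdefault((r.case_id, r.stage), []).append(getattr(r, use))
    points = []
    for (case_id, stage), decisions in sorted(by_point.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        points.append(PanelDecisionPoint(case_id, stage, tuple(decisions)))
    return points
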