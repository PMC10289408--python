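"""Domain types and tabular IO for the decision-quality study.

The study design: early breast cancer cases are split into nine case groups,
each reviewed by a panel of three physicians (one per hospital grade, with
distinct seniority levels).  Every case contributes one decision point per
adjuvant treatment stage (targeted, chemotherapy, radiotherapy, endocrine).
Each physician records an *initial* decision, views the CDSS report, and
records a *final* decision.  Independently, the CDSS and a guideline expert
group issue tiered reference recommendations per (case, stage).

Physicians carry a four-digit code: hospital grade digit (1=county,
2=municipal, 3=provincial), two seniority digits (01=senior, 02=middle,
03=junior), and an index digit (1-4), e.g. ``3034`` = provincial junior
physician 4.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "HospitalGrade",
    "Seniority",
    "ReviewerCode",
    "parse_reviewer_code",
    "format_reviewer_code",
    "all_reviewer_codes",
    "TreatmentStage",
    "AgeGroup",
    "MenstrualStatus",
    "BreastSurgery",
    "AxillarySurgery",
    "TnmStage",
    "MolecularSubtype",
    "CaseProfile",
    "Decision",
    "TieredRecommendation",
    "DiscordanceReason",
    "DecisionRecord",
    "StudyBundle",
    "StudyValidationError",
    "canonical_label",
    "read_study",
    "write_study",
]


class StudyValidationError(ValueError):
    """Raised when an input table or domain object violates a study invariant."""


# ---------------------------------------------------------------------------
# Reviewer codes
# ---------------------------------------------------------------------------

class HospitalGrade(IntEnum):
    COUNTY = 1
    MUNICIPAL = 2
    PROVINCIAL = 3


class Seniority(IntEnum):
    SENIOR = 1
    MIDDLE = 2
    JUNIOR = 3


@dataclass(frozen=True, order=True)
class ReviewerCode:
    """Four-digit physician identifier: grade, seniority, within-stratum index."""

    grade: HospitalGrade
    seniority: Seniority
    index: int

    def __post_init__(self) -> None:
        if self.grade not in tuple(HospitalGrade):
            raise StudyValidationError(f"undefined hospital grade {self.grade!r}")
        if self.seniority not in tuple(Seniority):
            raise StudyValidationError(f"undefined seniority {self.seniority!r}")
        if not 1 <= self.index <= 4:
            raise StudyValidationError(f"reviewer index {self.index} out of range 1-4")

    @property
    def code(self) -> str:
        return f"{int(self.grade)}{int(self.seniority):02d}{self.index}"

    @property
    def stratum(self) -> str:
        """Grade x seniority stratum label, e.g. '301' = provincial senior."""
        return f"{int(self.grade)}{int(self.seniority):02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_reviewer_code(code: str) -> ReviewerCode:
    """Decode a 4-digit physician code, e.g. ``"3034"`` -> provincial junior 4."""
    if not isinstance(code, str) or not re.fullmatch(r"\d{4}", code):
        raise StudyValidationError(f"reviewer code {code!r} is not a 4-digit string")
    grade_d, seniority_d, index_d = int(code[0]), int(code[1:3]), int(code[3])
    try:
        grade = HospitalGrade(grade_d)
    except ValueError:
        raise StudyValidationError(
            f"reviewer code {code!r}: grade digit {grade_d} not in 1-3"
        ) from None
    try:
        seniority = Seniority(seniority_d)
    except ValueError:
        raise StudyValidationError(
            f"reviewer code {code!r}: seniority digits {code[1:3]} not in 01-03"
        ) from None
    if not 1 <= index_d <= 4:
        raise StudyValidationError(
            f"reviewer code {code!r}: index digit {index_d} not in 1-4"
        )
    return ReviewerCode(grade, seniority, index_d)


def format_reviewer_code(rc: ReviewerCode) -> str:
    """Inverse of :func:`parse_reviewer_code`."""
    return rc.code


def all_reviewer_codes() -> list[ReviewerCode]:
    """The 36 syntactically valid codes (3 grades x 3 seniorities x 4 indices)."""
    return [
        ReviewerCode(g, s, i)
        for g in HospitalGrade
        for s in Seniority
        for i in range(1, 5)
    ]


# ---------------------------------------------------------------------------
# Cases and stages
# ---------------------------------------------------------------------------

class TreatmentStage(str, Enum):
    """The four adjuvant treatment stages; each case has one decision point per stage."""

    TARGETED = "targeted"
    CHEMOTHERAPY = "chemotherapy"
    RADIOTHERAPY = "radiotherapy"
    ENDOCRINE = "endocrine"


class AgeGroup(str, Enum):
    LE_44 = "<=44"
    Y45_54 = "45-54"
    GE_55 = ">=55"


class MenstrualStatus(str, Enum):
    PRE = "pre"
    POST = "post"


class BreastSurgery(str, Enum):
    BCS = "BCS"
    SM = "SM"


class AxillarySurgery(str, Enum):
    ALND = "ALND"
    SLNB = "SLNB"


class TnmStage(str, Enum):
    I = "I"
    II = "II"
    III = "III"


class MolecularSubtype(str, Enum):
    HER2_POS_HR_NEG = "HER2+HR-"
    HER2_POS_HR_POS = "HER2+HR+"
    LUMINAL_A = "LuminalA"
    LUMINAL_B_HER2_NEG = "LuminalB_HER2-"
    TNBC = "TNBC"


CASE_GROUPS = tuple(f"G{i}" for i in range(1, 10))

#: The seven case-level covariates used for subgroup rates and propensity matching.
COVARIATE_FIELDS = (
    "age_group",
    "menstrual_status",
    "breast_surgery",
    "axillary_surgery",
    "tnm_stage",
    "molecular_subtype",
)


@dataclass(frozen=True)
class CaseProfile:
    """Covariates of one enrolled case; all fields required (complete-information enrolment)."""

    case_id: str
    case_group: str
    age_group: AgeGroup
    menstrual_status: MenstrualStatus
    breast_surgery: BreastSurgery
    axillary_surgery: AxillarySurgery
    tnm_stage: TnmStage
    molecular_subtype: MolecularSubtype

    def __post_init__(self) -> None:
        if self.case_group not in CASE_GROUPS:
            raise StudyValidationError(
                f"case {self.case_id!r}: unknown case group {self.case_group!r}"
            )
        for f in ("case_id",) + COVARIATE_FIELDS:
            if getattr(self, f) in (None, ""):
                raise StudyValidationError(f"case {self.case_id!r}: missing {f}")


# ---------------------------------------------------------------------------
# Decisions and tiered recommendations
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def canonical_label(label: str) -> str:
    """Canonical regimen token: case-folded, inner whitespace collapsed, stripped."""
    return _WS.sub(" ", label.strip()).casefold()


@dataclass(frozen=True)
class Decision:
    """One treatment proposal: a regimen label, or a 'not recommended' verdict."""

    recommended: bool
    regimen: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "regimen", canonical_label(self.regimen))
        if not self.recommended and self.regimen:
            raise StudyValidationError("not-recommended decision carries a regimen label")
        if self.recommended and not self.regimen:
            raise StudyValidationError("recommended decision lacks a regimen label")

    @classmethod
    def recommend(cls, regimen: str) -> "Decision":
        return cls(True, regimen)

    @classmethod
    def not_recommended(cls) -> "Decision":
        return cls(False, "")


@dataclass(frozen=True)
class TieredRecommendation:
    """A reference recommendation set with Level I/II(/III) tiers or a not-recommended flag.

    Level III exists only for guideline references; the CDSS emits Levels I-II.
    """

    recommended: bool
    level1: frozenset[str] = frozenset()
    level2: frozenset[str] = frozenset()
    level3: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for tier in ("level1", "level2", "level3"):
            object.__setattr__(
                self, tier, frozenset(canonical_label(x) for x in getattr(self, tier))
            )
        if not self.recommended and (self.level1 or self.level2 or self.level3):
            raise StudyValidationError("not-recommended reference has non-empty tiers")
        if self.recommended and not self.level1:
            raise StudyValidationError("recommended reference has empty Level I tier")
        if (self.level1 & self.level2) or (self.level1 & self.level3) or (
            self.level2 & self.level3
        ):
            raise StudyValidationError("recommendation tiers are not pairwise disjoint")

    @classmethod
    def not_recommended(cls) -> "TieredRecommendation":
        return cls(False)

    @classmethod
    def of(
        cls,
        level1: Iterable[str],
        level2: Iterable[str] = (),
        level3: Iterable[str] = (),
    ) -> "TieredRecommendation":
        return cls(True, frozenset(level1), frozenset(level2), frozenset(level3))


class DiscordanceReason(str, Enum):
    """Adjudicated reason for a physician/CDSS discordance."""

    STRATEGY_DIFFERENCE = "strategy_difference"
    MISSING_OR_MISREAD_INFO = "missing_or_misread_info"
    INCORRECT_CONCORDANCE_ASSESSMENT = "incorrect_concordance_assessment"


@dataclass(frozen=True)
class DecisionRecord:
    """One (case, stage, reviewer) row: initial and final decisions plus annotations."""

    case_id: str
    stage: TreatmentStage
    reviewer: ReviewerCode
    initial: Decision
    final: Decision
    discordance_reason: Optional[DiscordanceReason] = None


# ---------------------------------------------------------------------------
# Study bundle
# ---------------------------------------------------------------------------

RefMap = Mapping[tuple[str, TreatmentStage], TieredRecommendation]


@dataclass
class StudyBundle:
    """A complete study: cases, both reference maps, decision records, panel rosters."""

    cases: list[CaseProfile]
    ai_reference: dict[tuple[str, TreatmentStage], TieredRecommendation]
    guideline_reference: dict[tuple[str, TreatmentStage], TieredRecommendation]
    records: list[DecisionRecord]
    panel_assignment: dict[str, frozenset[ReviewerCode]] = field(default_factory=dict)

    def validate(self) -> None:
        """Check all structural invariants; raise StudyValidationError on the first breach."""
        case_ids = {c.case_id for c in self.cases}
        if len(case_ids) != len(self.cases):
            raise StudyValidationError("duplicate case_id in case table")
        for c in self.cases:
            for st in TreatmentStage:
                if (c.case_id, st) not in self.ai_reference:
                    raise StudyValidationError(
                        f"missing AI reference for ({c.case_id}, {st.value})"
                    )
                if (c.case_id, st) not in self.guideline_reference:
                    raise StudyValidationError(
                        f"missing guideline reference for ({c.case_id}, {st.value})"
                    )
        group_of = {c.case_id: c.case_group for c in self.cases}
        for i, r in enumerate(self.records):
            if r.case_id not in case_ids:
                raise StudyValidationError(
                    f"record {i}: unknown case_id {r.case_id!r}"
                )
        if self.panel_assignment:
            for g, panel in self.panel_assignment.items():
                if len(panel) != 3:
                    raise StudyValidationError(f"panel {g} has {len(panel)} reviewers, not 3")
            for i, r in enumerate(self.records):
                panel = self.panel_assignment.get(group_of[r.case_id], frozenset())
                if r.reviewer not in panel:
                    raise StudyValidationError(
                        f"record {i}: reviewer {r.reviewer.code} not on panel "
                        f"of group {group_of[r.case_id]}"
                    )
        expected = len(self.cases) * len(TreatmentStage) * 3
        if self.records and len(self.records) != expected:
            raise StudyValidationError(
                f"record count {len(self.records)} != |cases| x 4 stages x 3 "
                f"reviewers = {expected}"
            )

    @property
    def n_decision_points(self) -> int:
        return len(self.cases) * len(TreatmentStage)

    def case_map(self) -> dict[str, CaseProfile]:
        return {c.case_id: c for c in self.cases}

    def derive_panels(self) -> dict[str, frozenset[ReviewerCode]]:
        """Reconstruct panel rosters from the records (reviewers seen per case group)."""
        group_of = {c.case_id: c.case_group for c in self.cases}
        panels: dict[str, set[ReviewerCode]] = {}
        for r in self.records:
            panels.setdefault(group_of[r.case_id], set()).add(r.reviewer)
        return {g: frozenset(s) for g, s in panels.items()}


# ---------------------------------------------------------------------------
# Serialization: three CSV tables or one JSON document
# ---------------------------------------------------------------------------

def _tier_str(tier: frozenset[str]) -> str:
    return "|".join(sorted(tier))


def _tier_set(s: str) -> frozenset[str]:
    if not isinstance(s, str) or not s.strip():
        return frozenset()
    return frozenset(x for x in s.split("|") if x.strip())


def _cases_frame(cases: Iterable[CaseProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "case_group": c.case_group,
                "age_group": c.age_group.value,
                "menstrual_status": c.menstrual_status.value,
                "breast_surgery": c.breast_surgery.value,
                "axillary_surgery": c.axillary_surgery.value,
                "tnm_stage": c.tnm_stage.value,
                "molecular_subtype": c.molecular_subtype.value,
            }
            for c in cases
        ],
        columns=[
            "case_id", "case_group", "age_group", "menstrual_status",
            "breast_surgery", "axillary_surgery", "tnm_stage", "molecular_subtype",
        ],
    )


def _reference_frame(bundle: StudyBundle) -> pd.DataFrame:
    rows = []
    for source, ref in (("ai", bundle.ai_reference), ("guideline", bundle.guideline_reference)):
        for (case_id, stage), tr in sorted(ref.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
            rows.append(
                {
                    "case_id": case_id,
                    "stage": stage.value,
                    "source": source,
                    "recommended": int(tr.recommended),
                    "level1": _tier_str(tr.level1),
                    "level2": _tier_str(tr.level2),
                    "level3": _tier_str(tr.level3),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["case_id", "stage", "source", "recommended", "level1", "level2", "level3"],
    )


def _decisions_frame(records: Iterable[DecisionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "stage": r.stage.value,
                "reviewer_code": r.reviewer.code,
                "initial_recommended": int(r.initial.recommended),
                "initial_regimen": r.initial.regimen,
                "final_recommended": int(r.final.recommended),
                "final_regimen": r.final.regimen,
                "discordance_reason": r.discordance_reason.value if r.discordance_reason else "",
            }
            for r in records
        ],
        columns=[
            "case_id", "stage", "reviewer_code", "initial_recommended", "initial_regimen",
            "final_recommended", "final_regimen", "discordance_reason",
        ],
    )


def write_study(bundle: StudyBundle, path: str | Path) -> None:
    """Write a bundle to ``path``: a ``*.json`` file or a directory of three CSV tables.

    ``read_study(write_study(b)) == b`` field for field.
    """
    path = Path(path)
    if path.suffix == ".json":
        doc = {
            "cases": _cases_frame(bundle.cases).to_dict(orient="records"),
            "reference": _reference_frame(bundle).to_dict(orient="records"),
            "decisions": _decisions_frame(bundle.records).to_dict(orient="records"),
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))
        return
    path.mkdir(parents=True, exist_ok=True)
    _cases_frame(bundle.cases).to_csv(path / "cases.csv", index=False)
    _reference_frame(bundle).to_csv(path / "reference.csv", index=False)
    _decisions_frame(bundle.records).to_csv(path / "decisions.csv", index=False)


def _row_error(table: str, i: int, msg: str) -> StudyValidationError:
    return StudyValidationError(f"{table} row {i}: {msg}")


def _bundle_from_frames(
    cases_df: pd.DataFrame, ref_df: pd.DataFrame, dec_df: pd.DataFrame
) -> StudyBundle:
    cases = []
    for i, row in cases_df.iterrows():
        try:
            cases.append(
                CaseProfile(
                    case_id=str(row["case_id"]),
                    case_group=str(row["case_group"]),
                    age_group=AgeGroup(row["age_group"]),
                    menstrual_status=MenstrualStatus(row["menstrual_status"]),
                    breast_surgery=BreastSurgery(row["breast_surgery"]),
                    axillary_surgery=AxillarySurgery(row["axillary_surgery"]),
                    tnm_stage=TnmStage(row["tnm_stage"]),
                    molecular_subtype=MolecularSubtype(row["molecular_subtype"]),
                )
            )
        except (ValueError, KeyError) as e:
            raise _row_error("cases", i, str(e)) from None

    ai_ref: dict[tuple[str, TreatmentStage], TieredRecommendation] = {}
    guide_ref: dict[tuple[str, TreatmentStage], TieredRecommendation] = {}
    for i, row in ref_df.iterrows():
        try:
            key = (str(row["case_id"]), TreatmentStage(row["stage"]))
            tr = (
                TieredRecommendation(
                    True,
                    _tier_set(row["level1"]),
                    _tier_set(row["level2"]),
                    _tier_set(row["level3"]),
                )
                if int(row["recommended"])
                else TieredRecommendation.not_recommended()
            )
            source = str(row["source"])
            target = {"ai": ai_ref, "guideline": guide_ref}[source]
        except (ValueError, KeyError) as e:
            raise _row_error("reference", i, str(e)) from None
        if key in target:
            raise _row_error("reference", i, f"duplicate {source} entry for {key}")
        target[key] = tr

    records = []
    for i, row in dec_df.iterrows():
        try:
            reason = str(row["discordance_reason"]) if not pd.isna(row["discordance_reason"]) else ""
            records.append(
                DecisionRecord(
                    case_id=str(row["case_id"]),
                    stage=TreatmentStage(row["stage"]),
                    reviewer=parse_reviewer_code(str(row["reviewer_code"])),
                    initial=Decision(bool(int(row["initial_recommended"])),
                                     "" if pd.isna(row["initial_regimen"]) else str(row["initial_regimen"])),
                    final=Decision(bool(int(row["final_recommended"])),
                                   "" if pd.isna(row["final_regimen"]) else str(row["final_regimen"])),
                    discordance_reason=DiscordanceReason(reason) if reason else None,
                )
            )
        except (ValueError, KeyError) as e:
            raise _row_error("decisions", i, str(e)) from None

    bundle = StudyBundle(
        cases=cases, ai_reference=ai_ref, guideline_reference=guide_ref, records=records
    )
    bundle.panel_assignment = bundle.derive_panels()
    bundle.validate()
    return bundle


def read_study(path: str | Path) -> StudyBundle:
    """Load and validate a bundle from a ``*.json`` file or a directory of CSV tables."""
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        return _bundle_from_frames(
            pd.DataFrame(doc["cases"], columns=_cases_frame([]).columns),
            pd.DataFrame(doc["reference"], columns=_reference_frame(
                StudyBundle([], {}, {}, [])).columns),
            pd.DataFrame(doc["decisions"], columns=_decisions_frame([]).columns),
        )
    for name in ("cases.csv", "reference.csv", "decisions.csv"):
        if not (path / name).is_file():
            raise StudyValidationError(f"missing study table {name} under {path}")
    return _bundle_from_frames(
        pd.read_csv(path / "cases.csv", dtype=str).fillna(""),
        pd.read_csv(path / "reference.csv", dtype=str).fillna(""),
        pd.read_csv(path / "decisions.csv", dtype=str).fillna(""),
    )
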