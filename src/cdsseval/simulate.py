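"""Synthetic study generator.

Emulates the trial design — 531 cases in nine groups of 59, reviewed by 27
physicians in nine panels of three (one physician per hospital grade, with
distinct seniorities, in each panel), four adjuvant treatment stages, hence
2124 decision points and 6372 decision opinions per pass — together with a
parameterised stochastic model of guideline/CDSS references, physician
conformity, discordance reasons and final-decision switching, so that every
indicator in the package is testable without the (undeposited) trial data.

Default covariate frequencies are the study's overall case-mix; default
per-stratum conformity and stability probabilities reproduce the study's
printed stratum values where printed and its seniority/grade marginals
elsewhere (see docs/methods.md).  Per-stage reference "not recommended"
frequencies are not reported by the study; the defaults here are the
package's own choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    AgeGroup,
    AxillarySurgery,
    BreastSurgery,
    CASE_GROUPS,
    CaseProfile,
    Decision,
    DecisionRecord,
    DiscordanceReason,
    MenstrualStatus,
    MolecularSubtype,
    ReviewerCode,
    StudyBundle,
    StudyValidationError,
    TieredRecommendation,
    TnmStage,
    TreatmentStage,
    parse_reviewer_code,
)
from .indicators import classify_concordance, is_concordant

__all__ = ["GeneratorConfig", "generate_cases", "generate_references",
           "generate_decisions", "assemble_study", "DEFAULT_PANELS"]


def _panels(spec: Mapping[str, Sequence[str]]) -> dict[str, frozenset[ReviewerCode]]:
    return {g: frozenset(parse_reviewer_code(c) for c in codes) for g, codes in spec.items()}


#: Latin-square panel rosters: each panel pairs one provincial, one municipal
#: and one county physician of three distinct seniorities; the G1, G7, G8 and
#: G9 rosters are the study's published ones, the rest complete the pattern.
DEFAULT_PANELS: dict[str, tuple[str, str, str]] = {
    "G1": ("3034", "2013", "1023"),
    "G2": ("3032", "2011", "1021"),
    "G3": ("3033", "2012", "1022"),
    "G4": ("3021", "2031", "1011"),
    "G5": ("3022", "2032", "1012"),
    "G6": ("3023", "2033", "1013"),
    "G7": ("3011", "2022", "1033"),
    "G8": ("3013", "2021", "1031"),
    "G9": ("3012", "2023", "1032"),
}

STRATA = ("101", "102", "103", "201", "202", "203", "301", "302", "303")

_STAGES = tuple(TreatmentStage)


def _dist(pairs: Sequence[tuple[object, float]]) -> dict:
    return dict(pairs)


@dataclass
class GeneratorConfig:
    """All dials of the synthetic study; defaults are the study conditions."""

    n_groups: int = 9
    cases_per_group: int = 59
    seed: int = 0

    #: categorical covariate probabilities (overall case-mix of the trial)
    covariate_distributions: dict = field(default_factory=lambda: {
        "age_group": _dist([(AgeGroup.LE_44, 143 / 531), (AgeGroup.Y45_54, 255 / 531),
                            (AgeGroup.GE_55, 133 / 531)]),
        "menstrual_status": _dist([(MenstrualStatus.PRE, 319 / 531),
                                   (MenstrualStatus.POST, 212 / 531)]),
        "breast_surgery": _dist([(BreastSurgery.BCS, 96 / 531), (BreastSurgery.SM, 435 / 531)]),
        "axillary_surgery": _dist([(AxillarySurgery.ALND, 379 / 531),
                                   (AxillarySurgery.SLNB, 152 / 531)]),
        "tnm_stage": _dist([(TnmStage.I, 191 / 531), (TnmStage.II, 265 / 531),
                            (TnmStage.III, 75 / 531)]),
        "molecular_subtype": _dist([
            (MolecularSubtype.HER2_POS_HR_NEG, 48 / 531),
            (MolecularSubtype.HER2_POS_HR_POS, 111 / 531),
            (MolecularSubtype.LUMINAL_A, 81 / 531),
            (MolecularSubtype.LUMINAL_B_HER2_NEG, 223 / 531),
            (MolecularSubtype.TNBC, 68 / 531),
        ]),
    })

    #: panel rosters (case group -> three reviewer codes)
    panels: dict = field(default_factory=lambda: dict(DEFAULT_PANELS))

    #: abstract per-stage regimen vocabulary; the first ``level1_pool`` labels
    #: are Level-I-eligible
    vocabulary_size: int = 6
    level1_pool: int = 4

    #: reference model: per-stage probability that the guideline recommends
    #: exemption from the stage (not reported by the study; package defaults)
    p_not_recommended: dict = field(default_factory=lambda: {
        TreatmentStage.TARGETED: 0.30,
        TreatmentStage.CHEMOTHERAPY: 0.10,
        TreatmentStage.RADIOTHERAPY: 0.35,
        TreatmentStage.ENDOCRINE: 0.20,
    })
    #: probability the CDSS Level-I set conforms to the guideline Level-I set
    p_ai: float = 0.975
    #: nonconforming CDSS draw mixture: (Level-II match, not available, dispute)
    ai_nonconform_mixture: tuple[float, float, float] = (0.4, 0.4, 0.2)
    #: probability a recommending guideline lists two Level-I options
    p_two_level1: float = 0.3

    #: physician model: per-stratum probability that the initial decision
    #: conforms to the guideline Level-I set
    p_conf: dict = field(default_factory=lambda: {
        "301": 0.836, "302": 0.760, "303": 0.750,
        "201": 0.780, "202": 0.823, "203": 0.791,
        "101": 0.802, "102": 0.802, "103": 0.856,
    })
    #: nonconforming physician draw mixture: (Level-II match, not available, dispute)
    phys_nonconform_mixture: tuple[float, float, float] = (0.35, 0.35, 0.30)
    #: per-stratum discordance-reason mixture (strategy, misread, mis-assessment)
    reason_mixture: dict = field(default_factory=lambda: {
        "301": (88 / 116, 18 / 116, 10 / 116),
        "302": (120 / 169, 21 / 169, 28 / 169),
        "303": (91 / 178, 22 / 178, 65 / 178),
        "201": (104 / 154, 11 / 154, 39 / 154),
        "202": (121 / 134, 7 / 134, 6 / 134),
        "203": (86 / 137, 11 / 137, 40 / 137),
        "101": (104 / 143, 7 / 143, 32 / 143),
        "102": (70 / 137, 19 / 137, 48 / 137),
        "103": (78 / 97, 10 / 97, 9 / 97),
    })
    #: per-stratum probability that an AI-discordant initial decision is kept
    p_stable: dict = field(default_factory=lambda: {
        "301": 0.527, "302": 0.545, "303": 0.491,
        "201": 0.377, "202": 0.254, "203": 0.386,
        "101": 0.350, "102": 0.527, "103": 0.197,
    })

    def validate(self) -> None:
        if self.n_groups < 1 or self.n_groups > 9:
            raise StudyValidationError("n_groups must be in 1-9 (panel rosters exist for G1-G9)")
        if self.cases_per_group < 1:
            raise StudyValidationError("cases_per_group must be positive")
        if not 2 <= self.level1_pool <= self.vocabulary_size - 2:
            raise StudyValidationError(
                "need level1_pool >= 2 and at least two non-Level-I labels per stage"
            )
        for name, d in self.covariate_distributions.items():
            if abs(sum(d.values()) - 1.0) > 1e-9 or any(p < 0 for p in d.values()):
                raise StudyValidationError(f"covariate distribution {name!r} is not a probability vector")
        for mix in (self.ai_nonconform_mixture, self.phys_nonconform_mixture,
                    *self.reason_mixture.values()):
            if abs(sum(mix) - 1.0) > 1e-9 or any(p < 0 for p in mix):
                raise StudyValidationError("mixture weights must form a probability vector")
        for d in (self.p_conf, self.p_stable):
            for s in STRATA:
                if s not in d:
                    raise StudyValidationError(f"missing stratum parameter for {s}")
                if not 0.0 <= d[s] <= 1.0:
                    raise StudyValidationError(f"stratum probability {s}={d[s]} outside [0, 1]")
        if not 0.0 <= self.p_ai <= 1.0:
            raise StudyValidationError("p_ai outside [0, 1]")
        groups = [f"G{i}" for i in range(1, self.n_groups + 1)]
        for g in groups:
            codes = self.panels.get(g, ())
            if len(codes) != 3:
                raise StudyValidationError(f"panel {g} must list exactly 3 reviewer codes")

    def vocabulary(self, stage: TreatmentStage) -> list[str]:
        prefix = stage.value[:3]
        return [f"{prefix}-{chr(ord('a') + i)}" for i in range(self.vocabulary_size)]


def _draw(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist)
    return keys[rng.choice(len(keys), p=np.asarray([dist[k] for k in keys]))]


def generate_cases(cfg: GeneratorConfig, rng: np.random.Generator) -> list[CaseProfile]:
    """Case table: ``n_groups x cases_per_group`` cases, covariates iid from the config."""
    cfg.validate()
    cases = []
    for gi in range(cfg.n_groups):
        group = CASE_GROUPS[gi]
        for k in range(cfg.cases_per_group):
            cid = f"C{gi + 1}{k + 1:03d}"
            cov = {f: _draw(rng, d) for f, d in cfg.covariate_distributions.items()}
            cases.append(CaseProfile(case_id=cid, case_group=group, **cov))
    return cases


def _guideline_draw(
    cfg: GeneratorConfig, stage: TreatmentStage, rng: np.random.Generator
) -> TieredRecommendation:
    if rng.random() < cfg.p_not_recommended[stage]:
        return TieredRecommendation.not_recommended()
    vocab = cfg.vocabulary(stage)
    n1 = 2 if rng.random() < cfg.p_two_level1 else 1
    l1 = rng.choice(cfg.level1_pool, size=n1, replace=False)
    level1 = {vocab[i] for i in l1}
    rest = [v for v in vocab if v not in level1]
    level2 = {rest[rng.integers(len(rest))]}
    return TieredRecommendation.of(level1, level2)


def _ai_draw(
    cfg: GeneratorConfig,
    stage: TreatmentStage,
    guide: TieredRecommendation,
    rng: np.random.Generator,
) -> TieredRecommendation:
    vocab = cfg.vocabulary(stage)
    if rng.random() < cfg.p_ai:  # conforming configuration
        if not guide.recommended:
            return TieredRecommendation.not_recommended()
        return TieredRecommendation.of(guide.level1, guide.level2)
    # nonconforming draw
    if not guide.recommended:
        return TieredRecommendation.of({vocab[rng.integers(cfg.level1_pool)]})
    kind = rng.choice(3, p=np.asarray(cfg.ai_nonconform_mixture))
    if kind == 0:  # Level-II match: CDSS promotes a guideline Level-II option
        return TieredRecommendation.of({sorted(guide.level2)[0]})
    if kind == 1:  # not available: a label outside every guideline tier
        outside = [v for v in vocab if v not in guide.level1 | guide.level2 | guide.level3]
        return TieredRecommendation.of({outside[rng.integers(len(outside))]})
    return TieredRecommendation.not_recommended()  # recommend dispute


def generate_references(
    cases: Sequence[CaseProfile], cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[dict, dict]:
    """(AI, guideline) tiered-recommendation maps over every (case, stage)."""
    ai, guide = {}, {}
    for c in cases:
        for stage in _STAGES:
            g = _guideline_draw(cfg, stage, rng)
            guide[(c.case_id, stage)] = g
            ai[(c.case_id, stage)] = _ai_draw(cfg, stage, g, rng)
    return ai, guide


def _initial_draw(
    cfg: GeneratorConfig,
    stage: TreatmentStage,
    stratum: str,
    guide: TieredRecommendation,
    rng: np.random.Generator,
) -> Decision:
    vocab = cfg.vocabulary(stage)
    if rng.random() < cfg.p_conf[stratum]:  # conforms to the guideline
        if not guide.recommended:
            return Decision.not_recommended()
        l1 = sorted(guide.level1)
        return Decision.recommend(l1[rng.integers(len(l1))])
    # nonconforming draw
    if not guide.recommended:
        return Decision.recommend(vocab[rng.integers(cfg.level1_pool)])  # dispute
    kind = rng.choice(3, p=np.asarray(cfg.phys_nonconform_mixture))
    if kind == 0:
        return Decision.recommend(sorted(guide.level2)[0])  # Level-II match
    if kind == 1:
        outside = [v for v in vocab if v not in guide.level1 | guide.level2 | guide.level3]
        return Decision.recommend(outside[rng.integers(len(outside))])  # not available
    return Decision.not_recommended()  # recommend dispute


_REASONS = (
    DiscordanceReason.STRATEGY_DIFFERENCE,
    DiscordanceReason.MISSING_OR_MISREAD_INFO,
    DiscordanceReason.INCORRECT_CONCORDANCE_ASSESSMENT,
)


def generate_decisions(
    cases: Sequence[CaseProfile],
    ai_reference: Mapping,
    guideline_reference: Mapping,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[DecisionRecord]:
    """Two-pass decision records for every (case, stage, panel reviewer).

    The initial decision conforms to the guideline Level-I set with the
    stratum's conformity probability.  If the initial decision is discordant
    with the CDSS reference, a discordance reason is drawn from the stratum
    mixture and the final decision keeps the initial one with the stratum's
    stability probability, otherwise switches to a CDSS Level-I option;
    CDSS-concordant decisions never switch.
    """
    records = []
    for c in cases:
        panel = sorted(parse_reviewer_code(x) for x in cfg.panels[c.case_group])
        for stage in _STAGES:
            guide = guideline_reference[(c.case_id, stage)]
            ai = ai_reference[(c.case_id, stage)]
            for rc in panel:
                stratum = rc.stratum
                initial = _initial_draw(cfg, stage, stratum, guide, rng)
                reason = None
                final = initial
                if not is_concordant(classify_concordance(initial, ai)):
                    reason = _REASONS[rng.choice(3, p=np.asarray(cfg.reason_mixture[stratum]))]
                    if rng.random() >= cfg.p_stable[stratum]:  # switches to the CDSS
                        if ai.recommended:
                            l1 = sorted(ai.level1)
                            final = Decision.recommend(l1[rng.integers(len(l1))])
                        else:
                            final = Decision.not_recommended()
                records.append(
                    DecisionRecord(
                        case_id=c.case_id, stage=stage, reviewer=rc,
                        initial=initial, final=final, discordance_reason=reason,
                    )
                )
    return records


def assemble_study(cfg: GeneratorConfig | None = None) -> StudyBundle:
    """Generate a full validated StudyBundle from a config (defaults = study conditions)."""
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cases = generate_cases(cfg, rng)
    ai_ref, guide_ref = generate_references(cases, cfg, rng)
    records = generate_decisions(cases, ai_ref, guide_ref, cfg, rng)
    panels = {
        f"G{i + 1}": frozenset(parse_reviewer_code(x) for x in cfg.panels[f"G{i + 1}"])
        for i in range(cfg.n_groups)
    }
    bundle = StudyBundle(
        cases=cases, ai_reference=ai_ref, guideline_reference=guide_ref,
        records=records, panel_assignment=panels,
    )
    bundle.validate()
    return bundle
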