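"""End-to-end assessment: classify every decision record, match, compute all
indicators, calibrate them by decision stability, summarise internal
variation, and run the supporting inferential tests.

The report reproduces the study's reportable tables from any StudyBundle:
concordance and conformity rates (overall and by hospital grade, seniority,
grade x seniority stratum, individual physician, case group, and the case
covariates), concordance with the designated high-level physicians,
consensus per case group, decision stability before and after propensity
matching, stability-calibrated indicators, pairwise-difference variation
summaries, the discordance-reason table with chi-square tests, and a paired
McNemar comparison of physician vs CDSS guideline conformity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np
import pandas as pd

from .calibration import (
    BenchmarkPolicy,
    CalibrationTable,
    VariationSummary,
    build_calibration_table,
    pairwise_difference_matrix,
)
from .indicators import (
    IndicatorResult,
    OVERALL,
    classify_concordance,
    classify_guideline_conformity,
    classify_hl_concordance,
    indicator_rate,
    is_concordant,
    is_conforming,
    is_hl_concordant,
)
from .model import (
    COVARIATE_FIELDS,
    Decision,
    HospitalGrade,
    Seniority,
    StudyBundle,
    StudyValidationError,
    TreatmentStage,
)
from .stability import panel_decision_points, consensus_rate, stability_rate
from .stats import (
    ChiSquareResult,
    ContingencyTable,
    McNemarResult,
    chi_square_test,
    mcnemar_test,
    propensity_match,
)

logger = logging.getLogger("cdsseval")

__all__ = ["AssessmentOptions", "AssessmentReport", "classify_records",
           "run_assessment", "reason_summary", "write_report"]

_GRADE_LABEL = {HospitalGrade.COUNTY: "county", HospitalGrade.MUNICIPAL: "municipal",
                HospitalGrade.PROVINCIAL: "provincial"}
_SENIORITY_LABEL = {Seniority.SENIOR: "senior", Seniority.MIDDLE: "middle",
                    Seniority.JUNIOR: "junior"}

#: grouping name -> classified-frame column
GROUPINGS = {
    "grade": "grade",
    "seniority": "seniority",
    "stratum": "stratum",
    "physician": "reviewer_code",
    "case_group": "case_group",
    "age_group": "age_group",
    "menstrual_status": "menstrual_status",
    "breast_surgery": "breast_surgery",
    "axillary_surgery": "axillary_surgery",
    "tnm_stage": "tnm_stage",
    "molecular_subtype": "molecular_subtype",
    "treatment_stage": "stage",
}


@dataclass
class AssessmentOptions:
    """Tunable choices of the assessment run."""

    decision_pass: str = "initial"       # pass feeding concordance/conformity/HL
    consensus_pass: str = "initial"
    hl_pass: str = "initial"             # which HL decision is the standard
    calibration_policy: BenchmarkPolicy | str = BenchmarkPolicy.MAX_STABILITY
    calibration_reference: str | None = None
    do_matching: bool = True
    caliper: float = 0.01
    seed: int = 0
    sd_ddof: int = 1


@dataclass
class AssessmentReport:
    classified: pd.DataFrame
    concordance: dict[str, dict[Hashable, IndicatorResult]]
    conformity_physician: dict[str, dict[Hashable, IndicatorResult]]
    conformity_ai: dict[str, dict[Hashable, IndicatorResult]]
    hl_concordance: pd.DataFrame
    consensus: dict[Hashable, IndicatorResult]
    stability_pre: dict[str, dict[Hashable, IndicatorResult]]
    stability_post: dict[str, dict[Hashable, IndicatorResult]] | None
    match_summary: pd.DataFrame | None
    calibration: dict[str, CalibrationTable]
    variation: dict[str, VariationSummary]
    variation_gaps: dict[str, float]
    reasons: dict[str, tuple[ContingencyTable, pd.DataFrame]]
    tests: dict[str, dict]

    def rates_frame(self, tables: Mapping[str, Mapping[Hashable, IndicatorResult]]) -> pd.DataFrame:
        rows = []
        for grouping, table in tables.items():
            for group, res in table.items():
                rows.append({"grouping": grouping, "group": str(group),
                             "numerator": res.numerator, "denominator": res.denominator,
                             "rate": res.rate})
        return pd.DataFrame(rows, columns=["grouping", "group", "numerator", "denominator", "rate"])


# ---------------------------------------------------------------------------
# Record classification
# ---------------------------------------------------------------------------

def classify_records(bundle: StudyBundle, decision_pass: str = "initial") -> pd.DataFrame:
    """One row per decision record with every classification attached.

    Columns include the reviewer's grade/seniority/stratum, the case
    covariates, the five-way CDSS concordance and guideline conformity
    categories with their boolean flags, and (for CDSS-discordant records)
    the stability flag and discordance reason.
    """
    if decision_pass not in ("initial", "final"):
        raise StudyValidationError("decision_pass must be 'initial' or 'final'")
    cases = bundle.case_map()
    rows = []
    for r in bundle.records:
        case = cases[r.case_id]
        ai = bundle.ai_reference[(r.case_id, r.stage)]
        guide = bundle.guideline_reference[(r.case_id, r.stage)]
        decision: Decision = getattr(r, decision_pass)
        conc = classify_concordance(decision, ai)
        conf = classify_guideline_conformity(decision, guide)
        initial_conc = classify_concordance(r.initial, ai)
        discordant = not is_concordant(initial_conc)
        rows.append({
            "case_id": r.case_id,
            "stage": r.stage.value,
            "reviewer_code": r.reviewer.code,
            "grade": _GRADE_LABEL[r.reviewer.grade],
            "seniority": _SENIORITY_LABEL[r.reviewer.seniority],
            "stratum": r.reviewer.stratum,
            "case_group": case.case_group,
            **{f: getattr(case, f).value for f in COVARIATE_FIELDS},
            "initial_recommended": r.initial.recommended,
            "initial_regimen": r.initial.regimen,
            "final_recommended": r.final.recommended,
            "final_regimen": r.final.regimen,
            "concordance_category": conc.value,
            "concordant": int(is_concordant(conc)),
            "conformity_category": conf.value,
            "conforming": int(is_conforming(conf)),
            "ai_discordant_initial": int(discordant),
            "stable": int(r.final == r.initial) if discordant else pd.NA,
            "discordance_reason": r.discordance_reason.value if r.discordance_reason else "",
        })
    return pd.DataFrame(rows)


def _grouped_rates(df: pd.DataFrame, flag_col: str) -> dict[str, dict[Hashable, IndicatorResult]]:
    """indicator_rate over every standard grouping of a classified frame."""
    recs = list(df[[flag_col, *set(GROUPINGS.values())]].itertuples(index=False))
    flag = lambda r: getattr(r, flag_col)  # noqa: E731
    out: dict[str, dict[Hashable, IndicatorResult]] = {
        "overall": indicator_rate(recs, flag)
    }
    for name, col in GROUPINGS.items():
        table = indicator_rate(recs, flag, grouping=lambda r: getattr(r, col))
        table.pop(OVERALL)
        out[name] = table
    return out


def _ai_conformity_frame(bundle: StudyBundle) -> pd.DataFrame:
    """Per decision point: conformity of the CDSS Level-I set with the guideline."""
    cases = bundle.case_map()
    rows = []
    for c in bundle.cases:
        for stage in TreatmentStage:
            ai = bundle.ai_reference[(c.case_id, stage)]
            guide = bundle.guideline_reference[(c.case_id, stage)]
            cat = classify_guideline_conformity(ai, guide)
            rows.append({
                "case_id": c.case_id,
                "stage": stage.value,
                "case_group": cases[c.case_id].case_group,
                **{f: getattr(c, f).value for f in COVARIATE_FIELDS},
                "conformity_category": cat.value,
                "conforming": int(is_conforming(cat)),
            })
    return pd.DataFrame(rows)


_AI_GROUPINGS = {k: v for k, v in GROUPINGS.items()
                 if v not in ("grade", "seniority", "stratum", "reviewer_code")}


def _ai_grouped_rates(df: pd.DataFrame) -> dict[str, dict[Hashable, IndicatorResult]]:
    recs = list(df.itertuples(index=False))
    out = {"overall": indicator_rate(recs, lambda r: r.conforming)}
    for name, col in _AI_GROUPINGS.items():
        table = indicator_rate(recs, lambda r: r.conforming, grouping=lambda r: getattr(r, col))
        table.pop(OVERALL)
        out[name] = table
    return out


# ---------------------------------------------------------------------------
# High-level concordance
# ---------------------------------------------------------------------------

def _hl_concordance(bundle: StudyBundle, opts: AssessmentOptions) -> pd.DataFrame:
    """Concordance of the other panel physicians and the CDSS with the
    high-level physician, per case group served by a provincial-senior code."""
    group_of = {c.case_id: c.case_group for c in bundle.cases}
    panels = bundle.panel_assignment or bundle.derive_panels()
    hl_groups = {
        g: next(iter(rc for rc in panel if rc.stratum == "301"))
        for g, panel in panels.items()
        if any(rc.stratum == "301" for rc in panel)
    }
    by_rev: dict[tuple[str, TreatmentStage, str], Decision] = {}
    for r in bundle.records:
        by_rev[(r.case_id, r.stage, r.reviewer.code)] = getattr(r, opts.hl_pass)
    init_by_rev: dict[tuple[str, TreatmentStage, str], Decision] = {
        (r.case_id, r.stage, r.reviewer.code): getattr(r, opts.decision_pass)
        for r in bundle.records
    }
    rows = []
    for g, hl_code in sorted(hl_groups.items()):
        subjects = sorted(rc.code for rc in panels[g] if rc != hl_code)
        case_ids = [c.case_id for c in bundle.cases if group_of[c.case_id] == g]
        for case_id in case_ids:
            for stage in TreatmentStage:
                hl = by_rev[(case_id, stage, hl_code.code)]
                for code in subjects:
                    cat = classify_hl_concordance(init_by_rev[(case_id, stage, code)], hl)
                    rows.append({"case_group": g, "subject": code,
                                 "category": cat.value, "concordant": int(is_hl_concordant(cat))})
                cat = classify_hl_concordance(bundle.ai_reference[(case_id, stage)], hl)
                rows.append({"case_group": g, "subject": "CDSS",
                             "category": cat.value, "concordant": int(is_hl_concordant(cat))})
    if not rows:
        return pd.DataFrame(columns=["case_group", "subject", "numerator", "denominator", "rate"])
    df = pd.DataFrame(rows)
    out = []
    for (g, subj), sub in df.groupby(["case_group", "subject"]):
        res = IndicatorResult(int(sub["concordant"].sum()), len(sub))
        out.append({"case_group": g, "subject": subj, "numerator": res.numerator,
                    "denominator": res.denominator, "rate": res.rate})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Matching and stability
# ---------------------------------------------------------------------------

_MATCH_COVARIATES = [*COVARIATE_FIELDS, "stage"]


def _post_matching_discordant(
    bundle: StudyBundle, classified: pd.DataFrame, opts: AssessmentOptions
) -> tuple[list, pd.DataFrame]:
    """For each physician stratum, match its CDSS-discordant records 1:1
    against the pooled remainder on the seven covariates; return the matched
    records and a per-stratum match summary."""
    disc = classified[classified["ai_discordant_initial"] == 1].reset_index(drop=True)
    records_by_key = {
        (r.case_id, r.stage.value, r.reviewer.code): r for r in bundle.records
    }
    matched_records = []
    summary = []
    for stratum in sorted(disc["stratum"].unique()):
        side_a = disc[disc["stratum"] == stratum].reset_index(drop=True)
        side_b = disc[disc["stratum"] != stratum].reset_index(drop=True)
        result = propensity_match(
            side_a[_MATCH_COVARIATES], side_b[_MATCH_COVARIATES],
            caliper=opts.caliper, seed=opts.seed,
        )
        for ia, _ in result.pairs:
            row = side_a.iloc[ia]
            matched_records.append(records_by_key[(row["case_id"], row["stage"], row["reviewer_code"])])
        summary.append({"stratum": stratum, "n_discordant": len(side_a),
                        "n_matched_pairs": result.n_pairs})
    return matched_records, pd.DataFrame(summary)


def _stability_tables(
    bundle: StudyBundle, records: list
) -> dict[str, dict[Hashable, IndicatorResult]]:
    out: dict[str, dict[Hashable, IndicatorResult]] = {}
    if not records:
        return out
    out["overall"] = stability_rate(records, bundle.ai_reference)
    for name, key in (
        ("grade", lambda r: _GRADE_LABEL[r.reviewer.grade]),
        ("seniority", lambda r: _SENIORITY_LABEL[r.reviewer.seniority]),
        ("stratum", lambda r: r.reviewer.stratum),
        ("physician", lambda r: r.reviewer.code),
    ):
        table = stability_rate(records, bundle.ai_reference, grouping=key)
        table.pop(OVERALL)
        out[name] = table
    return out


# ---------------------------------------------------------------------------
# Discordance reasons
# ---------------------------------------------------------------------------

_REASON_COLS = ["strategy_difference", "missing_or_misread_info",
                "incorrect_concordance_assessment"]


def reason_summary(
    classified: pd.DataFrame, grouping: str = "seniority"
) -> tuple[ContingencyTable, pd.DataFrame]:
    """Counts and row shares of discordance reasons per subgroup.

    Discordant records lacking a reason label are tallied in an extra
    ``unlabeled`` column with a warning, so the table always cross-foots.
    """
    col = GROUPINGS.get(grouping, grouping)
    disc = classified[classified["ai_discordant_initial"] == 1]
    if disc.empty:
        raise StudyValidationError("no discordant records to summarise")
    labels = list(_REASON_COLS)
    unlabeled = (disc["discordance_reason"] == "").sum()
    if unlabeled:
        logger.warning("%d discordant records lack a reason label", unlabeled)
        labels.append("unlabeled")
    groups = sorted(disc[col].unique(), key=str)
    counts = np.zeros((len(groups), len(labels)), dtype=int)
    for i, g in enumerate(groups):
        sub = disc[disc[col] == g]
        for j, reason in enumerate(labels):
            if reason == "unlabeled":
                counts[i, j] = (sub["discordance_reason"] == "").sum()
            else:
                counts[i, j] = (sub["discordance_reason"] == reason).sum()
    table = ContingencyTable(counts, tuple(str(g) for g in groups), tuple(labels))
    shares = table.to_frame()
    shares = shares.div(shares.sum(axis=1), axis=0) * 100.0
    return table, shares


# ---------------------------------------------------------------------------
# The full run
# ---------------------------------------------------------------------------

def _exact_rates(table: Mapping[Hashable, IndicatorResult]) -> dict[str, float]:
    return {str(k): v.exact_rate for k, v in table.items() if k != OVERALL}


def run_assessment(bundle: StudyBundle, options: AssessmentOptions | None = None) -> AssessmentReport:
    """Compute the complete assessment report for a validated bundle."""
    opts = options or AssessmentOptions()
    bundle.validate()
    logger.info("assessing bundle: %d cases, %d decision points, %d records",
                len(bundle.cases), bundle.n_decision_points, len(bundle.records))

    classified = classify_records(bundle, opts.decision_pass)
    concordance = _grouped_rates(classified, "concordant")
    conformity_phys = _grouped_rates(classified, "conforming")
    ai_frame = _ai_conformity_frame(bundle)
    conformity_ai = _ai_grouped_rates(ai_frame)

    hl = _hl_concordance(bundle, opts)

    points = panel_decision_points(bundle, use=opts.consensus_pass)
    group_of = {c.case_id: c.case_group for c in bundle.cases}
    consensus = consensus_rate(points, grouping=lambda p: group_of[p.case_id])

    disc_records = [
        r for r in bundle.records
        if not is_concordant(classify_concordance(r.initial, bundle.ai_reference[(r.case_id, r.stage)]))
    ]
    logger.info("discordance subgroup: %d of %d records", len(disc_records), len(bundle.records))
    stability_pre = _stability_tables(bundle, disc_records)
    stability_post = None
    match_summary = None
    if opts.do_matching and disc_records:
        matched, match_summary = _post_matching_discordant(bundle, classified, opts)
        stability_post = _stability_tables(bundle, matched)
        logger.info("post-matching discordance subgroup: %d records", len(matched))

    stability_for_cal = stability_post if stability_post else stability_pre
    calibration: dict[str, CalibrationTable] = {}
    for indicator, tables in (("concordance", concordance), ("conformity", conformity_phys)):
        for grouping in ("seniority", "grade", "stratum"):
            stab = _exact_rates(stability_for_cal.get(grouping, {}))
            orig = _exact_rates(tables[grouping])
            keys = sorted(set(stab) & set(orig))
            if len(keys) < 2:
                continue
            calibration[f"{indicator}_{grouping}"] = build_calibration_table(
                {k: orig[k] for k in keys}, {k: stab[k] for k in keys},
                policy=opts.calibration_policy, reference=opts.calibration_reference,
            )

    variation: dict[str, VariationSummary] = {}
    gaps: dict[str, float] = {}
    phys_strat = _exact_rates(conformity_phys["stratum"])
    if len(phys_strat) >= 2:
        variation["physician_conformity_stratum"] = pairwise_difference_matrix(
            phys_strat, ddof=opts.sd_ddof)
    ai_groups = _exact_rates(conformity_ai["case_group"])
    if len(ai_groups) >= 2:
        variation["ai_conformity_case_group"] = pairwise_difference_matrix(
            ai_groups, ddof=opts.sd_ddof)
    gaps["conformity_overall_gap"] = (
        conformity_ai["overall"][OVERALL].exact_rate
        - conformity_phys["overall"][OVERALL].exact_rate
    )
    if len(variation) == 2:
        gaps["conformity_sd_gap"] = (
            variation["physician_conformity_stratum"].sd
            - variation["ai_conformity_case_group"].sd
        )
        gaps["conformity_mean_diff_gap"] = (
            variation["physician_conformity_stratum"].mean_abs_diff
            - variation["ai_conformity_case_group"].mean_abs_diff
        )

    reasons: dict[str, tuple[ContingencyTable, pd.DataFrame]] = {}
    tests: dict[str, dict] = {}
    if (classified["ai_discordant_initial"] == 1).any():
        for grouping in ("seniority", "grade", "stratum"):
            table, shares = reason_summary(classified, grouping)
            reasons[grouping] = (table, shares)
            counts = table.counts[:, table.counts.sum(axis=0) > 0]
            if counts.shape[0] >= 2 and counts.shape[1] >= 2:
                try:
                    res: ChiSquareResult = chi_square_test(counts)
                    tests[f"chi_square_reasons_{grouping}"] = dataclasses.asdict(res)
                except StudyValidationError as e:
                    tests[f"chi_square_reasons_{grouping}"] = {"error": str(e)}

    # paired physician-vs-CDSS guideline conformity (McNemar over records)
    ai_conf_by_point = {
        (r.case_id, r.stage): r.conforming
        for r in ai_frame[["case_id", "stage", "conforming"]].itertuples(index=False)
    }
    phys_flags = classified["conforming"].to_numpy()
    ai_flags = np.asarray([
        ai_conf_by_point[(cid, st)]
        for cid, st in zip(classified["case_id"], classified["stage"])
    ])
    b = int(((phys_flags == 0) & (ai_flags == 1)).sum())
    c = int(((phys_flags == 1) & (ai_flags == 0)).sum())
    mc: McNemarResult = mcnemar_test(b, c)
    tests["mcnemar_conformity_physician_vs_ai"] = {
        "b": b, "c": c, "statistic": mc.statistic, "p_value": mc.p_value, "method": mc.method,
    }

    return AssessmentReport(
        classified=classified,
        concordance=concordance,
        conformity_physician=conformity_phys,
        conformity_ai=conformity_ai,
        hl_concordance=hl,
        consensus=consensus,
        stability_pre=stability_pre,
        stability_post=stability_post,
        match_summary=match_summary,
        calibration=calibration,
        variation=variation,
        variation_gaps=gaps,
        reasons=reasons,
        tests=tests,
    )


# ---------------------------------------------------------------------------
# Report directory
# ---------------------------------------------------------------------------

def write_report(report: AssessmentReport, out_dir: str | Path, manifest: dict | None = None) -> None:
    """Write the report as CSV tables plus tests.json and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.classified.to_csv(out / "classified_records.csv", index=False)
    report.rates_frame(report.concordance).to_csv(out / "concordance.csv", index=False)
    report.rates_frame(report.conformity_physician).to_csv(
        out / "conformity_physician.csv", index=False)
    report.rates_frame(report.conformity_ai).to_csv(out / "conformity_ai.csv", index=False)
    report.hl_concordance.to_csv(out / "hl_concordance.csv", index=False)
    report.rates_frame({"case_group": report.consensus}).to_csv(
        out / "consensus.csv", index=False)
    report.rates_frame(report.stability_pre).to_csv(out / "stability_pre.csv", index=False)
    if report.stability_post is not None:
        report.rates_frame(report.stability_post).to_csv(out / "stability_post.csv", index=False)
    if report.match_summary is not None:
        report.match_summary.to_csv(out / "match_summary.csv", index=False)
    for name, table in report.calibration.items():
        table.to_frame().to_csv(out / f"calibration_{name}.csv", index=False)
    for name, vs in report.variation.items():
        vs.pairwise_matrix.round(3).to_csv(out / f"heatmap_{name}.csv")
    for name, (table, shares) in report.reasons.items():
        table.to_frame().to_csv(out / f"reasons_{name}.csv")
        shares.round(1).to_csv(out / f"reasons_{name}_shares.csv")
    payload = dict(report.tests)
    payload["variation_gaps"] = {k: round(v, 3) for k, v in report.variation_gaps.items()}
    payload["variation_summary"] = {
        name: {"sd": round(vs.sd, 3), "mean_abs_diff": round(vs.mean_abs_diff, 3)}
        for name, vs in report.variation.items()
    }
    (out / "tests.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest or {}, indent=1, sort_keys=True))
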