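"""End-to-end analysis: cohort tables in, matched-cohort report out.

Stage order mirrors the study: eligibility filtering, dichotomization by
peak CRP within 48 h, 1:4 gestational-age matching, NIRS session
summarization for the matched subjects, POP-Score computation, and
diagnostic evaluation at the pre-specified cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import MissingOutcomeError
from .evaluate import (
    DEFAULT_CUTOFF,
    DiagnosticReport,
    build_report,
    compare_groups,
    confusion_and_rates,
    spearman_rho,
    sweep_cutoffs,
)
from .matching import (
    CRP_CASE_THRESHOLD,
    MATCH_RATIO,
    MATCH_TOLERANCE_WEEKS,
    MatchedCohort,
    apply_eligibility,
    assign_group,
    match_cases_controls,
)
from .model import CrpSample, NeonateRecord, NirsSession, highest_crp
from .nirs import DEFAULT_MAX_SD, DEFAULT_WINDOW_S, OxygenationSummary, summarize_session
from .score import PopScoreResult, score_cohort

#: Continuous variables of the published comparison table, in its order.
TABLE_CONTINUOUS = [
    "apgar1", "apgar5", "apgar10", "ua_ph", "postnatal_age_min", "fat_cm",
    "forearm_cm", "temp_c", "spo2_mean", "hr_mean", "sabp_mean",
    "leukocytes_per_ul", "it_ratio", "ptoi_mean", "pftoe",
    "ga_weeks", "bw_g", "crp_peak", "pop_score",
]
TABLE_CATEGORICAL = ["sex"]


@dataclass
class PipelineResult:
    """All stage outputs of one analysis run."""

    matched: MatchedCohort
    crp_peaks: dict[str, float]
    ungroupable: list[tuple[str, str]]
    summaries: list[OxygenationSummary]
    scores: list[PopScoreResult]
    unjoinable: list[tuple[str, str]]
    diagnostics: DiagnosticReport
    report: dict = field(default_factory=dict)


def group_cohort(
    records: list[NeonateRecord],
    crp_samples: list[CrpSample],
    crp_threshold: float = CRP_CASE_THRESHOLD,
    window_h: float = 48.0,
) -> tuple[dict[str, float], dict[str, str], list[tuple[str, str]]]:
    """Peak CRP and case/control label per neonate.

    Returns ``(peaks, labels, ungroupable)``; neonates with no CRP
    sample inside the window are listed as ungroupable, not dropped
    silently.
    """
    by_id: dict[str, list[CrpSample]] = {}
    for s in crp_samples:
        by_id.setdefault(s.neonate_id, []).append(s)
    peaks: dict[str, float] = {}
    labels: dict[str, str] = {}
    ungroupable: list[tuple[str, str]] = []
    for r in records:
        try:
            peak = highest_crp(by_id.get(r.id, []), window=window_h)
        except MissingOutcomeError as e:
            ungroupable.append((r.id, str(e)))
            continue
        peaks[r.id] = peak
        labels[r.id] = assign_group(peak, threshold=crp_threshold)
    return peaks, labels, ungroupable


def analysis_frame(
    records: list[NeonateRecord],
    summaries: list[OxygenationSummary],
    scores: list[PopScoreResult],
    labels: dict[str, str],
    peaks: dict[str, float],
) -> pd.DataFrame:
    """One row per scored neonate with everything the comparison table needs."""
    rec = {r.id: r for r in records}
    summ = {s.neonate_id: s for s in summaries}
    rows = []
    for result in scores:
        r = rec[result.neonate_id]
        s = summ[result.neonate_id]
        rows.append({
            "id": r.id,
            "group": labels[r.id],
            "ga_weeks": r.gestational_age,
            "bw_g": r.birth_weight,
            "sex": r.sex,
            "delivery_mode": r.delivery_mode,
            "apgar1": r.apgar_1, "apgar5": r.apgar_5, "apgar10": r.apgar_10,
            "ua_ph": r.ua_ph,
            "postnatal_age_min": r.postnatal_age_at_measurement,
            "fat_cm": r.fat_thickness,
            "forearm_cm": r.forearm_diameter,
            "temp_c": r.body_temperature,
            "leukocytes_per_ul": r.leukocyte_count,
            "it_ratio": r.it_ratio,
            "ptoi_mean": s.ptoi_mean,
            "spo2_mean": s.spo2_mean,
            "hr_mean": s.hr_mean,
            "sabp_mean": s.sabp_mean,
            "pftoe": s.pftoe,
            "crp_peak": peaks[r.id],
            "pop_score": result.score,
        })
    return pd.DataFrame(rows)


def run_pipeline(
    records: list[NeonateRecord],
    crp_samples: list[CrpSample],
    sessions: list[NirsSession],
    *,
    crp_threshold: float = CRP_CASE_THRESHOLD,
    ratio: int = MATCH_RATIO,
    tolerance: float = MATCH_TOLERANCE_WEEKS,
    cutoff: float = DEFAULT_CUTOFF,
    window: float = DEFAULT_WINDOW_S,
    max_sd: float = DEFAULT_MAX_SD,
    with_group_comparison: bool = True,
    with_sweep: bool = True,
) -> PipelineResult:
    """Run the full analysis and assemble the report."""
    eligible, elig_log = apply_eligibility(records)
    peaks, labels, ungroupable = group_cohort(records, crp_samples, crp_threshold)
    cases = [r for r in eligible if labels.get(r.id) == "case"]
    controls = [r for r in eligible if labels.get(r.id) == "control"]
    matched = match_cases_controls(cases, controls, ratio=ratio,
                                   tolerance=tolerance, eligibility_log=elig_log)

    matched_ids = set(matched.case_ids) | set(matched.control_ids)
    session_by_id = {s.neonate_id: s for s in sessions}
    rec_by_id = {r.id: r for r in records}
    summaries = [
        summarize_session(session_by_id[nid], rec_by_id.get(nid),
                          window=window, max_sd=max_sd)
        for nid in sorted(matched_ids)
    ]
    scores, unjoinable = score_cohort(summaries, records)

    pairs = [(r.score, labels[r.neonate_id]) for r in scores]
    diagnostics = confusion_and_rates(pairs, cutoff=cutoff)
    frame = analysis_frame(records, summaries, scores, labels, peaks)
    rho_p = spearman_rho(frame["pop_score"], frame["crp_peak"])

    comparison = {}
    if with_group_comparison:
        comparison = compare_groups(frame, TABLE_CONTINUOUS, TABLE_CATEGORICAL)
    case_scores = frame.loc[frame["group"] == "case", "pop_score"]
    ctrl_scores = frame.loc[frame["group"] == "control", "pop_score"]
    score_summary = {
        "case": (float(case_scores.median()), float(case_scores.min()),
                 float(case_scores.max())),
        "control": (float(ctrl_scores.median()), float(ctrl_scores.min()),
                    float(ctrl_scores.max())),
    }
    flow = {
        "n_input": len(records),
        "n_ineligible": len(elig_log),
        "n_ungroupable": len(ungroupable),
        "n_cases_eligible": len(cases),
        "n_controls_eligible": len(controls),
        "n_cases_matched": len(matched.case_ids),
        "n_controls_matched": len(matched.control_ids),
        "n_cases_dropped": len(matched.dropped_cases),
        "n_controls_unused": len(matched.unused_controls),
        "n_final": matched.n_subjects,
    }
    report = build_report(
        flow=flow,
        group_comparison=comparison,
        score_summary=score_summary,
        diagnostics=diagnostics,
        correlation=rho_p,
        cutoff_sweep=sweep_cutoffs(pairs) if with_sweep else None,
    )
    return PipelineResult(
        matched=matched,
        crp_peaks=peaks,
        ungroupable=ungroupable,
        summaries=summaries,
        scores=scores,
        unjoinable=unjoinable,
        diagnostics=diagnostics,
        report=report,
    )
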