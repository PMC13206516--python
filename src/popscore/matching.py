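"""Eligibility filtering, CRP dichotomization and 1:4 gestational-age matching.

The study design keeps term and late-preterm neonates that are
reasonably uniform at birth — birth weight ≥ 2000 g, umbilical-artery
pH strictly above 7.20, NIRS measurement within six hours of birth —
then dichotomizes by the highest CRP within 48 h (cases: ≥ 20 mg/L) and
matches each case to four controls of similar gestational age
(|ΔGA| ≤ 2.0 weeks).

The matcher is greedy without replacement and fully deterministic:
cases are processed most-constrained-first (fewest in-tolerance
candidates, ties by id) and each case takes the ``ratio`` remaining
candidates with smallest |ΔGA| (ties by id).  A case that cannot be
given ``ratio`` in-tolerance controls is dropped with a reason, and
leftover controls are reported as unused rather than silently
discarded.  Greedy matching can in principle under-match relative to a
globally optimal assignment; :func:`max_matchable_cases` provides a
max-flow upper bound for auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ConfigError, MissingOutcomeError
from .model import NeonateRecord

#: Eligibility thresholds.
MIN_BIRTH_WEIGHT_G = 2000
UA_PH_THRESHOLD = 7.20
MAX_AGE_AT_MEASUREMENT_MIN = 360.0

#: Grouping and matching defaults.
CRP_CASE_THRESHOLD = 20.0   # mg/L
MATCH_RATIO = 4
MATCH_TOLERANCE_WEEKS = 2.0


@dataclass(frozen=True)
class MatchedCohort:
    """Outcome of 1:ratio gestational-age matching, with full accounting."""

    pairs: list[tuple[str, list[str]]]        # (case_id, control_ids)
    ratio: int
    tolerance: float
    dropped_cases: list[tuple[str, str]] = field(default_factory=list)
    unused_controls: list[str] = field(default_factory=list)
    eligibility_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [cid for _, ctrls in self.pairs for cid in ctrls]

    @property
    def n_subjects(self) -> int:
        return len(self.case_ids) + len(self.control_ids)


def apply_eligibility(
    records: list[NeonateRecord],
    max_age_min: float = MAX_AGE_AT_MEASUREMENT_MIN,
    min_birth_weight: int = MIN_BIRTH_WEIGHT_G,
    ua_ph_threshold: float = UA_PH_THRESHOLD,
) -> tuple[list[NeonateRecord], list[tuple[str, str]]]:
    """Keep records meeting all three inclusion criteria.

    Inclusion requires birth weight ≥ ``min_birth_weight`` g, umbilical
    pH strictly greater than ``ua_ph_threshold`` (a pH of exactly 7.20
    is excluded), and measurement age ≤ ``max_age_min`` minutes.  Each
    exclusion is logged with the first failing criterion, in that order.
    This is a filter, not a validator: it never raises.
    """
    eligible: list[NeonateRecord] = []
    log: list[tuple[str, str]] = []
    for r in records:
        if r.birth_weight < min_birth_weight:
            log.append((r.id, f"birth weight {r.birth_weight} g < {min_birth_weight} g"))
        elif not r.ua_ph > ua_ph_threshold:
            log.append((r.id, f"umbilical pH {r.ua_ph} not > {ua_ph_threshold}"))
        elif r.postnatal_age_at_measurement > max_age_min:
            log.append((
                r.id,
                f"measured at {r.postnatal_age_at_measurement:.0f} min > {max_age_min:.0f} min",
            ))
        else:
            eligible.append(r)
    return eligible, log


def assign_group(crp_peak: float, threshold: float = CRP_CASE_THRESHOLD) -> str:
    """Dichotomize by peak CRP: ``"case"`` iff ``crp_peak >= threshold``."""
    if crp_peak is None or (isinstance(crp_peak, float) and math.isnan(crp_peak)):
        raise MissingOutcomeError("peak CRP unavailable; neonate cannot be grouped")
    return "case" if crp_peak >= threshold else "control"


def match_cases_controls(
    cases: list[NeonateRecord],
    controls: list[NeonateRecord],
    ratio: int = MATCH_RATIO,
    tolerance: float = MATCH_TOLERANCE_WEEKS,
    eligibility_log: list[tuple[str, str]] | None = None,
) -> MatchedCohort:
    """Greedy 1:``ratio`` matching on gestational age within ``tolerance`` weeks.

    Deterministic procedure: compute each case's in-tolerance candidate
    count over the full control pool; process cases in ascending count
    (ties by id); give each case the ``ratio`` remaining candidates with
    smallest |ΔGA| (ties by id), consuming them.  A case with fewer than
    ``ratio`` remaining in-tolerance candidates is dropped.
    """
    if ratio < 1:
        raise ConfigError(f"ratio must be >= 1, got {ratio}")
    if tolerance < 0:
        raise ConfigError(f"tolerance must be >= 0, got {tolerance}")
    case_ids = {c.id for c in cases}
    if case_ids & {c.id for c in controls}:
        raise ConfigError("case and control groups must be disjoint")

    def candidates(case: NeonateRecord, pool: dict[str, NeonateRecord]):
        return [
            ctrl for ctrl in pool.values()
            if abs(case.gestational_age - ctrl.gestational_age) <= tolerance
        ]

    full_pool = {c.id: c for c in controls}
    order = sorted(cases, key=lambda c: (len(candidates(c, full_pool)), c.id))

    remaining = dict(full_pool)
    pairs: list[tuple[str, list[str]]] = []
    dropped: list[tuple[str, str]] = []
    for case in order:
        cands = candidates(case, remaining)
        if len(cands) < ratio:
            dropped.append((
                case.id,
                f"only {len(cands)} in-tolerance control(s) remaining, need {ratio}",
            ))
            continue
        cands.sort(key=lambda ctrl: (abs(case.gestational_age - ctrl.gestational_age),
                                     ctrl.id))
        chosen = cands[:ratio]
        for ctrl in chosen:
            del remaining[ctrl.id]
        pairs.append((case.id, [ctrl.id for ctrl in chosen]))
    pairs.sort(key=lambda p: p[0])
    return MatchedCohort(
        pairs=pairs,
        ratio=ratio,
        tolerance=tolerance,
        dropped_cases=dropped,
        unused_controls=sorted(remaining),
        eligibility_log=list(eligibility_log or []),
    )


def max_matchable_cases(
    cases: list[NeonateRecord],
    controls: list[NeonateRecord],
    ratio: int = MATCH_RATIO,
    tolerance: float = MATCH_TOLERANCE_WEEKS,
) -> int:
    """Maximum number of cases that can all receive ``ratio`` distinct controls.

    Audit oracle for the greedy matcher, exact on small instances.  A
    case subset S is feasible iff the max-flow on
    source →(ratio)→ case →(1)→ in-tolerance control →(1)→ sink,
    restricted to S, equals ``ratio * |S|``; the oracle scans subsets in
    decreasing size (intended for audit instances with at most ~6 cases).
    """
    from itertools import combinations

    def feasible(subset: tuple[NeonateRecord, ...]) -> bool:
        g = nx.DiGraph()
        for case in subset:
            g.add_edge("s", ("case", case.id), capacity=ratio)
            for ctrl in controls:
                if abs(case.gestational_age - ctrl.gestational_age) <= tolerance:
                    g.add_edge(("case", case.id), ("ctrl", ctrl.id), capacity=1)
        for ctrl in controls:
            g.add_edge(("ctrl", ctrl.id), "t", capacity=1)
        if "s" not in g or "t" not in g:
            return len(subset) == 0
        return nx.maximum_flow_value(g, "s", "t") == ratio * len(subset)

    for k in range(len(cases), 0, -1):
        if any(feasible(sub) for sub in combinations(cases, k)):
            return k
    return 0


def cohort_frame(
    matched: MatchedCohort,
    ineligible: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Role table in the ``cohort.csv`` schema with full accounting."""
    rows = []
    for case_id, ctrl_ids in matched.pairs:
        rows.append({"id": case_id, "role": "case", "matched_case_id": "", "reason": ""})
        for cid in ctrl_ids:
            rows.append({"id": cid, "role": "control",
                         "matched_case_id": case_id, "reason": ""})
    for cid, reason in matched.dropped_cases:
        rows.append({"id": cid, "role": "dropped", "matched_case_id": "", "reason": reason})
    for cid in matched.unused_controls:
        rows.append({"id": cid, "role": "unused", "matched_case_id": "", "reason": ""})
    for cid, reason in (ineligible if ineligible is not None else matched.eligibility_log):
        rows.append({"id": cid, "role": "ineligible", "matched_case_id": "", "reason": reason})
    return pd.DataFrame(rows, columns=["id", "role", "matched_case_id", "reason"])
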