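"""The POP-Score: a non-weighted composite of oxygenation and perfusion.

The peripheral(-muscle) oxygenation and perfusion score combines five
non-invasively measured quantities into a single raw ratio::

    POP-Score = (pTOI [%] × fat thickness [cm] × heart rate [bpm])
                ─────────────────────────────────────────────────────
                      (SpO2 [%] × systolic blood pressure [mmHg])

No weighting, transformation, clamping or recalibration is applied: the
score is the plain product/quotient of the components, each entering in
its native unit.  It is strictly increasing in pTOI, fat thickness and
heart rate and strictly decreasing in SpO2 and systolic pressure, and it
scales exactly linearly in each multiplicative component.

Scores are carried at full floating precision; rounding (to 2 decimal
places) happens only when tables are serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError
from .model import NeonateRecord
from .nirs import OxygenationSummary

#: Fat-layer thickness above which a millimetre/centimetre mix-up is suspected.
FAT_UNIT_SUSPICION_CM = 5.0


@dataclass(frozen=True)
class PopScoreResult:
    """POP-Score for one neonate, with its components and inherited flags."""

    neonate_id: str
    score: float
    components: dict = field(default_factory=dict)  # ptoi, fat, hr, spo2, sabp
    flags: tuple[str, ...] = ()


def compute_pop_score(
    ptoi: float,
    fat: float,
    hr: float,
    spo2: float,
    sabp: float,
    neonate_id: str = "",
    flags: tuple[str, ...] = (),
) -> PopScoreResult:
    """Evaluate the POP-Score from its five components.

    All inputs must be strictly positive and in their declared units —
    in particular the subcutaneous fat layer thickness in centimetres
    (neonatal forearm fat is a few millimetres to ~1 cm; a value above
    5 cm triggers a unit-suspicion flag because it almost certainly
    means millimetres were supplied).
    """
    for name, value in (("ptoi", ptoi), ("fat", fat), ("hr", hr),
                        ("spo2", spo2), ("sabp", sabp)):
        if not value > 0:
            raise DomainError(f"POP-Score component {name} must be > 0, got {value}")
    out_flags = list(flags)
    if fat > FAT_UNIT_SUSPICION_CM:
        out_flags.append(
            f"fat thickness {fat} cm is implausibly large (millimetres supplied?)"
        )
    score = (ptoi * fat * hr) / (spo2 * sabp)
    return PopScoreResult(
        neonate_id=neonate_id,
        score=score,
        components={"ptoi": ptoi, "fat": fat, "hr": hr, "spo2": spo2, "sabp": sabp},
        flags=tuple(out_flags),
    )


def score_cohort(
    summaries: list[OxygenationSummary],
    records: list[NeonateRecord],
) -> tuple[list[PopScoreResult], list[tuple[str, str]]]:
    """Score every neonate whose summary joins to a record with fat thickness.

    Returns ``(results, unjoinable)`` where ``unjoinable`` lists
    ``(id, reason)`` for summaries that could not be scored — nothing is
    silently dropped.  Duplicate summaries for one id are an error.
    """
    seen: set[str] = set()
    for s in summaries:
        if s.neonate_id in seen:
            raise DomainError(f"duplicate summary for neonate {s.neonate_id!r}")
        seen.add(s.neonate_id)

    by_id = {r.id: r for r in records}
    results: list[PopScoreResult] = []
    unjoinable: list[tuple[str, str]] = []
    for s in summaries:
        record = by_id.get(s.neonate_id)
        if record is None:
            unjoinable.append((s.neonate_id, "no matching neonate record"))
            continue
        if record.fat_thickness is None:
            unjoinable.append((s.neonate_id, "record lacks fat_thickness"))
            continue
        results.append(
            compute_pop_score(
                ptoi=s.ptoi_mean,
                fat=record.fat_thickness,
                hr=s.hr_mean,
                spo2=s.spo2_mean,
                sabp=s.sabp_mean,
                neonate_id=s.neonate_id,
                flags=s.flags,
            )
        )
    return results, unjoinable


def scores_frame(results: list[PopScoreResult]) -> pd.DataFrame:
    """Results as a DataFrame in the ``scores.csv`` schema (score at 2 dp)."""
    return pd.DataFrame(
        [{
            "id": r.neonate_id,
            "pop_score": round(r.score, 2),
            "ptoi": r.components["ptoi"],
            "fat_cm": r.components["fat"],
            "hr": r.components["hr"],
            "spo2": r.components["spo2"],
            "sabp": r.components["sabp"],
            "flags": "; ".join(r.flags),
        } for r in results],
        columns=["id", "pop_score", "ptoi", "fat_cm", "hr", "spo2", "sabp", "flags"],
    )
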