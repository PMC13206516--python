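"""Readers and writers for the delimited-text study tables.

Four comma-separated, UTF-8, header-row tables describe a cohort:

``neonates.csv``
    id, ga_weeks, bw_g, sex, delivery_mode, apgar1, apgar5, apgar10,
    ua_ph, postnatal_age_min, fat_cm, forearm_cm, temp_c,
    leukocytes_per_ul, it_ratio, bg_ph, bg_pco2_mmhg, bg_hco3_mmol_l,
    bg_be_mmol_l, bg_lactate_mmol_l
``crp.csv``
    id, time_h, crp_mg_l
``signals.csv`` (long format)
    id, reapplication_idx (0 for the continuous SpO2/HR streams,
    1..5 for pTOI sensor placements), time_s, channel, value
``bp.csv``
    id, phase (before|after), sabp_mmhg, dabp_mmhg, mabp_mmhg

Missing optional values are empty cells, never sentinel numbers.
Every ``crp``/``signals``/``bp`` row must reference an id present in
``neonates.csv``; a dangling id is a referential error, a missing
required column a schema error.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReferentialError, SchemaError
from .model import (
    BloodGas,
    BloodPressurePanel,
    CrpSample,
    NeonateRecord,
    NirsSession,
    SignalTrace,
)

NEONATE_COLUMNS = [
    "id", "ga_weeks", "bw_g", "sex", "delivery_mode",
    "apgar1", "apgar5", "apgar10", "ua_ph", "postnatal_age_min",
    "fat_cm", "forearm_cm", "temp_c", "leukocytes_per_ul", "it_ratio",
    "bg_ph", "bg_pco2_mmhg", "bg_hco3_mmol_l", "bg_be_mmol_l",
    "bg_lactate_mmol_l",
]
CRP_COLUMNS = ["id", "time_h", "crp_mg_l"]
SIGNAL_COLUMNS = ["id", "reapplication_idx", "time_s", "channel", "value"]
BP_COLUMNS = ["id", "phase", "sabp_mmhg", "dabp_mmhg", "mabp_mmhg"]


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _opt(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


def _record_from_row(row: pd.Series) -> NeonateRecord:
    return NeonateRecord(
        id=str(row["id"]),
        gestational_age=float(row["ga_weeks"]),
        birth_weight=int(row["bw_g"]),
        sex=str(row["sex"]),
        delivery_mode=str(row["delivery_mode"]),
        apgar_1=int(row["apgar1"]),
        apgar_5=int(row["apgar5"]),
        apgar_10=int(row["apgar10"]),
        ua_ph=float(row["ua_ph"]),
        postnatal_age_at_measurement=float(row["postnatal_age_min"]),
        fat_thickness=_opt(row["fat_cm"]),
        forearm_diameter=_opt(row["forearm_cm"]),
        body_temperature=_opt(row["temp_c"]),
        leukocyte_count=_opt(row["leukocytes_per_ul"]),
        it_ratio=_opt(row["it_ratio"]),
        blood_gas=BloodGas(
            ph=_opt(row["bg_ph"]),
            pco2=_opt(row["bg_pco2_mmhg"]),
            hco3=_opt(row["bg_hco3_mmol_l"]),
            base_excess=_opt(row["bg_be_mmol_l"]),
            lactate=_opt(row["bg_lactate_mmol_l"]),
        ),
    )


def _sessions_from_frames(
    signals: pd.DataFrame, bp: pd.DataFrame
) -> list[NirsSession]:
    sessions = []
    bp_by_id = dict(tuple(bp.groupby("id", sort=False))) if len(bp) else {}
    for nid, g in signals.groupby("id", sort=False):
        reapps = []
        ptoi = g[(g["channel"] == "pTOI") & (g["reapplication_idx"] > 0)]
        for _, seg in ptoi.groupby("reapplication_idx", sort=True):
            seg = seg.sort_values("time_s")
            reapps.append(
                SignalTrace("pTOI", seg["time_s"].to_numpy(), seg["value"].to_numpy())
            )
        streams = {}
        for channel in ("SpO2", "HR"):
            s = g[g["channel"] == channel].sort_values("time_s")
            if s.empty:
                raise SchemaError(f"signals: neonate {nid!r} has no {channel} stream")
            streams[channel] = SignalTrace(
                channel, s["time_s"].to_numpy(), s["value"].to_numpy()
            )
        panels = []
        for _, row in bp_by_id.get(nid, pd.DataFrame(columns=BP_COLUMNS)).iterrows():
            panels.append(
                BloodPressurePanel(
                    phase=str(row["phase"]),
                    sabp=float(row["sabp_mmhg"]),
                    dabp=float(row["dabp_mmhg"]),
                    mabp=float(row["mabp_mmhg"]),
                )
            )
        sessions.append(
            NirsSession(
                neonate_id=str(nid),
                reapplications=tuple(reapps),
                spo2_stream=streams["SpO2"],
                hr_stream=streams["HR"],
                bp_panels=tuple(panels),
            )
        )
    return sessions


def read_cohort(
    directory: str | Path,
) -> tuple[list[NeonateRecord], list[CrpSample], list[NirsSession]]:
    """Read a cohort from ``neonates.csv``/``crp.csv``/``signals.csv``/``bp.csv``.

    Every row is either parsed or reported: a missing required column
    raises :class:`SchemaError` naming the column, and a ``crp``,
    ``signals`` or ``bp`` row whose id is absent from the neonate table
    raises :class:`ReferentialError`.
    """
    directory = Path(directory)
    neonates = pd.read_csv(directory / "neonates.csv", dtype={"id": str})
    crp = pd.read_csv(directory / "crp.csv", dtype={"id": str})
    signals = pd.read_csv(directory / "signals.csv", dtype={"id": str})
    bp = pd.read_csv(directory / "bp.csv", dtype={"id": str})

    _require_columns(neonates, NEONATE_COLUMNS, "neonates.csv")
    _require_columns(crp, CRP_COLUMNS, "crp.csv")
    _require_columns(signals, SIGNAL_COLUMNS, "signals.csv")
    _require_columns(bp, BP_COLUMNS, "bp.csv")

    known = set(neonates["id"].astype(str))
    for table_name, df in (("crp.csv", crp), ("signals.csv", signals), ("bp.csv", bp)):
        if len(df):
            dangling = sorted(set(df["id"].astype(str)) - known)
            if dangling:
                raise ReferentialError(
                    f"{table_name}: id(s) {dangling} not present in neonates.csv"
                )

    records = [_record_from_row(row) for _, row in neonates.iterrows()]
    crp_samples = [
        CrpSample(str(r["id"]), float(r["time_h"]), float(r["crp_mg_l"]))
        for _, r in crp.iterrows()
    ]
    sessions = _sessions_from_frames(signals, bp)
    return records, crp_samples, sessions


def records_frame(records: list[NeonateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "ga_weeks": r.gestational_age,
            "bw_g": r.birth_weight,
            "sex": r.sex,
            "delivery_mode": r.delivery_mode,
            "apgar1": r.apgar_1,
            "apgar5": r.apgar_5,
            "apgar10": r.apgar_10,
            "ua_ph": r.ua_ph,
            "postnatal_age_min": r.postnatal_age_at_measurement,
            "fat_cm": r.fat_thickness,
            "forearm_cm": r.forearm_diameter,
            "temp_c": r.body_temperature,
            "leukocytes_per_ul": r.leukocyte_count,
            "it_ratio": r.it_ratio,
            "bg_ph": r.blood_gas.ph,
            "bg_pco2_mmhg": r.blood_gas.pco2,
            "bg_hco3_mmol_l": r.blood_gas.hco3,
            "bg_be_mmol_l": r.blood_gas.base_excess,
            "bg_lactate_mmol_l": r.blood_gas.lactate,
        })
    return pd.DataFrame(rows, columns=NEONATE_COLUMNS)


def signals_frame(sessions: list[NirsSession]) -> pd.DataFrame:
    ids, idxs, times, channels, values = [], [], [], [], []

    def _push(nid: str, idx: int, trace: SignalTrace) -> None:
        n = len(trace.times)
        ids.extend([nid] * n)
        idxs.extend([idx] * n)
        times.append(trace.times)
        channels.extend([trace.channel] * n)
        values.append(trace.values)

    for s in sessions:
        for k, trace in enumerate(s.reapplications, start=1):
            _push(s.neonate_id, k, trace)
        _push(s.neonate_id, 0, s.spo2_stream)
        _push(s.neonate_id, 0, s.hr_stream)
    return pd.DataFrame({
        "id": ids,
        "reapplication_idx": idxs,
        "time_s": np.concatenate(times) if times else np.array([]),
        "channel": channels,
        "value": np.concatenate(values) if values else np.array([]),
    })


def write_cohort(
    records: list[NeonateRecord],
    crp_samples: list[CrpSample],
    sessions: list[NirsSession],
    directory: str | Path,
) -> None:
    """Write a cohort as the four study CSVs (full numeric precision)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records_frame(records).to_csv(directory / "neonates.csv", index=False)
    pd.DataFrame(
        [{"id": s.neonate_id, "time_h": s.time_after_birth, "crp_mg_l": s.crp}
         for s in crp_samples],
        columns=CRP_COLUMNS,
    ).to_csv(directory / "crp.csv", index=False)
    signals_frame(sessions).to_csv(directory / "signals.csv", index=False)
    pd.DataFrame(
        [{"id": s.neonate_id, "phase": p.phase, "sabp_mmhg": p.sabp,
          "dabp_mmhg": p.dabp, "mabp_mmhg": p.mabp}
         for s in sessions for p in s.bp_panels],
        columns=BP_COLUMNS,
    ).to_csv(directory / "bp.csv", index=False)
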