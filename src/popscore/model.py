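"""Domain model for a neonatal peripheral-oxygenation monitoring study.

One :class:`NeonateRecord` holds the demographics, anthropometrics and
laboratory values charted for a single neonate.  Raw monitoring data for
the single NIRS session performed within the first hours after birth are
held in a :class:`NirsSession`: up to five short peripheral-muscle tissue
oxygenation index (pTOI) traces from repeated sensor applications,
continuous pulse-oximetry (SpO2) and heart-rate streams, and cuff blood
pressures taken immediately before and after the session.

Timed C-reactive protein values are :class:`CrpSample` rows; the grouping
outcome of the study design is the highest CRP within a fixed window after
birth (:func:`highest_crp`).

All times are stored relative to birth — hours for laboratory samples,
minutes for the measurement age, seconds from session start for signal
traces — so no calendar arithmetic is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MissingOutcomeError

SEX_VALUES = ("female", "male")
DELIVERY_MODES = ("primary_cesarean", "secondary_cesarean", "vaginal")
SIGNAL_CHANNELS = ("pTOI", "SpO2", "HR")
BP_PHASES = ("before", "after")

#: Grouping window for infection labs: highest value within this many
#: hours after birth defines the outcome.
CRP_WINDOW_HOURS = 48.0


@dataclass(frozen=True)
class BloodGas:
    """Umbilical-artery blood-gas panel (first postnatal sample)."""

    ph: float | None = None
    pco2: float | None = None          # mmHg
    hco3: float | None = None          # mmol/L
    base_excess: float | None = None   # mmol/L
    lactate: float | None = None       # mmol/L


@dataclass(frozen=True)
class NeonateRecord:
    """Demographics, anthropometrics and infection labs for one neonate.

    ``fat_thickness`` is the ultrasound-measured subcutaneous fat layer of
    the right forearm in centimetres — a direct multiplier in the
    POP-Score, so its unit matters (a value above 5 cm almost certainly
    means millimetres were entered).
    """

    id: str
    gestational_age: float                     # completed weeks, decimal
    birth_weight: int                          # grams
    sex: str                                   # "female" | "male"
    delivery_mode: str
    apgar_1: int
    apgar_5: int
    apgar_10: int
    ua_ph: float                               # umbilical artery pH
    postnatal_age_at_measurement: float        # minutes after birth
    fat_thickness: float | None = None         # cm
    forearm_diameter: float | None = None      # cm
    body_temperature: float | None = None      # °C
    leukocyte_count: float | None = None       # per µL
    it_ratio: float | None = None              # immature/total neutrophils
    blood_gas: BloodGas = field(default_factory=BloodGas)


@dataclass(frozen=True)
class CrpSample:
    """One timed C-reactive protein measurement."""

    neonate_id: str
    time_after_birth: float  # hours
    crp: float               # mg/L


@dataclass(frozen=True)
class BloodPressurePanel:
    """Cuff blood pressure panel taken before or after the NIRS session."""

    phase: str   # "before" | "after"
    sabp: float  # systolic, mmHg
    dabp: float  # diastolic, mmHg
    mabp: float  # mean arterial, mmHg


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly-ordered monitoring signal segment.

    ``times`` are seconds from session start, strictly increasing;
    ``values`` are in the channel's native units (% for pTOI and SpO2,
    bpm for HR).
    """

    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) else 0.0


@dataclass(frozen=True)
class NirsSession:
    """Raw monitoring data for one peripheral-muscle NIRS session.

    ``reapplications`` are the pTOI traces from the repeated sensor
    placements (protocol: five placements of ~30 s separated by 10-s
    rests).  SpO2 and HR run continuously across the whole session; blood
    pressure is a before/after panel pair.
    """

    neonate_id: str
    reapplications: tuple[SignalTrace, ...]
    spo2_stream: SignalTrace
    hr_stream: SignalTrace
    bp_panels: tuple[BloodPressurePanel, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.reapplications) <= 5:
            raise ValueError("a session has between 1 and 5 sensor reapplications")

    def bp_panel(self, phase: str) -> BloodPressurePanel | None:
        for p in self.bp_panels:
            if p.phase == phase:
                return p
        return None


def validate_record(r: NeonateRecord) -> list[str]:
    """Check a record against its physiological invariants.

    Returns a list of human-readable violations naming the field and the
    bound; the empty list means the record is valid.  Validation never
    raises — absent optional fields are simply not checked.
    """
    v: list[str] = []

    def _num(x) -> bool:
        return x is not None and not (isinstance(x, float) and math.isnan(x))

    if not (22.0 <= r.gestational_age <= 44.0):
        v.append(f"gestational_age {r.gestational_age} outside [22, 44] weeks")
    if not r.birth_weight > 0:
        v.append(f"birth_weight {r.birth_weight} must be > 0 g")
    for name in ("apgar_1", "apgar_5", "apgar_10"):
        a = getattr(r, name)
        if not 0 <= a <= 10:
            v.append(f"{name} {a} outside [0, 10]")
    if r.sex not in SEX_VALUES:
        v.append(f"sex {r.sex!r} not one of {SEX_VALUES}")
    if r.delivery_mode not in DELIVERY_MODES:
        v.append(f"delivery_mode {r.delivery_mode!r} not one of {DELIVERY_MODES}")
    if _num(r.fat_thickness) and not r.fat_thickness > 0:
        v.append(f"fat_thickness {r.fat_thickness} must be > 0 cm")
    if _num(r.it_ratio) and not 0.0 <= r.it_ratio <= 1.0:
        v.append(f"it_ratio {r.it_ratio} outside [0, 1]")
    if r.postnatal_age_at_measurement < 0:
        v.append(
            f"postnatal_age_at_measurement {r.postnatal_age_at_measurement} must be >= 0 min"
        )
    return v


def highest_crp(samples: list[CrpSample], window: float = CRP_WINDOW_HOURS) -> float:
    """Highest CRP (mg/L) among samples taken within ``window`` hours of birth.

    The window is closed: a sample at exactly ``window`` hours counts.
    Samples beyond the window are ignored entirely.

    Raises :class:`MissingOutcomeError` when no sample falls inside the
    window — the neonate then has no grouping outcome.
    """
    inside = [s.crp for s in samples if 0.0 <= s.time_after_birth <= window]
    if not inside:
        raise MissingOutcomeError(
            f"no CRP sample within {window} h after birth "
            f"({len(samples)} sample(s) supplied)"
        )
    return max(inside)
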