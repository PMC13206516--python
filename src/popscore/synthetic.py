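"""Synthetic neonatal cohorts with the study's two-group structure.

The generator emulates a matched case-control dataset of term and
late-preterm neonates monitored within six hours of birth: cases are
neonates whose C-reactive protein peaks at or above 20 mg/L within 48 h,
controls stay below.  Each group's per-variable distribution is pinned
to a published median/minimum/maximum triplet: draws come from a Beta
distribution rescaled to [min, max] whose shape is solved so the
distribution median equals the printed median (a triangular family with
apex at the median is available as an explicit alternative).  Support is
bounded, so every draw respects the printed extremes by construction.

Five physiologically coupled variables — pTOI, SpO2, heart rate,
systolic pressure, and subcutaneous fat thickness — share a Gaussian
copula.  The printed evidence fixes only the *signs* of their
associations (SpO2 and fat positively, heart rate negatively related to
pTOI); the default rank-correlation magnitudes are free parameters and
user-overridable.  Mean and diastolic pressure are comonotone with the
systolic draw (one shared latent), which preserves their marginals
exactly while guaranteeing SABP > MABP > DABP.

Raw monitoring signals are built around each subject's latent values:
five pTOI sensor placements (a noisy settling phase, then a stable
plateau with per-placement offset), continuous SpO2/HR streams spanning
the session, and before/after cuff-pressure panels jittered
antithetically so their mean equals the latent pressure.  CRP follows a
logistic rise to a per-subject peak centred 10–12 h after birth — the
classic delay of the CRP response — with the peak drawn uniformly from
the printed group range, so cases cross 20 mg/L within 48 h and controls
never do.

Reproducibility: one root seed; subject ``i`` of group ``g`` uses the
substream ``SeedSequence(seed, spawn_key=(g, i))``, so changing cohort
sizes never reshuffles earlier subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError
from .model import (
    BloodGas,
    BloodPressurePanel,
    CrpSample,
    NeonateRecord,
    NirsSession,
    SignalTrace,
)

#: Variables coupled through the Gaussian copula, in latent order.
COPULA_VARS = ("ptoi", "spo2", "hr", "sabp", "fat_thickness")

#: Published per-group median (min; max) triplets: the calibration targets.
#: Groups: "case" = CRP >= 20 mg/L (n=6), "control" = CRP < 20 mg/L (n=24).
PUBLISHED_SUMMARIES: dict[str, dict[str, tuple[float, float, float]]] = {
    "case": {
        "gestational_age": (39.1, 36.6, 41.3),
        "birth_weight": (3561, 2985, 4360),
        "apgar1": (9, 8, 9),
        "apgar5": (9, 8, 10),
        "apgar10": (10, 9, 10),
        "ua_ph": (7.32, 7.31, 7.39),
        "postnatal_age": (147, 114, 343),
        "fat_thickness": (0.65, 0.46, 0.74),
        "forearm_diameter": (3.6, 3.2, 4.1),
        "body_temperature": (37.4, 36.7, 38.1),
        "spo2": (95, 91, 96),
        "hr": (158, 144, 163),
        "sabp": (59, 54, 69),
        "dabp": (36, 32, 42),
        "mabp": (45, 40, 51),
        "leukocytes": (19825, 11300, 25160),
        "it_ratio": (0.03, 0.01, 0.23),
        "ptoi": (74.5, 69.0, 80.2),
        "bg_ph": (7.37, 7.30, 7.41),
        "bg_pco2": (42.0, 35.0, 58.4),
        "bg_hco3": (22.8, 22.7, 24.7),
        "bg_be": (-1.0, -2.3, 2.7),
        "bg_lactate": (2.0, 1.5, 3.2),
    },
    "control": {
        "gestational_age": (37.3, 36.1, 41.9),
        "birth_weight": (3260, 2120, 3950),
        "apgar1": (9, 4, 9),
        "apgar5": (9, 8, 10),
        "apgar10": (9, 9, 10),
        "ua_ph": (7.30, 7.24, 7.42),
        "postnatal_age": (205, 75, 354),
        "fat_thickness": (0.49, 0.25, 0.96),
        "forearm_diameter": (3.3, 2.6, 3.6),
        "body_temperature": (37.2, 36.9, 37.7),
        "spo2": (96, 91, 99),
        "hr": (132, 114, 156),
        "sabp": (58, 50, 65),
        "dabp": (33, 28, 44),
        "mabp": (41, 36, 49),
        "leukocytes": (16950, 11680, 24700),
        "it_ratio": (0.02, 0.00, 0.10),
        "ptoi": (73.2, 68.8, 80.2),
        "bg_ph": (7.31, 7.23, 7.41),
        "bg_pco2": (51.1, 40.1, 67.1),
        "bg_hco3": (23.1, 21.4, 26.3),
        "bg_be": (-0.5, -2.8, 2.5),
        "bg_lactate": (1.5, 0.7, 7.0),
    },
}

UNITS = {
    "gestational_age": "weeks", "birth_weight": "g", "apgar1": "", "apgar5": "",
    "apgar10": "", "ua_ph": "pH", "postnatal_age": "min", "fat_thickness": "cm",
    "forearm_diameter": "cm", "body_temperature": "degC", "spo2": "%",
    "hr": "bpm", "sabp": "mmHg", "dabp": "mmHg", "mabp": "mmHg",
    "leukocytes": "/uL", "it_ratio": "", "ptoi": "%", "bg_ph": "pH",
    "bg_pco2": "mmHg", "bg_hco3": "mmol/L", "bg_be": "mmol/L",
    "bg_lactate": "mmol/L",
}

#: Published peak-CRP ranges (mg/L) per group; case range sits entirely at
#: or above the 20 mg/L grouping threshold, the control range entirely below.
CRP_PEAK_RANGE = {"case": (20.8, 36.2), "control": (1.0, 14.3)}

#: Published categorical compositions.
SEX_P_FEMALE = {"case": 1 / 6, "control": 11 / 24}
DELIVERY_PROBS = {
    "case": {"primary_cesarean": 4 / 6, "secondary_cesarean": 2 / 6, "vaginal": 0.0},
    "control": {"primary_cesarean": 21 / 24, "secondary_cesarean": 1 / 24,
                "vaginal": 2 / 24},
}

#: Charted decimal places per record variable (measurement precision).
_QUANTIZE = {
    "gestational_age": 1, "birth_weight": 0, "apgar1": 0, "apgar5": 0,
    "apgar10": 0, "ua_ph": 2, "postnatal_age": 0, "fat_thickness": 2,
    "forearm_diameter": 2, "body_temperature": 1, "leukocytes": 0,
    "it_ratio": 2, "bg_ph": 2, "bg_pco2": 1, "bg_hco3": 1, "bg_be": 1,
    "bg_lactate": 1,
}

#: Total Beta concentration a + b used by the median-matching solve.
_BETA_CONCENTRATION = 6.0


@lru_cache(maxsize=512)
def _solve_beta_shapes(m: float) -> tuple[float, float]:
    """Shape pair (a, b) with a + b fixed so that Beta median equals ``m``.

    ``m`` is the median on the unit interval; boundary medians are clamped
    to [0.005, 0.995] (a median exactly at the support edge is not
    representable by any continuous Beta).
    """
    m = min(max(m, 0.005), 0.995)
    kappa = _BETA_CONCENTRATION

    def gap(a: float) -> float:
        return stats.beta.ppf(0.5, a, kappa - a) - m

    a = optimize.brentq(gap, 1e-3, kappa - 1e-3, xtol=1e-12)
    return a, kappa - a


@dataclass(frozen=True)
class VariableSpec:
    """Bounded distribution pinned to a median/min/max triplet."""

    name: str
    median: float
    min: float
    max: float
    family: str = "scaled_beta"  # "scaled_beta" | "triangular"
    units: str = ""

    def validate(self) -> None:
        if not self.min <= self.median <= self.max:
            raise ConfigError(
                f"{self.name}: median {self.median} outside [{self.min}, {self.max}]"
            )
        if self.family not in ("scaled_beta", "triangular"):
            raise ConfigError(f"{self.name}: unknown family {self.family!r}")

    def ppf(self, u):
        """Quantile transform of uniforms ``u`` onto [min, max]."""
        u = np.asarray(u, dtype=float)
        span = self.max - self.min
        if span == 0:
            return np.full_like(u, self.min)
        m = (self.median - self.min) / span
        if self.family == "triangular":
            c = min(max(m, 1e-9), 1 - 1e-9)
            return self.min + span * stats.triang.ppf(u, c)
        a, b = _solve_beta_shapes(round(m, 12))
        return self.min + span * stats.beta.ppf(u, a, b)


@dataclass(frozen=True)
class GroupSpec:
    """All per-group distributions and categorical compositions."""

    variables: dict[str, VariableSpec]
    sex_p_female: float
    delivery_probs: dict[str, float]
    crp_peak_range: tuple[float, float]


@dataclass(frozen=True)
class SignalParams:
    """Raw-signal texture; free parameters, not published claims."""

    segment_noise_sd: float = 1.0        # %-points within a stable plateau
    reapplication_offset_sd: float = 1.5  # %-points between sensor placements
    stream_rate_hz: float = 1.0
    settle_s: float = 10.0
    settle_sd: float = 3.0
    plateau_s: float = 45.0
    rest_s: float = 10.0
    spo2_noise_sd: float = 0.8
    hr_noise_sd: float = 3.0
    bp_phase_jitter_sd: float = 2.0


@dataclass(frozen=True)
class CrpParams:
    """Logistic CRP rise: value(t) = peak / (1 + exp(-(t - t50)/tau))."""

    t50_h: float = 11.0   # mid-rise 10-12 h after birth (CRP response delay)
    tau_h: float = 2.0
    sample_times_h: tuple[float, ...] = (12.0, 24.0, 40.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Complete recipe for a synthetic two-group cohort."""

    case: GroupSpec
    control: GroupSpec
    rank_corr: dict[tuple[str, str], float]
    signal: SignalParams = field(default_factory=SignalParams)
    crp: CrpParams = field(default_factory=CrpParams)
    n_case: int = 6
    n_control: int = 24
    seed: int = 42
    crp_threshold: float = 20.0

    def validate(self) -> None:
        for group_name, group in (("case", self.case), ("control", self.control)):
            for spec in group.variables.values():
                spec.validate()
            total = sum(group.delivery_probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{group_name}: delivery probabilities sum to {total}")
            if not 0.0 <= group.sex_p_female <= 1.0:
                raise ConfigError(f"{group_name}: sex_p_female outside [0, 1]")
        lo, hi = self.case.crp_peak_range
        if not (lo <= hi and lo >= self.crp_threshold):
            raise ConfigError(
                f"case peak-CRP range [{lo}, {hi}] must sit entirely at or above "
                f"{self.crp_threshold} mg/L"
            )
        lo, hi = self.control.crp_peak_range
        if not (lo <= hi and hi < self.crp_threshold):
            raise ConfigError(
                f"control peak-CRP range [{lo}, {hi}] must sit entirely below "
                f"{self.crp_threshold} mg/L"
            )
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("group sizes must be >= 1")
        m = self.spearman_matrix()
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
            raise ConfigError("rank-correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-9:
            raise ConfigError("rank-correlation matrix must be positive semidefinite")

    def spearman_matrix(self) -> np.ndarray:
        m = np.eye(len(COPULA_VARS))
        index = {v: i for i, v in enumerate(COPULA_VARS)}
        for (a, b), rho in self.rank_corr.items():
            i, j = index[a], index[b]
            m[i, j] = m[j, i] = rho
        return m

    # -- JSON round-trip -------------------------------------------------

    def to_json(self) -> str:
        d = {
            "case": _group_to_dict(self.case),
            "control": _group_to_dict(self.control),
            "rank_corr": [[a, b, rho] for (a, b), rho in sorted(self.rank_corr.items())],
            "signal": asdict(self.signal),
            "crp": {**asdict(self.crp), "sample_times_h": list(self.crp.sample_times_h)},
            "n_case": self.n_case,
            "n_control": self.n_control,
            "seed": self.seed,
            "crp_threshold": self.crp_threshold,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        return cls(
            case=_group_from_dict(d["case"]),
            control=_group_from_dict(d["control"]),
            rank_corr={(a, b): rho for a, b, rho in d["rank_corr"]},
            signal=SignalParams(**d["signal"]),
            crp=CrpParams(**{**d["crp"],
                             "sample_times_h": tuple(d["crp"]["sample_times_h"])}),
            n_case=d["n_case"],
            n_control=d["n_control"],
            seed=d["seed"],
            crp_threshold=d.get("crp_threshold", 20.0),
        )


def _group_to_dict(g: GroupSpec) -> dict:
    return {
        "variables": {name: asdict(spec) for name, spec in sorted(g.variables.items())},
        "sex_p_female": g.sex_p_female,
        "delivery_probs": g.delivery_probs,
        "crp_peak_range": list(g.crp_peak_range),
    }


def _group_from_dict(d: dict) -> GroupSpec:
    return GroupSpec(
        variables={name: VariableSpec(**spec) for name, spec in d["variables"].items()},
        sex_p_female=d["sex_p_female"],
        delivery_probs=d["delivery_probs"],
        crp_peak_range=tuple(d["crp_peak_range"]),
    )


def default_config() -> GeneratorConfig:
    """Default generator, calibrated to the published group summaries.

    Every distribution triplet equals the printed per-group median
    (minimum; maximum); categorical compositions and peak-CRP ranges
    likewise.  The copula rank correlations carry only published signs
    (SpO2 and fat positively, heart rate negatively associated with
    pTOI); their magnitudes are free defaults.
    """
    groups = {}
    for group_name, table in PUBLISHED_SUMMARIES.items():
        groups[group_name] = GroupSpec(
            variables={
                name: VariableSpec(name=name, median=med, min=lo, max=hi,
                                   units=UNITS[name])
                for name, (med, lo, hi) in table.items()
            },
            sex_p_female=SEX_P_FEMALE[group_name],
            delivery_probs=dict(DELIVERY_PROBS[group_name]),
            crp_peak_range=CRP_PEAK_RANGE[group_name],
        )
    return GeneratorConfig(
        case=groups["case"],
        control=groups["control"],
        rank_corr={
            ("ptoi", "spo2"): +0.4,
            ("ptoi", "fat_thickness"): +0.3,
            ("ptoi", "hr"): -0.2,
        },
    )


@dataclass
class SyntheticCohort:
    """Generated cohort; iterator-unpacks as (records, crp_samples, sessions).

    ``latent`` holds the raw (pre-quantization, pre-noise) per-subject
    draws for every variable plus the peak CRP — the calibration ground
    truth behind the noisy signals and charted records.
    """

    records: list[NeonateRecord]
    crp_samples: list[CrpSample]
    sessions: list[NirsSession]
    latent: "object"  # pandas.DataFrame

    def __iter__(self):
        return iter((self.records, self.crp_samples, self.sessions))


def _subject_rng(seed: int, group_code: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(group_code, index)))


def _correlated_uniforms(z: np.ndarray, chol: np.ndarray) -> np.ndarray:
    return stats.norm.cdf(chol @ z)


def _build_session(
    nid: str,
    rng: np.random.Generator,
    latent: dict[str, float],
    p: SignalParams,
) -> NirsSession:
    seg_len = p.settle_s + p.plateau_s
    dt = 1.0 / p.stream_rate_hz
    n_settle = int(round(p.settle_s / dt))
    n_plateau = int(round(p.plateau_s / dt))
    offsets = rng.normal(0.0, p.reapplication_offset_sd, size=5)
    reapps = []
    for k in range(5):
        start = k * (seg_len + p.rest_s)
        times = start + dt * np.arange(n_settle + n_plateau)
        level = latent["ptoi"] + offsets[k]
        values = np.concatenate([
            level + rng.normal(0.0, p.settle_sd, size=n_settle),
            level + rng.normal(0.0, p.segment_noise_sd, size=n_plateau),
        ])
        # device display precision: pTOI to 0.01 %
        reapps.append(SignalTrace("pTOI", times, np.round(values, 2)))
    span = 5 * seg_len + 4 * p.rest_s
    stream_t = dt * np.arange(int(round(span / dt)))
    spo2 = np.minimum(
        latent["spo2"] + rng.normal(0.0, p.spo2_noise_sd, size=len(stream_t)), 100.0
    )
    hr = latent["hr"] + rng.normal(0.0, p.hr_noise_sd, size=len(stream_t))
    spo2, hr = np.round(spo2, 1), np.round(hr, 1)
    d = rng.normal(0.0, p.bp_phase_jitter_sd)
    panels = tuple(
        BloodPressurePanel(
            phase=phase,
            sabp=round(latent["sabp"] + sign * d),  # cuff reads whole mmHg
            dabp=round(latent["dabp"] + sign * d),
            mabp=round(latent["mabp"] + sign * d),
        )
        for phase, sign in (("before", +1.0), ("after", -1.0))
    )
    return NirsSession(
        neonate_id=nid,
        reapplications=tuple(reapps),
        spo2_stream=SignalTrace("SpO2", stream_t, spo2),
        hr_stream=SignalTrace("HR", stream_t, hr),
        bp_panels=panels,
    )


def _quantize(name: str, value: float) -> float | int:
    dp = _QUANTIZE.get(name)
    if dp == 0:
        return int(round(value))
    if dp is not None:
        return round(value, dp)
    return value


def generate_cohort(
    config: GeneratorConfig,
    n_case: int | None = None,
    n_control: int | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort of cases and controls.

    Per subject: a 5-dimensional Gaussian copula draw couples pTOI, SpO2,
    heart rate, systolic pressure and fat thickness; the remaining
    variables use independent uniforms (mean/diastolic pressure reuse the
    systolic latent, keeping SABP > MABP > DABP with exact marginals);
    raw signals, CRP samples and the charted record are then built around
    the latent values.  Identical arguments give byte-identical output.
    """
    import pandas as pd

    config.validate()
    n_case = config.n_case if n_case is None else n_case
    n_control = config.n_control if n_control is None else n_control
    seed = config.seed if seed is None else seed
    if n_case < 1 or n_control < 1:
        raise ConfigError("n_case and n_control must be >= 1")

    pearson = 2.0 * np.sin(np.pi * config.spearman_matrix() / 6.0)
    np.fill_diagonal(pearson, 1.0)
    # Guard against tiny indefiniteness after the Spearman->Pearson map.
    w, v = np.linalg.eigh(pearson)
    pearson = (v * np.maximum(w, 1e-10)) @ v.T
    chol = np.linalg.cholesky(pearson)

    plans = [("case", 1, config.case, n_case), ("control", 0, config.control, n_control)]
    records, crp_samples, sessions, latent_rows = [], [], [], []
    for group_name, group_code, group, n in plans:
        independent = sorted(
            name for name in group.variables
            if name not in COPULA_VARS and name not in ("dabp", "mabp")
        )
        for i in range(n):
            rng = _subject_rng(seed, group_code, i)
            nid = f"{'c' if group_code else 'n'}{i + 1:03d}"

            u_cop = _correlated_uniforms(rng.standard_normal(len(COPULA_VARS)), chol)
            draws = {
                name: float(group.variables[name].ppf(u))
                for name, u in zip(COPULA_VARS, u_cop)
            }
            u_sabp = u_cop[COPULA_VARS.index("sabp")]
            # Comonotone with SABP: marginals exact, ordering physiological.
            draws["mabp"] = float(group.variables["mabp"].ppf(u_sabp))
            draws["dabp"] = float(group.variables["dabp"].ppf(u_sabp))
            for name in independent:
                draws[name] = float(group.variables[name].ppf(rng.random()))
            sex = "female" if rng.random() < group.sex_p_female else "male"
            u_mode = rng.random()
            cum = 0.0
            delivery = "vaginal"
            for mode, p_mode in group.delivery_probs.items():
                cum += p_mode
                if u_mode < cum:
                    delivery = mode
                    break
            lo, hi = group.crp_peak_range
            crp_peak = float(lo + (hi - lo) * rng.random())

            for t in config.crp.sample_times_h:
                level = crp_peak / (1.0 + np.exp(-(t - config.crp.t50_h) / config.crp.tau_h))
                # lab report precision: 0.1 mg/L
                crp_samples.append(CrpSample(nid, float(t), round(float(level), 1)))

            sessions.append(_build_session(nid, rng, draws, config.signal))

            records.append(NeonateRecord(
                id=nid,
                gestational_age=_quantize("gestational_age", draws["gestational_age"]),
                birth_weight=_quantize("birth_weight", draws["birth_weight"]),
                sex=sex,
                delivery_mode=delivery,
                apgar_1=_quantize("apgar1", draws["apgar1"]),
                apgar_5=_quantize("apgar5", draws["apgar5"]),
                apgar_10=_quantize("apgar10", draws["apgar10"]),
                ua_ph=_quantize("ua_ph", draws["ua_ph"]),
                postnatal_age_at_measurement=_quantize("postnatal_age",
                                                       draws["postnatal_age"]),
                fat_thickness=_quantize("fat_thickness", draws["fat_thickness"]),
                forearm_diameter=_quantize("forearm_diameter", draws["forearm_diameter"]),
                body_temperature=_quantize("body_temperature", draws["body_temperature"]),
                leukocyte_count=_quantize("leukocytes", draws["leukocytes"]),
                it_ratio=_quantize("it_ratio", draws["it_ratio"]),
                blood_gas=BloodGas(
                    ph=_quantize("bg_ph", draws["bg_ph"]),
                    pco2=_quantize("bg_pco2", draws["bg_pco2"]),
                    hco3=_quantize("bg_hco3", draws["bg_hco3"]),
                    base_excess=_quantize("bg_be", draws["bg_be"]),
                    lactate=_quantize("bg_lactate", draws["bg_lactate"]),
                ),
            ))
            latent_rows.append({"id": nid, "group": group_name,
                                **draws, "crp_peak": crp_peak})

    return SyntheticCohort(
        records=records,
        crp_samples=crp_samples,
        sessions=sessions,
        latent=pd.DataFrame(latent_rows),
    )


def generate_null_cohort(
    config: GeneratorConfig,
    n_case: int | None = None,
    n_control: int | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Cohort in which the score carries no signal about the CRP group.

    Both groups draw every physiological variable from the *control*
    distributions; only the CRP trajectory (hence the group label)
    differs.  Under this null the POP-Score is independent of the
    outcome, which pins down the false-positive behaviour of any
    downstream comparison.
    """
    null_case = GroupSpec(
        variables=dict(config.control.variables),
        sex_p_female=config.control.sex_p_female,
        delivery_probs=dict(config.control.delivery_probs),
        crp_peak_range=config.case.crp_peak_range,
    )
    return generate_cohort(
        replace(config, case=null_case), n_case=n_case, n_control=n_control, seed=seed
    )


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_json())


def read_config(path: str | Path) -> GeneratorConfig:
    return GeneratorConfig.from_json(Path(path).read_text())
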