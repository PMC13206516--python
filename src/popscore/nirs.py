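"""Protocol summarization of a peripheral-muscle NIRS session.

The measurement protocol places the NIRS sensor on the right forearm,
waits for a stable signal of about 30 s, removes the sensor for a 10-s
rest, and repeats for a total of five placements.  The session summary is

* ``ptoi_mean`` — the unweighted mean of the per-placement stable-segment
  means of the tissue oxygenation index (pTOI),
* ``spo2_mean`` / ``hr_mean`` — means of the continuously recorded pulse
  oximetry and heart rate over the accepted pTOI segments only (rest
  periods between placements are excluded),
* ``sabp_mean`` — the mean of the systolic cuff pressures taken
  immediately before and after the session,
* ``pftoe`` — peripheral fractional tissue oxygen extraction,
  ``(SpO2 − pTOI) / SpO2``, the balance of tissue oxygen consumption
  against delivery.

"Stable" is operationalized as a rolling sample standard deviation at or
below a threshold over a 30-s window.  The threshold defaults to
2.0 %-points (:data:`DEFAULT_MAX_SD`): roughly twice the short-term sd of
a quiet neonatal pTOI signal, so that genuinely stable segments are not
rejected by sampling noise in the sd estimate itself.  Both the window
and the threshold are explicit knobs.

All time windows are half-open ``[start, end)`` in seconds from session
start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InstabilityError, PopscoreError
from .model import BloodPressurePanel, NeonateRecord, NirsSession, SignalTrace

#: Minimum stable-window length, seconds ("approximately 30 s" → exact minimum).
DEFAULT_WINDOW_S = 30.0
#: Default rolling-sd stability threshold for pTOI, %-points.
DEFAULT_MAX_SD = 2.0
#: Number of sensor placements the full protocol prescribes.
PROTOCOL_SEGMENTS = 5


@dataclass(frozen=True)
class OxygenationSummary:
    """Protocol-derived summary of one NIRS session."""

    neonate_id: str
    ptoi_mean: float          # %
    spo2_mean: float          # %
    hr_mean: float            # bpm
    sabp_mean: float          # mmHg
    pftoe: float              # fraction
    n_segments_used: int
    measurement_window: tuple[float, float]  # (start_s, end_s) across segments
    flags: tuple[str, ...] = ()


def detect_stable_segment(
    trace: SignalTrace,
    window: float = DEFAULT_WINDOW_S,
    max_sd: float = DEFAULT_MAX_SD,
) -> tuple[float, float]:
    """Earliest half-open window ``[start, start + window)`` with sd ≤ ``max_sd``.

    Candidate windows start at each sample time; a window qualifies when
    the sample standard deviation (ddof=1) of the samples inside it is at
    most ``max_sd`` and the trace's sampling covers the whole window.
    The earliest qualifying start wins (deterministic tie-break).

    Raises :class:`InstabilityError` (carrying the minimal achieved sd)
    when no window qualifies, and :class:`DomainError` when the trace is
    shorter than one window.
    """
    t, x = trace.times, trace.values
    if len(t) < 2:
        raise DomainError("trace has fewer than 2 samples")
    dt = float(np.median(np.diff(t)))
    if t[-1] + dt < t[0] + window:
        raise DomainError(
            f"trace spans {t[-1] - t[0] + dt:.1f} s, shorter than the "
            f"{window:.0f}-s window"
        )
    min_sd = np.inf
    for i in range(len(t)):
        end = t[i] + window
        if t[-1] + dt < end:  # window no longer fully sampled
            break
        j = int(np.searchsorted(t, end, side="left"))
        seg = x[i:j]
        if len(seg) < 2:
            continue
        sd = float(np.std(seg, ddof=1))
        min_sd = min(min_sd, sd)
        if sd <= max_sd:
            return float(t[i]), float(end)
    raise InstabilityError(
        f"no {window:.0f}-s window with sd <= {max_sd} "
        f"(minimum achieved sd {min_sd:.3f})",
        min_sd=min_sd,
    )


def _segment_mean(trace: SignalTrace, start: float, end: float) -> float:
    mask = (trace.times >= start) & (trace.times < end)
    return float(np.mean(trace.values[mask]))


def stable_segments(
    session: NirsSession,
    window: float = DEFAULT_WINDOW_S,
    max_sd: float = DEFAULT_MAX_SD,
) -> tuple[list[tuple[float, float]], list[float], list[int]]:
    """Stable windows and their means for every usable sensor placement.

    Returns ``(windows, means, skipped)`` where ``windows`` and ``means``
    are aligned over usable placements and ``skipped`` lists the indices
    (0-based) of placements with no qualifying window.
    """
    windows: list[tuple[float, float]] = []
    means: list[float] = []
    skipped: list[int] = []
    for k, trace in enumerate(session.reapplications):
        try:
            start, end = detect_stable_segment(trace, window=window, max_sd=max_sd)
        except (InstabilityError, DomainError):
            skipped.append(k)
            continue
        windows.append((start, end))
        means.append(_segment_mean(trace, start, end))
    return windows, means, skipped


def summarize_ptoi(
    session: NirsSession,
    require_n: int = PROTOCOL_SEGMENTS,
    window: float = DEFAULT_WINDOW_S,
    max_sd: float = DEFAULT_MAX_SD,
) -> tuple[float, int]:
    """Mean pTOI over usable stable segments.

    Per-placement stable-segment means are computed first; their
    unweighted arithmetic mean is returned together with the number of
    segments used.  Fewer than ``require_n`` usable segments is permitted
    (the shortfall is visible in ``n_segments_used`` and flagged by
    :func:`summarize_session`); zero usable segments raises
    :class:`InstabilityError`.
    """
    _, means, _ = stable_segments(session, window=window, max_sd=max_sd)
    if not means:
        raise InstabilityError(
            f"session {session.neonate_id!r}: no usable stable pTOI segment "
            f"in {len(session.reapplications)} placement(s)"
        )
    return float(np.mean(means)), len(means)


def summarize_vitals(
    session: NirsSession,
    windows: list[tuple[float, float]],
) -> tuple[float, float]:
    """Mean SpO2 and HR over the union of accepted pTOI segment windows.

    Only stream samples falling inside an accepted half-open window count
    — the protocol averages vitals *during* the NIRS measurements, not
    over the rest periods between sensor placements.
    """
    if not windows:
        raise DomainError("no accepted segment windows")

    def _mean_in_windows(stream: SignalTrace) -> float:
        mask = np.zeros(len(stream.times), dtype=bool)
        for start, end in windows:
            mask |= (stream.times >= start) & (stream.times < end)
        if not mask.any():
            raise DomainError(
                f"{stream.channel} stream has no samples inside the accepted windows"
            )
        return float(np.mean(stream.values[mask]))

    return _mean_in_windows(session.spo2_stream), _mean_in_windows(session.hr_stream)


def mean_sabp(panels: tuple[BloodPressurePanel, ...] | list[BloodPressurePanel]) -> float:
    """Mean of the systolic pressures measured before and after the session.

    Both phases must be present; there is no single-phase fallback.
    """
    by_phase = {p.phase: p for p in panels}
    missing = [ph for ph in ("before", "after") if ph not in by_phase]
    if missing:
        raise DomainError(f"missing blood-pressure phase(s): {missing}")
    return (by_phase["before"].sabp + by_phase["after"].sabp) / 2.0


def compute_pftoe(spo2: float, ptoi: float) -> float:
    """Peripheral fractional tissue oxygen extraction, ``(SpO2 − pTOI)/SpO2``.

    Negative values are mathematically permitted (tissue index above
    arterial saturation) and are flagged by :func:`summarize_session`.
    """
    if spo2 <= 0:
        raise DomainError(f"spo2 must be > 0, got {spo2}")
    return (spo2 - ptoi) / spo2


def summarize_session(
    session: NirsSession,
    record: NeonateRecord | None = None,
    *,
    window: float = DEFAULT_WINDOW_S,
    max_sd: float = DEFAULT_MAX_SD,
    require_n: int = PROTOCOL_SEGMENTS,
) -> OxygenationSummary:
    """Full protocol summary of one session.

    Composes stable-segment detection, pTOI averaging, vitals averaging
    over the accepted windows, before/after SABP averaging and the pFTOE
    identity.  Component errors are re-raised with the neonate id
    attached.  ``record`` is accepted for symmetry with the per-neonate
    pipeline; the summary itself uses only session data.
    """
    nid = session.neonate_id
    try:
        windows, means, skipped = stable_segments(session, window=window, max_sd=max_sd)
        if not means:
            raise InstabilityError(
                f"no usable stable pTOI segment in "
                f"{len(session.reapplications)} placement(s)"
            )
        ptoi_mean = float(np.mean(means))
        n_used = len(means)
        spo2_mean, hr_mean = summarize_vitals(session, windows)
        sabp = mean_sabp(session.bp_panels)
        pftoe = compute_pftoe(spo2_mean, ptoi_mean)
    except PopscoreError as e:
        if isinstance(e, InstabilityError):
            raise InstabilityError(f"session {nid!r}: {e}", min_sd=e.min_sd) from e
        raise type(e)(f"session {nid!r}: {e}") from e

    flags = []
    if n_used < require_n:
        flags.append(f"only {n_used} of {require_n} stable segments")
    if skipped:
        flags.append(f"unstable placement(s) at index {skipped}")
    if pftoe < 0:
        flags.append("negative pFTOE (pTOI above SpO2)")
    return OxygenationSummary(
        neonate_id=nid,
        ptoi_mean=ptoi_mean,
        spo2_mean=spo2_mean,
        hr_mean=hr_mean,
        sabp_mean=sabp,
        pftoe=pftoe,
        n_segments_used=n_used,
        measurement_window=(windows[0][0], windows[-1][1]),
        flags=tuple(flags),
    )


def summaries_frame(summaries: list[OxygenationSummary]):
    """Summaries as a DataFrame in the ``summaries.csv`` schema."""
    import pandas as pd

    return pd.DataFrame(
        [{
            "id": s.neonate_id,
            "ptoi_mean": s.ptoi_mean,
            "spo2_mean": s.spo2_mean,
            "hr_mean": s.hr_mean,
            "sabp_mean": s.sabp_mean,
            "pftoe": s.pftoe,
            "n_segments_used": s.n_segments_used,
        } for s in summaries],
        columns=["id", "ptoi_mean", "spo2_mean", "hr_mean", "sabp_mean",
                 "pftoe", "n_segments_used"],
    )
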