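"""Independent oracles and small builders shared across the test suite.

Everything here deliberately re-derives results by brute force —
exhaustive scans, pair counting, full enumeration — so that the
implementation under test is checked against a second, independent
route, not against itself.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from popscore.model import BloodPressurePanel, NirsSession, SignalTrace


# ---------------------------------------------------------------------------
# builders

def make_trace(values, channel="pTOI", t0=0.0, dt=1.0):
    values = np.asarray(values, dtype=float)
    return SignalTrace(channel, t0 + dt * np.arange(len(values)), values)


def make_session(
    segment_values,
    spo2=95.0,
    hr=158.0,
    sabp=(58.0, 60.0),
    nid="x001",
    rest_s=10.0,
):
    """Session with given per-placement pTOI sample arrays laid out in time.

    ``spo2`` / ``hr`` may be constants or callables of the stream time
    array; streams run at 1 Hz across the whole session.
    """
    reapps = []
    t = 0.0
    for seg in segment_values:
        seg = np.asarray(seg, dtype=float)
        reapps.append(make_trace(seg, t0=t))
        t += len(seg) + rest_s
    span = int(t - rest_s)
    stream_t = np.arange(span, dtype=float)
    spo2_v = spo2(stream_t) if callable(spo2) else np.full(span, float(spo2))
    hr_v = hr(stream_t) if callable(hr) else np.full(span, float(hr))
    before, after = sabp
    panels = (
        BloodPressurePanel("before", before, before - 25.0, before - 15.0),
        BloodPressurePanel("after", after, after - 25.0, after - 15.0),
    )
    return NirsSession(
        neonate_id=nid,
        reapplications=tuple(reapps),
        spo2_stream=SignalTrace("SpO2", stream_t, spo2_v),
        hr_stream=SignalTrace("HR", stream_t, hr_v),
        bp_panels=panels,
    )


# ---------------------------------------------------------------------------
# oracles

def exhaustive_stable_scan(trace, window, max_sd):
    """All-windows scan with the same window semantics, written naively.

    Returns the earliest qualifying (start, end) or None.
    """
    t, x = trace.times, trace.values
    dt = float(np.median(np.diff(t)))
    for i in range(len(t)):
        end = t[i] + window
        if t[-1] + dt < end:
            break
        seg = [x[j] for j in range(len(t)) if t[i] <= t[j] < end]
        if len(seg) < 2:
            continue
        mean = sum(seg) / len(seg)
        sd = math.sqrt(sum((s - mean) ** 2 for s in seg) / (len(seg) - 1))
        if sd <= max_sd:
            return (float(t[i]), float(end))
    return None


def recount_confusion(scores_with_labels, cutoff):
    """Naive per-subject recount of the confusion table."""
    tp = fp = tn = fn = 0
    for score, label in scores_with_labels:
        if score >= cutoff:
            if label == "case":
                tp += 1
            else:
                fp += 1
        else:
            if label == "case":
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def mwu_enumeration_p(x, y):
    """Exact two-sided Mann–Whitney p by direct pair counting per assignment."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    centre = nx * (len(pooled) - nx) / 2.0
    observed = abs(u_stat(tuple(range(nx))) - centre)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        hits += abs(u_stat(idx) - centre) >= observed - 1e-9
        total += 1
    return hits / total


def fisher_enumeration_p(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    observed = stats.hypergeom.pmf(a, n, col1, row1)
    p = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = stats.hypergeom.pmf(k, n, col1, row1)
        if pk <= observed * (1 + 1e-9):
            p += pk
    return min(p, 1.0)


def spearman_permutation_p(x, y):
    """Exact two-sided Spearman p by scipy rho over all n! orderings."""
    observed = abs(stats.spearmanr(x, y).statistic)
    hits = total = 0
    for perm in itertools.permutations(y):
        hits += abs(stats.spearmanr(x, perm).statistic) >= observed - 1e-12
        total += 1
    return hits / total


def median_tolerance(spec, n, z=3.29):
    """Half-width of the order-statistic band for the sample median.

    The sample median of ``n`` draws lies between the distribution
    quantiles at 0.5 ± z·sqrt(0.25/n).  The default z gives ~99.9%
    per-variable coverage so that checking ~46 variables simultaneously
    keeps the familywise false-alarm rate around 5%.
    """
    delta = z * math.sqrt(0.25 / n)
    lo = float(spec.ppf(0.5 - delta))
    hi = float(spec.ppf(0.5 + delta))
    return max(hi - spec.median, spec.median - lo)
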