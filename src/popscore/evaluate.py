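"""Diagnostic evaluation of the POP-Score against the CRP grouping.

The study question is whether a single pre-specified score cut-off
(1.00) separates neonates whose CRP peaks at or above 20 mg/L from
those below.  This module provides the cut-off classification and its
confusion table, sensitivity/specificity (full-precision fractions plus
the integer-percent convention of the source tables, which truncates
toward zero — 21/24 = 87.5% is reported as 87%), an exploratory cut-off
sweep, Spearman rank correlation between score and CRP, and a
group-comparison table in the published layout.

Small-sample statistics are exact by contract, not by library default:

* Mann–Whitney U — exact by full enumeration of group assignments
  (tie-aware) when the combined sample is at most 30 and the number of
  assignments at most 2×10⁶ (the study-shaped 6-vs-24 comparison has
  C(30,6) ≈ 5.9×10⁵); otherwise the tie-corrected normal approximation.
  Without ties the enumeration is delegated to scipy's exact method.
* Fisher's exact test for 2×2 categorical tables (chi-square for wider
  tables such as delivery mode).
* Spearman p — exact permutation over all n! orderings for n ≤ 9, the
  t approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, PopscoreError

#: Pre-specified score cut-off.
DEFAULT_CUTOFF = 1.00

#: Exact-enumeration limits for the Mann-Whitney test.
MWU_EXACT_MAX_N = 30
MWU_EXACT_MAX_ASSIGNMENTS = 2_000_000

SPEARMAN_EXACT_MAX_N = 9


@dataclass(frozen=True)
class DiagnosticReport:
    """Confusion table and rates of the score cut-off."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float      # exact fraction tp / (tp + fn)
    specificity: float      # exact fraction tn / (tn + fp)
    sensitivity_pct: int    # integer percent, truncated toward zero
    specificity_pct: int


def classify(score: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """``"positive"`` iff ``score >= cutoff`` (boundary inclusive)."""
    if not math.isfinite(score):
        raise DomainError(f"score must be finite, got {score}")
    return "positive" if score >= cutoff else "negative"


def _truncate_pct(fraction: float) -> int:
    return int(math.floor(fraction * 100.0 + 1e-9))


def confusion_and_rates(
    scores_with_labels: list[tuple[float, str]],
    cutoff: float = DEFAULT_CUTOFF,
) -> DiagnosticReport:
    """Confusion counts and rates at a cut-off.

    ``scores_with_labels`` pairs each score with its outcome label
    (``"case"`` / ``"control"``).  Rates are undefined with a
    single-class input, which raises :class:`DomainError`.
    """
    tp = fp = tn = fn = 0
    for score, label in scores_with_labels:
        if label not in ("case", "control"):
            raise DomainError(f"unknown label {label!r}")
        positive = classify(score, cutoff) == "positive"
        if label == "case":
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    if tp + fn == 0 or tn + fp == 0:
        raise DomainError("need at least one case and one control")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return DiagnosticReport(
        cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        sensitivity_pct=_truncate_pct(sens),
        specificity_pct=_truncate_pct(spec),
    )


def sweep_cutoffs(
    scores_with_labels: list[tuple[float, str]],
) -> list[tuple[float, float, float]]:
    """Exploratory (cutoff, sensitivity, specificity) sweep.

    Candidate cut-offs are the midpoints between consecutive sorted
    unique scores, bracketed by ∓infinity sentinels (everything
    positive / everything negative).  Along increasing cut-off,
    sensitivity is non-increasing and specificity non-decreasing.

    The study pre-specified its single cut-off; this sweep is a
    diagnostic aid, not a study quantity.
    """
    scores = np.array([s for s, _ in scores_with_labels], dtype=float)
    labels = np.array([lab == "case" for _, lab in scores_with_labels])
    n_case, n_control = int(labels.sum()), int((~labels).sum())
    if n_case == 0 or n_control == 0:
        raise DomainError("need at least one case and one control")
    unique = np.unique(scores)
    candidates = [-np.inf, *((unique[:-1] + unique[1:]) / 2.0), np.inf]
    out = []
    for c in candidates:
        positive = scores >= c
        sens = float((positive & labels).sum() / n_case)
        spec = float((~positive & ~labels).sum() / n_control)
        out.append((float(c), sens, spec))
    return out


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a documented exact-p contract.

    Ties receive average ranks.  The two-sided p-value is computed by
    exact enumeration of all n! orderings for n ≤ 9 and by the
    t approximation for larger n.  Constant input has no defined rank
    correlation and raises :class:`DomainError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise DomainError(f"need paired samples with n >= 4, got n = {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("rank correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    rho = float(rx_c @ ry_c) / denom

    if n <= SPEARMAN_EXACT_MAX_N:
        target = abs(rho) - 1e-12
        hits = total = 0
        ry_list = list(ry_c)
        for perm in itertools.permutations(ry_list):
            r = sum(a * b for a, b in zip(rx_c, perm)) / denom
            hits += abs(r) >= target
            total += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def mann_whitney(x, y) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U test of two independent samples.

    Returns ``(U, p, method)`` where ``U`` counts pairs with the first
    sample larger (ties half).  Method is ``"exact"`` (enumeration /
    scipy exact, combined n ≤ 30 and ≤ 2×10⁶ assignments) or
    ``"asymptotic"`` (tie-corrected normal approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise DomainError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < nx + ny
    n = nx + ny
    if n <= MWU_EXACT_MAX_N and math.comb(n, nx) <= MWU_EXACT_MAX_ASSIGNMENTS:
        if not has_ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return u_x, float(res.pvalue), "exact"
        # Tie-aware exact null: enumerate every assignment of pooled ranks
        # to the first group; U is symmetric about nx*ny/2 under exchange.
        centre = nx * ny / 2.0
        target = abs(u_x - centre) - 1e-9
        hits = total = 0
        offset = nx * (nx + 1) / 2.0
        for combo in itertools.combinations(ranks, nx):
            u = sum(combo) - offset
            hits += abs(u - centre) >= target
            total += 1
        return u_x, hits / total, "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_x, float(res.pvalue), "asymptotic"


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 count table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def _triplet(values: pd.Series) -> tuple[float, float, float]:
    return (float(values.median()), float(values.min()), float(values.max()))


def compare_groups(
    frame: pd.DataFrame,
    continuous: list[str],
    categorical: list[str] = (),
    group_col: str = "group",
) -> dict[str, dict]:
    """Per-variable group summaries and two-sided p-values.

    ``frame`` holds one row per neonate with a ``group`` column
    ("case"/"control").  Continuous variables get median (min; max) per
    group and a Mann–Whitney p; categorical variables get per-level
    counts and a Fisher exact p (2 levels) or chi-square p (more).
    A variable with no observations in one group is flagged and skipped.
    """
    case = frame[frame[group_col] == "case"]
    control = frame[frame[group_col] == "control"]
    if len(case) == 0 or len(control) == 0:
        raise DomainError("both groups must be non-empty")
    out: dict[str, dict] = {}
    for var in continuous:
        a = case[var].dropna()
        b = control[var].dropna()
        if len(a) == 0 or len(b) == 0:
            out[var] = {"skipped": "variable absent in one group"}
            continue
        if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
            p, method = 1.0, "degenerate"  # all values identical
        else:
            _, p, method = mann_whitney(a.to_numpy(), b.to_numpy())
        out[var] = {
            "case": _triplet(a), "control": _triplet(b),
            "p": p, "test": f"mann-whitney ({method})",
        }
    for var in categorical:
        a = case[var].dropna()
        b = control[var].dropna()
        if len(a) == 0 or len(b) == 0:
            out[var] = {"skipped": "variable absent in one group"}
            continue
        levels = sorted(set(a) | set(b))
        counts = np.array([[int((g == lv).sum()) for lv in levels] for g in (a, b)])
        if len(levels) == 1:
            p, test = 1.0, "degenerate"
        elif len(levels) == 2:
            p, test = fisher_exact_2x2(counts), "fisher"
        else:
            p, test = float(stats.chi2_contingency(counts)[1]), "chi-square"
        out[var] = {
            "levels": levels,
            "case": [int(c) for c in counts[0]],
            "control": [int(c) for c in counts[1]],
            "p": p, "test": test,
        }
    return out


def build_report(
    *,
    flow: dict,
    group_comparison: dict,
    score_summary: dict,
    diagnostics: DiagnosticReport,
    correlation: tuple[float, float],
    cutoff_sweep: list[tuple[float, float, float]] | None = None,
) -> dict:
    """Assemble the machine-readable analysis report.

    All stages are required (``flow`` accounting, the group-comparison
    table, per-group score summaries, the diagnostic report and the
    score-CRP correlation); a missing one raises naming it.  The cut-off
    sweep is optional and explicitly labelled exploratory.
    """
    stages = {"flow": flow, "group_comparison": group_comparison,
              "score_summary": score_summary, "diagnostics": diagnostics,
              "correlation": correlation}
    for name, value in stages.items():
        if value is None:
            raise PopscoreError(f"cannot build report: missing stage {name!r}")
    rho, p = correlation
    report = {
        "flow": flow,
        "group_comparison": group_comparison,
        "score_summary": score_summary,
        "diagnostics": {
            "cutoff": diagnostics.cutoff,
            "tp": diagnostics.tp, "fp": diagnostics.fp,
            "tn": diagnostics.tn, "fn": diagnostics.fn,
            "sensitivity": diagnostics.sensitivity,
            "specificity": diagnostics.specificity,
            "sensitivity_pct": diagnostics.sensitivity_pct,
            "specificity_pct": diagnostics.specificity_pct,
        },
        "correlation": {"spearman_rho": rho, "p": p},
    }
    if cutoff_sweep is not None:
        report["cutoff_sweep_exploratory"] = [
            {"cutoff": c, "sensitivity": s, "specificity": sp}
            for c, s, sp in cutoff_sweep
        ]
    return report


def render_report(report: dict) -> str:
    """Human-readable table set for a report dictionary."""
    lines = []
    flow = report["flow"]
    lines.append("Cohort flow")
    for key, value in flow.items():
        lines.append(f"  {key}: {value}")
    lines.append("")
    lines.append("Group comparison  [median (min; max), two-sided p]")
    for var, entry in report["group_comparison"].items():
        if "skipped" in entry:
            lines.append(f"  {var}: skipped ({entry['skipped']})")
            continue
        if "levels" in entry:
            pairs = ", ".join(
                f"{lv}: {a} vs {b}"
                for lv, a, b in zip(entry["levels"], entry["case"], entry["control"])
            )
            lines.append(f"  {var}: {pairs}  p={entry['p']:.3f} ({entry['test']})")
        else:
            ca, co = entry["case"], entry["control"]
            lines.append(
                f"  {var}: {ca[0]:g} ({ca[1]:g}; {ca[2]:g}) vs "
                f"{co[0]:g} ({co[1]:g}; {co[2]:g})  p={entry['p']:.3f} ({entry['test']})"
            )
    lines.append("")
    ss = report["score_summary"]
    lines.append("POP-Score  [median (min; max)]")
    for group in ("case", "control"):
        med, lo, hi = ss[group]
        lines.append(f"  {group}: {med:.2f} ({lo:.2f}; {hi:.2f})")
    d = report["diagnostics"]
    lines.append("")
    lines.append(
        f"Cut-off {d['cutoff']:.2f}: sensitivity {d['sensitivity_pct']}% "
        f"({d['tp']}/{d['tp'] + d['fn']}), specificity {d['specificity_pct']}% "
        f"({d['tn']}/{d['tn'] + d['fp']})"
    )
    c = report["correlation"]
    lines.append(f"Spearman rho = {c['spearman_rho']:.3f}, p = {c['p']:.3f}")
    return "\n".join(lines)
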