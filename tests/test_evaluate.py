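"""Cut-off diagnostics, exact small-sample tests, and report assembly."""

import json

import numpy as np
import pytest
from scipy import stats

from helpers import (
    fisher_enumeration_p,
    mwu_enumeration_p,
    recount_confusion,
    spearman_permutation_p,
)
from popscore.errors import DomainError, PopscoreError
from popscore.evaluate import (
    DiagnosticReport,
    build_report,
    classify,
    compare_groups,
    confusion_and_rates,
    fisher_exact_2x2,
    mann_whitney,
    spearman_rho,
    sweep_cutoffs,
)


class TestClassify:
    @pytest.mark.parametrize(
        ("score", "expected"),
        [(1.00, "positive"), (1.05, "positive"), (1.96, "positive"),
         (0.43, "negative"), (0.9999, "negative")],
    )
    def test_boundary_inclusive_threshold(self, score, expected):
        assert classify(score) == expected

    def test_non_finite_score_rejected(self):
        with pytest.raises(DomainError):
            classify(float("nan"))


class TestConfusionAndRates:
    def test_study_shaped_cohort_reproduces_printed_rates(self):
        # 6 cases inside the printed case range, 21 controls below the
        # cut-off, 3 controls at or above it.
        rng = np.random.default_rng(0)
        pairs = [(float(s), "case") for s in rng.uniform(1.05, 1.96, 6)]
        pairs += [(float(s), "control") for s in rng.uniform(0.43, 0.99, 21)]
        pairs += [(1.00, "control"), (1.31, "control"), (1.75, "control")]
        report = confusion_and_rates(pairs, cutoff=1.00)
        assert (report.tp, report.fp, report.tn, report.fn) == (6, 3, 21, 0)
        assert report.sensitivity == 1.0
        assert report.specificity == 21 / 24
        assert report.sensitivity_pct == 100
        assert report.specificity_pct == 87  # 87.5% truncated toward zero

    def test_perfect_separation(self):
        pairs = [(1.2, "case"), (1.5, "case"), (0.6, "control"), (0.9, "control")]
        report = confusion_and_rates(pairs, cutoff=1.0)
        assert report.sensitivity_pct == 100 and report.specificity_pct == 100

    def test_counts_match_independent_recount_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            pairs = [(float(rng.uniform(0.2, 2.2)),
                      "case" if rng.random() < 0.4 else "control") for _ in range(n)]
            labels = {lab for _, lab in pairs}
            cutoff = float(rng.uniform(0.5, 1.5))
            if labels != {"case", "control"}:
                with pytest.raises(DomainError):
                    confusion_and_rates(pairs, cutoff)
                continue
            r = confusion_and_rates(pairs, cutoff)
            assert (r.tp, r.fp, r.tn, r.fn) == recount_confusion(pairs, cutoff)
            assert r.tp + r.fn + r.tn + r.fp == n

    def test_single_class_input_is_error(self):
        with pytest.raises(DomainError):
            confusion_and_rates([(1.2, "case"), (0.9, "case")], 1.0)


class TestSweep:
    def test_separable_set_has_perfect_cutoff(self):
        pairs = [(1.2, "case"), (1.5, "case"), (0.6, "control"), (0.9, "control")]
        assert any(s == 1.0 and sp == 1.0 for _, s, sp in sweep_cutoffs(pairs))

    def test_identical_scores_give_degenerate_endpoints(self):
        pairs = [(1.0, "case"), (1.0, "control"), (1.0, "control")]
        sweep = sweep_cutoffs(pairs)
        assert [(s, sp) for _, s, sp in sweep] == [(1.0, 0.0), (0.0, 1.0)]

    def test_monotone_and_agrees_with_recount(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            pairs = [(float(rng.choice([0.5, 0.8, 1.0, 1.2, 1.5])),
                      "case" if rng.random() < 0.5 else "control") for _ in range(n)]
            if {lab for _, lab in pairs} != {"case", "control"}:
                continue
            sweep = sweep_cutoffs(pairs)
            sens = [s for _, s, _ in sweep]
            spec = [sp for _, _, sp in sweep]
            assert all(a >= b for a, b in zip(sens, sens[1:]))
            assert all(a <= b for a, b in zip(spec, spec[1:]))
            n_case = sum(lab == "case" for _, lab in pairs)
            n_ctrl = len(pairs) - n_case
            for cutoff, s, sp in sweep:
                tp, fp, tn, fn = recount_confusion(pairs, cutoff)
                assert s == tp / n_case and sp == tn / n_ctrl


class TestSpearman:
    def test_perfectly_increasing_and_decreasing(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_rho(x, [2.0, 4.0, 6.0, 8.0, 10.0])[0] == pytest.approx(1.0)
        assert spearman_rho(x, [10.0, 8.0, 6.0, 4.0, 2.0])[0] == pytest.approx(-1.0)

    def test_exact_p_equals_full_permutation_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.uniform(0, 2, 6)
            y = 0.5 * x + rng.uniform(0, 1, 6)
            rho, p = spearman_rho(x, y)
            assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)
            assert p == pytest.approx(spearman_permutation_p(x, y), abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 30)
        y = x + rng.uniform(0, 1, 30)
        rho, p = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_is_error(self):
        with pytest.raises(DomainError):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestMannWhitney:
    def test_exact_no_ties_matches_enumeration(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 4)
        y = rng.uniform(0.3, 1.3, 5)
        _, p, method = mann_whitney(x, y)
        assert method == "exact"
        assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 3.0, 3.0, 4.0, 4.0]
        _, p, method = mann_whitney(x, y)
        assert method == "exact"
        assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)

    def test_disjoint_support_small_groups(self):
        x = [5.0, 6.0, 7.0]
        y = [1.0, 2.0, 3.0, 4.0]
        _, p, _ = mann_whitney(x, y)
        assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)
        assert p == pytest.approx(2 / 35, abs=1e-12)  # 2 of C(7,3) assignments

    def test_large_samples_use_tie_corrected_asymptotics(self):
        rng = np.random.default_rng(9)
        x = np.round(rng.uniform(0, 5, 25), 0)
        y = np.round(rng.uniform(1, 6, 25), 0)
        _, p, method = mann_whitney(x, y)
        assert method == "asymptotic"
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestFisher:
    def test_published_sex_table_reproduces_printed_p(self):
        # female 1/6 cases vs 11/24 controls -> [[1, 5], [11, 13]]
        p = fisher_exact_2x2([[1, 5], [11, 13]])
        assert p == pytest.approx(fisher_enumeration_p([[1, 5], [11, 13]]), abs=1e-9)
        assert round(p, 3) == 0.358

    def test_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_enumeration_p(table), abs=1e-9
            )


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        import pandas as pd
        frame = pd.DataFrame({
            "group": ["case"] * 4 + ["control"] * 4,
            "x": [1.0, 2.0, 3.0, 4.0] * 2,
            "sex": ["female", "male"] * 4,
        })
        out = compare_groups(frame, ["x"], ["sex"])
        assert out["x"]["p"] == pytest.approx(1.0)
        assert out["sex"]["p"] == pytest.approx(1.0)

    def test_disjoint_support_matches_enumeration(self):
        import pandas as pd
        case_vals = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        ctrl_vals = list(np.arange(1.0, 25.0) / 10.0)
        frame = pd.DataFrame({
            "group": ["case"] * 6 + ["control"] * 24,
            "x": case_vals + ctrl_vals,
        })
        out = compare_groups(frame, ["x"])
        assert out["x"]["p"] == pytest.approx(2 / 593775, abs=1e-12)
        assert out["x"]["case"] == (7.5, 5.0, 10.0)

    def test_variable_absent_in_one_group_is_flagged(self):
        import pandas as pd
        frame = pd.DataFrame({
            "group": ["case", "case", "control", "control"],
            "x": [1.0, 2.0, None, None],
        })
        out = compare_groups(frame, ["x"])
        assert "skipped" in out["x"]


class TestBuildReport:
    def _diag(self):
        return DiagnosticReport(1.0, 6, 3, 21, 0, 1.0, 0.875, 100, 87)

    def test_missing_stage_is_named(self):
        with pytest.raises(PopscoreError, match="correlation"):
            build_report(flow={}, group_comparison={}, score_summary={},
                         diagnostics=self._diag(), correlation=None)

    def test_report_json_is_deterministic(self):
        kwargs = dict(
            flow={"n_final": 30}, group_comparison={},
            score_summary={"case": (1.1, 1.0, 2.0), "control": (0.8, 0.4, 1.7)},
            diagnostics=self._diag(), correlation=(0.34, 0.07),
        )
        a = json.dumps(build_report(**kwargs), sort_keys=True)
        b = json.dumps(build_report(**kwargs), sort_keys=True)
        assert a == b

    def test_confusion_block_consistent_with_counts(self):
        report = build_report(
            flow={}, group_comparison={}, score_summary={},
            diagnostics=self._diag(), correlation=(0.0, 1.0),
        )
        d = report["diagnostics"]
        assert d["sensitivity"] == d["tp"] / (d["tp"] + d["fn"])
        assert d["specificity"] == d["tn"] / (d["tn"] + d["fp"])
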