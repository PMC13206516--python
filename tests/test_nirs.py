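"""Stable-segment detection and protocol summarization."""

import numpy as np
import pytest

from helpers import exhaustive_stable_scan, make_session, make_trace
from popscore.errors import DomainError, InstabilityError
from popscore.model import BloodPressurePanel
from popscore.nirs import (
    compute_pftoe,
    detect_stable_segment,
    mean_sabp,
    stable_segments,
    summarize_ptoi,
    summarize_session,
    summarize_vitals,
)


class TestDetectStableSegment:
    def test_constant_trace_returns_earliest_window(self):
        trace = make_trace(np.full(60, 74.0))
        assert detect_stable_segment(trace, window=30, max_sd=1.0) == (0.0, 30.0)

    def test_window_starts_after_settling(self):
        # 20 s of alternating +-5 swings, then a 40-s plateau of sd ~0.3
        rng = np.random.default_rng(0)
        settle = 74.0 + 5.0 * (-1.0) ** np.arange(20)
        plateau = 74.0 + 0.3 * rng.standard_normal(40)
        trace = make_trace(np.concatenate([settle, plateau]))
        start, end = detect_stable_segment(trace, window=30, max_sd=1.0)
        assert 15.0 <= start <= 20.0  # swings keep any earlier window above sd 1
        assert end == start + 30.0

    def test_white_noise_raises_instability_with_min_sd(self):
        rng = np.random.default_rng(1)
        trace = make_trace(74.0 + 5.0 * rng.standard_normal(120))
        with pytest.raises(InstabilityError) as exc:
            detect_stable_segment(trace, window=30, max_sd=1.0)
        assert exc.value.min_sd is not None and exc.value.min_sd > 1.0

    def test_trace_shorter_than_window_is_domain_error(self):
        with pytest.raises(DomainError):
            detect_stable_segment(make_trace(np.full(20, 74.0)), window=30)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(35, 200))
        values = 74.0 + rng.choice([0.3, 1.5, 4.0]) * rng.standard_normal(n)
        if rng.random() < 0.5:  # prepend an unstable stretch
            values[: n // 3] += 6.0 * rng.standard_normal(n // 3)
        trace = make_trace(values)
        max_sd = float(rng.choice([0.5, 1.0, 2.0]))
        expected = exhaustive_stable_scan(trace, 30.0, max_sd)
        if expected is None:
            with pytest.raises(InstabilityError):
                detect_stable_segment(trace, window=30, max_sd=max_sd)
        else:
            assert detect_stable_segment(trace, window=30, max_sd=max_sd) == expected


class TestSummarizePtoi:
    def test_mean_of_five_segment_means(self):
        session = make_session([np.full(35, v) for v in (70, 72, 74, 76, 78)])
        ptoi, n_used = summarize_ptoi(session)
        assert ptoi == 74.0 and n_used == 5

    def test_idempotent_on_identical_segments(self):
        session = make_session([np.full(35, 74.5)] * 5)
        assert summarize_ptoi(session)[0] == 74.5

    def test_unstable_placements_are_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        noisy = lambda: 74.0 + 8.0 * rng.standard_normal(35)
        session = make_session(
            [np.full(35, 70.0), noisy(), np.full(35, 74.0), noisy(), np.full(35, 78.0)]
        )
        ptoi, n_used = summarize_ptoi(session, max_sd=1.0)
        assert ptoi == 74.0 and n_used == 3
        summary = summarize_session(session, max_sd=1.0)
        assert summary.n_segments_used == 3
        assert any("3 of 5" in f for f in summary.flags)

    def test_invariant_to_reapplication_order(self, cohort30):
        session = cohort30.sessions[0]
        shuffled = type(session)(
            neonate_id=session.neonate_id,
            reapplications=tuple(reversed(session.reapplications)),
            spo2_stream=session.spo2_stream,
            hr_stream=session.hr_stream,
            bp_panels=session.bp_panels,
        )
        assert summarize_ptoi(shuffled)[0] == pytest.approx(
            summarize_ptoi(session)[0], abs=1e-12
        )

    def test_zero_usable_segments_is_error(self):
        rng = np.random.default_rng(3)
        session = make_session([74.0 + 8.0 * rng.standard_normal(35) for _ in range(5)])
        with pytest.raises(InstabilityError):
            summarize_ptoi(session, max_sd=0.5)


class TestSummarizeVitals:
    def test_constant_streams(self):
        session = make_session([np.full(35, 74.5)] * 5, spo2=95.0, hr=158.0)
        windows, _, _ = stable_segments(session)
        assert summarize_vitals(session, windows) == (95.0, 158.0)

    def test_ramp_across_one_window_averages_to_midpoint(self):
        session = make_session(
            [np.full(30, 74.0)],
            hr=lambda t: 120.0 + (140.0 - 120.0) * t / len(t),
        )
        windows, _, _ = stable_segments(session)
        _, hr_mean = summarize_vitals(session, windows)
        assert hr_mean == pytest.approx(130.0, abs=0.5)

    def test_samples_only_outside_windows_is_error(self):
        session = make_session([np.full(35, 74.0)])
        with pytest.raises(DomainError):
            summarize_vitals(session, [(1000.0, 1030.0)])

    def test_no_windows_is_error(self):
        session = make_session([np.full(35, 74.0)])
        with pytest.raises(DomainError):
            summarize_vitals(session, [])


class TestMeanSabp:
    def test_mean_of_before_and_after(self):
        session = make_session([np.full(35, 74.0)], sabp=(58.0, 60.0))
        assert mean_sabp(session.bp_panels) == 59.0

    def test_identical_phases_returns_value(self):
        session = make_session([np.full(35, 74.0)], sabp=(61.0, 61.0))
        assert mean_sabp(session.bp_panels) == 61.0

    def test_missing_phase_is_error(self):
        panel = BloodPressurePanel("before", 58.0, 33.0, 43.0)
        with pytest.raises(DomainError, match="after"):
            mean_sabp((panel,))


class TestPftoe:
    def test_equal_inputs_give_zero(self):
        assert compute_pftoe(95.0, 95.0) == 0.0

    def test_published_case_medians(self):
        assert compute_pftoe(95.0, 74.5) == pytest.approx(0.21579, abs=5e-6)

    def test_negative_extraction_is_flagged_in_summary(self):
        assert compute_pftoe(90.0, 99.0) == pytest.approx(-0.1, abs=1e-12)
        session = make_session([np.full(35, 99.0)] * 5, spo2=90.0)
        summary = summarize_session(session)
        assert summary.pftoe < 0
        assert any("negative" in f for f in summary.flags)

    def test_nonpositive_spo2_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_pftoe(0.0, 74.0)


class TestSummarizeSession:
    def test_equals_composition_of_components(self, cohort30):
        session = cohort30.sessions[0]
        summary = summarize_session(session)
        windows, means, _ = stable_segments(session)
        ptoi, n_used = summarize_ptoi(session)
        spo2, hr = summarize_vitals(session, windows)
        sabp = mean_sabp(session.bp_panels)
        assert summary.ptoi_mean == ptoi
        assert summary.n_segments_used == n_used
        assert (summary.spo2_mean, summary.hr_mean) == (spo2, hr)
        assert summary.sabp_mean == sabp
        assert summary.pftoe == compute_pftoe(spo2, ptoi)

    def test_constant_signal_session_reproduces_inputs(self):
        session = make_session([np.full(35, 74.5)] * 5, spo2=95.0, hr=158.0,
                               sabp=(59.0, 59.0))
        s = summarize_session(session)
        assert (s.ptoi_mean, s.spo2_mean, s.hr_mean, s.sabp_mean) == \
               (74.5, 95.0, 158.0, 59.0)
        assert s.pftoe == pytest.approx(0.21579, abs=5e-6)

    def test_single_reapplication_yields_flagged_summary(self):
        session = make_session([np.full(35, 74.0)])
        s = summarize_session(session)
        assert s.n_segments_used == 1
        assert any("1 of 5" in f for f in s.flags)

    def test_pftoe_identity_holds_on_synthetic_cohort(self, cohort30):
        for session in cohort30.sessions:
            s = summarize_session(session)
            assert abs(s.pftoe - (s.spo2_mean - s.ptoi_mean) / s.spo2_mean) < 1e-12

    def test_hr_stream_does_not_affect_other_quantities(self, cohort30):
        session = cohort30.sessions[5]
        base = summarize_session(session)
        altered = type(session)(
            neonate_id=session.neonate_id,
            reapplications=session.reapplications,
            spo2_stream=session.spo2_stream,
            hr_stream=make_trace(
                np.full(len(session.hr_stream.times), 999.0), channel="HR",
            ),
            bp_panels=session.bp_panels,
        )
        modified = summarize_session(altered)
        assert modified.hr_mean != base.hr_mean
        assert (modified.ptoi_mean, modified.spo2_mean,
                modified.sabp_mean, modified.pftoe) == \
               (base.ptoi_mean, base.spo2_mean, base.sabp_mean, base.pftoe)

    def test_errors_carry_session_id(self):
        session = make_session([np.full(35, 74.0)], nid="z123")
        broken = type(session)(
            neonate_id="z123",
            reapplications=session.reapplications,
            spo2_stream=session.spo2_stream,
            hr_stream=session.hr_stream,
            bp_panels=(session.bp_panels[0],),
        )
        with pytest.raises(DomainError, match="z123"):
            summarize_session(broken)
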