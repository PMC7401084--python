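"""Transient detection, the abnormality rule, and scan summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catrace import (
    ConfigError,
    DataError,
    FluorescenceTrace,
    TransientEvent,
    TraceSimParams,
    simulate_trace,
    constant_baseline,
    detrend,
    detect_events,
    classify_events,
    summarize_scan,
    fold_change,
)
from conftest import run_pipeline, expected_labels


def make_events(amplitudes, returned=None):
    """Build a time-ordered event list from amplitudes and return flags."""
    returned = returned or [True] * len(amplitudes)
    return [
        TransientEvent(index=i, t_start_s=2.0 * i, t_peak_s=2.0 * i + 0.3,
                       t_end_s=2.0 * i + 1.5, amplitude=a,
                       returned_to_baseline=r)
        for i, (a, r) in enumerate(zip(amplitudes, returned))
    ]


def rule_oracle(amplitudes, returned, threshold=0.75):
    """Direct statement of the abnormality rule, evaluated event by event."""
    labels = []
    for i, (a, r) in enumerate(zip(amplitudes, returned)):
        if not r:
            labels.append("abnormal_double_peak")
        elif i > 0 and a < threshold * amplitudes[i - 1]:
            labels.append("abnormal_small_amplitude")
        else:
            labels.append("normal")
    return labels


class TestDetect:
    def test_flat_trace_has_no_events(self):
        tr = FluorescenceTrace(np.arange(400) * 0.075, np.full(400, 5.0))
        corrected = detrend(tr, constant_baseline(tr, 5.0))
        assert detect_events(corrected) == []

    def test_clean_train_recovered_exactly(self, clean_train):
        trace, truth = clean_train
        corrected = detrend(trace, constant_baseline(trace, 1.0))
        events = detect_events(corrected, smooth_s=0.0)
        assert len(events) == truth.n_events == 10
        for ev, t_true in zip(events, truth.event_times):
            assert ev.amplitude == pytest.approx(1.0, abs=1e-6)
            assert ev.returned_to_baseline
            assert ev.t_peak_s == pytest.approx(t_true, abs=1e-9)
            assert ev.t_start_s < ev.t_peak_s < ev.t_end_s

    def test_injected_double_peak_fails_return(self, clean_train_params):
        p = TraceSimParams(**{**clean_train_params.__dict__,
                              "p_double_peak": 1.0, "seed": 2})
        trace, truth = simulate_trace(p)
        corrected = detrend(trace, constant_baseline(trace, 1.0))
        events = detect_events(corrected, smooth_s=0.0)
        assert len(events) == truth.n_events
        for ev, lab in zip(events, truth.abnormal_flags):
            assert ev.returned_to_baseline == (lab != "double_peak")
            if lab == "double_peak":
                assert ev.n_peaks >= 2

    def test_all_nan_trace_is_error(self):
        tr = FluorescenceTrace(np.arange(100) * 0.075, np.ones(100))
        corrected = detrend(tr, constant_baseline(tr, 1.0))
        corrected.df_over_f0[:] = np.nan
        with pytest.raises(DataError, match="NaN"):
            detect_events(corrected)

    def test_short_trace_warns_and_returns_empty(self):
        tr = FluorescenceTrace(np.arange(3) * 0.075, np.array([1.0, 2.0, 1.0]))
        corrected = detrend(tr, constant_baseline(tr, 1.0))
        with pytest.warns(UserWarning, match="short"):
            assert detect_events(corrected, min_interval_s=10.0) == []

    def test_invalid_options_rejected(self):
        tr = FluorescenceTrace(np.arange(100) * 0.075, np.ones(100))
        corrected = detrend(tr, constant_baseline(tr, 1.0))
        with pytest.raises(ConfigError):
            detect_events(corrected, prominence_frac=1.5)
        with pytest.raises(ConfigError):
            detect_events(corrected, min_interval_s=0.0)


class TestClassify:
    @pytest.mark.parametrize(
        "amps,expected",
        [
            # 0.7 < 0.75*1.0 makes the middle event small; the third event's
            # ratio 1.0/0.7 clears the threshold again
            ([1.0, 0.7, 1.0],
             ["normal", "abnormal_small_amplitude", "normal"]),
            # 0.76 >= 0.75 and 0.58 >= 0.75*0.76 = 0.57: nothing abnormal
            ([1.0, 0.76, 0.58], ["normal", "normal", "normal"]),
        ],
    )
    def test_previous_amplitude_rule(self, amps, expected):
        labelled = classify_events(make_events(amps))
        assert [e.label for e in labelled] == expected
        assert [e.label for e in labelled] == rule_oracle(
            amps, [True] * len(amps)
        )

    def test_single_unreturned_event_is_double_peak(self):
        labelled = classify_events(make_events([1.0], returned=[False]))
        assert [e.label for e in labelled] == ["abnormal_double_peak"]

    def test_double_peak_takes_precedence_over_small_amplitude(self):
        labelled = classify_events(
            make_events([1.0, 0.5], returned=[True, False])
        )
        assert labelled[1].label == "abnormal_double_peak"

    def test_first_event_immune_to_amplitude_rule(self):
        labelled = classify_events(make_events([0.1, 1.0]))
        assert labelled[0].label == "normal"

    @given(
        amps=st.lists(st.floats(0.1, 10.0), min_size=1, max_size=12),
        returned=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_rule_oracle_and_is_causal(self, amps, returned):
        flags = [returned.draw(st.booleans()) for _ in amps]
        labelled = classify_events(make_events(amps, flags))
        assert [e.label for e in labelled] == rule_oracle(amps, flags)
        # causality: labels of a prefix never depend on later events
        k = len(amps) // 2 or 1
        prefix = classify_events(make_events(amps[:k], flags[:k]))
        assert [e.label for e in prefix] == [e.label for e in labelled][:k]


class TestSummarize:
    def test_percentage_arithmetic(self):
        events = classify_events(
            make_events([1.0] * 20,
                        returned=[True] * 18 + [False] * 2)
        )
        summary = summarize_scan(events, duration_s=300.0)
        assert summary.pct_abnormal == pytest.approx(10.0)
        assert summary.n_abnormal == 2

    def test_zero_abnormal_is_zero_percent(self):
        events = classify_events(make_events([1.0] * 20))
        assert summarize_scan(events, 300.0).pct_abnormal == 0.0

    def test_beat_rate(self):
        events = classify_events(make_events([1.0] * 150))
        assert summarize_scan(events, 300.0).beat_rate_bpm == pytest.approx(30.0)

    def test_empty_scan_reports_missing_not_zero(self):
        summary = summarize_scan([], 300.0)
        assert summary.pct_abnormal is None
        assert summary.n_events == 0


class TestFoldChange:
    def test_published_genotype_percentages_give_ten_fold(self):
        res = fold_change(11.2, 1.1)
        assert res["ratio"] == pytest.approx(10.18, abs=0.01)
        assert res["nearest_fold"] == 10

    def test_self_fold_is_one(self):
        assert fold_change(4.2, 4.2)["ratio"] == pytest.approx(1.0)

    def test_drug_comparison_ratio(self):
        assert fold_change(15.65, 6.7)["ratio"] == pytest.approx(2.34, abs=0.01)

    def test_zero_denominator_is_missing(self):
        assert fold_change(5.0, 0.0)["ratio"] is None


class TestPipelineAgainstGroundTruth:
    def test_noise_free_label_agreement(self):
        for seed in range(5):
            p = TraceSimParams(duration_s=120.0, noise_sd=0.0,
                               p_double_peak=0.08, p_small_amplitude=0.08,
                               seed=seed)
            trace, truth = simulate_trace(p)
            events, _ = run_pipeline(trace)
            assert [e.label for e in events] == expected_labels(truth)

    def test_lowering_small_ratio_never_decreases_abnormal_count(self):
        # ratios kept above the detection threshold so the injected events
        # stay detectable while becoming more clearly abnormal
        counts = []
        for ratio in (0.7, 0.6, 0.45):
            p = TraceSimParams(duration_s=300.0, noise_sd=0.0,
                               p_small_amplitude=0.1,
                               small_amplitude_ratio=ratio, seed=21)
            trace, truth = simulate_trace(p)
            events, _ = run_pipeline(trace)
            counts.append(sum(e.label != "normal" for e in events))
            assert counts[-1] == truth.n_abnormal
        assert counts[0] <= counts[1] <= counts[2]
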