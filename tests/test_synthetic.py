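"""Synthetic generator: determinism, ground-truth structure, noise scaling."""

import math

import numpy as np
import pytest

from catrace import (
    ConfigError,
    TraceSimParams,
    GroundTruth,
    collapse_to_trace,
    simulate_trace,
    simulate_linescan,
    simulate_cell_intensities,
    simulate_ct_table,
)


def params(**kw):
    base = dict(duration_s=60.0, noise_sd=0.0, seed=0)
    base.update(kw)
    return TraceSimParams(**base)


class TestSimulateTrace:
    def test_no_abnormality_gives_identical_normal_events(self):
        trace, truth = simulate_trace(
            params(duration_s=27.0, beat_rate_hz=0.4, amplitude=2.0,
                   bleach_tau_s=np.inf)
        )
        assert truth.n_events == 10
        assert all(lab == "normal" for lab in truth.abnormal_flags)
        assert np.allclose(truth.event_amplitudes, 2.0)

    def test_degenerate_constant_trace(self):
        trace, truth = simulate_trace(
            params(beat_rate_hz=0.0, bleach_tau_s=np.inf, f0=7.5)
        )
        assert truth.n_events == 0
        assert np.allclose(trace.intensity, 7.5)

    def test_seed_determinism_and_independence(self):
        p1 = params(noise_sd=3.0, seed=1)
        t1a, _ = simulate_trace(p1)
        t1b, _ = simulate_trace(params(noise_sd=3.0, seed=1))
        t2, _ = simulate_trace(params(noise_sd=3.0, seed=2))
        assert np.array_equal(t1a.intensity, t1b.intensity)
        assert not np.array_equal(t1a.intensity, t2.intensity)

    def test_event_times_strictly_increasing_and_jittered(self):
        _, truth = simulate_trace(params(duration_s=300.0, beat_rate_hz=0.5))
        t = np.array(truth.event_times)
        assert np.all(np.diff(t) > 0)
        # jitter makes intervals non-constant
        assert np.std(np.diff(t)) > 0.01

    def test_small_amplitude_injection_scales_amplitude(self):
        _, truth = simulate_trace(
            params(duration_s=300.0, p_small_amplitude=0.3,
                   small_amplitude_ratio=0.5, amplitude=10.0, seed=4)
        )
        small = [a for a, l in zip(truth.event_amplitudes, truth.abnormal_flags)
                 if l == "small_amplitude"]
        assert small and np.allclose(small, 5.0)

    def test_first_event_never_small_amplitude(self):
        for seed in range(10):
            _, truth = simulate_trace(
                params(duration_s=120.0, p_small_amplitude=0.9, seed=seed)
            )
            assert truth.abnormal_flags[0] != "small_amplitude"

    def test_no_consecutive_injected_abnormal(self):
        _, truth = simulate_trace(
            params(duration_s=300.0, p_double_peak=0.5, p_small_amplitude=0.5,
                   seed=5)
        )
        flags = truth.abnormal_flags
        assert all(
            not (a != "normal" and b != "normal")
            for a, b in zip(flags, flags[1:])
        )

    @pytest.mark.parametrize(
        "field,value",
        [
            ("duration_s", -1.0),
            ("line_period_s", 0.0),
            ("rise_tau_s", math.nan),
            ("noise_sd", -0.1),
            ("p_double_peak", 1.5),
            ("small_amplitude_ratio", 0.8),
        ],
    )
    def test_invalid_params_rejected_naming_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            params(**{field: value})


class TestSimulateLinescan:
    def test_single_pixel_no_noise_collapses_to_trace(self):
        p = params(duration_s=30.0, seed=3)
        scan, _ = simulate_linescan(p, n_pixels=1)
        trace, _ = simulate_trace(p)
        assert np.array_equal(collapse_to_trace(scan).intensity, trace.intensity)

    def test_row_mean_error_shrinks_with_pixel_count(self):
        # Monte-Carlo check of averaging: sd of (row-mean - clean trace)
        # stays below 1.5x the theoretical noise_sd/sqrt(n_pixels)
        errs = []
        for rep in range(100):
            p = params(duration_s=5.0, noise_sd=0.1, seed=1000 + rep)
            scan, _ = simulate_linescan(p, n_pixels=64)
            clean, _ = simulate_trace(
                TraceSimParams(**{**p.__dict__, "noise_sd": 0.0})
            )
            errs.append(collapse_to_trace(scan).intensity - clean.intensity)
        sd = np.std(np.concatenate(errs))
        assert sd < 1.5 * 0.1 / math.sqrt(64)

    def test_five_minute_scan_geometry(self):
        p = params(duration_s=300.0, line_period_s=0.075)
        scan, _ = simulate_linescan(p, n_pixels=4)
        assert scan.n_lines == 4000
        assert scan.duration_s == pytest.approx(300.0)

    def test_rejects_zero_pixels(self):
        with pytest.raises(ConfigError, match="n_pixels"):
            simulate_linescan(params(), n_pixels=0)


class TestSimulateCells:
    def test_all_positive(self):
        t = simulate_cell_intensities(100, 1.0, 100.0, 10.0, 1.0, seed=0)
        assert t["is_positive"].all()

    def test_empty_table_is_not_an_error(self):
        t = simulate_cell_intensities(0, 0.5, 100.0, 10.0, 1.0, seed=0)
        assert len(t) == 0

    def test_positive_fraction_within_binomial_bound(self):
        p, n = 0.9106, 100_000
        t = simulate_cell_intensities(n, p, 1000.0, 50.0, 30.0, seed=2)
        frac = t["is_positive"].mean()
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_rejects_inverted_means(self):
        with pytest.raises(ConfigError, match="mu_pos"):
            simulate_cell_intensities(10, 0.5, 10.0, 100.0, 1.0)


class TestSimulateCt:
    def test_fold_one_means_identical_delta_ct(self):
        t = simulate_ct_table(true_fold=1.0, noise_sd=0.0)
        ct = t.groupby(["sample_label", "gene_label"])["ct"].mean()
        d_cal = ct["calibrator", "TARGET"] - ct["calibrator", "HK"]
        d_sam = ct["sample", "TARGET"] - ct["sample", "HK"]
        assert d_sam == pytest.approx(d_cal)

    def test_fold_32_is_five_cycles(self):
        t = simulate_ct_table(true_fold=32.0, noise_sd=0.0)
        ct = t.groupby(["sample_label", "gene_label"])["ct"].mean()
        assert ct["calibrator", "TARGET"] - ct["sample", "TARGET"] == pytest.approx(5.0)

    def test_noisy_ddct_error_propagation(self):
        # ddCt of Ct means over r replicates has sd = noise*sqrt(4/r)
        sd, reps = 0.2, 3
        t = simulate_ct_table(true_fold=1000.0, noise_sd=sd, replicates=reps,
                              seed=7)
        ct = t.groupby(["sample_label", "gene_label"])["ct"].mean()
        ddct = (ct["sample", "TARGET"] - ct["sample", "HK"]) - (
            ct["calibrator", "TARGET"] - ct["calibrator", "HK"]
        )
        assert abs(ddct - (-math.log2(1000))) < 3 * sd * math.sqrt(4 / reps)

    def test_rejects_nonpositive_fold(self):
        with pytest.raises(ConfigError, match="true_fold"):
            simulate_ct_table(true_fold=0.0)


class TestGroundTruth:
    def test_validation(self):
        with pytest.raises(ConfigError):
            GroundTruth([1.0, 0.5], [1.0, 1.0], ["normal", "normal"])
        with pytest.raises(ConfigError):
            GroundTruth([1.0], [1.0, 2.0], ["normal", "normal"])

    def test_json_round_trip(self, tmp_path):
        g = GroundTruth([1.0, 2.5], [3.0, 1.5], ["normal", "double_peak"])
        path = g.to_json(tmp_path / "truth.json")
        g2 = GroundTruth.from_json(path)
        assert g2 == g
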