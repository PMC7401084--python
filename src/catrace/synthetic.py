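"""Synthetic line scans, traces, per-cell intensity tables and qPCR Ct tables.

The trace simulator emulates a spontaneously beating cardiomyocyte expressing
a genetically encoded Ca2+ indicator, acquired in confocal line-scan mode:
a train of Ca2+ transients (difference-of-exponentials kernel) riding on a
monoexponentially photobleaching baseline, plus i.i.d. additive Gaussian
noise.  Two abnormality classes can be injected with known probability:

``double_peak``
    the transient fails to return to baseline and shows a secondary peak
    (the inter-peak trough is clamped well above baseline), violating the
    return-to-baseline criterion by construction;
``small_amplitude``
    the transient's amplitude is scaled below 75% of its predecessor's,
    violating the previous-amplitude criterion by construction.

Every injected event is recorded in a :class:`GroundTruth` sidecar so that
detector and classifier output can be scored against known labels.  An
abnormal event is never followed immediately by another injected abnormal
event; this keeps the ground-truth labels exactly consistent with the
previous-amplitude rule (no ambiguous runs of small transients).

All randomness flows from a single integer seed through independent
substreams (event structure, trace noise, pixel noise), so a line scan and
a trace simulated from the same seed share the same underlying beat train.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import LineScan, FluorescenceTrace, DEFAULT_LINE_PERIOD_S

NORMAL = "normal"
DOUBLE_PEAK = "double_peak"
SMALL_AMPLITUDE = "small_amplitude"
LABELS = (NORMAL, DOUBLE_PEAK, SMALL_AMPLITUDE)

#: Secondary-peak scale and inter-peak trough clamp for injected double peaks,
#: as fractions of the primary amplitude.  The trough is held at 0.40 x
#: amplitude — above the default 0.25 return tolerance with margin to spare
#: at signal-to-noise 10 — so the event fails the return-to-baseline test
#: by construction.
DOUBLE_PEAK_SECONDARY_SCALE = 0.7
DOUBLE_PEAK_TROUGH_FRAC = 0.40
#: Secondary peak offset, as a fraction of the beat cycle after the primary.
#: The secondary hump uses halved rise/decay time constants so the composite
#: transient still settles back to baseline well before the next beat.
DOUBLE_PEAK_OFFSET_FRAC = 0.30

#: Uniform jitter applied to event times, as a fraction of the mean interval.
EVENT_JITTER_FRAC = 0.10


@dataclass
class TraceSimParams:
    """Parameters of the synthetic Ca2+ transient trace generator.

    Defaults describe a five-minute line-scan acquisition (75 ms/line) of a
    cell beating at 0.5 Hz with transient kinetics typical of immature
    cardiomyocytes (rise ~50 ms, decay ~400 ms) and mild photobleaching.
    """

    duration_s: float = 300.0
    line_period_s: float = DEFAULT_LINE_PERIOD_S
    beat_rate_hz: float = 0.4
    amplitude: float = 100.0
    rise_tau_s: float = 0.15
    decay_tau_s: float = 0.3
    f0: float = 100.0
    bleach_tau_s: float = 600.0  # may be math.inf for no bleaching
    noise_sd: float = 2.0
    p_double_peak: float = 0.0
    p_small_amplitude: float = 0.0
    small_amplitude_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "duration_s": self.duration_s,
            "line_period_s": self.line_period_s,
            "amplitude": self.amplitude,
            "rise_tau_s": self.rise_tau_s,
            "decay_tau_s": self.decay_tau_s,
            "f0": self.f0,
            "bleach_tau_s": self.bleach_tau_s,
        }
        for name, val in positive.items():
            if math.isnan(val) or val <= 0:
                raise ConfigError(f"{name} must be positive, got {val}")
        for name, val in {
            "beat_rate_hz": self.beat_rate_hz,
            "noise_sd": self.noise_sd,
        }.items():
            if not math.isfinite(val) or val < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {val}")
        for name, val in {
            "p_double_peak": self.p_double_peak,
            "p_small_amplitude": self.p_small_amplitude,
        }.items():
            if not (0.0 <= val <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if self.p_double_peak + self.p_small_amplitude > 1.0:
            raise ConfigError("p_double_peak + p_small_amplitude must be <= 1")
        if not (0.0 < self.small_amplitude_ratio < 0.75):
            raise ConfigError(
                "small_amplitude_ratio must be in (0, 0.75) so that injected "
                f"events are abnormal by construction, got {self.small_amplitude_ratio}"
            )
        if self.rise_tau_s >= self.decay_tau_s:
            raise ConfigError(
                "rise_tau_s must be smaller than decay_tau_s "
                f"({self.rise_tau_s} >= {self.decay_tau_s})"
            )


@dataclass
class GroundTruth:
    """Injected events of one simulated scan: times, amplitudes and labels."""

    event_times: list[float] = field(default_factory=list)
    event_amplitudes: list[float] = field(default_factory=list)
    abnormal_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.event_times)
        if len(self.event_amplitudes) != n or len(self.abnormal_flags) != n:
            raise ConfigError("ground-truth lists must have equal length")
        if any(b <= a for a, b in zip(self.event_times, self.event_times[1:])):
            raise ConfigError("ground-truth event times must be strictly increasing")
        for lab in self.abnormal_flags:
            if lab not in LABELS:
                raise ConfigError(f"unknown label {lab!r}")

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def n_abnormal(self) -> int:
        return sum(1 for lab in self.abnormal_flags if lab != NORMAL)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        events = [
            {"t": t, "amplitude": a, "label": lab}
            for t, a, lab in zip(
                self.event_times, self.event_amplitudes, self.abnormal_flags
            )
        ]
        path.write_text(json.dumps({"events": events}, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        ev = obj["events"]
        return cls(
            [e["t"] for e in ev],
            [e["amplitude"] for e in ev],
            [e["label"] for e in ev],
        )


def _kernel(dt: float, rise_tau: float, decay_tau: float, length: int) -> np.ndarray:
    """Difference-of-exponentials transient kernel sampled on the grid.

    Normalized so the sampled maximum is exactly 1; the returned array starts
    at the event onset (value 0) and the peak sits at ``argmax``.
    """
    s = np.arange(length) * dt
    k = np.exp(-s / decay_tau) - np.exp(-s / rise_tau)
    peak = k.max()
    if peak <= 0:
        raise ConfigError("degenerate transient kernel; check rise/decay taus")
    return k / peak


def _event_schedule(params: TraceSimParams, rng: np.random.Generator):
    """Jittered event peak times (grid-snapped indices) and labels."""
    dt = params.line_period_s
    n = int(round(params.duration_s / dt))
    if params.beat_rate_hz == 0:
        return n, [], []
    period = 1.0 / params.beat_rate_hz
    tail_margin = max(0.6 * period, 3.0 * params.decay_tau_s)
    peak_indices: list[int] = []
    labels: list[str] = []
    k = 0
    while True:
        t_nom = (k + 0.75) * period
        jitter = rng.uniform(-EVENT_JITTER_FRAC, EVENT_JITTER_FRAC) * period
        t_peak = t_nom + jitter
        if t_peak > params.duration_s - tail_margin:
            break
        idx = int(round(t_peak / dt))
        u = rng.uniform()
        if labels and labels[-1] != NORMAL:
            lab = NORMAL  # never two injected abnormal events in a row
        elif u < params.p_double_peak:
            lab = DOUBLE_PEAK
        elif u < params.p_double_peak + params.p_small_amplitude and labels:
            # the previous-amplitude rule cannot judge the first event,
            # so a small-amplitude injection there would be unlabelable
            lab = SMALL_AMPLITUDE
        else:
            lab = NORMAL
        if peak_indices and idx <= peak_indices[-1]:
            idx = peak_indices[-1] + 1
        peak_indices.append(idx)
        labels.append(lab)
        k += 1
    return n, peak_indices, labels


def _clean_signal(params: TraceSimParams) -> tuple[np.ndarray, GroundTruth]:
    """Noise-free transient train plus photobleaching baseline."""
    dt = params.line_period_s
    rng_events = np.random.default_rng([int(params.seed), 0])
    n, peak_indices, labels = _event_schedule(params, rng_events)
    t = np.arange(n) * dt

    if math.isinf(params.bleach_tau_s):
        signal = np.full(n, params.f0, dtype=float)
    else:
        signal = params.f0 * np.exp(-t / params.bleach_tau_s)

    kern_len = min(n, max(8, int(round(10.0 * params.decay_tau_s / dt))))
    kern = _kernel(dt, params.rise_tau_s, params.decay_tau_s, kern_len)
    j_peak = int(np.argmax(kern))
    # narrower kernel for the secondary hump of injected double peaks
    kern2 = _kernel(dt, params.rise_tau_s / 2.0, params.decay_tau_s / 2.0, kern_len)
    j2_peak = int(np.argmax(kern2))
    period = 1.0 / params.beat_rate_hz if params.beat_rate_hz else 0.0

    times: list[float] = []
    amps: list[float] = []
    out_labels: list[str] = []
    for idx, lab in zip(peak_indices, labels):
        amp = params.amplitude
        if lab == SMALL_AMPLITUDE:
            amp *= params.small_amplitude_ratio
        wave = np.zeros(n)
        i0 = idx - j_peak
        _add_kernel(wave, kern, i0, amp)
        if lab == DOUBLE_PEAK:
            off = int(round(DOUBLE_PEAK_OFFSET_FRAC * period / dt))
            i2_peak = idx + max(off, 1)
            _add_kernel(wave, kern2, i2_peak - j2_peak, DOUBLE_PEAK_SECONDARY_SCALE * amp)
            lo, hi = idx, min(i2_peak, n - 1)
            if hi > lo:
                clamp = DOUBLE_PEAK_TROUGH_FRAC * amp
                seg = wave[lo : hi + 1]
                np.maximum(seg, clamp, out=seg)
        signal += wave
        times.append(idx * dt)
        amps.append(amp)
        out_labels.append(lab)
    return signal, GroundTruth(times, amps, out_labels)


def _add_kernel(wave: np.ndarray, kern: np.ndarray, i0: int, amp: float) -> None:
    n = wave.size
    lo = max(i0, 0)
    hi = min(i0 + kern.size, n)
    if hi > lo:
        wave[lo:hi] += amp * kern[lo - i0 : hi - i0]


def simulate_trace(params: TraceSimParams) -> tuple[FluorescenceTrace, GroundTruth]:
    """Simulate one fluorescence trace with labelled ground truth.

    The trace is ``f0 * exp(-t / bleach_tau_s) + sum of transients +
    N(0, noise_sd)``.  Identical seeds give bit-identical output.
    """
    params.validate()
    signal, truth = _clean_signal(params)
    rng_noise = np.random.default_rng([int(params.seed), 1])
    if params.noise_sd > 0:
        signal = signal + rng_noise.normal(0.0, params.noise_sd, signal.size)
    t = np.arange(signal.size) * params.line_period_s
    trace = FluorescenceTrace(t, signal, origin_label=f"sim(seed={params.seed})")
    return trace, truth


def simulate_linescan(
    params: TraceSimParams, n_pixels: int
) -> tuple[LineScan, GroundTruth]:
    """Simulate a kymograph whose row-means recover the underlying trace.

    Each scan line holds the noise-free trace value at that line's time plus
    independent per-pixel Gaussian noise of standard deviation ``noise_sd``,
    so the row-mean error shrinks as ``noise_sd / sqrt(n_pixels)``.
    """
    params.validate()
    if n_pixels < 1:
        raise ConfigError(f"n_pixels must be >= 1, got {n_pixels}")
    signal, truth = _clean_signal(params)
    rng_noise = np.random.default_rng([int(params.seed), 1])
    matrix = signal[:, None] + (
        rng_noise.normal(0.0, params.noise_sd, (signal.size, n_pixels))
        if params.noise_sd > 0
        else 0.0
    )
    matrix = np.maximum(matrix, 0.0)  # fluorescence counts are non-negative
    scan = LineScan(
        matrix,
        line_period_s=params.line_period_s,
        origin_label=f"sim(seed={params.seed})",
    )
    return scan, truth


def simulate_cell_intensities(
    n_cells: int,
    p_positive: float,
    mu_pos: float,
    mu_neg: float,
    sd: float,
    seed: int = 0,
    condition_label: str = "sim",
    timepoint_label: str = "t0",
) -> pd.DataFrame:
    """Two-component Gaussian mixture of per-cell reporter intensities.

    Returns a table with columns ``cell_id, condition_label, timepoint_label,
    intensity, is_positive`` where ``is_positive`` is the true component
    membership.  Intensities are floored at a tiny positive value so that
    log-domain thresholding is always defined.
    """
    if not (0.0 <= p_positive <= 1.0):
        raise ConfigError(f"p_positive must be in [0, 1], got {p_positive}")
    if mu_pos <= mu_neg:
        raise ConfigError(
            f"mu_pos must exceed mu_neg (got {mu_pos} <= {mu_neg}); "
            "the positivity threshold is undefined otherwise"
        )
    rng = np.random.default_rng(int(seed))
    positive = rng.uniform(size=n_cells) < p_positive
    mu = np.where(positive, mu_pos, mu_neg)
    intensity = rng.normal(mu, sd) if n_cells else np.array([])
    # detector floor: a Gaussian tail below zero is unphysical for
    # fluorescence, and a tight floor keeps log-domain thresholding sane
    intensity = np.maximum(intensity, 1e-3 * max(mu_pos, 1.0))
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "condition_label": condition_label,
            "timepoint_label": timepoint_label,
            "intensity": intensity,
            "is_positive": positive,
        }
    )


def simulate_ct_table(
    true_fold: float,
    ct_housekeeping: float = 20.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    target_gene: str = "TARGET",
    housekeeping_gene: str = "HK",
    sample_label: str = "sample",
    calibrator_label: str = "calibrator",
    ct_target_calibrator: float = 28.0,
) -> pd.DataFrame:
    """Forward model of perfect-efficiency qPCR for the ddCt method.

    The sample's target Ct sits ``log2(true_fold)`` cycles below the
    calibrator's; housekeeping Ct is identical in expectation across samples.
    Gaussian cycle noise of ``noise_sd`` is added per replicate.
    """
    if not (true_fold > 0) or not math.isfinite(true_fold):
        raise ConfigError(f"true_fold must be positive and finite, got {true_fold}")
    if replicates < 1:
        raise ConfigError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(int(seed))
    rows = []
    means = {
        (calibrator_label, housekeeping_gene): ct_housekeeping,
        (calibrator_label, target_gene): ct_target_calibrator,
        (sample_label, housekeeping_gene): ct_housekeeping,
        (sample_label, target_gene): ct_target_calibrator - math.log2(true_fold),
    }
    for (sample, gene), mean_ct in means.items():
        for rep in range(replicates):
            ct = mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "sample_label": sample,
                    "gene_label": gene,
                    "replicate_id": rep,
                    "ct": ct,
                }
            )
    return pd.DataFrame(rows)


def params_to_dict(params: TraceSimParams) -> dict:
    """JSON-serializable dump (inf encoded as the string 'inf')."""
    d = asdict(params)
    if math.isinf(d["bleach_tau_s"]):
        d["bleach_tau_s"] = "inf"
    return d


def params_from_dict(d: dict) -> TraceSimParams:
    d = dict(d)
    if d.get("bleach_tau_s") in ("inf", ".inf", "Infinity"):
        d["bleach_tau_s"] = math.inf
    return TraceSimParams(**d)
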