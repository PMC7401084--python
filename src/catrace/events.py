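"""Ca2+ transient detection, abnormality classification and scan summaries.

Detection runs on a baseline-corrected (dF/F0) trace.  Candidate peaks are
found by prominence on a median-filtered copy of the trace; successive
candidate peaks with no return to baseline between them are merged into a
single multi-peak event — that is what a "double peak" is: one transient
whose fluorescence rises again before ever reaching baseline.

Classification applies the abnormality rule used for spontaneously beating
cardiomyocyte recordings: a transient is abnormal if it

(a) fails to return to baseline and shows a double peak, or
(b) has an amplitude below 75% of the previous transient's amplitude.

Criterion (a) takes precedence when both hold (one event, one label; the
return failure is the more specific defect), and the first event of a scan
can only be abnormal via (a) because it has no predecessor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .baseline import CorrectedTrace
from .errors import ConfigError, DataError

LABEL_NORMAL = "normal"
LABEL_DOUBLE_PEAK = "abnormal_double_peak"
LABEL_SMALL_AMPLITUDE = "abnormal_small_amplitude"

#: Default fraction of an event's own amplitude above its pre-event baseline
#: within which the trace must fall back to count as "returned to baseline".
DEFAULT_RETURN_TOLERANCE_FRAC = 0.25
#: Default prominence threshold as a fraction of the robust (1st-99th
#: percentile) range of the corrected trace.
DEFAULT_PROMINENCE_FRAC = 0.2
#: Default minimum peak separation; resolves beating up to ~3 Hz.
DEFAULT_MIN_INTERVAL_S = 0.3
#: Window before event onset over which the pre-event baseline is the median.
#: Kept well inside the inter-beat valley at spontaneous rates up to ~1 Hz;
#: a longer window averages down baseline noise, which the amplitude ratio
#: of the abnormality rule is directly sensitive to.
DEFAULT_BASELINE_WINDOW_S = 0.75
#: Span of the Savitzky-Golay (order 2) filter used as the measurement trace
#: for peaks, amplitudes and baseline-return checks; 0 disables smoothing.
DEFAULT_SMOOTH_S = 0.5
#: Number of consecutive smoothed samples that must sit at or below the
#: return threshold for a transient to count as returned to baseline; a
#: single dipping sample is treated as noise.
RETURN_RUN_SAMPLES = 2


@dataclass
class TransientEvent:
    """One detected Ca2+ transient."""

    index: int
    t_start_s: float
    t_peak_s: float
    t_end_s: float
    amplitude: float
    returned_to_baseline: bool
    n_peaks: int = 1
    pre_baseline: float = 0.0
    amplitude_ratio_to_previous: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (self.t_start_s < self.t_peak_s < self.t_end_s):
            raise DataError(
                f"event {self.index}: need t_start < t_peak < t_end, got "
                f"({self.t_start_s}, {self.t_peak_s}, {self.t_end_s})"
            )
        if not (self.amplitude > 0):
            raise DataError(f"event {self.index}: amplitude must be positive")


@dataclass
class ScanSummary:
    """Per-scan statistics: event count, beat rate and abnormal fraction."""

    n_events: int
    duration_s: float
    n_abnormal: int
    n_double_peak: int
    n_small_amplitude: int

    @property
    def n_normal(self) -> int:
        return self.n_events - self.n_abnormal

    @property
    def beat_rate_bpm(self) -> float:
        return 60.0 * self.n_events / self.duration_s

    @property
    def pct_abnormal(self) -> float | None:
        """Percent of events deemed abnormal; None (missing) for empty scans."""
        if self.n_events == 0:
            return None
        return 100.0 * self.n_abnormal / self.n_events

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "duration_s": self.duration_s,
            "beat_rate_bpm": self.beat_rate_bpm,
            "n_abnormal": self.n_abnormal,
            "n_double_peak": self.n_double_peak,
            "n_small_amplitude": self.n_small_amplitude,
            "pct_abnormal": self.pct_abnormal,
        }


def detect_events(
    trace: CorrectedTrace,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_interval_s: float = DEFAULT_MIN_INTERVAL_S,
    return_tolerance_frac: float = DEFAULT_RETURN_TOLERANCE_FRAC,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    smooth_s: float = DEFAULT_SMOOTH_S,
) -> list[TransientEvent]:
    """Detect transient events on a corrected trace (unlabelled).

    Peaks with prominence at least ``prominence_frac`` times the robust
    (1st-99th percentile) range of the trace and separation at least
    ``min_interval_s`` are candidates.  A candidate whose preceding trough
    stays above ``pre_baseline + return_tolerance_frac * amplitude`` of the
    running event is merged into it (double/multi-peak transient).  Each
    event's pre-event baseline is the median of the corrected trace over
    ``baseline_window_s`` before its onset, and its amplitude is the raw
    peak value minus that baseline.
    """
    if not (0.0 < prominence_frac < 1.0):
        raise ConfigError(f"prominence_frac must be in (0, 1), got {prominence_frac}")
    if not (min_interval_s > 0):
        raise ConfigError(f"min_interval_s must be > 0, got {min_interval_s}")
    y = trace.df_over_f0
    if np.all(np.isnan(y)):
        raise DataError("all-NaN trace")
    dt = trace.dt_s
    n = y.size
    if trace.duration_s < min_interval_s:
        warnings.warn("trace shorter than min_interval_s; no events detected",
                      stacklevel=2)
        return []

    ys = _measurement_trace(y, dt, smooth_s)

    p1, p99 = np.percentile(ys, [1.0, 99.0])
    robust_range = p99 - p1
    if robust_range <= 0:
        return []
    prominence = prominence_frac * robust_range
    distance = max(1, int(round(min_interval_s / dt)))
    peaks, _ = find_peaks(ys, prominence=prominence, distance=distance)
    if peaks.size == 0:
        return []

    base_win = max(1, int(round(baseline_window_s / dt)))
    tol = return_tolerance_frac
    smoothing = smooth_s > 0 and ys is not y

    def peak_height(idx: int) -> float:
        # with smoothing on, average the three samples bracketing the apex
        if smoothing and 0 < idx < n - 1:
            return float(np.mean(ys[idx - 1 : idx + 2]))
        return float(ys[idx])

    groups: list[dict] = []
    for pk in (int(p) for p in peaks):
        if groups:
            g = groups[-1]
            thr = g["base"] + tol * g["amp"]
            if not _sustained_below(ys[g["peaks"][-1] : pk + 1], thr):
                # no baseline return since the previous peak: same transient
                g["peaks"].append(pk)
                g["amp"] = max(g["amp"], peak_height(pk) - g["base"])
                continue
            seg_lo = g["peaks"][-1]
        else:
            seg_lo = 0
        # event onset: the last near-minimum sample of the preceding valley,
        # so the pre-baseline window sits in the valley floor, not on the
        # previous transient's decay tail
        seg = ys[seg_lo:pk]
        if seg.size == 0:
            start = max(pk - 1, 0)
        else:
            vmin = float(seg.min())
            near_min = np.flatnonzero(seg <= vmin + 0.5 * prominence)
            start = seg_lo + int(near_min[-1])
        base = float(np.median(y[max(start - base_win + 1, 0) : start + 1]))
        groups.append({"peaks": [pk], "start": start, "base": base,
                       "amp": peak_height(pk) - base})

    # peaks inside the smoothing window of either trace edge are truncated
    # and cannot be measured or scored reliably
    edge_guard = max(1, int(round(max(smooth_s, dt) / dt)))

    events: list[TransientEvent] = []
    for gi, g in enumerate(groups):
        main = max(g["peaks"], key=lambda i: ys[i])
        last = g["peaks"][-1]
        if gi + 1 < len(groups):
            nxt = groups[gi + 1]["peaks"][0]
            end = last + int(np.argmin(ys[last : nxt + 1]))
        else:
            end = n - 1
        end = min(max(end, main + 1), n - 1)
        start = min(g["start"], main - 1)
        if start < 0 or end <= main:
            continue  # peak flush against a trace edge: not a scoreable event
        if main < edge_guard or main >= n - edge_guard:
            continue
        amp = peak_height(main) - g["base"]
        if amp < prominence:
            # height above the event's own pre-baseline must meet the same
            # threshold as the peak prominence; slope-riding noise bumps can
            # have inflated prominences but tiny amplitudes
            continue
        if len(g["peaks"]) > 1:
            returned = False
        else:
            thr = g["base"] + tol * amp
            returned = _sustained_below(ys[main : end + 1], thr)
        events.append(
            TransientEvent(
                index=len(events),
                t_start_s=float(trace.time_s[start]),
                t_peak_s=float(trace.time_s[main]),
                t_end_s=float(trace.time_s[end]),
                amplitude=amp,
                returned_to_baseline=returned,
                n_peaks=len(g["peaks"]),
                pre_baseline=g["base"],
            )
        )
    return events


def _measurement_trace(y: np.ndarray, dt: float, smooth_s: float) -> np.ndarray:
    """Savitzky-Golay (order 2) smoothed copy used for all measurements.

    The quadratic fit preserves smooth transient peaks while averaging down
    per-sample noise; ``smooth_s = 0`` returns the raw trace (useful for
    noise-free data where exact sample values are wanted).
    """
    if smooth_s <= 0:
        return y
    win = int(round(smooth_s / dt))
    if win % 2 == 0:
        win += 1
    if win < 5 or win >= y.size:
        return y
    return savgol_filter(y, win, polyorder=2)


def _sustained_below(segment: np.ndarray, threshold: float) -> bool:
    """True if the segment holds at or below threshold for a sustained run.

    Requires :data:`RETURN_RUN_SAMPLES` consecutive samples at or below the
    threshold (any sample suffices for very short segments), so that a
    single noise dip does not count as a baseline return.
    """
    below = segment <= threshold
    if segment.size < RETURN_RUN_SAMPLES:
        return bool(below.any())
    run = 0
    for b in below:
        run = run + 1 if b else 0
        if run >= RETURN_RUN_SAMPLES:
            return True
    return False


def classify_events(
    events: list[TransientEvent],
    ratio_threshold: float = 0.75,
) -> list[TransientEvent]:
    """Label events as normal / abnormal by the double-peak and 75% rules.

    Event *i* is ``abnormal_double_peak`` if it did not return to baseline;
    otherwise ``abnormal_small_amplitude`` if ``amplitude_i <
    ratio_threshold * amplitude_{i-1}``; otherwise ``normal``.  The label of
    an event depends only on its own return flag and the amplitude of its
    immediate predecessor, so relabelling is causal.
    """
    if not (0.0 < ratio_threshold < 1.0):
        raise ConfigError(f"ratio_threshold must be in (0, 1), got {ratio_threshold}")
    out: list[TransientEvent] = []
    prev_amp: float | None = None
    for ev in events:
        ratio = None if prev_amp is None else ev.amplitude / prev_amp
        if not ev.returned_to_baseline:
            label = LABEL_DOUBLE_PEAK
        elif ratio is not None and ratio < ratio_threshold:
            label = LABEL_SMALL_AMPLITUDE
        else:
            label = LABEL_NORMAL
        out.append(replace(ev, amplitude_ratio_to_previous=ratio, label=label))
        prev_amp = ev.amplitude
    return out


def summarize_scan(events: list[TransientEvent], duration_s: float) -> ScanSummary:
    """Aggregate labelled events into per-scan statistics."""
    if not (duration_s > 0):
        raise ConfigError(f"duration_s must be > 0, got {duration_s}")
    n_dp = sum(1 for e in events if e.label == LABEL_DOUBLE_PEAK)
    n_sa = sum(1 for e in events if e.label == LABEL_SMALL_AMPLITUDE)
    if any(e.label is None for e in events):
        raise DataError("events must be classified before summarizing")
    return ScanSummary(
        n_events=len(events),
        duration_s=float(duration_s),
        n_abnormal=n_dp + n_sa,
        n_double_peak=n_dp,
        n_small_amplitude=n_sa,
    )


def fold_change(pct_a: float, pct_b: float) -> dict:
    """Ratio of two percentages, with its nearest-integer fold.

    ``pct_b = 0`` yields a missing ratio (None), not an error.
    """
    if pct_b == 0:
        return {"ratio": None, "nearest_fold": None}
    ratio = pct_a / pct_b
    return {"ratio": ratio, "nearest_fold": int(round(ratio))}


def events_to_dataframe(events: list[TransientEvent]) -> pd.DataFrame:
    """Flatten events for CSV export."""
    return pd.DataFrame(
        [
            {
                "index": e.index,
                "t_start_s": e.t_start_s,
                "t_peak_s": e.t_peak_s,
                "t_end_s": e.t_end_s,
                "amplitude": e.amplitude,
                "returned_to_baseline": e.returned_to_baseline,
                "n_peaks": e.n_peaks,
                "ratio_to_previous": e.amplitude_ratio_to_previous,
                "label": e.label,
            }
            for e in events
        ]
    )
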