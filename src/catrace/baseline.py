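"""Photobleaching baseline correction and dF/F0 normalization.

Confocal time series of fluorescent Ca2+ reporters decay slowly as the
fluorophore photobleaches; to first order the decay of the resting baseline
is monoexponential.  Two baseline models are provided:

``exponential`` (default)
    least-squares fit of ``f_inf + a * exp(-t / tau)`` to the trace's lower
    envelope — the samples at or below a rolling 20th-percentile track — so
    that the positive-going transients do not bias the fit;
``rolling_percentile``
    a centered rolling-window percentile track (default 10 s window, 10th
    percentile), used directly as the baseline and as the fallback when the
    exponential fit does not converge.

The corrected trace is ``dF/F0 = (F - B) / B`` with F0 the fitted baseline
itself, i.e. time-varying; this is scale invariant and robust to bleaching
over multi-minute scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import percentile_filter
from scipy.optimize import curve_fit

from .errors import ConfigError, DataError
from .io import FluorescenceTrace

EXPONENTIAL = "exponential"
ROLLING_PERCENTILE = "rolling_percentile"

#: Percentile used to build the lower-envelope mask for the exponential fit.
ENVELOPE_PERCENTILE = 20.0


@dataclass
class BaselineModel:
    """Fitted baseline: model kind, parameters and per-sample values."""

    kind: str
    params: dict
    fitted_values: np.ndarray

    def __post_init__(self) -> None:
        self.fitted_values = np.asarray(self.fitted_values, dtype=float)


@dataclass
class CorrectedTrace:
    """Baseline-corrected trace in dF/F0 units."""

    time_s: np.ndarray
    df_over_f0: np.ndarray
    baseline: BaselineModel
    f0_definition: str = "fitted baseline (time-varying)"
    origin_label: str = field(default="")

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.df_over_f0 = np.asarray(self.df_over_f0, dtype=float)

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0]) if self.time_s.size > 1 else float("nan")

    @property
    def duration_s(self) -> float:
        if self.time_s.size < 2:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0] + self.dt_s)

    def __len__(self) -> int:
        return int(self.time_s.size)


def _window_samples(window_s: float, dt: float, n: int) -> int:
    w = int(round(window_s / dt))
    w = max(3, min(w, n))
    if w % 2 == 0:
        w += 1 if w < n else -1
    return max(w, 1)


def _rolling_percentile_track(
    intensity: np.ndarray, dt: float, window_s: float, percentile: float
) -> np.ndarray:
    size = _window_samples(window_s, dt, intensity.size)
    return percentile_filter(intensity, percentile, size=size, mode="nearest")


def fit_baseline(
    trace: FluorescenceTrace,
    kind: str = EXPONENTIAL,
    window_s: float = 10.0,
    percentile: float = 10.0,
) -> BaselineModel:
    """Fit a photobleaching baseline to a raw fluorescence trace.

    Parameters
    ----------
    trace
        Raw trace; at least 10 samples.
    kind
        ``"exponential"`` or ``"rolling_percentile"``.
    window_s
        Rolling window span in seconds (both kinds use it: the exponential
        kind builds its lower-envelope mask from a rolling 20th percentile
        over this window).
    percentile
        Percentile of the ``rolling_percentile`` track, in (0, 50].

    An exponential fit that fails to converge falls back to the rolling
    percentile with a warning; a baseline that is not strictly positive
    anywhere raises :class:`DataError`.
    """
    if len(trace) < 10:
        raise DataError(f"trace too short to fit a baseline ({len(trace)} samples)")
    if kind not in (EXPONENTIAL, ROLLING_PERCENTILE):
        raise ConfigError(f"unknown baseline kind {kind!r}")
    if not (0.0 < percentile <= 50.0):
        raise ConfigError(f"percentile must be in (0, 50], got {percentile}")
    t = trace.time_s - trace.time_s[0]
    y = trace.intensity
    dt = trace.dt_s

    if kind == ROLLING_PERCENTILE:
        fitted = _rolling_percentile_track(y, dt, window_s, percentile)
        model = BaselineModel(
            ROLLING_PERCENTILE,
            {"window_s": window_s, "percentile": percentile},
            fitted,
        )
    else:
        model = _fit_exponential(t, y, dt, window_s)
        if model is None:
            warnings.warn(
                "exponential baseline fit did not converge; "
                "falling back to rolling percentile",
                stacklevel=2,
            )
            fitted = _rolling_percentile_track(y, dt, window_s, percentile)
            model = BaselineModel(
                ROLLING_PERCENTILE,
                {"window_s": window_s, "percentile": percentile, "fallback": True},
                fitted,
            )
    if np.any(model.fitted_values <= 0):
        raise DataError("fitted baseline is not strictly positive")
    return model


def _fit_exponential(
    t: np.ndarray, y: np.ndarray, dt: float, window_s: float
) -> BaselineModel | None:
    envelope = _rolling_percentile_track(y, dt, window_s, ENVELOPE_PERCENTILE)
    mask = y <= envelope
    if mask.sum() < 4:
        mask = np.ones_like(mask)
    tm, ym = t[mask], y[mask]

    def model_fn(tt, f_inf, a, tau):
        return f_inf + a * np.exp(-tt / tau)

    span = max(t[-1] - t[0], dt)
    y_lo, y_hi = float(ym.min()), float(ym.max())
    p0 = [y_lo, max(y_hi - y_lo, 1e-12), span / 3.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model_fn,
                tm,
                ym,
                p0=p0,
                bounds=([-np.inf, 0.0, dt], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError):
        return None

    # second pass: the lower-envelope subset is a low-biased noise quantile;
    # refit on all points within +2 sigma of the first-pass curve (transient
    # samples stay excluded, both noise tails of the baseline return)
    sigma = 1.4826 * float(np.median(np.abs(np.diff(y)))) / np.sqrt(2.0)
    resid = y - model_fn(t, *popt)
    mask2 = resid <= 2.0 * sigma + 1e-12 * max(abs(y).max(), 1.0)
    if mask2.sum() >= 4:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model_fn,
                    t[mask2],
                    y[mask2],
                    p0=popt,
                    bounds=([-np.inf, 0.0, dt], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            pass
    f_inf, a, tau = (float(v) for v in popt)
    fitted = model_fn(t, f_inf, a, tau)
    return BaselineModel(
        EXPONENTIAL,
        {"f_inf": f_inf, "amplitude": a, "tau_s": tau},
        fitted,
    )


def detrend(trace: FluorescenceTrace, model: BaselineModel) -> CorrectedTrace:
    """Normalize a trace to dF/F0 against a fitted baseline.

    ``df_over_f0[i] = (F[i] - B[i]) / B[i]``; the corrected baseline
    fluctuates around zero.  Raises :class:`DataError` if the baseline is
    not strictly positive or was fitted on a different-length trace.
    """
    b = model.fitted_values
    if b.shape != trace.intensity.shape:
        raise DataError("baseline model does not match trace length")
    if np.any(b <= 0):
        raise DataError("baseline must be strictly positive to normalize")
    df = (trace.intensity - b) / b
    return CorrectedTrace(
        trace.time_s, df, model, origin_label=trace.origin_label
    )


def correct_trace(
    trace: FluorescenceTrace,
    kind: str = EXPONENTIAL,
    window_s: float = 10.0,
    percentile: float = 10.0,
) -> CorrectedTrace:
    """Fit a baseline and detrend in one step."""
    return detrend(trace, fit_baseline(trace, kind, window_s, percentile))


def constant_baseline(trace: FluorescenceTrace, value: float) -> BaselineModel:
    """A user-supplied flat baseline (e.g. a known resting fluorescence)."""
    if value <= 0:
        raise ConfigError(f"baseline value must be positive, got {value}")
    return BaselineModel(
        "constant", {"value": float(value)}, np.full(len(trace), float(value))
    )


def write_corrected(corrected: CorrectedTrace, path) -> None:
    """3-column CSV: time_s, df_over_f0, baseline."""
    import csv
    from pathlib import Path

    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "df_over_f0", "baseline"])
        for t, d, b in zip(
            corrected.time_s, corrected.df_over_f0, corrected.baseline.fitted_values
        ):
            w.writerow([repr(float(t)), repr(float(d)), repr(float(b))])
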