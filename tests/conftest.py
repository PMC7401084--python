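import numpy as np
import pytest

from catrace import (
    TraceSimParams,
    simulate_trace,
    fit_baseline,
    detrend,
    detect_events,
    classify_events,
)

#: ground-truth label -> classifier label
LABEL_MAP = {
    "normal": "normal",
    "double_peak": "abnormal_double_peak",
    "small_amplitude": "abnormal_small_amplitude",
}


def run_pipeline(trace, **detect_kwargs):
    """Detrend with the default exponential baseline, detect and classify."""
    corrected = detrend(trace, fit_baseline(trace))
    events = detect_events(corrected, **detect_kwargs)
    return classify_events(events), corrected


def expected_labels(truth):
    return [LABEL_MAP[lab] for lab in truth.abnormal_flags]


@pytest.fixture
def clean_train_params():
    """Ten identical noise-free transients on a flat baseline.

    Fast kinetics relative to the beat period so that consecutive
    transients do not overlap at all (tail < 1e-9 of the amplitude by the
    next beat) and sampled values are exact.
    """
    return TraceSimParams(
        duration_s=27.0,
        beat_rate_hz=0.4,
        amplitude=1.0,
        f0=1.0,
        rise_tau_s=0.05,
        decay_tau_s=0.1,
        bleach_tau_s=np.inf,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def clean_train(clean_train_params):
    return simulate_trace(clean_train_params)
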