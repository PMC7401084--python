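"""End-to-end orchestration: simulate/load -> detrend -> detect -> classify
-> summarize -> compare, with reproducible configuration and provenance.

A run is described by a :class:`RunConfig` (usually loaded from YAML).  The
synthetic mode simulates several experimental conditions (e.g. genotypes
that differ in their injected abnormal-transient probabilities), analyses
every scan with the same detection settings, aggregates per-scan abnormal
percentages (scans are the replication unit) and runs the configured group
comparison.  Identical config + seed gives byte-identical summary JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .baseline import fit_baseline, detrend
from .events import (
    classify_events,
    detect_events,
    events_to_dataframe,
    fold_change,
    summarize_scan,
)
from .quantify import group_compare
from .synthetic import TraceSimParams, simulate_trace, params_from_dict, params_to_dict

logger = logging.getLogger("catrace")

_SIM_DEFAULTS = {
    k: v for k, v in asdict(TraceSimParams()).items() if k != "seed"
}


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    seed: int = 0
    n_scans_per_condition: int = 6
    conditions: dict = field(
        default_factory=lambda: {"control": {"p_double_peak": 0.0,
                                             "p_small_amplitude": 0.0}}
    )
    sim: dict = field(default_factory=dict)  # TraceSimParams overrides
    baseline: dict = field(
        default_factory=lambda: {"kind": "exponential", "window_s": 10.0,
                                 "percentile": 10.0}
    )
    detection: dict = field(
        default_factory=lambda: {
            "prominence_frac": 0.2,
            "min_interval_s": 0.3,
            "return_tolerance_frac": 0.25,
        }
    )
    classification: dict = field(default_factory=lambda: {"ratio_threshold": 0.75})
    summary_mode: str = "per_scan"  # or "pooled"
    stats: dict = field(
        default_factory=lambda: {"method": "kruskal_dunn", "control": None}
    )

    def __post_init__(self) -> None:
        ratio = self.classification.get("ratio_threshold", 0.75)
        if not (0.0 < ratio < 1.0):
            raise ConfigError(f"ratio_threshold must be in (0, 1), got {ratio}")
        if self.summary_mode not in ("per_scan", "pooled"):
            raise ConfigError(f"unknown summary_mode {self.summary_mode!r}")
        if self.n_scans_per_condition < 1:
            raise ConfigError("n_scans_per_condition must be >= 1")
        self.classification.setdefault("ratio_threshold", 0.75)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_demo_config() -> RunConfig:
    """The bundled three-genotype demo configuration."""
    with resources.files("catrace.data").joinpath("demo.yaml").open() as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _scan_seed(base_seed: int, cond_index: int, scan_index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), cond_index, scan_index])
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_trace(trace, config: RunConfig):
    """Detrend, detect and classify one raw trace; returns (events, summary)."""
    model = fit_baseline(trace, **config.baseline)
    corrected = detrend(trace, model)
    events = detect_events(corrected, **config.detection)
    events = classify_events(events, **config.classification)
    return events, summarize_scan(events, corrected.duration_s)


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic pipeline described by ``config``.

    Per condition, simulates ``n_scans_per_condition`` scans, analyses each
    one, aggregates abnormal percentages (mean over scans in ``per_scan``
    mode, event-pooled in ``pooled`` mode) against the injected ground
    truth, compares conditions with the configured test, and reports the
    fold change of each condition's pooled abnormal percentage over the
    first (reference) condition.
    """
    scan_rows = []
    condition_stats = {}
    per_scan_pct: dict[str, list] = {}
    for ci, (label, overrides) in enumerate(config.conditions.items()):
        pooled_events = 0
        pooled_abnormal = 0
        injected_events = 0
        injected_abnormal = 0
        per_scan_pct[label] = []
        for si in range(config.n_scans_per_condition):
            sim_kwargs = {**_SIM_DEFAULTS, **config.sim, **overrides}
            params = params_from_dict(
                {**sim_kwargs, "seed": _scan_seed(config.seed, ci, si)}
            )
            trace, truth = simulate_trace(params)
            try:
                events, summary = analyze_trace(trace, config)
            except Exception as exc:  # noqa: BLE001 - abort with context
                raise type(exc)(
                    f"stage 'analyze' failed for condition {label!r} scan {si}: {exc}"
                ) from exc
            scan_rows.append(
                {
                    "condition": label,
                    "scan": si,
                    "seed": params.seed,
                    **summary.to_dict(),
                    "injected_events": truth.n_events,
                    "injected_abnormal": truth.n_abnormal,
                }
            )
            pooled_events += summary.n_events
            pooled_abnormal += summary.n_abnormal
            injected_events += truth.n_events
            injected_abnormal += truth.n_abnormal
            if summary.pct_abnormal is not None:
                per_scan_pct[label].append(summary.pct_abnormal)
        pooled_pct = (
            100.0 * pooled_abnormal / pooled_events if pooled_events else None
        )
        injected_pct = (
            100.0 * injected_abnormal / injected_events if injected_events else None
        )
        mean_scan_pct = (
            float(np.mean(per_scan_pct[label])) if per_scan_pct[label] else None
        )
        condition_stats[label] = {
            "n_scans": config.n_scans_per_condition,
            "n_events": pooled_events,
            "n_abnormal": pooled_abnormal,
            "pct_abnormal_pooled": pooled_pct,
            "pct_abnormal_mean_of_scans": mean_scan_pct,
            "injected_pct_abnormal": injected_pct,
        }

    labels = list(config.conditions)
    ref = labels[0]
    folds = {}
    ref_pct = condition_stats[ref]["pct_abnormal_pooled"]
    for label in labels[1:]:
        pct = condition_stats[label]["pct_abnormal_pooled"]
        if ref_pct not in (None, 0) and pct is not None:
            folds[f"{label}_vs_{ref}"] = fold_change(pct, ref_pct)

    comparison = None
    usable = {k: v for k, v in per_scan_pct.items() if len(v) >= 2}
    if len(usable) >= 2:
        method = config.stats.get("method", "kruskal_dunn")
        control = config.stats.get("control") or ref
        try:
            res = group_compare(usable, method=method, control=control)
            comparison = {
                "method": res["method"],
                "control": res["control"],
                "overall": res["overall"],
                "comparisons": res["comparisons"].to_dict(orient="records"),
            }
        except ConfigError as exc:
            logger.warning("group comparison skipped: %s", exc)

    report = {
        "provenance": {
            "catrace_version": __version__,
            "numpy_version": np.__version__,
            "config_hash": config.hash(),
            "seed": config.seed,
            "config": config.to_dict(),
        },
        "conditions": condition_stats,
        "fold_changes": folds,
        "comparison": comparison,
        "summary_mode": config.summary_mode,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(scan_rows).to_csv(out_dir / "scans.csv", index=False)
        (out_dir / "summary.json").write_text(report_json(report))
        logger.info("wrote %s", out_dir / "summary.json")
    report["scans"] = scan_rows
    return report


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a run report."""
    report = {k: v for k, v in report.items() if k != "scans"}
    return json.dumps(report, sort_keys=True, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_events(events, path: str | Path) -> None:
    events_to_dataframe(events).to_csv(path, index=False)
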