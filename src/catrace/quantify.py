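"""Transgene-expression and qPCR quantification.

* ``percent_positive`` — fraction of reporter-positive cells per
  (condition, timepoint) group from a per-cell intensity table, with an
  optional automatic 2-cluster threshold on log-intensity.
* ``silencing_ratio`` — before/after comparison of positive percentages
  (fold drop and percentage-point drop) for transgene-silencing time
  courses.
* ``ddct`` — classic Livak relative quantification: per-sample
  ``dCt = mean Ct(target) - mean Ct(housekeeping)``, ``ddCt`` referenced to
  a calibrator sample, ``fold = 2**(-ddCt)``, with replicate SD propagated.
  Amplification efficiency is fixed at 2 per cycle (no efficiency
  correction).
* ``group_compare`` — a thin facade over standard hypothesis tests
  (one-way ANOVA with Tukey / Dunnett / Sidak post-hoc, Kruskal-Wallis with
  Dunn's post-hoc, unpaired t-test) with the usual star coding
  (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    """Significance stars at the conventional thresholds ('ns' otherwise)."""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


# ---------------------------------------------------------------------------
# percent positive


def auto_threshold(intensities: np.ndarray) -> float:
    """2-means threshold on log10 intensity: midpoint of the cluster centers.

    Raises :class:`DataError` when the data look unimodal (cluster centers
    closer than the pooled within-cluster spread), in which case a manual
    threshold must be supplied.
    """
    from sklearn.cluster import KMeans

    x = np.log10(np.maximum(np.asarray(intensities, dtype=float), 1e-12))
    if x.size < 2:
        raise DataError("need at least 2 cells to fit an automatic threshold")
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(x.reshape(-1, 1))
    c = np.sort(km.cluster_centers_.ravel())
    labels = km.labels_
    spreads = [np.std(x[labels == k]) for k in range(2)]
    pooled = float(np.sqrt(np.mean(np.square(spreads))))
    # a single Gaussian split at its mean gives separation ~2.65x the
    # within-cluster spread; require well beyond that before trusting the cut
    if (c[1] - c[0]) < 4.0 * pooled:
        raise DataError(
            "intensity distribution looks unimodal; automatic thresholding is "
            "unreliable — supply an explicit threshold"
        )
    return float(10 ** ((c[0] + c[1]) / 2.0))


def percent_positive(
    table: pd.DataFrame,
    threshold: float | str = "auto",
    intensity_col: str = "intensity",
    group_cols: tuple[str, ...] = ("condition_label", "timepoint_label"),
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percent of cells above threshold per (condition, timepoint) group.

    With ``threshold="auto"`` the cutoff is fitted by 2-means on
    log-intensity, on ``reference`` if given (a designated mixed
    negative+positive set) else on the whole table, and the threshold used
    is recorded in every output row.
    """
    if intensity_col not in table.columns:
        raise DataError(f"missing column {intensity_col!r}")
    vals = table[intensity_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        raise DataError("intensities must be finite and >= 0")
    if threshold == "auto":
        fit_on = reference if reference is not None else table
        thr = auto_threshold(fit_on[intensity_col].to_numpy(dtype=float))
    else:
        thr = float(threshold)

    group_cols = [c for c in group_cols if c in table.columns]
    rows = []
    grouped = table.groupby(list(group_cols), sort=True) if group_cols else [((), table)]
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        if n == 0:
            warnings.warn(f"empty group {key}; reporting missing value", stacklevel=2)
            pct = None
            npos = 0
        else:
            npos = int((grp[intensity_col] > thr).sum())
            pct = 100.0 * npos / n
        rows.append(
            dict(zip(group_cols, key))
            | {"n_cells": n, "n_positive": npos, "pct_positive": pct, "threshold": thr}
        )
    return pd.DataFrame(rows)


def silencing_ratio(pct_before: float, pct_after: float) -> dict:
    """Fold drop and percentage-point drop between two positive percentages."""
    for name, v in {"pct_before": pct_before, "pct_after": pct_after}.items():
        if not (0.0 <= v <= 100.0):
            raise ConfigError(f"{name} must be in [0, 100], got {v}")
    if pct_before <= 0:
        raise ConfigError("pct_before must be > 0")
    ratio = None if pct_after == 0 else pct_before / pct_after
    return {"ratio": ratio, "drop_percentage_points": pct_before - pct_after}


# ---------------------------------------------------------------------------
# ddCt


def ddct(
    table: pd.DataFrame,
    target_gene: str,
    housekeeping_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Livak ddCt relative quantification, one row per sample.

    ``delta_ct = mean Ct(target) - mean Ct(housekeeping)`` per sample,
    ``delta_delta_ct = delta_ct(sample) - delta_ct(calibrator)`` and
    ``fold = 2**(-delta_delta_ct)``.  The replicate standard deviation is
    propagated as ``sqrt(sd_t^2/n_t + sd_h^2/n_h)`` and reported as
    ``sd_delta_ct``.  Samples missing a housekeeping measurement are
    skipped with a warning; a missing calibrator is an error.
    """
    required = {"sample_label", "gene_label", "ct"}
    if not required.issubset(table.columns):
        raise DataError(f"Ct table must have columns {sorted(required)}")
    if not np.all(np.isfinite(table["ct"])):
        raise DataError("non-finite Ct value in table")

    def sample_stats(sample: str):
        sub = table[table["sample_label"] == sample]
        tgt = sub[sub["gene_label"] == target_gene]["ct"]
        hk = sub[sub["gene_label"] == housekeeping_gene]["ct"]
        if len(hk) == 0 or len(tgt) == 0:
            return None
        sd = math.sqrt(
            (tgt.std(ddof=1) ** 2 / len(tgt) if len(tgt) > 1 else 0.0)
            + (hk.std(ddof=1) ** 2 / len(hk) if len(hk) > 1 else 0.0)
        )
        return float(tgt.mean() - hk.mean()), sd

    samples = list(dict.fromkeys(table["sample_label"]))
    if calibrator_sample not in samples:
        raise DataError(f"calibrator sample {calibrator_sample!r} not in table")
    cal = sample_stats(calibrator_sample)
    if cal is None:
        raise DataError(
            f"calibrator {calibrator_sample!r} lacks target or housekeeping Ct"
        )
    rows = []
    for sample in samples:
        st = sample_stats(sample)
        if st is None:
            warnings.warn(
                f"sample {sample!r} lacks {target_gene!r} or "
                f"{housekeeping_gene!r} measurements; skipped",
                stacklevel=2,
            )
            continue
        dct, sd = st
        ddct_val = dct - cal[0]
        rows.append(
            {
                "sample_label": sample,
                "delta_ct": dct,
                "delta_delta_ct": ddct_val,
                "fold": 2.0 ** (-ddct_val),
                "sd_delta_ct": sd,
                "housekeeping_gene": housekeeping_gene,
                "target_gene": target_gene,
                "calibrator": calibrator_sample,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons

METHODS = ("anova_tukey", "anova_dunnett", "anova_sidak", "kruskal_dunn", "t_test")


def group_compare(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    method: str = "anova_tukey",
    control: str | None = None,
    value_col: str = "value",
    group_col: str = "group",
) -> dict:
    """Compare ≥2 groups of measurements with a standard test battery.

    Returns ``{"method", "overall": {statistic, pvalue}, "groups":
    DataFrame(group, n, mean, sd), "comparisons": DataFrame(group1, group2,
    p_adj, stars)}``.  ``control`` selects the reference group for
    Dunnett/Dunn-vs-control designs (default: first group).
    """
    if isinstance(groups, pd.DataFrame):
        groups = {
            str(k): g[value_col].to_numpy(dtype=float)
            for k, g in groups.groupby(group_col, sort=False)
        }
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; choose from {METHODS}")
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    min_n = 1 if method == "kruskal_dunn" else 2
    for name, v in groups.items():
        if len(v) < min_n or np.any(~np.isfinite(v)):
            raise ConfigError(f"degenerate group {name!r}: need >= {min_n} finite values")
    names = list(groups)
    if control is None:
        control = names[0]
    if control not in groups:
        raise ConfigError(f"control group {control!r} not found")
    arrays = [groups[k] for k in names]

    gstats = pd.DataFrame(
        {
            "group": names,
            "n": [len(v) for v in arrays],
            "mean": [float(np.mean(v)) for v in arrays],
            "sd": [float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
                   for v in arrays],
        }
    )

    if method == "t_test":
        if len(names) != 2:
            raise ConfigError("t_test requires exactly 2 groups")
        res = stats.ttest_ind(arrays[0], arrays[1])
        overall = {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
        comps = [(names[0], names[1], float(res.pvalue))]
    elif method == "kruskal_dunn":
        res = stats.kruskal(*arrays)
        overall = {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
        comps = _dunn(groups, names, control)
    else:
        res = stats.f_oneway(*arrays)
        overall = {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
        if method == "anova_tukey":
            comps = _tukey(groups, names)
        elif method == "anova_dunnett":
            treat = [groups[k] for k in names if k != control]
            dres = stats.dunnett(*treat, control=groups[control])
            comps = [
                (k, control, float(p))
                for k, p in zip([k for k in names if k != control], dres.pvalue)
            ]
        else:  # anova_sidak
            comps = _pairwise_sidak(groups, names)

    comparisons = pd.DataFrame(
        [
            {"group1": a, "group2": b, "p_adj": p, "stars": stars(p)}
            for a, b, p in comps
        ]
    )
    return {
        "method": method,
        "control": control,
        "overall": overall,
        "groups": gstats,
        "comparisons": comparisons,
    }


def _tukey(groups: dict, names: list[str]) -> list[tuple[str, str, float]]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([groups[k] for k in names])
    labels = np.concatenate([[k] * len(groups[k]) for k in names])
    res = pairwise_tukeyhsd(values, labels)
    frame = res.summary()
    return [
        (str(row[0]), str(row[1]), float(p))
        for row, p in zip(frame.data[1:], res.pvalues)
    ]


def _pairwise_sidak(groups: dict, names: list[str]) -> list[tuple[str, str, float]]:
    from statsmodels.stats.multitest import multipletests

    pairs = list(itertools.combinations(names, 2))
    raw = [
        float(stats.ttest_ind(groups[a], groups[b]).pvalue) for a, b in pairs
    ]
    _, adj, _, _ = multipletests(raw, method="sidak")
    return [(a, b, float(p)) for (a, b), p in zip(pairs, adj)]


def _dunn(
    groups: dict, names: list[str], control: str
) -> list[tuple[str, str, float]]:
    """Dunn's rank-based post-hoc z-tests vs control, Bonferroni-adjusted.

    Uses the standard large-sample normal approximation on mean ranks with
    tie correction, as implemented in common statistics packages.
    """
    pooled = np.concatenate([groups[k] for k in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(groups[k]) for k in names])
    mean_ranks = {
        k: float(np.mean(ranks[offsets[i] : offsets[i + 1]]))
        for i, k in enumerate(names)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    comps = []
    others = [k for k in names if k != control]
    m = len(others)
    for k in others:
        se = math.sqrt(var_base * (1.0 / len(groups[k]) + 1.0 / len(groups[control])))
        z = (mean_ranks[k] - mean_ranks[control]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        comps.append((k, control, min(1.0, p * m)))
    return comps
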