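"""Longitudinal statistics and nadir-based response assessment.

Covers: trend classification and pooled trend agreement between measurement
methods, Spearman rank correlation, consistency ICC, time-to-progression
(TTP) under nadir-relative thresholds, threshold sweeps against an expert
reference, and the TTP-OS correlation used to sanity-check thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .rano import RanoConfig
from .series import PatientSeries

TREND_INCREASING = "increasing"
TREND_DECREASING = "decreasing"
TREND_CONSTANT = "constant"


def classify_trend(prev: float, curr: float, rel_eps: float = 1e-9) -> str:
    """Label the change between two adjacent time points.

    ``constant`` when the relative change is below ``rel_eps`` (effectively
    exact equality for continuous measures), else increasing/decreasing.
    """
    if prev < 0 or curr < 0:
        raise ValueError("burden values must be non-negative")
    if abs(curr - prev) <= rel_eps * max(prev, curr, 1.0):
        return TREND_CONSTANT
    return TREND_INCREASING if curr > prev else TREND_DECREASING


def trend_agreement(series_a, series_b, rel_eps: float = 1e-9) -> float:
    """Percentage of adjacent-pair trends on which two methods agree.

    Both inputs are aligned value sequences of the same time points
    (length >= 2). Returns 100 * matches / transitions.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two aligned time points")
    ta = [classify_trend(a[i], a[i + 1], rel_eps) for i in range(a.size - 1)]
    tb = [classify_trend(b[i], b[i + 1], rel_eps) for i in range(b.size - 1)]
    matches = sum(1 for x, y in zip(ta, tb) if x == y)
    return 100.0 * matches / len(ta)


def pooled_trend_agreement(pairs, rel_eps: float = 1e-9) -> float:
    """Trend agreement pooled over many patients' transitions.

    ``pairs`` is an iterable of (values_a, values_b) aligned per patient; all
    transitions are pooled before the percentage is computed (one
    cohort-level figure).
    """
    matches = 0
    total = 0
    for a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("length mismatch in pooled pair")
        for i in range(a.size - 1):
            total += 1
            if classify_trend(a[i], a[i + 1], rel_eps) == classify_trend(b[i], b[i + 1], rel_eps):
                matches += 1
    if total == 0:
        raise ValueError("no transitions to pool")
    return 100.0 * matches / total


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on average-tie fractional ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length sequences of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _exact_spearman_p(x, y) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx0 = rx - rx.mean()
    obs = abs(float(np.dot(rx0, ry - ry.mean())))
    count = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        p = np.asarray(perm)
        if abs(float(np.dot(rx0, p - p.mean()))) >= obs - 1e-12:
            count += 1
    return count / total


def icc_consistency(scores) -> float:
    """ICC(3,1): two-way single-measurement consistency.

    (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error) from a two-way
    ANOVA without interaction over a complete subjects x raters table.
    Invariant to a constant offset per rater, which is the property that
    matters for relative response assessment.
    """
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete table of >= 2 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise ValueError("table must be complete (no missing cells)")
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise ValueError("degenerate table: zero variance everywhere")
    return float((ms_rows - ms_err) / denom)


# ---------------------------------------------------------------------------
# time-to-progression
# ---------------------------------------------------------------------------


@dataclass
class TtpResult:
    """Outcome of the nadir-based progression scan for one patient."""

    patient_id: str
    metric: str
    threshold: float
    ttp_days: int
    progressed: bool
    progression_index: int | None
    nadir_trace: list[float]
    zero_nadir_call: bool = False  # progression called on re-appearance after 0 burden


def compute_ttp(
    series: PatientSeries,
    metric: str = "volume",
    threshold: float | None = None,
    nadir_mode: str = "auto",
) -> TtpResult:
    """First time point whose burden exceeds the nadir by the threshold.

    Scanning time points in order, the reference is the running minimum of
    the metric over all prior time points including baseline (``auto``), or
    the value at the most recent expert-flagged nadir (``expert``). The first
    time point with value >= (1+threshold) * reference is progression and its
    ``days_from_surgery`` is the TTP. If the threshold is never reached, TTP
    is set to the overall-survival time and ``progressed`` is False.

    ``nadir_mode='auto'`` falls back gracefully; pass ``'expert'`` to require
    flags, or ``'prefer-expert'`` to use them when present (the mode that
    avoids reference re-assignment by under-segmented automated masks).
    """
    if len(series.timepoints) < 2:
        raise ValueError("need at least two time points")
    if threshold is None:
        threshold = RanoConfig().threshold_for(metric)
    values = series.metric_values(metric)
    mode = nadir_mode
    if mode == "prefer-expert":
        mode = "expert" if series.has_expert_nadir_flags() else "auto"
    if mode == "expert" and not series.has_expert_nadir_flags():
        raise ValueError(f"{series.patient_id}: nadir_mode='expert' but no expert flags")
    if mode not in ("auto", "expert"):
        raise ValueError(f"unknown nadir_mode {nadir_mode!r}")

    nadir_trace: list[float] = []
    ref = values[0]
    progression_index = None
    zero_call = False
    for t, v in enumerate(values):
        if mode == "auto":
            # running minimum over all prior time points, baseline included
            ref = min(values[:t]) if t > 0 else values[0]
        else:
            flagged = [
                i
                for i, tp in enumerate(series.timepoints[:t])
                if tp.expert_is_nadir
            ]
            ref = values[flagged[-1]] if flagged else values[0]
        nadir_trace.append(ref)
        if t == 0:
            continue
        if ref == 0:
            if v > 0:
                progression_index = t
                zero_call = True
                break
            continue
        if v >= (1.0 + threshold) * ref:
            progression_index = t
            break

    progressed = progression_index is not None
    ttp_days = (
        series.timepoints[progression_index].days_from_surgery if progressed else series.os_days
    )
    return TtpResult(
        patient_id=series.patient_id,
        metric=metric,
        threshold=float(threshold),
        ttp_days=int(ttp_days),
        progressed=progressed,
        progression_index=progression_index,
        nadir_trace=nadir_trace,
        zero_nadir_call=zero_call,
    )


def expert_ttp(series: PatientSeries) -> int:
    """Expert TTP: day of the first follow-up rated progressive disease.

    Falls back to the OS time when no time point is rated PD, matching the
    handling of never-progressing automated series.
    """
    for tp in series.timepoints:
        if tp.expert_rating == "PD":
            return tp.days_from_surgery
    return series.os_days


def threshold_sweep(
    cohort: list[PatientSeries],
    metric: str,
    thresholds,
    nadir_mode: str = "auto",
    expert_ttps: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean (automated TTP - expert TTP) in days, per candidate threshold.

    ``expert_ttps`` maps patient_id to the expert TTP; when omitted it is
    derived from each series' expert PD ratings.
    """
    rows = []
    for thr in thresholds:
        diffs = []
        for s in cohort:
            exp = expert_ttps[s.patient_id] if expert_ttps else expert_ttp(s)
            auto = compute_ttp(s, metric=metric, threshold=thr, nadir_mode=nadir_mode)
            diffs.append(auto.ttp_days - exp)
        rows.append(
            {"threshold": float(thr), "mean_diff_days": float(np.mean(diffs)), "n": len(diffs)}
        )
    return pd.DataFrame(rows)


def ttp_os_correlation(
    cohort: list[PatientSeries],
    metric: str = "volume",
    threshold: float | None = None,
    nadir_mode: str = "auto",
    ttp_days: list[int] | None = None,
) -> tuple[float, float]:
    """Spearman correlation between per-patient TTP and overall survival.

    The p-value is the exact two-sided permutation p for n <= 9 patients and
    the t-approximation otherwise. Pass ``ttp_days`` to correlate
    externally-computed TTPs (e.g. the expert's) instead.
    """
    if len(cohort) < 3:
        raise ValueError("need at least three patients")
    if ttp_days is None:
        ttp_days = [
            compute_ttp(s, metric=metric, threshold=threshold, nadir_mode=nadir_mode).ttp_days
            for s in cohort
        ]
    os_days = [s.os_days for s in cohort]
    rho = spearman_rho(ttp_days, os_days)
    if len(cohort) <= 9:
        p = _exact_spearman_p(ttp_days, os_days)
    else:
        p = float(stats.spearmanr(ttp_days, os_days).pvalue)
    return rho, p
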