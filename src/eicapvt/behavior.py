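"""Reaction-time classification, adherence filters, and behavioral statistics.

The psychomotor vigilance task (PVT) yields one reaction time (RT) per
stimulus.  RTs are partitioned into four classes: *lapses* (RT > 500 ms,
the marker of an attention failure), *normal* responses (200-450 ms),
*ambiguous* responses in the deliberately left-open 450-500 ms gap, and
*spurious* responses (< 200 ms, anticipations or accidental presses).
Only lapses and normal responses are analyzed; the other two classes are
relegated to nuisance covariates downstream.

Session-level filters mirror the study protocol: more than 75 lapses in a
session marks task non-adherence, and subjects whose nightly sleep-period
difference between the short-sleep and healthy-sleep weeks averaged less
than half an hour are sleep non-adherent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RtClass",
    "PerformanceSummary",
    "classify_rt",
    "classify_rts",
    "check_task_adherence",
    "check_sleep_adherence",
    "summarize_performance",
    "sleep_by_setting_model",
    "isi_speed_regression",
    "LAPSE_THRESHOLD_MS",
    "NORMAL_RANGE_MS",
    "SPURIOUS_THRESHOLD_MS",
    "TASK_LAPSE_LIMIT",
    "SLEEP_DIFF_MIN_H",
]

LAPSE_THRESHOLD_MS = 500.0
NORMAL_RANGE_MS = (200.0, 450.0)
SPURIOUS_THRESHOLD_MS = 200.0
#: more lapses than this in one session -> task non-adherence (strict >)
TASK_LAPSE_LIMIT = 75
#: minimum mean nightly sleep-period difference between conditions (hours)
SLEEP_DIFF_MIN_H = 0.5


class RtClass(str, enum.Enum):
    """Reaction-time class; the four classes partition [0, inf) ms."""

    NORMAL = "normal"
    LAPSE = "lapse"
    AMBIGUOUS = "ambiguous"
    SPURIOUS = "spurious"

    def __str__(self) -> str:  # so str(cls) round-trips through TSV
        return self.value


def classify_rt(rt_ms: float) -> RtClass:
    """Classify a single reaction time in milliseconds.

    Boundary convention (the study text leaves the bounds half-open in
    places): 200 ms and 450 ms are NORMAL (closed interval), 500 ms is
    AMBIGUOUS, anything strictly above 500 ms is a LAPSE, anything
    strictly below 200 ms is SPURIOUS.  Timeout trials (RT capped at
    2400 ms) classify as lapses.

    Raises
    ------
    ValueError
        If ``rt_ms`` is negative or not finite.
    """
    rt = float(rt_ms)
    if not np.isfinite(rt) or rt < 0:
        raise ValueError(f"reaction time must be finite and >= 0 ms, got {rt_ms!r}")
    if rt < SPURIOUS_THRESHOLD_MS:
        return RtClass.SPURIOUS
    if rt <= NORMAL_RANGE_MS[1]:
        return RtClass.NORMAL
    if rt <= LAPSE_THRESHOLD_MS:
        return RtClass.AMBIGUOUS
    return RtClass.LAPSE


def classify_rts(rts_ms: Iterable[float]) -> list[RtClass]:
    """Vector form of :func:`classify_rt`."""
    return [classify_rt(rt) for rt in np.asarray(list(rts_ms), dtype=float)]


@dataclass(frozen=True)
class PerformanceSummary:
    """Per-session behavioral summary."""

    median_rt_ms: float
    mean_rt_ms: float
    n_lapses: int
    n_trials: int
    adherent: bool


def check_task_adherence(rts_ms: Iterable[float]) -> bool:
    """True unless the session shows limited engagement (> 75 lapses)."""
    n_lapses = sum(1 for c in classify_rts(rts_ms) if c is RtClass.LAPSE)
    return n_lapses <= TASK_LAPSE_LIMIT


def check_sleep_adherence(mean_period_ss_h: float, mean_period_hs_h: float) -> bool:
    """True unless |HS - SS| nightly sleep period averaged < 0.5 h.

    Both arguments are mean nightly sleep periods in hours; the boundary
    (exactly 0.5 h) counts as adherent (strict inequality).
    """
    if mean_period_ss_h <= 0 or mean_period_hs_h <= 0:
        raise ValueError("sleep periods must be positive hours")
    return abs(mean_period_hs_h - mean_period_ss_h) >= SLEEP_DIFF_MIN_H


def summarize_performance(rts_ms: Iterable[float]) -> PerformanceSummary:
    """Median/mean RT and lapse count over the responded trials of a session."""
    rts = np.asarray(list(rts_ms), dtype=float)
    if rts.size == 0:
        raise ValueError("no responded trials to summarize")
    classes = classify_rts(rts)
    n_lapses = sum(1 for c in classes if c is RtClass.LAPSE)
    return PerformanceSummary(
        median_rt_ms=float(np.median(rts)),
        mean_rt_ms=float(np.mean(rts)),
        n_lapses=int(n_lapses),
        n_trials=int(rts.size),
        adherent=n_lapses <= TASK_LAPSE_LIMIT,
    )


def sleep_by_setting_model(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Mixed two-factor ANOVA: within-subject sleep (SS/HS) x between-subject setting.

    The model is computed from sums of squares directly.  ``table`` must be
    long-format with columns ``subject``, ``sleep`` (two levels), ``setting``
    (two or more groups) and the value column; every subject contributes
    exactly one value per sleep level and belongs to one setting group.

    Returns a DataFrame indexed by effect (``setting``, ``sleep``,
    ``sleep:setting``) with columns ``ss``, ``df``, ``ms``, ``F``, ``p``,
    ``partial_eta2``.  Partial eta squared is SS_effect / (SS_effect +
    SS_error) with the error term of that effect's stratum.
    """
    from scipy import stats

    df = table[["subject", "sleep", "setting", value]].copy()
    df = df.rename(columns={value: "y"})
    sleeps = sorted(df["sleep"].unique())
    if len(sleeps) != 2:
        raise ValueError(f"sleep factor must have 2 levels, got {sleeps}")
    counts = df.groupby(["subject", "sleep"]).size().unstack(fill_value=0)
    if counts.shape[1] != 2 or (counts != 1).any().any():
        raise ValueError("each subject needs exactly one value per sleep level")
    if df["setting"].nunique() < 2:
        raise ValueError("setting factor needs >= 2 groups")
    groups = df.groupby("subject")["setting"].nunique()
    if (groups != 1).any():
        raise ValueError("each subject must belong to exactly one setting group")

    grand = df["y"].mean()
    n_levels = len(sleeps)
    subj = df.groupby("subject").agg(mean=("y", "mean"), setting=("setting", "first"))
    n_subjects = len(subj)
    group_sizes = subj.groupby("setting").size()
    if (group_sizes < 2).any():
        raise ValueError("need >= 2 subjects per setting group")
    n_groups = len(group_sizes)

    # between-subject stratum
    ss_between = n_levels * float(((subj["mean"] - grand) ** 2).sum())
    group_means = subj.groupby("setting")["mean"].mean()
    ss_setting = n_levels * float((group_sizes * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_between - ss_setting
    df_setting = n_groups - 1
    df_subj_within = n_subjects - n_groups

    # within-subject stratum
    subj_mean_map = subj["mean"]
    ss_within_total = float(
        ((df["y"] - df["subject"].map(subj_mean_map)) ** 2).sum()
    )
    sleep_means = df.groupby("sleep")["y"].mean()
    ss_sleep = n_subjects * float(((sleep_means - grand) ** 2).sum())
    cell = df.groupby(["setting", "sleep"])["y"].mean()
    ss_inter = 0.0
    for (g, c), m in cell.items():
        ss_inter += group_sizes[g] * (m - group_means[g] - sleep_means[c] + grand) ** 2
    ss_err_within = ss_within_total - ss_sleep - ss_inter
    df_sleep = n_levels - 1
    df_inter = df_setting * df_sleep
    df_err_within = df_subj_within * df_sleep

    def _row(ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        if ms_err > 0:
            F = ms_eff / ms_err
            p = float(stats.f.sf(F, df_eff, df_err))
        else:  # zero error variance: effect either absent or infinitely strong
            F = np.inf if ss_eff > 0 else 0.0
            p = 0.0 if ss_eff > 0 else 1.0
        denom = ss_eff + ss_err
        peta2 = ss_eff / denom if denom > 0 else 0.0
        return {"ss": ss_eff, "df": df_eff, "ms": ms_eff, "F": F, "p": p,
                "partial_eta2": peta2}

    out = pd.DataFrame(
        {
            "setting": _row(ss_setting, df_setting, ss_subj_within, df_subj_within),
            "sleep": _row(ss_sleep, df_sleep, ss_err_within, df_err_within),
            "sleep:setting": _row(ss_inter, df_inter, ss_err_within, df_err_within),
        }
    ).T
    out.index.name = "effect"
    return out


def isi_speed_regression(trials: pd.DataFrame) -> dict:
    """OLS of response speed (1/RT, 1/s) on the inter-stimulus interval (s).

    Longer ISIs afford more preparation and tend to speed responses, so a
    positive slope is the expected direction.  ``trials`` needs columns
    ``isi`` (seconds) and ``rt_ms``.

    Returns a dict with ``slope`` ((1/s) per s of ISI), ``intercept``,
    ``p`` (two-sided t-test on the slope) and the fitted statsmodels
    results object under ``fit``.
    """
    isi = np.asarray(trials["isi"], dtype=float)
    rt_s = np.asarray(trials["rt_ms"], dtype=float) / 1000.0
    if np.unique(isi).size < 2:
        raise ValueError("need >= 2 distinct ISI values for a regression")
    if np.any(rt_s <= 0):
        raise ValueError("reaction times must be positive")
    speed = 1.0 / rt_s
    X = sm.add_constant(isi)
    fit = sm.OLS(speed, X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "p": float(fit.pvalues[1]),
        "fit": fit,
    }
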