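"""Windowed polynomial inference on back-reconstructed component time courses.

Each 24-bin peri-stimulus time course splits into three windows: the
pre-stimulus period (-16 s up to the stimulus; 8 bins), the early
post-stimulus period (0-16 s inclusive; 9 bins) and the late
post-stimulus period (beyond 16 s; 7 bins).  The pre window is fitted
with a line (slope, intercept at t = 0); the early post window with a
cubic, from which the first peak's height and latency are extracted —
the first interior stationary point whose curvature matches the
component's dominant response sign (a maximum for task-positive
components, a minimum for task-negative ones such as the default mode).
The late window is segmented and exportable but not analyzed.

Uncertainty is propagated with a two-level bootstrap: per fit, 1000
residual resamples yield parameter distributions; per subject, a 2 x 2
(RT class x sleep condition) effect-coded ANOVA is repeated over 1000
draws from those cell distributions.  The per-subject mean coefficients
are tested across subjects with a one-sided Wilcoxon signed-rank test
against zero, with significance tiers p < 0.005 (adjusted for multiple
components) and 0.005-0.05 (trending).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fir import BIN_TIMES_S

EARLY_POST_END_S = 16.0
SIGNIFICANT_P = 0.005
TRENDING_P = 0.05
N_BOOT_DEFAULT = 1000

EFFECTS = ("rt_class", "sleep", "interaction")
CELLS = (("lapse", "SS"), ("lapse", "HS"), ("normal", "SS"), ("normal", "HS"))

__all__ = [
    "WindowSegments",
    "split_windows",
    "LinearFit",
    "CubicFit",
    "fit_pre",
    "fit_post_cubic",
    "PeakEstimate",
    "extract_first_peak",
    "bootstrap_window_fit",
    "subject_bootstrap_anova",
    "SignRankResult",
    "group_signrank",
    "significance_tier",
    "analyze_timecourses",
    "build_results_table",
    "format_results_table",
    "mean_timecourse_table",
    "response_sign",
]


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSegments:
    """One RT class's 24-bin time course split into the three windows."""

    pre_times: np.ndarray
    pre_values: np.ndarray
    early_times: np.ndarray
    early_values: np.ndarray
    late_times: np.ndarray
    late_values: np.ndarray


def split_windows(
    timecourse: np.ndarray, bin_times: np.ndarray = BIN_TIMES_S
) -> WindowSegments:
    """Partition a 24-bin time course; the t = 0 bin belongs to early post."""
    tc = np.asarray(timecourse, dtype=float)
    t = np.asarray(bin_times, dtype=float)
    if tc.shape != t.shape or tc.ndim != 1:
        raise ValueError(f"expected matching 1-D time course and bin times, got "
                         f"{tc.shape} vs {t.shape}")
    pre = t < 0.0
    early = (t >= 0.0) & (t <= EARLY_POST_END_S)
    late = t > EARLY_POST_END_S
    return WindowSegments(
        pre_times=t[pre], pre_values=tc[pre],
        early_times=t[early], early_values=tc[early],
        late_times=t[late], late_values=tc[late],
    )


# --------------------------------------------------------------------------
# fits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearFit:
    slope: float  # units / s
    intercept: float  # units, evaluated at t = 0 (stimulus time)
    fitted: np.ndarray
    residuals: np.ndarray


@dataclass(frozen=True)
class CubicFit:
    coefs: np.ndarray  # descending powers, length 4
    fitted: np.ndarray
    residuals: np.ndarray


def fit_pre(times: np.ndarray, values: np.ndarray) -> LinearFit:
    """Least-squares line over the pre-stimulus window."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("pre-window fit needs >= 2 points")
    coefs = np.polyfit(t, y, 1)
    fitted = np.polyval(coefs, t)
    return LinearFit(slope=float(coefs[0]), intercept=float(coefs[1]),
                     fitted=fitted, residuals=y - fitted)


def fit_post_cubic(times: np.ndarray, values: np.ndarray) -> CubicFit:
    """Least-squares cubic over the early post-stimulus window."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("cubic fit needs >= 4 points")
    coefs = np.polyfit(t, y, 3)
    fitted = np.polyval(coefs, t)
    return CubicFit(coefs=coefs, fitted=fitted, residuals=y - fitted)


@dataclass(frozen=True)
class PeakEstimate:
    height: float
    latency: float  # s from stimulus, in [0, 16]
    at_boundary: bool  # no interior extremum of the right curvature


def extract_first_peak(
    coefs: np.ndarray,
    window: tuple[float, float] = (0.0, EARLY_POST_END_S),
    response_sign: int = 1,
) -> PeakEstimate:
    """First peak (or trough) of the fitted cubic inside the window.

    The first interior stationary point in (window) whose curvature
    matches ``response_sign`` (maximum for +1, minimum for -1).  If no
    such point exists the window-end value is returned, flagged.
    """
    if response_sign not in (1, -1):
        raise ValueError("response_sign must be +1 or -1")
    a, b, c, d = np.asarray(coefs, dtype=float)
    w0, w1 = window
    candidates: list[float] = []
    scale = max(abs(a), abs(b), abs(c), abs(d), 1e-300)
    if abs(a) > 1e-12 * scale:
        disc = 4.0 * b * b - 12.0 * a * c
        if disc >= 0:
            r = np.sqrt(disc)
            candidates = [(-2.0 * b - r) / (6.0 * a), (-2.0 * b + r) / (6.0 * a)]
    elif abs(b) > 1e-12 * scale:
        candidates = [-c / (2.0 * b)]
    good = []
    for t0 in candidates:
        if w0 < t0 < w1:
            curvature = 6.0 * a * t0 + 2.0 * b
            if np.sign(curvature) == -response_sign and curvature != 0.0:
                good.append(t0)
    if good:
        t_peak = min(good)
        return PeakEstimate(
            height=float(np.polyval([a, b, c, d], t_peak)),
            latency=float(t_peak),
            at_boundary=False,
        )
    return PeakEstimate(
        height=float(np.polyval([a, b, c, d], w1)),
        latency=float(w1),
        at_boundary=True,
    )


def response_sign(mean_early: np.ndarray, times: np.ndarray) -> int:
    """Dominant response direction of a component's group-mean early curve.

    The sign of the curve's largest excursion from its value at the
    stimulus-time bin: positive for activating (task-positive) networks,
    negative for deactivating (default-mode-like) ones.  Computed on the
    raw binned curve rather than a smooth fit, because a cubic smooths
    narrow peaks down while exaggerating edge undershoots.
    """
    v = np.asarray(mean_early, dtype=float) - float(mean_early[0])
    s = np.sign(v[np.argmax(np.abs(v))])
    return int(s) if s != 0 else 1


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def bootstrap_window_fit(
    times: np.ndarray,
    values: np.ndarray,
    kind: str,
    n_boot: int = N_BOOT_DEFAULT,
    rng: int | np.random.Generator = 0,
    response_sign: int = 1,
    scale_residuals: bool = True,
) -> dict[str, np.ndarray]:
    """Residual-bootstrap distributions of a window fit's parameters.

    Each replicate refits ``fitted + resample(residuals)``.  Residuals
    are rescaled by sqrt(n / (n - p)) by default so the bootstrap
    parameter sd is unbiased for the analytic OLS sd at these small
    window sizes.  ``kind`` is ``"pre"`` (slope, intercept) or
    ``"cubic"`` (peak_height, peak_latency, plus the coefficient draws).
    Deterministic under the given seed; zero residual variance yields a
    degenerate distribution with a warning.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    degree = 1 if kind == "pre" else 3
    if kind not in ("pre", "cubic"):
        raise ValueError("kind must be 'pre' or 'cubic'")
    n, p = t.size, degree + 1
    V = np.vander(t, p)  # columns: descending powers
    pinv = np.linalg.pinv(V)
    beta0 = pinv @ y
    fitted = V @ beta0
    resid = y - fitted
    if np.allclose(resid, 0.0):
        warnings.warn("zero residual variance: degenerate bootstrap distribution")
    if scale_residuals and n > p:
        resid = resid * np.sqrt(n / (n - p))
    idx = rng.integers(0, n, size=(n_boot, n))
    Yb = fitted[None, :] + resid[idx]
    betas = Yb @ pinv.T  # (n_boot, p)

    if kind == "pre":
        return {"slope": betas[:, 0].copy(), "intercept": betas[:, 1].copy()}
    heights = np.empty(n_boot)
    lats = np.empty(n_boot)
    for i in range(n_boot):
        pk = extract_first_peak(betas[i], response_sign=response_sign)
        heights[i] = pk.height
        lats[i] = pk.latency
    return {"peak_height": heights, "peak_latency": lats, "coefs": betas}


def subject_bootstrap_anova(
    cells: dict[tuple[str, str], np.ndarray],
    n_boot: int = N_BOOT_DEFAULT,
    rng: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Bootstrap the 2 x 2 effect-coded ANOVA coefficients for one subject.

    ``cells`` maps (rt_class, condition) — all four of lapse/normal x
    SS/HS — to that cell's bootstrap distribution of a fit parameter.
    Each replicate draws one value per cell and computes the effect-coded
    coefficients (lapse and SS on the positive poles):

    * ``rt_class``    = (L,SS + L,HS - N,SS - N,HS) / 4
    * ``sleep``       = (L,SS - L,HS + N,SS - N,HS) / 4
    * ``interaction`` = (L,SS - L,HS - N,SS + N,HS) / 4
    """
    missing = [k for k in CELLS if k not in cells]
    if missing:
        raise ValueError(f"missing ANOVA cells: {missing}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    vals = {k: np.asarray(cells[k], dtype=float) for k in CELLS}
    sizes = {v.size for v in vals.values()}
    if len(sizes) == 1:
        # one index stream shared across the (independent) cells: same
        # marginals, and relabeling cells permutes draws with the data
        idx = rng.integers(0, sizes.pop(), size=n_boot)
        draws = {k: v[idx] for k, v in vals.items()}
    else:
        draws = {k: v[rng.integers(0, v.size, size=n_boot)]
                 for k, v in vals.items()}
    lss, lhs = draws[("lapse", "SS")], draws[("lapse", "HS")]
    nss, nhs = draws[("normal", "SS")], draws[("normal", "HS")]
    return {
        "rt_class": (lss + lhs - nss - nhs) / 4.0,
        "sleep": (lss - lhs + nss - nhs) / 4.0,
        "interaction": (lss - lhs - nss + nhs) / 4.0,
    }


# --------------------------------------------------------------------------
# group inference
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SignRankResult:
    p: float
    tier: str
    direction: int
    n: int


def significance_tier(p: float) -> str:
    if p < SIGNIFICANT_P:
        return "significant"
    if p < TRENDING_P:
        return "trending"
    return "ns"


def group_signrank(
    coefficients: np.ndarray, direction: int | str = "auto"
) -> SignRankResult:
    """One-sided Wilcoxon signed-rank of per-subject coefficients vs zero.

    ``direction`` +1 tests for a positive median, -1 for negative;
    ``"auto"`` takes the sign of the group mean — convenient but
    exploratory, since choosing the tail from the data roughly doubles
    the effective one-sided type-I error (use a fixed direction for
    confirmatory calibration).
    """
    x = np.asarray(coefficients, dtype=float)
    if x.size < 5:
        raise ValueError("signed-rank test needs >= 5 subjects")
    if np.allclose(x, 0.0):
        warnings.warn("all coefficients zero: returning p = 1")
        return SignRankResult(p=1.0, tier="ns", direction=1, n=x.size)
    if direction == "auto":
        d = 1 if x.mean() >= 0 else -1
    else:
        d = int(direction)
        if d not in (1, -1):
            raise ValueError("direction must be +1, -1 or 'auto'")
    alternative = "greater" if d == 1 else "less"
    res = stats.wilcoxon(x, alternative=alternative)
    p = float(res.pvalue)
    return SignRankResult(p=p, tier=significance_tier(p), direction=d, n=x.size)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def _dataset_cells(
    timecourses: np.ndarray,
    index: pd.DataFrame,
    component: int,
    subject: str,
    bin_times: np.ndarray,
) -> dict[tuple[str, str], np.ndarray]:
    """24-point class curves per (class, condition) for one subject."""
    out = {}
    for cond in ("SS", "HS"):
        rows = index.index[(index["subject"] == subject)
                           & (index["condition"] == cond)]
        if len(rows) != 1:
            raise ValueError(f"subject {subject} needs exactly one {cond} dataset")
        tc48 = timecourses[rows[0], :, component]
        out[("normal", cond)] = tc48[: len(bin_times)]
        out[("lapse", cond)] = tc48[len(bin_times):]
    return out


def analyze_timecourses(
    timecourses: np.ndarray,
    index: pd.DataFrame,
    components: list[int] | None = None,
    bin_times: np.ndarray = BIN_TIMES_S,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
    direction: int | str = "auto",
    use_bootstrap_mean: bool = True,
) -> pd.DataFrame:
    """Full windowed-fit + two-level-bootstrap analysis of all components.

    ``timecourses`` has shape (n_datasets, 48, n_components) with frames
    ordered (class, bin): normal then lapse; ``index`` gives (subject,
    condition) per dataset.  For every component and parameter (pre:
    slope, intercept; early post: peak_height, peak_latency) the
    per-subject ANOVA coefficient distributions are reduced to their
    means (or point-fit values with ``use_bootstrap_mean=False``) and
    tested across subjects by signed rank.

    Returns the long-format results table: one row per (component,
    parameter, effect) with the group p-value, significance tier, mean
    coefficient and direction tested.
    """
    timecourses = np.asarray(timecourses, dtype=float)
    if components is None:
        components = list(range(timecourses.shape[2]))
    subjects = list(dict.fromkeys(index["subject"]))
    master = np.random.SeedSequence(seed)
    records = []
    for comp in components:
        # dominant direction from the group-mean early-post curve
        mean24 = timecourses[:, :, comp].reshape(len(index), 2, len(bin_times)).mean(
            axis=(0, 1)
        )
        seg = split_windows(mean24, bin_times)
        sign = response_sign(seg.early_values, seg.early_times)

        per_subject: dict[str, dict[tuple, dict[str, np.ndarray]]] = {}
        per_subject_point: dict[str, dict[tuple, dict[str, float]]] = {}
        for subj in subjects:
            cells24 = _dataset_cells(timecourses, index, comp, subj, bin_times)
            cell_dists: dict[tuple, dict[str, np.ndarray]] = {}
            cell_points: dict[tuple, dict[str, float]] = {}
            for key, tc24 in cells24.items():
                segs = split_windows(tc24, bin_times)
                rngs = [np.random.default_rng(s) for s in master.spawn(2)]
                pre = bootstrap_window_fit(
                    segs.pre_times, segs.pre_values, "pre",
                    n_boot=n_boot, rng=rngs[0],
                )
                post = bootstrap_window_fit(
                    segs.early_times, segs.early_values, "cubic",
                    n_boot=n_boot, rng=rngs[1], response_sign=sign,
                )
                cell_dists[key] = {
                    "slope": pre["slope"],
                    "intercept": pre["intercept"],
                    "peak_height": post["peak_height"],
                    "peak_latency": post["peak_latency"],
                }
                pre0 = fit_pre(segs.pre_times, segs.pre_values)
                pk0 = extract_first_peak(
                    fit_post_cubic(segs.early_times, segs.early_values).coefs,
                    response_sign=sign,
                )
                cell_points[key] = {
                    "slope": pre0.slope,
                    "intercept": pre0.intercept,
                    "peak_height": pk0.height,
                    "peak_latency": pk0.latency,
                }
            per_subject[subj] = cell_dists
            per_subject_point[subj] = cell_points

        for param in ("slope", "intercept", "peak_height", "peak_latency"):
            coef_means = {eff: [] for eff in EFFECTS}
            for subj in subjects:
                cells = {k: v[param] for k, v in per_subject[subj].items()}
                rng = np.random.default_rng(master.spawn(1)[0])
                if use_bootstrap_mean:
                    dists = subject_bootstrap_anova(cells, n_boot=n_boot, rng=rng)
                    for eff in EFFECTS:
                        coef_means[eff].append(float(dists[eff].mean()))
                else:  # point-fit coefficients (no cell resampling)
                    pts = {k: np.asarray([v[param]])
                           for k, v in per_subject_point[subj].items()}
                    dists = subject_bootstrap_anova(pts, n_boot=1, rng=rng)
                    for eff in EFFECTS:
                        coef_means[eff].append(float(dists[eff][0]))
            for eff in EFFECTS:
                coefs = np.asarray(coef_means[eff])
                res = group_signrank(coefs, direction=direction)
                records.append(
                    {
                        "component": comp,
                        "parameter": param,
                        "window": "pre" if param in ("slope", "intercept")
                        else "early_post",
                        "effect": eff,
                        "p": res.p,
                        "tier": res.tier,
                        "mean_coefficient": float(coefs.mean()),
                        "direction": res.direction,
                        "response_sign": sign,
                        "n_subjects": res.n,
                    }
                )
    return pd.DataFrame.from_records(records)


def build_results_table(results: pd.DataFrame,
                        parameters: tuple[str, ...] = ("peak_height",
                                                       "peak_latency")) -> pd.DataFrame:
    """Wide p-value table: rows component x parameter, columns the effects."""
    sub = results[results["parameter"].isin(parameters)]
    table = sub.pivot_table(
        index=["component", "parameter"], columns="effect", values="p"
    )[list(EFFECTS)]
    table.columns.name = None
    return table


def format_results_table(results: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Tier-notated table: ns / parenthesized trending / starred significant."""
    def fmt(p: float) -> str:
        tier = significance_tier(p)
        if tier == "ns":
            return "ns"
        if tier == "trending":
            return f"({p:.3g})"
        return f"{p:.3g}*"

    return build_results_table(results, **kwargs).map(fmt)


def mean_timecourse_table(
    timecourses: np.ndarray,
    index: pd.DataFrame,
    bin_times: np.ndarray = BIN_TIMES_S,
    classes: tuple[str, ...] = ("normal", "lapse"),
) -> pd.DataFrame:
    """Mean and SEM of per-dataset curves per component/condition/class."""
    timecourses = np.asarray(timecourses, dtype=float)
    rows = []
    for comp in range(timecourses.shape[2]):
        for cond in ("SS", "HS"):
            sel = np.asarray(index["condition"] == cond)
            for ci, cls in enumerate(classes):
                block = timecourses[sel, ci * len(bin_times):(ci + 1) * len(bin_times),
                                    comp]
                mean = block.mean(axis=0)
                sem = block.std(axis=0, ddof=1) / np.sqrt(block.shape[0])
                for t, m, s in zip(bin_times, mean, sem):
                    rows.append((comp, cond, cls, float(t), float(m), float(s)))
    return pd.DataFrame(
        rows, columns=["component", "condition", "rt_class", "bin_time",
                       "mean", "sem"]
    )
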