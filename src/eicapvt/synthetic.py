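"""Synthetic PVT sessions with known ground truth.

This module emulates the study conditions end to end so every pipeline
stage can be validated against an injected truth:

* **Stimulus schedules** — 14 consecutive sets, each a random permutation
  of the eight ISIs {3, 4, 5, 6, 8, 9, 10, 11} s, for 112 stimuli per
  session (~13 min of ISI time).  Trial-to-trial onset spacing is
  ISI + RT + 0.5 s of feedback by default; the feedback interval can be
  folded into the ISI instead (both conventions occur in PVT software).
* **Reaction-time streams** — a shifted-lognormal mixture: a fast
  "normal" component with a condition-dependent median, plus an explicit
  lapse component entirely above 500 ms.  The mixture weight makes the
  lapse probability an explicit dial; RTs are truncated at the 2.4-s
  alarm timeout.  Defaults follow the observed behavior: median RT
  ~377 ms (short sleep) / ~372 ms (healthy sleep) and lapse rates of
  roughly 13% / 10% of 112 trials.
* **Image sessions** — a small 4D grid (default 16 x 16 x 12 voxels,
  TR 2 s) containing spatially fixed Gaussian-blob networks.  Each
  network has a class- and condition-dependent evoked amplitude and
  latency (double-gamma response, translated in time), an optional
  pre-stimulus ramp, white (optionally AR(1)) noise, random-walk motion
  parameters, and optional injected artifact volumes that the QA stage
  must flag.

A single master seed fans out to named substreams (schedule, rt, noise,
motion) so each component is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import LAPSE_THRESHOLD_MS, classify_rts
from .session import SessionData

ISI_VALUES_S = (3.0, 4.0, 5.0, 6.0, 8.0, 9.0, 10.0, 11.0)
N_SETS = 14
FEEDBACK_S = 0.5
TIMEOUT_MS = 2400.0
TR_S = 2.0

__all__ = [
    "ISI_VALUES_S",
    "N_SETS",
    "FEEDBACK_S",
    "TIMEOUT_MS",
    "TR_S",
    "PvtSchedule",
    "RtModelParams",
    "GroundTruthNetwork",
    "SyntheticSessionSpec",
    "seed_streams",
    "generate_pvt_schedule",
    "generate_rt_stream",
    "effective_lapse_prob",
    "double_gamma",
    "canonical_response",
    "gaussian_blob_network",
    "default_networks",
    "synthesize_session",
    "synthesize_cohort",
]


def seed_streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Fan a master seed out into named independent generator streams."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PvtSchedule:
    """Stimulus schedule for one session.

    ``onsets`` are seconds from run start (strictly increasing); ``isis``
    the per-trial inter-stimulus interval.  Each consecutive block of
    ``len(isi_values)`` trials is a permutation of ``isi_values``.
    """

    onsets: np.ndarray
    isis: np.ndarray
    n_sets: int
    isi_values: tuple[float, ...]
    feedback_s: float = FEEDBACK_S

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def duration(self) -> float:
        """Time of the last onset (s)."""
        return float(self.onsets[-1])


def _onsets_from_gaps(
    isis: np.ndarray,
    rts_s: np.ndarray,
    feedback_s: float,
    isi_includes_feedback: bool,
    start_s: float,
) -> np.ndarray:
    """Cumulative onsets: gap before trial i is its ISI plus the previous
    trial's RT (and feedback unless folded into the ISI)."""
    extra = 0.0 if isi_includes_feedback else feedback_s
    gaps = isis.copy()
    gaps[1:] += rts_s[:-1] + extra
    return start_s + np.cumsum(gaps)


def generate_pvt_schedule(
    n_sets: int = N_SETS,
    isi_values: tuple[float, ...] = ISI_VALUES_S,
    feedback_s: float = FEEDBACK_S,
    seed: int | np.random.Generator = 0,
    rt_s: float | np.ndarray = 0.0,
    isi_includes_feedback: bool = False,
    start_s: float = 0.0,
) -> PvtSchedule:
    """Generate a PVT stimulus schedule.

    Each of the ``n_sets`` consecutive sets presents every ISI value once
    in random order.  ``rt_s`` (scalar or per-trial array, seconds) is
    the response time assumed when spacing onsets; pass the actual RTs
    (via :func:`reschedule_with_rts`) for response-dependent spacing.

    Raises on ``n_sets < 1`` or non-positive ISI values.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    isi_values = tuple(float(v) for v in isi_values)
    if len(isi_values) == 0 or any(v <= 0 for v in isi_values):
        raise ValueError("isi_values must be non-empty and positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    isis = np.concatenate(
        [rng.permutation(isi_values) for _ in range(n_sets)]
    )
    n = len(isis)
    rts = np.broadcast_to(np.asarray(rt_s, dtype=float), (n,)).copy()
    onsets = _onsets_from_gaps(isis, rts, feedback_s, isi_includes_feedback, start_s)
    return PvtSchedule(onsets=onsets, isis=isis, n_sets=n_sets,
                       isi_values=isi_values, feedback_s=feedback_s)


def reschedule_with_rts(
    schedule: PvtSchedule,
    rts_ms: np.ndarray,
    isi_includes_feedback: bool = False,
    start_s: float = 0.0,
) -> PvtSchedule:
    """Recompute onsets so each gap is ISI + previous RT (+ feedback)."""
    rts_s = np.asarray(rts_ms, dtype=float) / 1000.0
    if len(rts_s) != schedule.n_trials:
        raise ValueError("need one RT per trial")
    onsets = _onsets_from_gaps(
        schedule.isis, rts_s, schedule.feedback_s, isi_includes_feedback, start_s
    )
    return replace(schedule, onsets=onsets)


# --------------------------------------------------------------------------
# reaction times
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RtModelParams:
    """Shifted-lognormal mixture for one condition's RTs.

    The normal component is ``shift_ms + LogNormal`` with median
    ``median_ms - shift_ms`` and log-sd ``spread_ms / (median_ms -
    shift_ms)`` (so ``spread_ms`` is roughly the sd of the fast
    component in ms).  With probability ``lapse_prob`` the trial instead
    draws from the lapse component, ``500 + LogNormal`` with median
    ``lapse_median_extra_ms``.  All draws are truncated at
    ``timeout_ms`` (the alarm).
    """

    median_ms: float = 372.0
    spread_ms: float = 50.0
    lapse_prob: float = 0.10
    shift_ms: float = 180.0
    lapse_median_extra_ms: float = 250.0
    lapse_log_sd: float = 0.5
    timeout_ms: float = TIMEOUT_MS
    #: linear increase of response speed 1/RT (1/s) per second of ISI,
    #: centered on the mean ISI; models the preparation benefit of long ISIs
    isi_speed_slope: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_prob <= 1.0):
            raise ValueError("lapse_prob must lie in [0, 1]")
        if self.median_ms <= 200.0:
            raise ValueError("median_ms must exceed 200 ms")
        if self.median_ms <= self.shift_ms:
            raise ValueError("median_ms must exceed shift_ms")


#: defaults that emulate the observed behavior per condition
DEFAULT_RT_PARAMS = {
    "SS": RtModelParams(median_ms=376.8, lapse_prob=0.13),
    "HS": RtModelParams(median_ms=371.6, lapse_prob=0.10),
}


def generate_rt_stream(
    schedule: PvtSchedule,
    params: RtModelParams,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw one RT (ms) per scheduled trial."""
    if schedule.n_trials == 0:
        raise ValueError("schedule is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.n_trials

    # ISI-dependent median of the fast component (speed-domain linear)
    base_speed = 1000.0 / params.median_ms  # 1/s
    d_isi = schedule.isis - np.mean(schedule.isi_values)
    speed = base_speed + params.isi_speed_slope * d_isi
    speed = np.clip(speed, 1000.0 / params.timeout_ms, None)
    median_i = 1000.0 / speed  # ms, trial-wise

    body = median_i - params.shift_ms
    sigma = params.spread_ms / (params.median_ms - params.shift_ms)
    normal_rt = params.shift_ms + body * np.exp(sigma * rng.standard_normal(n))
    lapse_rt = LAPSE_THRESHOLD_MS + params.lapse_median_extra_ms * np.exp(
        params.lapse_log_sd * rng.standard_normal(n)
    )
    is_lapse = rng.random(n) < params.lapse_prob
    rts = np.where(is_lapse, lapse_rt, normal_rt)
    return np.minimum(rts, params.timeout_ms)


def effective_lapse_prob(params: RtModelParams) -> float:
    """Closed-form P(RT > 500 ms) of the mixture (lapse dial + fast tail)."""
    body = params.median_ms - params.shift_ms
    sigma = params.spread_ms / body
    thr = LAPSE_THRESHOLD_MS - params.shift_ms
    tail = stats.lognorm.sf(thr, s=sigma, scale=body) if thr > 0 else 1.0
    return float(params.lapse_prob + (1.0 - params.lapse_prob) * tail)


# --------------------------------------------------------------------------
# hemodynamic response and networks
# --------------------------------------------------------------------------

def double_gamma(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak height.

    Zero for t < 0; the positive lobe peaks near ``peak_delay`` s and is
    followed by an undershoot.  Scaled so the maximum equals 1, which
    makes network amplitudes read directly as peak signal change.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    h = h - undershoot_ratio * stats.gamma.pdf(
        t, undershoot_delay / dispersion, scale=dispersion
    )
    grid = np.linspace(0.0, 32.0, 3201)
    peak = (
        stats.gamma.pdf(grid, peak_delay / dispersion, scale=dispersion)
        - undershoot_ratio
        * stats.gamma.pdf(grid, undershoot_delay / dispersion, scale=dispersion)
    ).max()
    return h / peak


def canonical_response(
    t: np.ndarray,
    amp: float = 1.0,
    latency_shift: float = 0.0,
    peak_delay: float = 6.0,
    dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    support_s: float | None = None,
) -> np.ndarray:
    """Evoked response at peri-stimulus times ``t`` (s): amplitude-scaled,
    time-translated double-gamma.

    ``support_s`` truncates the response to [0, support_s) after the
    latency shift; the default keeps the full (infinite) tail.  A support
    equal to the deconvolution window makes the evoked signal exactly
    representable by the FIR basis, which the exact-recovery tests rely
    on; the residual tail beyond +32 s is otherwise of order 1e-4 of the
    peak.
    """
    dt = np.asarray(t, dtype=float) - latency_shift
    h = amp * double_gamma(dt, peak_delay=peak_delay, dispersion=dispersion,
                           undershoot_ratio=undershoot_ratio)
    if support_s is not None:
        h = np.where((dt >= 0) & (dt < support_s), h, 0.0)
    return h


CellKey = tuple[str, str]  # (rt_class, condition), e.g. ("lapse", "SS")


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A spatially fixed network with class/condition-dependent responses.

    ``amp`` maps (rt_class, condition) to peak evoked amplitude in signal
    units (negative for task-negative networks); ``latency_shift`` to a
    temporal translation in seconds; ``prestim_slope`` to a pre-stimulus
    ramp in units/s over the 16 s preceding each event.  The amplitude
    sign must be constant across cells.
    """

    name: str
    spatial_map: np.ndarray
    amp: dict[CellKey, float]
    latency_shift: dict[CellKey, float] = field(default_factory=dict)
    prestim_slope: dict[CellKey, float] = field(default_factory=dict)
    peak_delay: float = 6.0
    dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    #: truncate the evoked response to [0, support_s); None = full tail
    support_s: float | None = None

    def __post_init__(self) -> None:
        signs = {np.sign(v) for v in self.amp.values() if v != 0}
        if len(signs) > 1:
            raise ValueError(f"network {self.name}: amp sign must be constant")

    @property
    def sign(self) -> int:
        vals = [v for v in self.amp.values() if v != 0]
        return int(np.sign(vals[0])) if vals else 1

    def cell(self, rt_class: str, condition: str) -> tuple[float, float, float]:
        key = (rt_class, condition)
        return (
            self.amp.get(key, 0.0),
            self.latency_shift.get(key, 0.0),
            self.prestim_slope.get(key, 0.0),
        )


def gaussian_blob_network(
    shape: tuple[int, int, int],
    centers: list[tuple[float, float, float]],
    sigma_vox: float = 1.5,
    **kwargs,
) -> GroundTruthNetwork:
    """Build a network whose spatial map is a sum of Gaussian blobs,
    truncated to finite support at 3 sigma."""
    grid = np.indices(shape, dtype=float)
    m = np.zeros(shape)
    for c in centers:
        d2 = sum((grid[i] - c[i]) ** 2 for i in range(3))
        blob = np.exp(-d2 / (2.0 * sigma_vox**2))
        blob[d2 > (3.0 * sigma_vox) ** 2] = 0.0
        m += blob
    return GroundTruthNetwork(spatial_map=m, **kwargs)


def default_networks(
    shape: tuple[int, int, int] = (16, 16, 12),
    lapse_amp_factor: float = 1.6,
    lapse_latency_shift_s: float = 1.0,
    ss_normal_factor: float = 0.85,
    sigma_vox: float = 1.8,
) -> list[GroundTruthNetwork]:
    """Four study-flavored networks on the given grid.

    Three task-positive networks (fronto-parietal-, sensorimotor- and
    visual-like) and one task-negative (default-mode-like), each a
    multi-nodal set of Gaussian blobs.  The networks differ temporally —
    peak delay, response width, undershoot depth and pre-stimulus trend —
    as real networks do; temporal diversity is also what makes the
    spatial sources identifiable, since sources whose time courses are
    collinear at the noise level cannot be separated by any
    decomposition.  Lapses get ``lapse_amp_factor`` times the normal
    amplitude and a delayed peak in every network; the normal response
    under short sleep is attenuated by ``ss_normal_factor`` — the
    phenomenology the method is meant to recover.  Amplitudes are peak
    signal change in image units (~1% of the default baseline of 100).
    """
    nx, ny, nz = shape

    def at(fx: float, fy: float, fz: float) -> tuple[float, float, float]:
        return (nx * fx, ny * fy, nz * fz)

    def cells(base: float, lapse_fac: float) -> dict[CellKey, float]:
        return {
            ("normal", "HS"): base,
            ("normal", "SS"): base * ss_normal_factor,
            ("lapse", "HS"): base * lapse_fac,
            ("lapse", "SS"): base * lapse_fac,
        }

    def lat(shift: float) -> dict[CellKey, float]:
        return {("lapse", "HS"): shift, ("lapse", "SS"): shift}

    def pre(slope: float) -> dict[CellKey, float]:
        if slope == 0.0:
            return {}
        return {(c, cond): slope for c in ("normal", "lapse")
                for cond in ("SS", "HS")}

    # name, node centers, base amp, peak delay, dispersion, undershoot,
    # lapse amp factor (x lapse_amp_factor/1.6), latency factor, prestim
    specs = [
        ("frontoparietal",
         [at(0.25, 0.70, 0.60), at(0.70, 0.75, 0.65), at(0.50, 0.80, 0.40)],
         1.0, 5.5, 1.0, 1 / 6, 1.0, 1.0, -0.012),
        ("default_mode",
         [at(0.50, 0.25, 0.50), at(0.25, 0.38, 0.33), at(0.75, 0.38, 0.33)],
         -1.0, 7.5, 1.3, 0.0, 1.0, 1.0, +0.012),
        ("sensorimotor",
         [at(0.70, 0.50, 0.75), at(0.30, 0.50, 0.75)],
         1.2, 4.0, 0.7, 1 / 3, 1.125, 0.5, 0.0),
        ("visual",
         [at(0.50, 0.88, 0.25), at(0.30, 0.82, 0.25), at(0.70, 0.82, 0.25)],
         1.0, 6.5, 0.85, 0.05, 0.9375, 2.0, +0.006),
    ]
    return [
        gaussian_blob_network(
            shape,
            centers,
            sigma_vox=sigma_vox,
            name=name,
            amp=cells(base, lapse_amp_factor * lfac),
            latency_shift=lat(lapse_latency_shift_s * lat_fac),
            prestim_slope=pre(slope),
            peak_delay=delay,
            dispersion=disp,
            undershoot_ratio=under,
        )
        for name, centers, base, delay, disp, under, lfac, lat_fac, slope
        in specs
    ]


# --------------------------------------------------------------------------
# session synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSessionSpec:
    """Acquisition and noise model for one synthetic session."""

    shape: tuple[int, int, int] = (16, 16, 12)
    tr: float = TR_S
    n_volumes: int | None = None  # None -> cover last onset + 32 s
    baseline: float = 100.0
    noise_sigma: float = 0.5
    ar_rho: float = 0.0
    motion_step_mm: float = 0.02
    motion_step_rad: float = 2e-4
    artifact_volumes: tuple[int, ...] = ()
    artifact_motion_mm: float = 4.0
    artifact_intensity: float = 5.0
    discard_lead: int = 0
    seed: int = 0

    def resolve_n_volumes(self, schedule: PvtSchedule) -> int:
        needed = int(np.ceil((schedule.duration + 32.0) / self.tr)) + 1
        if self.n_volumes is None:
            return needed
        if self.n_volumes * self.tr < schedule.duration + 32.0:
            raise ValueError(
                f"n_volumes={self.n_volumes} does not cover the schedule "
                f"(needs >= {needed})"
            )
        return self.n_volumes


def evoked_network_series(
    times: np.ndarray,
    network: GroundTruthNetwork,
    events: pd.DataFrame,
    condition: str,
    prestim_window_s: float = 16.0,
) -> np.ndarray:
    """Noise-free network time course at scan ``times`` for one session.

    Every responded event contributes the canonical response of its RT
    class (spurious/ambiguous trials evoke the normal-class response: the
    brain responds even when the analysis relegates them) plus the
    class-specific pre-stimulus ramp over the ``prestim_window_s`` before
    onset.
    """
    series = np.zeros_like(times, dtype=float)
    for onset, rt_class in zip(events["onset"], events["rt_class"]):
        cls = rt_class if rt_class in ("normal", "lapse") else "normal"
        amp, lat, slope = network.cell(cls, condition)
        if amp != 0.0:
            series += canonical_response(
                times - onset, amp=amp, latency_shift=lat,
                peak_delay=network.peak_delay,
                dispersion=network.dispersion,
                undershoot_ratio=network.undershoot_ratio,
                support_s=network.support_s,
            )
        if slope != 0.0:
            pre = (times >= onset - prestim_window_s) & (times < onset)
            series[pre] += slope * (times[pre] - onset)
    return series


def _make_events(schedule: PvtSchedule, rts_ms: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset": schedule.onsets,
            "duration": np.asarray(rts_ms) / 1000.0,
            "isi": schedule.isis,
            "rt_ms": rts_ms,
            "rt_class": [str(c) for c in classify_rts(rts_ms)],
        }
    )


def synthesize_session(
    spec: SyntheticSessionSpec,
    schedule: PvtSchedule,
    rts_ms: np.ndarray,
    networks: list[GroundTruthNetwork],
    condition: str,
    subject: str = "sub-01",
) -> SessionData:
    """Render one 4D session: baseline + embedded networks + noise.

    Each voxel's series is ``baseline + sum_k map_k(voxel) * s_k(t) +
    noise`` where ``s_k`` is the network's noise-free evoked series.
    Injected artifact volumes receive both a motion jump and a global
    intensity spike so the QA thresholds fire.  Raises if the scan does
    not cover the schedule plus the 32-s post-stimulus window.
    """
    n_vol = spec.resolve_n_volumes(schedule)
    streams = seed_streams(spec.seed, "schedule", "rt", "noise", "motion")
    times = np.arange(n_vol) * spec.tr
    events = _make_events(schedule, np.asarray(rts_ms, dtype=float))

    nx, ny, nz = spec.shape
    n_vox = nx * ny * nz
    signal = np.zeros((n_vox, n_vol))
    for net in networks:
        if net.spatial_map.shape != spec.shape:
            raise ValueError(
                f"network {net.name} map shape {net.spatial_map.shape} != grid {spec.shape}"
            )
        series = evoked_network_series(times, net, events, condition)
        signal += net.spatial_map.reshape(-1, 1) * series[None, :]

    rng = streams["noise"]
    if spec.noise_sigma > 0:
        noise = rng.standard_normal((n_vox, n_vol)) * spec.noise_sigma
        if spec.ar_rho:
            for t in range(1, n_vol):
                noise[:, t] += spec.ar_rho * noise[:, t - 1]
        signal += noise

    image = (spec.baseline + signal).reshape(nx, ny, nz, n_vol)

    mrng = streams["motion"]
    motion = np.cumsum(
        mrng.standard_normal((n_vol, 6))
        * np.array([spec.motion_step_mm] * 3 + [spec.motion_step_rad] * 3),
        axis=0,
    )
    for idx in spec.artifact_volumes:
        if not (0 <= idx < n_vol):
            raise ValueError(f"artifact volume {idx} out of range")
        motion[idx:, 0] += spec.artifact_motion_mm  # sustained jump at idx
        image[..., idx] += spec.artifact_intensity  # global intensity spike

    return SessionData(
        image=image,
        tr=spec.tr,
        events=events,
        motion=motion,
        condition=condition,
        subject=subject,
        discard_lead=spec.discard_lead,
        ground_truth={
            "networks": [n.name for n in networks],
            "seed": spec.seed,
        },
    )


def synthesize_cohort(
    n_subjects: int,
    networks: list[GroundTruthNetwork],
    spec: SyntheticSessionSpec = SyntheticSessionSpec(),
    rt_params: dict[str, RtModelParams] | None = None,
    n_sets: int = N_SETS,
    seed: int = 0,
    conditions: tuple[str, ...] = ("SS", "HS"),
) -> list[SessionData]:
    """Synthesize a cohort: each subject scanned once per sleep condition.

    Every (subject, condition) session gets its own schedule, RT stream
    and noise seed, all fanned out from ``seed``.
    """
    rt_params = rt_params or DEFAULT_RT_PARAMS
    ss = np.random.SeedSequence(seed)
    sessions = []
    children = ss.spawn(n_subjects * len(conditions))
    i = 0
    for s in range(n_subjects):
        subject = f"sub-{s + 1:02d}"
        for cond in conditions:
            child = children[i]
            i += 1
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            streams = seed_streams(sub_seed, "schedule", "rt")
            sched = generate_pvt_schedule(
                n_sets=n_sets, seed=streams["schedule"], start_s=16.0
            )
            rts = generate_rt_stream(sched, rt_params[cond], seed=streams["rt"])
            sched = reschedule_with_rts(sched, rts, start_s=16.0)
            sess = synthesize_session(
                replace(spec, seed=sub_seed), sched, rts, networks, cond, subject
            )
            sessions.append(sess)
    return sessions
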