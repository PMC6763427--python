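"""End-to-end orchestration: synthesize -> QA -> deconvolve -> eICA -> stats.

A single JSON-serializable :class:`RunConfig` drives the whole run; every
random stage draws from named substreams of one master seed, so a config
reproduces its artifacts bit-identically.  The :class:`RunManifest`
records the config hash and per-stage checksums to make that verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ica as ica_mod
from . import qa as qa_mod
from . import synthetic, timecourse
from .fir import FirDeconvolver
from .session import SessionData

log = logging.getLogger("eicapvt")

STAGES = ("simulate", "qa", "deconvolve", "ica", "stats", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic demo by default)."""

    # cohort
    n_subjects: int = 8
    n_sets: int = synthetic.N_SETS
    grid: tuple[int, int, int] = (16, 16, 12)
    tr: float = synthetic.TR_S
    noise_sigma: float = 0.5
    # ground-truth effects
    lapse_amp_factor: float = 1.6
    lapse_latency_shift_s: float = 1.0
    ss_normal_factor: float = 0.85
    # decomposition
    n_components: int = 8
    dataset_dims: int = 30
    # statistics
    n_boot: int = 200
    direction: str | int = "auto"
    # thresholds
    qa_motion_mm: float = qa_mod.MOTION_THRESHOLD_MM
    qa_intensity_z: float = qa_mod.INTENSITY_Z_THRESHOLD
    z_threshold: float = ica_mod.Z_THRESHOLD
    consistency_threshold: float = 1.0
    rim_overlap_fraction: float = 0.25
    # variants
    short_isi_to_covariates: bool = False
    write_images: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        for name in ("qa_motion_mm", "qa_intensity_z", "z_threshold",
                     "consistency_threshold", "rim_overlap_fraction",
                     "noise_sigma", "tr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_components < 1 or self.dataset_dims < self.n_components // 2:
            raise ValueError("bad decomposition dims")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["grid"] = list(d["grid"])
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class RunArtifacts:
    sessions: list[SessionData] = field(default_factory=list)
    networks: list = field(default_factory=list)
    maps: list = field(default_factory=list)
    model: ica_mod.GroupEICA | None = None
    selection: ica_mod.ComponentSelection | None = None
    results: pd.DataFrame | None = None
    mean_timecourses: pd.DataFrame | None = None


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        if isinstance(a, pd.DataFrame):
            h.update(a.round(12).to_csv().encode())
        else:
            h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()[:16]


def rim_mask(shape: tuple[int, int, int], width: int = 1) -> np.ndarray:
    """Boundary mask of the grid: the synthetic analog of the brain
    periphery used to reject artifact-like components."""
    m = np.ones(shape, dtype=bool)
    m[width:-width, width:-width, width:-width] = False
    return m


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    stop_after: str = "report",
) -> tuple[RunManifest, RunArtifacts]:
    """Run the pipeline through ``stop_after``; returns manifest + artifacts.

    Stage order: simulate, qa, deconvolve, ica, stats, report.  Stage
    failures re-raise wrapped with the stage name.  With ``outdir`` the
    tabular artifacts (events, QA report, time courses, results tables,
    figures, manifest) are written there.
    """
    config.validate()
    if stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    last = STAGES.index(stop_after)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(config.to_json())

    manifest = RunManifest(config_hash=config.hash())
    art = RunArtifacts()

    def stage(name):
        def wrap(fn):
            if STAGES.index(name) > last:
                return
            t0 = time.time()
            try:
                fn()
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
            manifest.timings_s[name] = round(time.time() - t0, 3)
            log.info("stage %s done in %.1fs", name, manifest.timings_s[name])
        return wrap

    @stage("simulate")
    def _simulate():
        art.networks = synthetic.default_networks(
            config.grid,
            lapse_amp_factor=config.lapse_amp_factor,
            lapse_latency_shift_s=config.lapse_latency_shift_s,
            ss_normal_factor=config.ss_normal_factor,
        )
        spec = synthetic.SyntheticSessionSpec(
            shape=config.grid, tr=config.tr, noise_sigma=config.noise_sigma
        )
        art.sessions = synthetic.synthesize_cohort(
            config.n_subjects, art.networks, spec=spec, n_sets=config.n_sets,
            seed=config.seed,
        )
        manifest.checksums["simulate"] = _checksum(
            *(s.image[..., :8] for s in art.sessions)
        )
        if outdir is not None:
            for s in art.sessions:
                s.events.to_csv(
                    outdir / f"{s.subject}_{s.condition}_events.tsv",
                    sep="\t", index=False,
                )
                if config.write_images:
                    s.write(outdir)

    @stage("qa")
    def _qa():
        art.sessions = [
            qa_mod.run_qa(
                s,
                motion_threshold=config.qa_motion_mm,
                z_threshold=config.qa_intensity_z,
            )
            for s in art.sessions
        ]
        dropped = [s for s in art.sessions if not qa_mod.session_usable(s)]
        for s in dropped:
            manifest.warnings.append(
                f"session {s.subject}/{s.condition} rejected by QA"
            )
        art.sessions = [s for s in art.sessions if qa_mod.session_usable(s)]
        manifest.checksums["qa"] = _checksum(
            np.concatenate([s.qa_outliers for s in art.sessions])
            if any(s.qa_outliers.size for s in art.sessions)
            else np.zeros(1)
        )
        if outdir is not None:
            qa_mod.write_qa_report(art.sessions, outdir / "qa_report.json")

    @stage("deconvolve")
    def _deconvolve():
        art.maps = []
        for s in art.sessions:
            dec = FirDeconvolver(
                short_isi_to_covariates=config.short_isi_to_covariates
            ).fit(s)
            log.info(
                "FIR %s/%s condition number %.1f",
                s.subject, s.condition, dec.condition_number_,
            )
            art.maps.append(dec.maps_)
        manifest.checksums["deconvolve"] = _checksum(*(m.maps for m in art.maps))

    @stage("ica")
    def _ica():
        model = ica_mod.GroupEICA(
            n_components=config.n_components,
            dataset_dims=config.dataset_dims,
            random_state=config.seed,
        ).fit(art.maps)
        art.model = model
        art.selection = ica_mod.select_components(
            model,
            rim_mask(config.grid),
            overlap_fraction=config.rim_overlap_fraction,
            consistency_threshold=config.consistency_threshold,
            z_threshold=config.z_threshold,
        )
        if not model.converged_:
            manifest.warnings.append("Infomax did not fully converge")
        manifest.checksums["ica"] = _checksum(model.group_maps_, model.timecourses_)
        if outdir is not None:
            model.timecourse_table().to_csv(outdir / "timecourses.csv", index=False)
            (outdir / "selection.json").write_text(json.dumps(
                {
                    "retained": art.selection.retained,
                    "rejected": {str(k): v for k, v in
                                 art.selection.rejected.items()},
                    "consistency": {str(k): round(v, 4) for k, v in
                                    art.selection.consistency.items()},
                }, indent=1))

    @stage("stats")
    def _stats():
        comps = art.selection.retained or list(range(config.n_components))
        art.results = timecourse.analyze_timecourses(
            art.model.timecourses_,
            art.model.index_,
            components=comps,
            n_boot=config.n_boot,
            seed=config.seed,
            direction=config.direction,
        )
        art.mean_timecourses = timecourse.mean_timecourse_table(
            art.model.timecourses_, art.model.index_
        )
        manifest.checksums["stats"] = _checksum(
            art.results.drop(columns=["tier"])
        )
        if outdir is not None:
            art.results.to_csv(outdir / "results.csv", index=False)
            timecourse.build_results_table(art.results).to_csv(
                outdir / "pvalue_table.csv"
            )
            art.mean_timecourses.to_csv(outdir / "mean_timecourses.csv",
                                        index=False)

    @stage("report")
    def _report():
        if outdir is not None:
            render_report(art, outdir)
            formatted = timecourse.format_results_table(art.results)
            (outdir / "results_table.txt").write_text(formatted.to_string())
        manifest.checksums["report"] = manifest.checksums.get("stats", "")

    if outdir is not None:
        (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest, art


def render_report(art: RunArtifacts, outdir: str | Path) -> list[Path]:
    """Figure per retained component: mean time course with SEM error bars,
    split by sleep condition and RT class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if art.results is None or art.mean_timecourses is None:
        raise ValueError("stats stage outputs missing; run stats first")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    comps = sorted(art.results["component"].unique())
    mt = art.mean_timecourses
    for comp in comps:
        sub = mt[mt["component"] == comp]
        if sub.empty:
            log.warning("component %d has no time-course data; skipped", comp)
            continue
        fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
        for ax, cls in zip(axes, ("normal", "lapse")):
            for cond, color in (("SS", "tab:red"), ("HS", "tab:blue")):
                d = sub[(sub["rt_class"] == cls) & (sub["condition"] == cond)]
                ax.errorbar(d["bin_time"], d["mean"], yerr=d["sem"],
                            label=cond, color=color, capsize=2)
            ax.axvline(0.0, color="k", lw=0.5)
            ax.set_title(f"component {comp}: {cls}")
            ax.set_xlabel("peri-stimulus time (s)")
        axes[0].set_ylabel("response (a.u.)")
        axes[0].legend()
        path = outdir / f"component_{comp:02d}_timecourse.png"
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
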