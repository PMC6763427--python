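"""Finite-impulse-response deconvolution of peri-stimulus responses.

The evoked response is modeled with one free parameter per 2-s
peri-stimulus bin, 24 bins spanning 16 s before to 32 s after each
stimulus, separately for the two analyzed RT classes (normal, lapse) —
48 event parameters per session.  Bin k is the half-open interval
[-16 + 2k, -16 + 2(k+1)) s so each scan time within a window belongs to
exactly one bin.  Spurious (< 200 ms) and ambiguous (450-500 ms)
responses receive their own nuisance FIR blocks; the six motion
parameters, one-hot indicators for artifact volumes, an intercept, and a
linear drift complete the design.  Estimation is voxel-wise ordinary
least squares.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .session import SessionData

WINDOW_S = (-16.0, 32.0)
N_BINS = 24
BIN_WIDTH_S = 2.0
#: left edge of each peri-stimulus bin (s relative to stimulus onset)
BIN_TIMES_S = WINDOW_S[0] + BIN_WIDTH_S * np.arange(N_BINS)
ANALYZED_CLASSES = ("normal", "lapse")
NUISANCE_CLASSES = ("spurious", "ambiguous")
#: short-ISI trials relegated to covariates in the supplementary variant
SHORT_ISI_MAX_S = 4.0

__all__ = [
    "WINDOW_S",
    "N_BINS",
    "BIN_TIMES_S",
    "ANALYZED_CLASSES",
    "FirDesign",
    "DeconvMaps",
    "peristim_bin",
    "build_fir_design",
    "fit_fir",
    "FirDeconvolver",
]


def peristim_bin(
    t_scan: float,
    t_event: float,
    tr: float = 2.0,
    window: tuple[float, float] = WINDOW_S,
) -> int | None:
    """Peri-stimulus bin index of a scan time, or None outside the window.

    Returns k iff t_scan - t_event lies in [window0 + 2k, window0 + 2(k+1))
    for k in 0..23.  The window end (+32 s) is excluded (half-open bins).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = t_scan - t_event
    if dt < window[0] or dt >= window[1]:
        return None
    k = int(np.floor((dt - window[0]) / BIN_WIDTH_S + 1e-9))
    return k if 0 <= k < N_BINS else None


@dataclass
class FirDesign:
    """Design matrix with labeled columns.

    ``column_labels`` entries are tuples: ``("fir", rt_class, bin)`` for
    event columns, ``("motion", i)``, ``("outlier", volume)``,
    ``("drift", order)``.
    """

    matrix: np.ndarray
    column_labels: list[tuple]
    tr: float
    window: tuple[float, float] = WINDOW_S
    warnings_: list[str] = field(default_factory=list)

    @property
    def fir_columns(self) -> list[int]:
        return [i for i, lab in enumerate(self.column_labels) if lab[0] == "fir"]

    def fir_index(self, classes: tuple[str, ...] = ANALYZED_CLASSES) -> list[int]:
        """Column indices of the analyzed-class FIR block, ordered (class, bin)."""
        out = []
        for cls in classes:
            for k in range(N_BINS):
                out.append(self.column_labels.index(("fir", cls, k)))
        return out

    def to_frame(self) -> pd.DataFrame:
        names = ["_".join(str(p) for p in lab) for lab in self.column_labels]
        return pd.DataFrame(self.matrix, columns=names)


def build_fir_design(
    session: SessionData,
    window: tuple[float, float] = WINDOW_S,
    tr: float | None = None,
    drift: bool = True,
    short_isi_to_covariates: bool = False,
) -> FirDesign:
    """Build the peri-stimulus FIR design for one session.

    Every event of an analyzed class adds 1 to column (class, k) at each
    scan falling in its bin k; overlapping windows of nearby events
    superpose additively.  With ``short_isi_to_covariates`` the analyzed
    trials whose ISI is 3 or 4 s are relegated to an extra nuisance FIR
    block (the supplementary variant).
    """
    tr = tr if tr is not None else session.tr
    times = np.arange(session.n_volumes) * tr
    events = session.events

    def block_of(rt_class: str, isi: float) -> str:
        if (
            short_isi_to_covariates
            and rt_class in ANALYZED_CLASSES
            and isi <= SHORT_ISI_MAX_S
        ):
            return "short_isi"
        return rt_class

    blocks = [block_of(c, i) for c, i in zip(events["rt_class"], events["isi"])]
    nuisance_present = sorted(
        {b for b in blocks if b not in ANALYZED_CLASSES}
    )
    fir_classes = list(ANALYZED_CLASSES) + nuisance_present

    cols: dict[tuple, np.ndarray] = {}
    for cls in fir_classes:
        for k in range(N_BINS):
            cols[("fir", cls, k)] = np.zeros(len(times))
    for onset, blk in zip(events["onset"], blocks):
        lo = onset + window[0]
        hi = onset + window[1]
        j0 = max(0, int(np.ceil((lo - 1e-9) / tr)))
        j1 = min(len(times) - 1, int(np.floor((hi - 1e-9) / tr)))
        for j in range(j0, j1 + 1):
            k = peristim_bin(times[j], onset, tr, window)
            if k is not None:
                cols[("fir", blk, k)][j] += 1.0

    warns = []
    for cls in ANALYZED_CLASSES:
        if not any(b == cls for b in blocks):
            msg = f"no {cls} events: its 24 FIR columns are all zero"
            warns.append(msg)
            warnings.warn(msg)

    labels = list(cols.keys())
    matrix = [cols[lab] for lab in labels]

    for i in range(6):
        labels.append(("motion", i))
        matrix.append(session.motion[:, i] - session.motion[:, i].mean())
    for v in session.qa_outliers:
        onehot = np.zeros(len(times))
        onehot[v] = 1.0
        labels.append(("outlier", int(v)))
        matrix.append(onehot)
    labels.append(("drift", 0))
    matrix.append(np.ones(len(times)))
    if drift:
        labels.append(("drift", 1))
        matrix.append(np.linspace(-1.0, 1.0, len(times)))

    return FirDesign(
        matrix=np.column_stack(matrix),
        column_labels=labels,
        tr=tr,
        window=window,
        warnings_=warns,
    )


@dataclass
class DeconvMaps:
    """48 peri-stimulus parameter maps: the "pseudo time series" of a session.

    ``maps[i]`` is the flattened (or 3D) parameter map of frame i; frames
    are ordered (class, bin): 0-23 normal, 24-47 lapse.  Units: signal
    change per event.
    """

    maps: np.ndarray  # (48, x, y, z)
    bin_times: np.ndarray
    classes: tuple[str, ...]
    subject: str
    condition: str
    condition_number: float = np.nan

    @property
    def n_frames(self) -> int:
        return self.maps.shape[0]

    def frame_labels(self) -> list[tuple[str, float]]:
        return [
            (cls, float(t)) for cls in self.classes for t in self.bin_times
        ]

    def class_maps(self, rt_class: str) -> np.ndarray:
        i = self.classes.index(rt_class)
        return self.maps[i * N_BINS : (i + 1) * N_BINS]

    def write(self, path: str | Path) -> None:
        """4D NIfTI (48 frames) + JSON sidecar with (class, bin_time)."""
        path = Path(path)
        img = nib.Nifti1Image(
            np.moveaxis(self.maps, 0, -1).astype(np.float32),
            np.diag([3.0, 3.0, 3.0, 1.0]),
        )
        nib.save(img, path)
        sidecar = {
            "subject": self.subject,
            "condition": self.condition,
            "frames": [
                {"class": c, "bin_time_s": t} for c, t in self.frame_labels()
            ],
            "condition_number": None
            if np.isnan(self.condition_number)
            else self.condition_number,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def fit_fir(
    image: np.ndarray,
    design: FirDesign,
    ridge: bool = False,
    subject: str = "sub-01",
    condition: str = "SS",
) -> DeconvMaps:
    """Voxel-wise OLS of the session image on the FIR design.

    All-zero columns (absent event classes) are excluded from the solve
    and returned as zero maps.  A rank-deficient design raises with the
    offending columns named unless ``ridge`` enables the small-ridge
    fallback (lambda = 1e-6 x mean Gram diagonal).
    """
    image = np.asarray(image, dtype=float)
    n_vol = image.shape[-1]
    X = design.matrix
    if X.shape[0] != n_vol:
        raise ValueError(f"design rows ({X.shape[0]}) != volumes ({n_vol})")
    Y = image.reshape(-1, n_vol).T  # (t, voxels)

    nonzero = np.flatnonzero(np.abs(X).sum(axis=0) > 0)
    Xn = X[:, nonzero]
    gram = Xn.T @ Xn
    rank = np.linalg.matrix_rank(Xn)
    cond = float(np.linalg.cond(Xn))
    if rank < Xn.shape[1]:
        if not ridge:
            # name candidate collinear columns: near-zero pivots of the Gram QR
            _, r = np.linalg.qr(gram)
            bad = np.flatnonzero(np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max())
            names = [design.column_labels[nonzero[i]] for i in bad]
            raise np.linalg.LinAlgError(
                f"FIR design rank deficient (rank {rank} < {Xn.shape[1]}); "
                f"collinear columns: {names}; enable ridge fallback to proceed"
            )
        warnings.warn("rank-deficient FIR design: applying small-ridge fallback")
        lam = 1e-6 * np.mean(np.diag(gram))
        beta_n = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), Xn.T @ Y)
    else:
        beta_n, *_ = np.linalg.lstsq(Xn, Y, rcond=None)

    beta = np.zeros((X.shape[1], Y.shape[1]))
    beta[nonzero] = beta_n

    fir_idx = design.fir_index()
    maps = beta[fir_idx].reshape(len(fir_idx), *image.shape[:-1])
    return DeconvMaps(
        maps=maps,
        bin_times=BIN_TIMES_S.copy(),
        classes=ANALYZED_CLASSES,
        subject=subject,
        condition=condition,
        condition_number=cond,
    )


class FirDeconvolver(BaseEstimator):
    """Estimator wrapper: fit the 48-parameter FIR model to a session.

    Parameters
    ----------
    window : (float, float)
        Peri-stimulus window in seconds (default -16 to +32).
    drift : bool
        Include a linear drift column besides the intercept.
    ridge : bool
        Enable the small-ridge fallback for rank-deficient designs.
    short_isi_to_covariates : bool
        Relegate 3-4-s-ISI trials to a nuisance FIR block.

    Attributes (after fit)
    ----------------------
    design_ : FirDesign
    maps_ : DeconvMaps
    condition_number_ : float
    """

    def __init__(
        self,
        window: tuple[float, float] = WINDOW_S,
        drift: bool = True,
        ridge: bool = False,
        short_isi_to_covariates: bool = False,
    ):
        self.window = window
        self.drift = drift
        self.ridge = ridge
        self.short_isi_to_covariates = short_isi_to_covariates

    def fit(self, session: SessionData, y=None) -> "FirDeconvolver":
        self.design_ = build_fir_design(
            session,
            window=self.window,
            drift=self.drift,
            short_isi_to_covariates=self.short_isi_to_covariates,
        )
        self.maps_ = fit_fir(
            session.image,
            self.design_,
            ridge=self.ridge,
            subject=session.subject,
            condition=session.condition,
        )
        self.condition_number_ = self.maps_.condition_number
        return self

    def transform(self, session: SessionData) -> DeconvMaps:
        return self.fit(session).maps_
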