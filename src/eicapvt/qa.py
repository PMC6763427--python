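"""Volume-level quality assurance.

A volume is an artifact outlier if the volume-to-volume *composite
motion* exceeds 3 mm or the volume-to-volume global-intensity change has
|z| > 3 relative to the rest of the series.  Composite motion is the
maximum displacement of any point on a 65-mm-radius reference sphere
under the change in the rigid-body transform between consecutive volumes
— the convention of the standard automated artifact-detection toolbox,
whose exact formula is not published; this is a documented convention,
not a published definition.  Flagged volumes are not deleted: they become
one-hot nuisance regressors in the deconvolution design (scrubbing by
regression).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .session import SessionData, read_events, read_motion

HEAD_RADIUS_MM = 65.0
MOTION_THRESHOLD_MM = 3.0
INTENSITY_Z_THRESHOLD = 3.0
#: sessions with more than this fraction of flagged volumes are rejected
MAX_OUTLIER_FRACTION = 0.2


def _rigid_transform(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(R, t) for one 6-parameter row: tx, ty, tz (mm), rx, ry, rz (rad)."""
    from scipy.spatial.transform import Rotation

    t = np.asarray(params[:3], dtype=float)
    R = Rotation.from_euler("xyz", params[3:6]).as_matrix()
    return R, t


def composite_motion(motion: np.ndarray, head_radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Volume-to-volume composite motion (mm); element i refers to volume i.

    Element 0 is 0 by definition.  The measure is the maximum displacement
    over the six axis points at ``head_radius`` mm from the origin, so it
    is non-negative and exactly 0 for identical consecutive rows.
    """
    motion = np.asarray(motion, dtype=float)
    n = motion.shape[0]
    points = np.vstack([np.eye(3), -np.eye(3)]) * head_radius  # (6, 3)
    disp = np.zeros(n)
    R_prev, t_prev = _rigid_transform(motion[0])
    for i in range(1, n):
        R, t = _rigid_transform(motion[i])
        moved = points @ R.T + t - (points @ R_prev.T + t_prev)
        disp[i] = float(np.linalg.norm(moved, axis=1).max())
        R_prev, t_prev = R, t
    return disp


def detect_artifact_volumes(
    motion: np.ndarray,
    global_intensity: np.ndarray,
    motion_threshold: float = MOTION_THRESHOLD_MM,
    z_threshold: float = INTENSITY_Z_THRESHOLD,
    head_radius: float = HEAD_RADIUS_MM,
) -> np.ndarray:
    """Indices of artifact volumes.

    A volume is flagged when the composite motion from the previous
    volume exceeds ``motion_threshold`` mm, or when the z-score of its
    global-intensity change relative to the adjacent volume exceeds
    ``z_threshold`` in magnitude.  The later volume of each offending
    pair is flagged.  The z-scoring of the first-difference series makes
    the intensity criterion invariant to global intensity scaling.
    """
    motion = np.asarray(motion, dtype=float)
    g = np.asarray(global_intensity, dtype=float)
    if motion.shape[0] != g.shape[0]:
        raise ValueError(
            f"motion ({motion.shape[0]}) and intensity ({g.shape[0]}) lengths differ"
        )
    flagged = composite_motion(motion, head_radius) > motion_threshold
    dg = np.diff(g)
    sd = dg.std()
    if sd > 0:
        z = (dg - dg.mean()) / sd
        flagged[1:] |= np.abs(z) > z_threshold
    return np.flatnonzero(flagged)


def global_intensity(image: np.ndarray) -> np.ndarray:
    """Mean intensity per volume of a 4D series."""
    image = np.asarray(image, dtype=float)
    return image.reshape(-1, image.shape[3]).mean(axis=0)


def run_qa(session: SessionData, **kwargs) -> SessionData:
    """Attach artifact-volume flags to a session (idempotent)."""
    outliers = detect_artifact_volumes(
        session.motion, global_intensity(session.image), **kwargs
    )
    return session.replace(qa_outliers=outliers)


def session_usable(session: SessionData, max_fraction: float = MAX_OUTLIER_FRACTION) -> bool:
    """Whether the flagged-volume fraction is acceptable for analysis."""
    return session.qa_outliers.size <= max_fraction * session.n_volumes


def load_session(
    paths: dict,
    condition: str,
    subject: str = "sub-01",
    tr: float | None = None,
    discard_lead: int = 0,
    qa: bool = True,
) -> SessionData:
    """Load and validate one session from disk.

    ``paths`` maps ``image``/``events``/``motion`` (and optionally
    ``meta``) to files.  The initial ``discard_lead`` volumes (and motion
    rows) are dropped and event onsets are re-referenced to the first
    retained volume; events that then fall before the scan start are
    removed, events beyond the scan end raise.  If ``tr`` is given it
    must agree with the NIfTI header.
    """
    img = nib.load(str(paths["image"]))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise ValueError("TR missing from NIfTI header and not given")
        tr = header_tr
    elif header_tr > 0 and abs(header_tr - tr) > 1e-6:
        raise ValueError(f"TR mismatch: header {header_tr} s vs config {tr} s")

    events = read_events(paths["events"])
    motion = read_motion(paths["motion"])
    if motion.shape[0] != data.shape[3]:
        raise ValueError(
            f"motion rows ({motion.shape[0]}) != volumes ({data.shape[3]})"
        )

    if discard_lead:
        data = data[..., discard_lead:]
        motion = motion[discard_lead:]
        events = events.copy()
        events["onset"] = events["onset"] - discard_lead * tr
        dropped = events["onset"] < 0
        if dropped.any():
            warnings.warn(f"dropping {int(dropped.sum())} events before scan start")
            events = events.loc[~dropped].reset_index(drop=True)

    if len(events) and (events["onset"] >= data.shape[3] * tr).any():
        raise ValueError("event onset beyond scan end")

    session = SessionData(
        image=data,
        tr=tr,
        events=events,
        motion=motion,
        condition=condition,
        subject=subject,
        discard_lead=discard_lead,
    )
    if qa:
        session = run_qa(session)
    return session


def qa_report(session: SessionData) -> dict:
    """JSON-serializable QA summary for one session."""
    cm = composite_motion(session.motion)
    return {
        "subject": session.subject,
        "condition": session.condition,
        "n_volumes": session.n_volumes,
        "n_outliers": int(session.qa_outliers.size),
        "outlier_indices": [int(i) for i in session.qa_outliers],
        "outlier_fraction": float(session.qa_outliers.size / session.n_volumes),
        "max_composite_motion_mm": float(cm.max()),
        "usable": session_usable(session),
    }


def write_qa_report(sessions: list[SessionData], path: str | Path) -> None:
    Path(path).write_text(json.dumps([qa_report(s) for s in sessions], indent=1))
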