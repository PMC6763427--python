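"""The per-session data container and its on-disk representation.

A session is one PVT run in the scanner: a preprocessed 4D image series,
the event table (onset, ISI, RT, RT class), the six rigid-body motion
parameters per volume, and the sleep-condition label.  Images travel as
NIfTI with the TR in the header; events as a tab-separated table; motion
as whitespace-delimited text (translations in mm, rotations in radians).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

EVENT_COLUMNS = ["onset", "duration", "isi", "rt_ms", "rt_class"]

CONDITIONS = ("SS", "HS")  # short sleep / healthy sleep


@dataclass
class SessionData:
    """One scanned PVT session, ready for deconvolution.

    Attributes
    ----------
    image : ndarray, shape (x, y, z, t)
        Preprocessed BOLD series (lead volumes already discarded).
    tr : float
        Repetition time in seconds.
    events : DataFrame
        Columns ``onset`` (s, relative to the first retained volume),
        ``duration`` (s), ``isi`` (s), ``rt_ms``, ``rt_class``.
    motion : ndarray, shape (t, 6)
        Rigid-body parameters per retained volume (mm, radians).
    condition : str
        ``"SS"`` or ``"HS"``.
    qa_outliers : ndarray of int
        Indices of volumes flagged by artifact detection.
    discard_lead : int
        Number of initial volumes dropped before ``image``.
    """

    image: np.ndarray
    tr: float
    events: pd.DataFrame
    motion: np.ndarray
    condition: str
    subject: str = "sub-01"
    qa_outliers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    discard_lead: int = 0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.qa_outliers = np.asarray(self.qa_outliers, dtype=int)
        if self.image.ndim != 4:
            raise ValueError("image must be 4D (x, y, z, t)")
        if self.motion.shape != (self.n_volumes, 6):
            raise ValueError(
                f"motion must be ({self.n_volumes}, 6), got {self.motion.shape}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if len(self.events):
            end = self.n_volumes * self.tr
            if (self.events["onset"] >= end).any():
                raise ValueError("event onset beyond scan end")
        if self.qa_outliers.size and (
            self.qa_outliers.min() < 0 or self.qa_outliers.max() >= self.n_volumes
        ):
            raise ValueError("qa_outliers out of volume range")

    @property
    def n_volumes(self) -> int:
        return self.image.shape[3]

    @property
    def scan_times(self) -> np.ndarray:
        """Acquisition time of each retained volume (s)."""
        return np.arange(self.n_volumes) * self.tr

    # ---------------------------------------------------------------- I/O

    def write(self, directory: str | Path, prefix: str | None = None) -> dict:
        """Write image/events/motion/meta files; returns the path map."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prefix = prefix or f"{self.subject}_{self.condition}"
        paths = session_paths(directory, prefix)

        affine = np.diag([3.0, 3.0, 3.0, 1.0])  # RAS+, 3 mm isotropic
        img = nib.Nifti1Image(self.image.astype(np.float32), affine)
        img.header.set_zooms((3.0, 3.0, 3.0, float(self.tr)))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, paths["image"])

        self.events.to_csv(paths["events"], sep="\t", index=False)
        np.savetxt(paths["motion"], self.motion, fmt="%.8f")
        meta = {
            "subject": self.subject,
            "condition": self.condition,
            "tr": self.tr,
            "discard_lead": self.discard_lead,
            "qa_outliers": [int(i) for i in self.qa_outliers],
        }
        paths["meta"].write_text(json.dumps(meta, indent=1))
        return paths

    def replace(self, **changes) -> "SessionData":
        return dataclasses.replace(self, **changes)


def session_paths(directory: str | Path, prefix: str) -> dict:
    directory = Path(directory)
    return {
        "image": directory / f"{prefix}_bold.nii",
        "events": directory / f"{prefix}_events.tsv",
        "motion": directory / f"{prefix}_motion.txt",
        "meta": directory / f"{prefix}_meta.json",
    }


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns {missing}")
    return events


def read_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim == 1:
        motion = motion[None, :]
    if motion.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {motion.shape[1]}")
    return motion
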