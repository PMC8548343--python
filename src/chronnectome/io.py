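"""Cohort I/O and time-course post-processing.

A cohort lives on disk as one tab-separated matrix per subject (T rows ×
C columns, no header) plus a sample sheet TSV with columns
``subject_id``, ``group``, ``path`` and ``tr_seconds``.  Post-processing
applies the component time-course conditioning used before windowed
connectivity estimation: per-column least-squares detrending followed by
a zero-phase 5th-order low-pass Butterworth filter with a 0.15 Hz cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SubjectTimecourses",
    "MAIA_DIMENSIONS",
    "read_cohort",
    "write_samplesheet",
    "read_maia",
    "postprocess_timecourses",
]

SAMPLESHEET_COLUMNS = ("subject_id", "group", "path", "tr_seconds")

MAIA_DIMENSIONS = (
    "Noticing",
    "Not-distracting",
    "Not-worrying",
    "Attention Regulation",
    "Emotional Awareness",
    "Self-regulation",
    "Body Listening",
    "Trusting",
)


@dataclass
class SubjectTimecourses:
    """One subject's component time-course matrix with its metadata."""

    subject_id: str
    group: str
    tr_seconds: float
    data: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.data, dtype=float)
        if X.ndim != 2:
            raise ValueError("data must be a T x C matrix")
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need T >= 2 and C >= 2")
        if not np.all(np.isfinite(X)):
            raise ValueError(f"non-finite values in subject {self.subject_id}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.data = X

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


def write_samplesheet(
    cohort: Sequence[SubjectTimecourses], out_dir: str | Path
) -> Path:
    """Write per-subject TSVs plus the sample sheet; returns the sheet path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tc in cohort:
        p = out_dir / f"{tc.subject_id}.tsv"
        np.savetxt(p, tc.data, delimiter="\t", fmt="%.8g")
        rows.append(
            {
                "subject_id": tc.subject_id,
                "group": tc.group,
                "path": p.name,
                "tr_seconds": tc.tr_seconds,
            }
        )
    sheet = out_dir / "samplesheet.tsv"
    pd.DataFrame(rows, columns=list(SAMPLESHEET_COLUMNS)).to_csv(
        sheet, sep="\t", index=False
    )
    return sheet


def read_cohort(samplesheet_path: str | Path) -> list[SubjectTimecourses]:
    """Read a cohort from a sample sheet; enforces shape consistency.

    Relative ``path`` entries are resolved against the sample sheet's
    directory.
    """
    samplesheet_path = Path(samplesheet_path)
    sheet = pd.read_csv(samplesheet_path, sep="\t")
    missing = set(SAMPLESHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    cohort: list[SubjectTimecourses] = []
    shape: tuple[int, int] | None = None
    tr: float | None = None
    for row in sheet.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = samplesheet_path.parent / p
        if not p.exists():
            raise FileNotFoundError(f"time-course file not found: {p}")
        data = np.loadtxt(p, delimiter="\t", ndmin=2)
        tc = SubjectTimecourses(
            subject_id=str(row.subject_id),
            group=str(row.group),
            tr_seconds=float(row.tr_seconds),
            data=data,
        )
        if shape is None:
            shape, tr = data.shape, tc.tr_seconds
        elif data.shape != shape or tc.tr_seconds != tr:
            raise ValueError(
                f"subject {tc.subject_id} has shape {data.shape} / "
                f"TR {tc.tr_seconds}, expected {shape} / TR {tr}"
            )
        cohort.append(tc)
    if not cohort:
        raise ValueError("sample sheet lists no subjects")
    return cohort


def read_maia(path: str | Path) -> pd.DataFrame:
    """Read a MAIA score table (subject_id + the 8 dimension columns).

    Scores are mean item scores on the 0-5 scale; out-of-range values are
    rejected.
    """
    df = pd.read_csv(path, sep="\t")
    missing = ({"subject_id"} | set(MAIA_DIMENSIONS)) - set(df.columns)
    if missing:
        raise ValueError(f"MAIA table missing columns: {sorted(missing)}")
    scores = df[list(MAIA_DIMENSIONS)].to_numpy(dtype=float)
    if np.nanmin(scores) < 0 or np.nanmax(scores) > 5:
        raise ValueError("MAIA dimension scores must lie in [0, 5]")
    return df.set_index("subject_id")[list(MAIA_DIMENSIONS)]


def postprocess_timecourses(
    tc: SubjectTimecourses,
    cutoff_hz: float = 0.15,
    filter_order: int = 5,
) -> SubjectTimecourses:
    """Detrend and low-pass filter one subject's component time courses.

    Each column first has its least-squares line (mean + slope) removed,
    then is filtered with a low-pass Butterworth of the given order
    applied forward-backward (zero phase), so state-timing metrics
    downstream are not phase-shifted.
    """
    nyquist = 0.5 / tc.tr_seconds
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({nyquist} Hz)"
        )
    X = signal.detrend(tc.data, axis=0, type="linear")
    sos = signal.butter(
        filter_order, cutoff_hz, btype="lowpass", fs=1.0 / tc.tr_seconds,
        output="sos",
    )
    Y = signal.sosfiltfilt(sos, X, axis=0)
    return replace(tc, data=np.ascontiguousarray(Y))
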