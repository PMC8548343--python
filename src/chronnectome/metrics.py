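"""Per-subject state temporal metrics.

Three scalar summaries of a subject's window-by-window state label
sequence: *fractional windows* (proportion of windows spent in each
state), *mean dwell time* (mean length of maximal constant runs per
state; convertible to seconds as windows × step × TR), and the *number
of transitions* (count of label changes from one window to the next —
more transitions means less temporal stability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StateMetrics",
    "fractional_windows",
    "mean_dwell_time",
    "n_transitions",
    "run_lengths",
    "subject_state_metrics",
]


@dataclass
class StateMetrics:
    subject_id: str
    fractional_windows: np.ndarray
    mean_dwell_windows: np.ndarray  # NaN for never-visited states
    n_transitions: int
    mean_dwell_seconds: np.ndarray | None = None
    group: str = ""


def _check_labels(states: np.ndarray, k: int) -> np.ndarray:
    s = np.asarray(states, dtype=int)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("state sequence must be a non-empty 1-D array")
    if s.min() < 1 or s.max() > k:
        raise ValueError(f"state labels must lie in 1..{k}")
    return s


def fractional_windows(states: np.ndarray, k: int) -> np.ndarray:
    """Proportion of windows assigned to each of the k states."""
    s = _check_labels(states, k)
    return np.bincount(s, minlength=k + 1)[1:] / s.size


def run_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal constant runs: returns (run state labels, run lengths)."""
    s = np.asarray(states, dtype=int)
    change = np.flatnonzero(np.diff(s) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [s.size]])
    return s[starts], ends - starts


def mean_dwell_time(
    states: np.ndarray, k: int, tr_seconds: float | None = None,
    step_tr: int = 1,
) -> np.ndarray:
    """Mean maximal-run length per state, in windows.

    States never visited get NaN (not zero — a zero would bias group
    means downward).  If ``tr_seconds`` is given the result is in
    seconds (windows × step × TR).
    """
    s = _check_labels(states, k)
    labels, lengths = run_lengths(s)
    out = np.full(k, np.nan)
    for state in range(1, k + 1):
        mask = labels == state
        if mask.any():
            out[state - 1] = lengths[mask].mean()
    if tr_seconds is not None:
        out = out * step_tr * tr_seconds
    return out


def n_transitions(states: np.ndarray) -> int:
    """Number of positions where the state differs from the previous window."""
    s = np.asarray(states, dtype=int)
    if s.size == 0:
        raise ValueError("state sequence must be non-empty")
    return int(np.count_nonzero(np.diff(s)))


def subject_state_metrics(
    subject_id: str,
    states: np.ndarray,
    k: int,
    tr_seconds: float | None = None,
    step_tr: int = 1,
    group: str = "",
) -> StateMetrics:
    """All three temporal metrics for one subject's label sequence."""
    dwell_w = mean_dwell_time(states, k)
    return StateMetrics(
        subject_id=subject_id,
        fractional_windows=fractional_windows(states, k),
        mean_dwell_windows=dwell_w,
        n_transitions=n_transitions(states),
        mean_dwell_seconds=(
            dwell_w * step_tr * tr_seconds if tr_seconds is not None else None
        ),
        group=group,
    )
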