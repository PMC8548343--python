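"""Synthetic hidden-state cohorts of component time courses.

Subjects are simulated as a first-order Markov chain over k hidden
connectivity states; given the state at a TR, the observed component
vector is a zero-mean multivariate Gaussian draw with that state's
covariance.  The generator provides exact ground truth (the hidden state
sequence per subject) so that every downstream stage — windowed FC, state
clustering, temporal metrics, meta-states, group statistics — can be
scored against a known answer.

The default cohort emulates a three-group resting-state study: 29 + 19 +
22 subjects, 30 components, 235 retained volumes at TR = 2.5 s, with two
hidden states (one sparsely and one densely connected) whose occupancy
differs between groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StateSpec",
    "GroupSpec",
    "SyntheticTruth",
    "make_state_covariances",
    "simulate_subject",
    "simulate_cohort",
    "default_states",
    "default_groups",
    "write_cohort",
    "write_truth",
    "read_truth",
]

_PD_FLOOR = 1e-6


@dataclass
class StateSpec:
    """One hidden connectivity state.

    Parameters
    ----------
    label : int
        1-based state index.
    covariance : ndarray of shape (C, C)
        Symmetric positive-definite signal covariance (unit diagonal by
        construction when built with :func:`make_state_covariances`).
    description : str
        Free text, e.g. ``"dense triple-network state"``.
    """

    label: int
    covariance: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        S = np.asarray(self.covariance, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(S) <= 0):
            raise ValueError("covariance diagonal must be strictly positive")
        w = np.linalg.eigvalsh(S)
        if w.min() <= 0:
            raise ValueError(
                f"covariance for state {self.label} is not positive definite "
                f"(min eigenvalue {w.min():.3e})"
            )
        self.covariance = S

    @property
    def n_components(self) -> int:
        return self.covariance.shape[0]


@dataclass
class GroupSpec:
    """One subject group with its hidden-state Markov chain.

    ``transition_matrix`` is k×k row-stochastic (per-TR transition
    probabilities); ``initial_probs`` is the length-k start distribution.
    """

    name: str
    n_subjects: int
    transition_matrix: np.ndarray
    initial_probs: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        p0 = np.asarray(self.initial_probs, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition_matrix must be square")
        if np.any(P < 0) or np.any(p0 < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        if not np.isclose(p0.sum(), 1.0, atol=1e-12):
            raise ValueError("initial_probs must sum to 1")
        if p0.shape[0] != P.shape[0]:
            raise ValueError("initial_probs length must match transition_matrix")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        self.transition_matrix = P
        self.initial_probs = p0

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix at eigenvalue 1."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        return pi / pi.sum()


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort.

    ``state_sequence`` maps subject id to its length-T hidden state label
    vector (labels 1..k); ``window_state_sequence`` holds the per-window
    majority-state label (ties broken toward the earlier/lower label).
    """

    state_sequence: dict[str, np.ndarray]
    window_state_sequence: dict[str, np.ndarray] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def windowed(self, width_tr: int, step_tr: int = 1) -> "SyntheticTruth":
        """Fill ``window_state_sequence`` for the given window convention."""
        for sid, seq in self.state_sequence.items():
            self.window_state_sequence[sid] = window_majority_labels(
                seq, width_tr, step_tr
            )
        return self


def window_majority_labels(
    states: np.ndarray, width_tr: int, step_tr: int = 1
) -> np.ndarray:
    """Majority hidden-state label per sliding window (ties -> lower label)."""
    states = np.asarray(states)
    T = states.shape[0]
    n_w = (T - width_tr) // step_tr
    if n_w < 1:
        raise ValueError("scan shorter than window")
    k = int(states.max())
    out = np.empty(n_w, dtype=int)
    for w in range(n_w):
        seg = states[w * step_tr : w * step_tr + width_tr]
        counts = np.bincount(seg, minlength=k + 1)[1:]
        out[w] = int(np.argmax(counts)) + 1  # argmax takes the first max
    return out


def make_state_covariances(
    n_components: int,
    blocks: Sequence[Sequence[int]],
    within_strength: float | Sequence[float],
    between_strengths: dict[tuple[int, int], float] | None = None,
    noise_floor: float = 0.0,
) -> np.ndarray:
    """Build a block-structured unit-diagonal covariance matrix.

    ``blocks`` are 1-based component index sets (networks); entries within
    a block get ``within_strength`` (scalar or one value per block), the
    block pairs listed in ``between_strengths`` (1-based block indices,
    i < j) get their value, and all remaining off-diagonals get
    ``noise_floor``.  If the raw matrix is indefinite it is repaired by
    clipping eigenvalues below 1e-6 and re-normalised to unit diagonal.
    """
    between_strengths = between_strengths or {}
    flat: list[int] = [i for b in blocks for i in b]
    if len(flat) != len(set(flat)):
        raise ValueError("blocks must be disjoint (not a partition)")
    if any(i < 1 or i > n_components for i in flat):
        raise ValueError("block indices must be in 1..n_components")
    if np.isscalar(within_strength):
        withins = [float(within_strength)] * len(blocks)
    else:
        withins = [float(x) for x in within_strength]
        if len(withins) != len(blocks):
            raise ValueError("one within_strength per block required")
    for s in withins + list(between_strengths.values()) + [noise_floor]:
        if abs(s) >= 1.0:
            raise ValueError(f"|strength| must be < 1, got {s}")

    S = np.full((n_components, n_components), float(noise_floor))
    for b, w in zip(blocks, withins):
        idx = np.asarray(b, dtype=int) - 1
        S[np.ix_(idx, idx)] = w
    for (bi, bj), s in between_strengths.items():
        if not (1 <= bi <= len(blocks) and 1 <= bj <= len(blocks)):
            raise ValueError(f"between_strengths block pair {(bi, bj)} out of range")
        ii = np.asarray(blocks[bi - 1], dtype=int) - 1
        jj = np.asarray(blocks[bj - 1], dtype=int) - 1
        S[np.ix_(ii, jj)] = s
        S[np.ix_(jj, ii)] = s
    np.fill_diagonal(S, 1.0)

    w, V = np.linalg.eigh(S)
    if w.min() < _PD_FLOOR:
        w = np.clip(w, _PD_FLOOR, None)
        S = (V * w) @ V.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)  # re-normalise to unit diagonal
        S = (S + S.T) / 2.0
    return S


def _simulate_chain(
    rng: np.random.Generator, P: np.ndarray, p0: np.ndarray, T: int
) -> np.ndarray:
    k = P.shape[0]
    seq = np.empty(T, dtype=int)
    cum0 = np.cumsum(p0)
    cumP = np.cumsum(P, axis=1)
    u = rng.random(T)
    seq[0] = np.searchsorted(cum0, u[0], side="right")
    for t in range(1, T):
        seq[t] = np.searchsorted(cumP[seq[t - 1]], u[t], side="right")
    return seq + 1  # 1-based labels


def simulate_subject(
    group: GroupSpec,
    states: Sequence[StateSpec],
    T: int,
    TR: float,
    seed: int,
    subject_id: str = "sub-001",
    ar_coefficient: float = 0.0,
):
    """Simulate one subject's T×C component time courses.

    Returns ``(SubjectTimecourses, SyntheticTruth)``.  Observations are
    temporally white given the hidden state unless ``ar_coefficient`` > 0,
    in which case an AR(1) smoothing of the innovations is applied (the
    per-state covariance is then only approximate).
    """
    from .io import SubjectTimecourses  # local import to avoid cycle

    if T < 1:
        raise ValueError("T must be >= 1")
    Cs = {s.n_components for s in states}
    if len(Cs) != 1:
        raise ValueError("all states must share the same number of components")
    if group.n_states != len(states):
        raise ValueError(
            "transition matrix size does not match the number of states"
        )
    C = Cs.pop()
    rng = np.random.default_rng(seed)
    seq = _simulate_chain(rng, group.transition_matrix, group.initial_probs, T)
    chols = [np.linalg.cholesky(s.covariance) for s in states]
    innov = rng.standard_normal((T, C))
    data = np.empty((T, C))
    for t in range(T):
        data[t] = chols[seq[t] - 1] @ innov[t]
    if ar_coefficient > 0.0:
        for t in range(1, T):
            data[t] = ar_coefficient * data[t - 1] + np.sqrt(
                1.0 - ar_coefficient**2
            ) * data[t]
    tc = SubjectTimecourses(
        subject_id=subject_id, group=group.name, tr_seconds=TR, data=data
    )
    truth = SyntheticTruth(
        state_sequence={subject_id: seq},
        group_of={subject_id: group.name},
        seed=seed,
    )
    return tc, truth


def simulate_cohort(
    groups: Sequence[GroupSpec],
    states: Sequence[StateSpec],
    T: int = 235,
    TR: float = 2.5,
    seed: int = 0,
    ar_coefficient: float = 0.0,
):
    """Simulate a full cohort; per-subject seeds are master_seed + ordinal.

    Returns ``(list of SubjectTimecourses, SyntheticTruth)`` with subjects
    ordered group by group.
    """
    if not groups:
        raise ValueError("groups list must be non-empty")
    cohort = []
    truth = SyntheticTruth(state_sequence={}, group_of={}, seed=seed)
    ordinal = 0
    for g in groups:
        for j in range(g.n_subjects):
            sid = f"{g.name}-{j + 1:03d}"
            tc, st = simulate_subject(
                g,
                states,
                T,
                TR,
                seed=seed + ordinal,
                subject_id=sid,
                ar_coefficient=ar_coefficient,
            )
            cohort.append(tc)
            truth.state_sequence[sid] = st.state_sequence[sid]
            truth.group_of[sid] = g.name
            ordinal += 1
    return cohort, truth


# ---------------------------------------------------------------------------
# Default study-scale configuration: 29 TM / 19 CM / 22 CW subjects, 30
# components, two hidden states.  State 1 is sparse (weak within-network
# coupling only); state 2 is dense, with strong within-network coupling and
# positive/negative between-network couplings among the first three
# networks (a triple-network-like configuration).  Group chains share the
# two states but differ in stationary occupancy of the dense state
# (TM 0.36, CW 0.30, CM 0.24 — a planted TM > CM occupancy effect of 0.12)
# and in switching rate (CM switches most slowly).
# ---------------------------------------------------------------------------

DEFAULT_BLOCKS: tuple[tuple[int, ...], ...] = (
    tuple(range(1, 6)),  # salience-like
    tuple(range(6, 11)),  # default-mode-like
    tuple(range(11, 15)),  # executive-control-like
    tuple(range(15, 19)),  # sensorimotor-like
    tuple(range(19, 23)),  # visual-like
    tuple(range(23, 27)),  # auditory/language-like
    tuple(range(27, 31)),  # precuneus/visuospatial-like
)


def _default_blocks(n_components: int) -> tuple[tuple[int, ...], ...]:
    if n_components == 30:
        return DEFAULT_BLOCKS
    n_blocks = min(7, max(2, n_components // 4))
    edges = np.linspace(1, n_components + 1, n_blocks + 1).astype(int)
    return tuple(
        tuple(range(a, b)) for a, b in zip(edges[:-1], edges[1:])
    )


def default_states(n_components: int = 30) -> list[StateSpec]:
    """Two planted connectivity states: sparse and dense."""
    blocks = _default_blocks(n_components)
    between = {
        pair: s
        for pair, s in {(1, 2): -0.30, (1, 3): 0.35, (2, 3): 0.30}.items()
        if pair[1] <= len(blocks)
    }
    sparse = make_state_covariances(
        n_components,
        blocks,
        within_strength=0.25,
        between_strengths={},
        noise_floor=0.0,
    )
    dense = make_state_covariances(
        n_components,
        blocks,
        within_strength=0.55,
        between_strengths=between,
        noise_floor=0.05,
    )
    return [
        StateSpec(1, sparse, "sparse state (weak within-network only)"),
        StateSpec(2, dense, "dense triple-network state"),
    ]


def _two_state_chain(pi2: float, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Chain with stationary dense-state occupancy pi2 and total switch rate."""
    a = rate * pi2  # p(sparse -> dense)
    b = rate * (1.0 - pi2)  # p(dense -> sparse)
    P = np.array([[1 - a, a], [b, 1 - b]])
    p0 = np.array([1.0 - pi2, pi2])
    return P, p0


def default_groups() -> list[GroupSpec]:
    """Three groups with planted occupancy and switching-rate differences."""
    specs = [
        ("TM", 29, 0.36, 0.07),
        ("CM", 19, 0.24, 0.04),
        ("CW", 22, 0.30, 0.06),
    ]
    out = []
    for name, n, pi2, rate in specs:
        P, p0 = _two_state_chain(pi2, rate)
        out.append(GroupSpec(name, n, P, p0))
    return out


# --------------------------- disk round trip -------------------------------


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Write per-subject TSV matrices plus a sample sheet; returns its path."""
    from .io import write_samplesheet

    return write_samplesheet(cohort, out_dir)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "group_of": truth.group_of,
        "state_sequence": {k: v.tolist() for k, v in truth.state_sequence.items()},
        "window_state_sequence": {
            k: v.tolist() for k, v in truth.window_state_sequence.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        state_sequence={
            k: np.asarray(v, dtype=int)
            for k, v in payload["state_sequence"].items()
        },
        window_state_sequence={
            k: np.asarray(v, dtype=int)
            for k, v in payload.get("window_state_sequence", {}).items()
        },
        group_of=payload.get("group_of", {}),
        seed=payload.get("seed", 0),
    )
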