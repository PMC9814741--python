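"""Per-monomer state sequences, populations and transition matrices.

Macrostate labels per (frame, monomer) become an M x T state matrix; the
transition probability matrix at a lag of one sampling interval (1 ns in the
reference setups) is the row-normalized count matrix.  Interconversion
diagrams can also be exported with self-transitions removed and rows
renormalized, since published diagrams typically show only the relative
probability of moving *between* distinct states.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

__all__ = [
    "StateTrajectory",
    "TransitionModel",
    "state_trajectories",
    "state_populations",
    "transition_matrix",
    "interconversion_matrix",
    "simulate_markov_labels",
]


@dataclass
class StateTrajectory:
    """M x T integer macrostate labels; one row per monomer."""

    labels: np.ndarray
    sampling_interval: float = 1.0  # ns
    lag: int = 1

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be an M x T matrix")
        if self.labels.min(initial=0) < 0:
            raise ValueError("state labels must be non-negative")

    @property
    def n_states(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class TransitionModel:
    """Populations, transition counts and the row-stochastic matrix P."""

    populations: np.ndarray
    P: np.ndarray
    counts: np.ndarray
    lag: int
    defined_rows: np.ndarray

    def to_json(self, path=None, lag_ns: float | None = None):
        doc = {
            "populations": self.populations.tolist(),
            "P": [[None if not self.defined_rows[a] else float(x) for x in row]
                  for a, row in enumerate(self.P)],
            "counts": self.counts.tolist(),
            "lag_frames": int(self.lag),
        }
        if lag_ns is not None:
            doc["lag_ns"] = lag_ns
        if path is None:
            return doc
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return doc


def state_trajectories(point_labels, M: int, T: int,
                       frame_ids=None, center_ids=None,
                       sampling_interval: float = 1.0) -> StateTrajectory:
    """Assemble an M x T state matrix from per-(frame, center) labels.

    With no explicit keys, ``point_labels`` must be ordered frame-major
    (all centers of frame 0, then frame 1, ...).  With ``frame_ids`` and
    ``center_ids`` given, records may come in any order but must cover every
    (frame, center) pair exactly once.
    """
    labels = np.asarray(point_labels, dtype=int).ravel()
    if labels.size != M * T:
        raise IndexError(f"got {labels.size} labels for M*T = {M * T} slots")
    if frame_ids is None:
        mat = labels.reshape(T, M).T
    else:
        frame_ids = np.asarray(frame_ids, int)
        center_ids = np.asarray(center_ids, int)
        mat = np.full((M, T), -1, dtype=int)
        mat[center_ids, frame_ids] = labels
        if np.any(mat < 0):
            raise IndexError("missing (frame, center) pairs in state records")
    return StateTrajectory(labels=mat, sampling_interval=sampling_interval)


def state_populations(st: StateTrajectory, n_states: int | None = None) -> np.ndarray:
    """Fraction of all (monomer, frame) observations in each state."""
    K = n_states or st.n_states
    counts = np.bincount(st.labels.ravel(), minlength=K)
    return counts / counts.sum()


def transition_matrix(st: StateTrajectory, lag: int = 1,
                      n_states: int | None = None) -> TransitionModel:
    """Row-normalized lag-``lag`` transition counts (self-transitions kept).

    Rows for states never observed as a source are flagged undefined and
    left as zero rows.
    """
    L = st.labels
    if L.shape[1] <= lag:
        raise ValueError(f"need T > lag, got T={L.shape[1]}, lag={lag}")
    K = n_states or st.n_states
    src = L[:, :-lag].ravel()
    dst = L[:, lag:].ravel()
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (src, dst), 1)
    row = counts.sum(axis=1)
    defined = row > 0
    P = np.zeros((K, K))
    P[defined] = counts[defined] / row[defined, None]
    pops = state_populations(st, n_states=K)
    return TransitionModel(populations=pops, P=P, counts=counts, lag=lag,
                           defined_rows=defined)


def interconversion_matrix(model: TransitionModel) -> np.ndarray:
    """Off-diagonal-only variant of P, rows renormalized; NaN where a state
    never leaves itself."""
    Q = model.counts.astype(float)
    np.fill_diagonal(Q, 0.0)
    rows = Q.sum(axis=1)
    out = np.full_like(Q, np.nan)
    nz = rows > 0
    out[nz] = Q[nz] / rows[nz, None]
    return out


def simulate_markov_labels(P, M: int, T: int, seed: int,
                           initial=None) -> StateTrajectory:
    """Simulate M independent chains of length T from row-stochastic P."""
    P = np.asarray(P, dtype=float)
    K = P.shape[0]
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("P must be row-stochastic")
    rng = np.random.default_rng(seed)
    labels = np.empty((M, T), dtype=int)
    if initial is None:
        # stationary distribution as the start so populations are equilibrated
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
    else:
        pi = np.asarray(initial, dtype=float)
    labels[:, 0] = rng.choice(K, size=M, p=pi)
    cdf = np.cumsum(P, axis=1)
    for t in range(1, T):
        u = rng.random(M)
        labels[:, t] = (u[:, None] > cdf[labels[:, t - 1]]).sum(axis=1)
    return StateTrajectory(labels=labels)
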