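"""Conditional-activity mathematics: persistence times, exchange times,
the (non-symmetric) activity matrix, dynamical memory and eigendomains.

The kinetic clock of a residue X is its sequence of state-transition
times T(X, 1) < ... < T(X, N) observed over a trajectory of duration tau.
The forward recurrence time W(X, t) is the wait from time t until X's
next transition.  From these:

* persistence time      tau_p[X]    = (1 / 2 tau) * sum over the waiting
  intervals partitioning [0, tau] of (interval length)^2 — the mean wait
  from a uniformly random start time until X's next transition;
* exchange time         tau_p[X][Y] = (1 / tau) *
  sum_{i=1}^{N(Y)-1} W(X, T(Y, i+1)) * (T(Y, i+1) - T(Y, i));
* conditional activity  A[X][Y]     = -ln( tau_p[X][Y] / tau_p[X] ).

A[X][Y] > 0 means transitions of Y hasten the next transition of X
(exchange faster than persistence); A = 0 under independence; the matrix
is directional, A[X][Y] != A[Y][X].  The diagonal A[X][X] is the
dynamical memory: ~0 for a memoryless (Poisson) clock, positive when
successive waiting times are history-dependent.

Boundary censoring: the intervals [0, T(X,1)] and [T(X,N), tau] are
included in the partition (so the interval lengths sum exactly to tau),
and the forward recurrence time at or after the last transition is
censored at the trajectory end, W(X, t) = tau - t.  This is the only
convention that keeps every quantity finite and the random-start
normalization exact; it perturbs results at O(1/N) only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .types import ResidueKey, TransitionRecord

__all__ = [
    "waiting_intervals",
    "forward_recurrence",
    "persistence_time",
    "exchange_time",
    "conditional_activity",
    "ActivityMatrix",
    "activity_matrix",
    "pool_replicas",
    "DomainScores",
    "eigendomains",
]


def waiting_intervals(record: TransitionRecord) -> np.ndarray:
    """The waiting intervals partitioning [0, tau], boundary intervals included.

    Returns the N+1 interval lengths [0,T1], [T1,T2], ..., [TN, tau]; they
    sum exactly to tau.
    """
    edges = np.concatenate(([0.0], record.times, [record.tau]))
    return np.diff(edges)


def forward_recurrence(record: TransitionRecord, t) -> np.ndarray:
    """Forward recurrence time W(X, t): wait from t until X's next transition.

    At a transition time itself the *next* transition counts, so
    W(X, T(X,i)) = T(X,i+1) - T(X,i).  At or after the last transition the
    value is censored at the trajectory end: W = tau - t.
    """
    t = np.asarray(t, dtype=float)
    if record.n == 0:
        return record.tau - t
    idx = np.searchsorted(record.times, t, side="right")
    safe = np.minimum(idx, record.n - 1)
    nxt = np.where(idx < record.n, record.times[safe], record.tau)
    return nxt - t


def persistence_time(record: TransitionRecord) -> float:
    """Mean persistence time tau_p[X] = (1/2tau) * sum of squared waiting intervals.

    Equals the mean forward recurrence time from a uniformly random start
    time in [0, tau] (length-biased sampling of the waiting intervals).
    Returns NaN for an empty record — such residues should already have
    been dropped by the transition-count filter.
    """
    if record.n == 0:
        return float("nan")
    w = waiting_intervals(record)
    return float(np.sum(w * w) / (2.0 * record.tau))


def exchange_time(x: TransitionRecord, y: TransitionRecord) -> float:
    """Mean exchange time tau_p[X][Y] of X following transitions of Y.

    tau_p[X][Y] = (1/tau) sum_{i=1}^{N(Y)-1} W(X, T(Y,i+1)) * W(Y, T(Y,i))
    where W(Y, T(Y,i)) = T(Y,i+1) - T(Y,i) is Y's waiting interval and
    W(X, .) is X's forward recurrence time.  Requires N(Y) >= 2; NaN
    otherwise.
    """
    if abs(x.tau - y.tau) > 1e-9 * max(x.tau, y.tau):
        raise ValueError("records must share the observation time tau")
    if y.n < 2:
        return float("nan")
    wy = np.diff(y.times)                      # W(Y, T(Y,i)), i = 1..N-1
    wx = forward_recurrence(x, y.times[1:])    # W(X, T(Y,i+1))
    return float(np.sum(wx * wy) / x.tau)


def conditional_activity(x: TransitionRecord, y: TransitionRecord) -> float:
    """Conditional activity A[X][Y] = -ln( tau_p[X][Y] / tau_p[X] ).

    Positive when transitions of Y hasten X's next transition, zero under
    independence, negative when they delay it.  NaN when either time is
    undefined or the exchange time is exactly zero (fully censored).
    """
    tp = persistence_time(x)
    txy = exchange_time(x, y)
    if not np.isfinite(tp) or not np.isfinite(txy) or tp <= 0 or txy <= 0:
        return float("nan")
    return float(-np.log(txy / tp))


@dataclass
class ActivityMatrix:
    """Non-symmetric conditional-activity matrix over retained residues.

    Orientation: ``values[i, j] = A[X_i][Y_j]`` — row = affected residue X,
    column = influencing residue Y.  The diagonal is the dynamical memory.
    Missing (undefined) entries are NaN.
    """

    residue_index: list[ResidueKey]
    values: np.ndarray
    persistence_times: np.ndarray
    replica_id: int | str = 0
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_index)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over the residue index")

    @property
    def memory(self) -> np.ndarray:
        """Dynamical memory A[X][X] per residue (the diagonal)."""
        return np.diagonal(self.values).copy()

    def symmetrized(self) -> np.ndarray:
        """S = (M + M^T)/2 with missing entries treated as 0 (independence)."""
        m = np.nan_to_num(self.values, nan=0.0)
        return 0.5 * (m + m.T)

    def to_frame(self):
        import pandas as pd
        labels = [str(k) for k in self.residue_index]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def activity_matrix(records: Sequence[TransitionRecord],
                    replica_id: int | str | None = None) -> ActivityMatrix:
    """All pairwise conditional activities among retained records.

    Entry (i, j) holds A[X_i][Y_j]; the diagonal is the dynamical memory.
    Records must share tau.  Undefined pairs are NaN.
    """
    if len(records) < 1:
        raise ValueError("need at least one retained record")
    tau = records[0].tau
    for r in records:
        if abs(r.tau - tau) > 1e-9 * tau:
            raise ValueError("all records must share tau")
    n = len(records)
    values = np.full((n, n), np.nan)
    tp = np.array([persistence_time(r) for r in records])
    for i, x in enumerate(records):
        if not np.isfinite(tp[i]) or tp[i] <= 0:
            continue
        for j, y in enumerate(records):
            txy = exchange_time(x, y)
            if np.isfinite(txy) and txy > 0:
                values[i, j] = -np.log(txy / tp[i])
    rid = replica_id if replica_id is not None else records[0].replica_id
    return ActivityMatrix(residue_index=[r.key for r in records], values=values,
                          persistence_times=tp, replica_id=rid)


def pool_replicas(matrices: Sequence[ActivityMatrix]) -> ActivityMatrix:
    """Entrywise mean over replicas, with the SEM over replicas per entry.

    Replica matrices may cover different residue subsets; the pooled
    matrix spans the union, averaging each entry over the replicas where
    it is defined.  Entries defined in fewer than two replicas get NaN SEM.
    """
    if not matrices:
        raise ValueError("need at least one replica matrix")
    universe: list[ResidueKey] = []
    for m in matrices:
        for k in m.residue_index:
            if k not in universe:
                universe.append(k)
    universe.sort()
    n = len(universe)
    pos = {k: i for i, k in enumerate(universe)}
    stack = np.full((len(matrices), n, n), np.nan)
    tp_stack = np.full((len(matrices), n), np.nan)
    for r, m in enumerate(matrices):
        idx = np.array([pos[k] for k in m.residue_index])
        stack[np.ix_([r], idx, idx)] = m.values[None, :, :]
        tp_stack[r, idx] = m.persistence_times
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        count = np.sum(np.isfinite(stack), axis=0)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(count >= 2, sd / np.sqrt(np.maximum(count, 1)), np.nan)
    mean[count == 0] = np.nan
    tp_mean = np.nanmean(tp_stack, axis=0)
    return ActivityMatrix(residue_index=universe, values=mean,
                          persistence_times=tp_mean, replica_id="pooled",
                          sem=sem)


@dataclass
class DomainScores:
    """Principal eigenvector of the symmetrized activity matrix.

    Residues with large-magnitude components form the dynamically
    connected domain with the largest mode of correlated fluctuation.
    The vector has unit Euclidean norm and its global sign is fixed so
    the largest-magnitude component is positive.
    """

    residue_index: list[ResidueKey]
    components: np.ndarray
    eigenvalue: float

    @property
    def scores(self) -> np.ndarray:
        """Per-residue contribution = component magnitude."""
        return np.abs(self.components)


def eigendomains(matrix: ActivityMatrix) -> DomainScores:
    """Dynamically connected domains from the symmetrized activity matrix.

    Symmetrizes S = (M + M^T)/2 (missing entries imputed as 0, the defined
    independence value) and returns the unit-norm eigenvector of the
    largest eigenvalue.  Raises on an all-zero (degenerate) matrix.
    """
    s = matrix.symmetrized()
    if not np.any(s):
        raise ValueError("degenerate all-zero matrix: no domain structure")
    evals, evecs = np.linalg.eigh(s)
    v = evecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return DomainScores(residue_index=list(matrix.residue_index),
                        components=v, eigenvalue=float(evals[-1]))
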