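"""Plug-in mutual information between discretized state series.

MI(X, Y) = H(X) + H(Y) - H(X, Y) in nats, with entropies from the
empirical (plug-in) label frequencies over simultaneous frames and the
convention 0 ln 0 = 0.  MI is the entropic / thermodynamic correlation
baseline contrasted with the kinetic conditional activity: it sees
shared state occupancy, not shared transition timing.  The same state
alphabets are used as for conditional activity (3-state protein, 2-state
DNA) so the comparison is apples-to-apples.  No small-sample bias
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import StateSeries

__all__ = ["JointDistribution", "estimate_joint", "mutual_information",
           "mi_matrix"]


@dataclass
class JointDistribution:
    """Empirical joint and marginal label distributions of two series."""

    labels_x: tuple[str, ...]
    labels_y: tuple[str, ...]
    joint: np.ndarray  # P(X, Y), rows = labels_x
    sample_count: int

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        if abs(self.joint.sum() - 1.0) > 1e-12:
            raise ValueError("joint distribution must sum to 1")

    @property
    def marginal_x(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.joint.sum(axis=0)


def estimate_joint(x: StateSeries, y: StateSeries) -> JointDistribution:
    """Empirical joint distribution over simultaneous frames."""
    if x.n_frames != y.n_frames:
        raise ValueError("series must have equal length")
    if abs(x.frame_interval - y.frame_interval) > 1e-12:
        raise ValueError("series must share the frame interval")
    lx, ly = tuple(x.alphabet), tuple(y.alphabet)
    ix = {s: i for i, s in enumerate(lx)}
    iy = {s: i for i, s in enumerate(ly)}
    counts = np.zeros((len(lx), len(ly)))
    xi = np.array([ix[s] for s in x.labels])
    yi = np.array([iy[s] for s in y.labels])
    np.add.at(counts, (xi, yi), 1.0)
    return JointDistribution(labels_x=lx, labels_y=ly,
                             joint=counts / counts.sum(),
                             sample_count=x.n_frames)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mutual_information(joint: JointDistribution) -> float:
    """MI in nats: H(X) + H(Y) - H(X, Y), with 0 ln 0 = 0.  Always >= 0."""
    return (_entropy(joint.marginal_x) + _entropy(joint.marginal_y)
            - _entropy(joint.joint.ravel()))


def mi_matrix(series_collection: Sequence[StateSeries]) -> pd.DataFrame:
    """Symmetric MI matrix; the diagonal is each residue's state entropy."""
    if len(series_collection) < 2:
        raise ValueError("need at least two series")
    n = len(series_collection)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            mi = mutual_information(
                estimate_joint(series_collection[i], series_collection[j]))
            values[i, j] = values[j, i] = mi
    labels = [str(s.key) for s in series_collection]
    return pd.DataFrame(values, index=labels, columns=labels)
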