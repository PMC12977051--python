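"""Model/Results front-end over the conditional-activity machinery.

``ConditionalActivity`` is built from data — transition records, state
series, dihedral series, or an angle-matrix file — and ``fit()`` returns
a :class:`ActivityResults` carrying the activity matrix, the persistence
times, per-residue dynamical memory, eigendomain scores, and (optionally)
permutation p-values, with a text ``summary()``.  It wraps the functional
modules; nothing here re-derives the mathematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import kinetics, mi as mi_mod, significance as sig_mod, states as st
from .types import DihedralSeries, StateSeries, TransitionRecord

__all__ = ["ConditionalActivity", "ActivityResults"]


class ConditionalActivity:
    """Conditional-activity model of a set of residue kinetic clocks.

    Parameters
    ----------
    records : per-replica lists of TransitionRecord
        ``[[replica-0 records], [replica-1 records], ...]``.
    state_series : optional matching per-replica lists of StateSeries
        Needed only for the mutual-information baseline.
    min_transitions : minimum transition count per residue per replica
        (default 10) before a residue enters the analysis.
    """

    def __init__(self, records: Sequence[Sequence[TransitionRecord]],
                 state_series: Sequence[Sequence[StateSeries]] | None = None,
                 min_transitions: int = 10):
        self.replica_records = [st.filter_min_transitions(r, min_transitions)
                                for r in records]
        self.state_series = state_series
        self.min_transitions = min_transitions

    @classmethod
    def from_angles(cls, series_by_replica: Sequence[Sequence[DihedralSeries]],
                    min_transitions: int = 10,
                    min_dwell_frames: int = 1) -> "ConditionalActivity":
        """Build from per-replica dihedral series: discretize, detect, filter."""
        all_records, all_states = [], []
        for rep, series in enumerate(series_by_replica):
            states = [st.discretize(s) for s in series]
            records = [st.detect_transitions(s, replica_id=rep,
                                             min_dwell_frames=min_dwell_frames)
                       for s in states]
            all_states.append(states)
            all_records.append(records)
        return cls(all_records, state_series=all_states,
                   min_transitions=min_transitions)

    @classmethod
    def from_angle_matrix(cls, *paths, min_transitions: int = 10,
                          delimiter: str = "\t") -> "ConditionalActivity":
        """Build from angle-matrix text files, one file per replica."""
        from .io import load_angle_matrix
        series = [load_angle_matrix(p, delimiter=delimiter) for p in paths]
        return cls.from_angles(series, min_transitions=min_transitions)

    def fit(self, compute_mi: bool = False) -> "ActivityResults":
        """Compute per-replica activity matrices and pool them."""
        per_replica = [kinetics.activity_matrix(recs, replica_id=i)
                       for i, recs in enumerate(self.replica_records)
                       if len(recs) >= 1]
        if not per_replica:
            raise ValueError("no replica retained any residue after filtering")
        pooled = (kinetics.pool_replicas(per_replica)
                  if len(per_replica) > 1 else per_replica[0])
        mi_frame = None
        if compute_mi and self.state_series:
            retained = {str(r.key) for r in self.replica_records[0]}
            usable = [s for s in self.state_series[0] if str(s.key) in retained]
            if len(usable) >= 2:
                mi_frame = mi_mod.mi_matrix(usable)
        return ActivityResults(model=self, per_replica=per_replica,
                               pooled=pooled, mi=mi_frame)


@dataclass
class ActivityResults:
    """Fitted conditional-activity results.

    ``pooled`` is the replica-averaged ActivityMatrix (with per-entry SEM
    when more than one replica contributed); ``memory`` is its diagonal.
    """

    model: ConditionalActivity
    per_replica: list[kinetics.ActivityMatrix]
    pooled: kinetics.ActivityMatrix
    mi: pd.DataFrame | None = None
    _domains: kinetics.DomainScores | None = field(default=None, repr=False)

    @property
    def activity(self) -> pd.DataFrame:
        return self.pooled.to_frame()

    @property
    def memory(self) -> pd.Series:
        labels = [str(k) for k in self.pooled.residue_index]
        return pd.Series(self.pooled.memory, index=labels, name="memory")

    @property
    def persistence_times(self) -> pd.Series:
        labels = [str(k) for k in self.pooled.residue_index]
        return pd.Series(self.pooled.persistence_times, index=labels,
                         name="persistence_time")

    def eigendomains(self) -> kinetics.DomainScores:
        if self._domains is None:
            self._domains = kinetics.eigendomains(self.pooled)
        return self._domains

    def pvalues(self, pairs=None, n_permutations: int = 2000,
                seed: int = 0, replica: int = 0) -> pd.DataFrame:
        """Permutation p-values (circular-shift null) on one replica's records."""
        return sig_mod.significance_table(self.model.replica_records[replica],
                                          pairs=pairs,
                                          n_permutations=n_permutations,
                                          seed=seed)

    def top_couplings(self, k: int = 10) -> pd.DataFrame:
        """The k largest off-diagonal activities, long format, descending."""
        frame = self.activity
        values = frame.to_numpy(dtype=float).copy()
        np.fill_diagonal(values, np.nan)
        flat = [(frame.index[i], frame.columns[j], values[i, j])
                for i in range(values.shape[0]) for j in range(values.shape[1])
                if np.isfinite(values[i, j])]
        flat.sort(key=lambda t: -t[2])
        return pd.DataFrame(flat[:k], columns=["residue_X", "residue_Y", "A"])

    def summary(self, top: int = 5) -> str:
        mem = self.memory.dropna().sort_values(ascending=False)
        dom = None
        try:
            dom = self.eigendomains()
        except ValueError:
            pass
        lines = [
            "Conditional activity results",
            "=" * 60,
            f"residues retained        {len(self.pooled.residue_index)}",
            f"replicas                 {len(self.per_replica)}",
            f"min transitions filter   {self.model.min_transitions}",
            "",
            f"dynamical memory (top {top}):  [A[X][X], -ln units]",
        ]
        for key, value in mem.head(top).items():
            lines.append(f"  {key:<24s} {value:8.3f}")
        lines.append("")
        lines.append(f"strongest couplings (top {top}):  [A[X][Y]]")
        for _, row in self.top_couplings(top).iterrows():
            lines.append(f"  {row.residue_X:<18s} <- {row.residue_Y:<18s}"
                         f" {row.A:8.3f}")
        if dom is not None:
            lines.append("")
            lines.append(f"leading eigenvalue       {dom.eigenvalue:.3f}")
            order = np.argsort(-dom.scores)[:top]
            members = ", ".join(str(dom.residue_index[i]) for i in order)
            lines.append(f"top eigendomain residues {members}")
        return "\n".join(lines)
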