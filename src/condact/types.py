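"""Core containers shared across the analysis stages.

Residues are identified by :class:`ResidueKey`; per-frame dihedral angles
live in :class:`DihedralSeries`, their discretized states in
:class:`StateSeries`, and the resulting kinetic clock — the sorted times at
which a residue's degree of freedom changed state — in
:class:`TransitionRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ResidueKey",
    "DihedralSeries",
    "StateSeries",
    "TransitionRecord",
]

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "HIE", "HID", "HIP", "ILE", "LEU", "LYS", "MET", "PHE",
    "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_DNA_RESNAMES = {
    "DA", "DG", "DC", "DT", "ADE", "GUA", "CYT", "THY",
    "DA5", "DG5", "DC5", "DT5", "DA3", "DG3", "DC3", "DT3",
    "A", "G", "C", "T",
}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue within a system.

    ``residue_number`` is the author's numbering from the topology
    (1-based as written); ``polymer_class`` is ``"protein"`` or ``"dna"``.
    """

    segment: str
    residue_number: int
    residue_name: str
    polymer_class: str = "protein"

    def __post_init__(self) -> None:
        if self.polymer_class not in ("protein", "dna"):
            raise ValueError(f"polymer_class must be protein|dna, got {self.polymer_class!r}")

    def __str__(self) -> str:
        return f"{self.segment}:{self.residue_name}:{self.residue_number}"

    @classmethod
    def from_string(cls, text: str) -> "ResidueKey":
        """Parse the ``SEG:RESNAME:RESID`` header token used in text outputs."""
        seg, name, num = text.rsplit(":", 2)
        upper = name.upper()
        if upper in _DNA_RESNAMES:
            cls_ = "dna"
        else:
            cls_ = "protein"
        return cls(segment=seg, residue_number=int(num), residue_name=name,
                   polymer_class=cls_)


@dataclass
class DihedralSeries:
    """One residue's dihedral angle per frame, degrees in ``[0, 360)``.

    ``frame_interval`` is the time between successive frames (ps for MD
    input; arbitrary units for synthetic series). NaN marks frames where
    the dihedral was geometrically undefined.
    """

    key: ResidueKey
    angles: np.ndarray
    frame_interval: float
    atom_quadruple: tuple[str, str, str, str] | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1:
            raise ValueError("angles must be one-dimensional")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and ((finite < 0).any() or (finite >= 360).any()):
            raise ValueError("angles must lie in [0, 360)")

    @property
    def n_frames(self) -> int:
        return int(self.angles.size)


@dataclass
class StateSeries:
    """Discrete per-frame state labels for one residue."""

    key: ResidueKey
    labels: np.ndarray  # array of single-character state labels
    alphabet: tuple[str, ...]
    frame_interval: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        extra = set(np.unique(self.labels)) - set(self.alphabet)
        if extra:
            raise ValueError(f"labels outside alphabet: {sorted(extra)}")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)


@dataclass
class TransitionRecord:
    """Sorted transition times of one residue over an observation time tau.

    Times are strictly increasing and lie in ``(0, tau]``.  ``n`` is the
    transition count N; an empty record (N = 0) is legal but is normally
    removed by the minimum-transition filter before analysis.
    """

    key: ResidueKey
    times: np.ndarray
    tau: float
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.tau <= 0:
            raise ValueError("observation time tau must be positive")
        if self.times.size:
            if (np.diff(self.times) <= 0).any():
                raise ValueError("transition times must be strictly increasing")
            if self.times[0] <= 0 or self.times[-1] > self.tau:
                raise ValueError("transition times must lie in (0, tau]")

    @property
    def n(self) -> int:
        return int(self.times.size)

    def with_times(self, times: Sequence[float]) -> "TransitionRecord":
        return replace(self, times=np.asarray(times, dtype=float))
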