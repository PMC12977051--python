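"""State assignment to dihedral angles, transition detection, and the
minimum-transition filter.

Protein side-chain (chi1) angles get three rotamer states with fixed
boundaries:  X = [0, 120),  Y = [120, 240),  Z = [240, 360).
DNA glycosidic angles get two states:  S (syn) = [0, 140) u [330, 360)
and A (anti) = [140, 330).  The boundaries sit in the minima of the
empirical angle densities; ``density_profile`` is the diagnostic for
checking that on new systems.  Boundaries are fixed constants here, not
learned; override them by discretizing with a custom alphabet upstream
if a system demands it.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .types import DihedralSeries, StateSeries, TransitionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PROTEIN_ALPHABET",
    "DNA_ALPHABET",
    "assign_protein_state",
    "assign_dna_state",
    "discretize",
    "detect_transitions",
    "filter_min_transitions",
    "density_profile",
]

PROTEIN_ALPHABET: tuple[str, ...] = ("X", "Y", "Z")
DNA_ALPHABET: tuple[str, ...] = ("S", "A")

_PROTEIN_EDGES = np.array([0.0, 120.0, 240.0, 360.0])


def _check_range(angle: np.ndarray) -> None:
    bad = (angle < 0) | (angle >= 360)
    if np.any(bad & np.isfinite(angle)):
        raise ValueError("angle outside [0, 360)")


def assign_protein_state(angle):
    """Three-state rotamer assignment for protein chi1 angles.

    [0, 120) -> X, [120, 240) -> Y, [240, 360) -> Z (half-open bins, so
    120 itself belongs to Y).  Accepts scalars or arrays.
    """
    arr = np.asarray(angle, dtype=float)
    _check_range(arr)
    idx = np.minimum((arr // 120.0).astype(int), 2)
    labels = np.array(PROTEIN_ALPHABET)[idx]
    return labels if arr.ndim else str(labels)


def assign_dna_state(angle):
    """Two-state syn/anti assignment for DNA glycosidic angles.

    S (syn) on [0, 140) and [330, 360); A (anti) on [140, 330); half-open,
    so 330 itself belongs to S.  Accepts scalars or arrays.
    """
    arr = np.asarray(angle, dtype=float)
    _check_range(arr)
    is_anti = (arr >= 140.0) & (arr < 330.0)
    labels = np.where(is_anti, "A", "S")
    return labels if arr.ndim else str(labels)


def discretize(series: DihedralSeries,
               polymer_class: str | None = None) -> StateSeries:
    """Map a dihedral series to per-frame state labels.

    Frames with an undefined angle (NaN, from geometric degeneracy)
    propagate the previous frame's label so an isolated numerical failure
    cannot create a spurious transition; a leading NaN takes the first
    defined label.
    """
    pclass = polymer_class or series.key.polymer_class
    assign = assign_protein_state if pclass == "protein" else assign_dna_state
    alphabet = PROTEIN_ALPHABET if pclass == "protein" else DNA_ALPHABET
    angles = series.angles
    defined = np.isfinite(angles)
    if not defined.any():
        raise ValueError(f"{series.key}: no defined angles to discretize")
    labels = np.empty(angles.size, dtype="U1")
    labels[defined] = np.asarray(assign(angles[defined]))
    if not defined.all():
        # forward-fill undefined frames; back-fill a leading run
        first = int(np.argmax(defined))
        labels[:first] = labels[first]
        for i in range(first + 1, angles.size):
            if not defined[i]:
                labels[i] = labels[i - 1]
    return StateSeries(key=series.key, labels=labels, alphabet=alphabet,
                       frame_interval=series.frame_interval)


def detect_transitions(series: StateSeries, replica_id: int = 0,
                       min_dwell_frames: int = 1) -> TransitionRecord:
    """Detect state transitions in a label series.

    A transition is recorded at every frame i >= 1 whose label differs
    from frame i-1; its time is i * frame_interval (the first frame in
    the new state) and the observation time is tau = n_frames *
    frame_interval.

    ``min_dwell_frames`` > 1 enables an optional debouncing pass that
    removes excursions shorter than that many frames before detection.
    It is off by default: it materially changes the transition count and
    must be a deliberate choice.
    """
    if series.n_frames < 2:
        raise ValueError("need at least two frames to detect transitions")
    labels = series.labels
    if min_dwell_frames > 1:
        labels = _debounce(labels, min_dwell_frames)
    changed = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    dt = series.frame_interval
    return TransitionRecord(key=series.key, times=changed * dt,
                            tau=series.n_frames * dt, replica_id=replica_id)


def _debounce(labels: np.ndarray, min_dwell: int) -> np.ndarray:
    out = labels.copy()
    i = 0
    n = out.size
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if 0 < i and (j - i) < min_dwell:
            out[i:j] = out[i - 1]
        i = j
    return out


def filter_min_transitions(records: Iterable[TransitionRecord],
                           min_n: int = 10) -> list[TransitionRecord]:
    """Keep records with at least ``min_n`` transitions (default 10).

    Residues with too few transitions have poorly sampled waiting-time
    statistics and are excluded from the conditional-activity analysis.
    Applied per replica: a residue may survive in one replica and be
    dropped in another.  Dropped keys are logged.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    kept, dropped = [], []
    for rec in records:
        (kept if rec.n >= min_n else dropped).append(rec)
    if dropped:
        logger.info("transition filter (N >= %d) dropped %d residues: %s",
                    min_n, len(dropped),
                    ", ".join(str(r.key) for r in dropped[:20]))
    return kept


def density_profile(series_collection: Sequence[DihedralSeries],
                    bin_width: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Pooled probability density of dihedral angles over [0, 360).

    Returns (bin_centers, density) with the density normalized to
    integrate to 1 over degrees.  Diagnostic for verifying that the state
    boundaries sit in density minima (the rotamer-peak picture).
    """
    if 360.0 % bin_width:
        raise ValueError("bin_width must divide 360")
    pooled = np.concatenate([s.angles[np.isfinite(s.angles)]
                             for s in series_collection]) if series_collection else np.empty(0)
    if pooled.size == 0:
        raise ValueError("no angles to profile")
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    density, _ = np.histogram(pooled, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density
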