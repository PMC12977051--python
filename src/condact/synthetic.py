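"""Synthetic transition records and noisy dihedral series with known
kinetic structure.

Three generators cover the ground truths the downstream stages need:

* renewal (semi-Markov) clocks with exponential, fixed-period, or
  two-exponential-mixture waiting times — the null models for dynamical
  memory (Poisson -> memory ~ 0; periodic -> memory -> -ln 2);
* directional master--slave pairs in which each master transition
  triggers, with some probability and after a short lag, a response
  transition in the slave — the ground truth for recovering
  A[slave][master] > 0 and the matrix asymmetry;
* angle emission: turning a transition record plus a state sequence into
  a noisy per-frame dihedral series concentrated around rotamer-state
  centers, the round-trip test for discretization.

No physical dynamics are simulated; these are point processes and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import DihedralSeries, ResidueKey, StateSeries, TransitionRecord
from . import states as _states

__all__ = [
    "RenewalSpec",
    "CouplingSpec",
    "AngleEmissionSpec",
    "generate_renewal",
    "generate_coupled_pair",
    "emit_angle_series",
    "write_angle_matrix",
]


@dataclass(frozen=True)
class RenewalSpec:
    """A renewal transition process observed over ``[0, tau]``.

    ``waiting`` selects the waiting-time law:

    - ``("exponential", mean)`` — Poisson clock;
    - ``("fixed", period)`` — deterministic periodic clock;
    - ``("mixture", mean1, mean2, weight)`` — two-exponential mixture
      (weight = probability of drawing from the first component), a
      simple clock with history-dependent (non-Poisson) statistics.
    """

    waiting: tuple
    tau: float
    seed: int = 0
    key: ResidueKey = field(
        default_factory=lambda: ResidueKey("SYN", 1, "SYN", "protein"))

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("observation time tau must be positive")
        kind = self.waiting[0]
        if kind == "exponential":
            if self.waiting[1] <= 0:
                raise ValueError("exponential mean must be positive")
        elif kind == "fixed":
            if self.waiting[1] <= 0:
                raise ValueError("fixed period must be positive")
        elif kind == "mixture":
            _, m1, m2, w = self.waiting
            if m1 <= 0 or m2 <= 0:
                raise ValueError("mixture means must be positive")
            if not 0 <= w <= 1:
                raise ValueError("mixture weight must lie in [0, 1]")
        else:
            raise ValueError(f"unknown waiting-time law {kind!r}")

    @property
    def mean_waiting(self) -> float:
        kind = self.waiting[0]
        if kind == "exponential" or kind == "fixed":
            return float(self.waiting[1])
        _, m1, m2, w = self.waiting
        return float(w * m1 + (1 - w) * m2)


@dataclass(frozen=True)
class CouplingSpec:
    """Directional master -> slave coupling.

    Each master transition triggers, with probability
    ``trigger_probability``, one response transition in the slave at
    (master time + lag).  ``lag`` is ``("fixed", delay)`` or
    ``("exponential", mean)``; the default lag, chosen at pair-generation
    time, is exponential with mean 1% of the master's mean waiting time so
    exchange times stay well separated from persistence times.
    """

    trigger_probability: float
    lag: tuple | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.trigger_probability <= 1:
            raise ValueError("trigger_probability must lie in [0, 1]")
        if self.lag is not None:
            kind, value = self.lag
            if kind not in ("fixed", "exponential"):
                raise ValueError(f"unknown lag law {kind!r}")
            if value < 0:
                raise ValueError("lag must be non-negative")


@dataclass(frozen=True)
class AngleEmissionSpec:
    """Angle emission around rotamer-state centers.

    ``state_centers`` maps each state label to its center angle (degrees);
    every center must sit inside its own state bin, and the default noise
    (8 degrees s.d.) keeps >= 99% of emissions inside the bin for the
    default protein centers 60/180/300.
    """

    state_centers: dict[str, float]
    angular_noise_sd: float = 8.0
    frame_interval: float = 1.0
    polymer_class: str = "protein"

    def __post_init__(self) -> None:
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        assign = (_states.assign_protein_state if self.polymer_class == "protein"
                  else _states.assign_dna_state)
        for label, center in self.state_centers.items():
            if not 0 <= center < 360:
                raise ValueError(f"center {center} outside [0, 360)")
            if assign(center) != label:
                raise ValueError(
                    f"center {center} deg lies in state {assign(center)!r}, "
                    f"not its own state {label!r}")


def _draw_waitings(rng: np.random.Generator, waiting: tuple, size: int) -> np.ndarray:
    kind = waiting[0]
    if kind == "exponential":
        return rng.exponential(waiting[1], size=size)
    if kind == "fixed":
        return np.full(size, float(waiting[1]))
    _, m1, m2, w = waiting
    pick = rng.random(size) < w
    return np.where(pick, rng.exponential(m1, size=size),
                    rng.exponential(m2, size=size))


def generate_renewal(spec: RenewalSpec,
                     rng: np.random.Generator | None = None) -> TransitionRecord:
    """Simulate a renewal transition record on (0, tau].

    A fixed-period clock places transitions at period, 2*period, ...;
    stochastic laws accumulate i.i.d. waiting times until tau is passed.
    Reproducible from ``spec.seed`` unless an explicit generator is given.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.waiting[0] == "fixed":
        period = spec.waiting[1]
        n = int(np.floor(spec.tau / period + 1e-12))
        times = period * np.arange(1, n + 1)
        return TransitionRecord(key=spec.key, times=times, tau=spec.tau)
    # draw in blocks until past tau
    times: list[np.ndarray] = []
    total = 0.0
    block = max(16, int(2 * spec.tau / spec.mean_waiting) + 16)
    while total <= spec.tau:
        w = _draw_waitings(rng, spec.waiting, block)
        cum = total + np.cumsum(w)
        times.append(cum)
        total = cum[-1]
    all_times = np.concatenate(times)
    return TransitionRecord(key=spec.key,
                            times=all_times[all_times <= spec.tau],
                            tau=spec.tau)


def generate_coupled_pair(
    master: RenewalSpec,
    coupling: CouplingSpec,
    slave_baseline: RenewalSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TransitionRecord, TransitionRecord]:
    """Simulate a (master, slave) pair with directional coupling.

    The slave record merges its own baseline renewal transitions (if a
    baseline spec is given) with triggered responses: each master
    transition contributes, with ``trigger_probability``, one transition
    at master time + lag (responses past tau are dropped).  Coincident
    times are perturbed by +tau/1e6 to keep strict ordering.
    """
    if rng is None:
        rng = np.random.default_rng(master.seed)
    m_rec = generate_renewal(master, rng=rng)
    key = (slave_baseline.key if slave_baseline is not None
           else ResidueKey("SYN", master.key.residue_number + 1, "SYN", "protein"))
    parts = []
    if slave_baseline is not None:
        parts.append(generate_renewal(slave_baseline, rng=rng).times)
    if m_rec.n:
        fired = rng.random(m_rec.n) < coupling.trigger_probability
        lag_spec = coupling.lag or ("exponential", 0.01 * master.mean_waiting)
        if lag_spec[0] == "fixed":
            lags = np.full(int(fired.sum()), float(lag_spec[1]))
        else:
            lags = rng.exponential(lag_spec[1], size=int(fired.sum()))
        responses = m_rec.times[fired] + lags
        parts.append(responses[responses <= master.tau])
    merged = np.sort(np.concatenate(parts)) if parts else np.empty(0)
    if merged.size:
        eps = master.tau * 1e-6
        for i in range(1, merged.size):
            if merged[i] <= merged[i - 1]:
                merged[i] = merged[i - 1] + eps
        merged = merged[merged <= master.tau]
        merged = merged[merged > 0]
    s_rec = TransitionRecord(key=key, times=merged, tau=master.tau)
    return m_rec, s_rec


def emit_angle_series(
    record: TransitionRecord,
    emission: AngleEmissionSpec,
    state_sequence: Sequence[str],
    rng: np.random.Generator | None = None,
) -> DihedralSeries:
    """Emit a noisy per-frame angle series realizing a transition record.

    ``state_sequence`` names the occupied state on each of the N+1
    inter-transition intervals.  Frames at times (j+1)*frame_interval for
    j = 0..n_frames-1 take the active interval's center plus wrapped
    Gaussian noise; discretizing the output recovers the input record to
    within one frame interval (exactly, at zero noise).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if len(state_sequence) != record.n + 1:
        raise ValueError("need one state label per inter-transition interval "
                         f"({record.n + 1}), got {len(state_sequence)}")
    for a, b in zip(state_sequence[:-1], state_sequence[1:]):
        if a == b:
            raise ValueError("consecutive intervals must occupy different states")
    dt = emission.frame_interval
    n_frames = int(round(record.tau / dt))
    # frame i sits at time i*dt (frame 0 at t=0), matching the detection
    # convention that a transition's time is (first new-state frame) * dt
    frame_times = dt * np.arange(n_frames)
    # a frame exactly at a transition time is the first frame of the new state
    interval_idx = np.searchsorted(record.times, frame_times, side="right")
    centers = np.array([emission.state_centers[s] for s in state_sequence])
    angles = centers[interval_idx]
    if emission.angular_noise_sd > 0:
        angles = angles + rng.normal(0.0, emission.angular_noise_sd,
                                     size=n_frames)
    angles = np.mod(angles, 360.0)
    return DihedralSeries(key=record.key, angles=angles, frame_interval=dt)


def write_angle_matrix(path, series: Sequence[DihedralSeries],
                       delimiter: str = "\t") -> None:
    """Write synthetic angle series in the shared angle-matrix text dialect.

    One column per residue (header = ``SEG:RESNAME:RESID`` keys), one row
    per frame — identical to the dihedral-extraction output so the same
    files feed the discretization stage.
    """
    from .io import save_angle_matrix
    save_angle_matrix(path, series, delimiter=delimiter)
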