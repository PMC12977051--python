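"""Ready-made synthetic systems with planted kinetic structure.

``synthetic_system`` builds a small multi-residue system containing a
directional master->slave coupling, one high-memory (bursty) residue,
and independent Poisson clocks for the rest, then emits noisy angle
series for all of them.  Downstream analysis should recover the planted
pair as the top off-diagonal activity and the bursty residue as the top
dynamical memory — the end-to-end ground truth used by the test suite
and by ``condact simulate``.
"""

from __future__ import annotations

import numpy as np

from .states import PROTEIN_ALPHABET
from .synthetic import (AngleEmissionSpec, CouplingSpec, RenewalSpec,
                        emit_angle_series, generate_coupled_pair,
                        generate_renewal)
from .types import DihedralSeries, ResidueKey, TransitionRecord

__all__ = ["random_state_sequence", "synthetic_system"]

PROTEIN_CENTERS = {"X": 60.0, "Y": 180.0, "Z": 300.0}


def random_state_sequence(n_intervals: int, rng: np.random.Generator,
                          alphabet=PROTEIN_ALPHABET) -> list[str]:
    """A state per inter-transition interval; consecutive states differ."""
    seq = [str(rng.choice(alphabet))]
    for _ in range(n_intervals - 1):
        options = [s for s in alphabet if s != seq[-1]]
        seq.append(str(rng.choice(options)))
    return seq


def synthetic_system(n_residues: int = 6, tau: float = 2000.0,
                     mean_waiting: float = 10.0, coupled_pairs: int = 1,
                     seed: int = 0, noise_sd: float = 8.0,
                     frame_interval: float | None = None,
                     ) -> tuple[list[DihedralSeries], dict]:
    """Angle series for a synthetic system with known kinetic structure.

    Layout (residue numbers 1-based): residue 1 drives residue 2
    (trigger probability 1, short lag; additional pairs 3->4, ... when
    ``coupled_pairs`` > 1); the residue after the last coupled pair is a
    bursty two-exponential-mixture clock with strong positive dynamical
    memory; remaining residues are independent Poisson clocks.  Returns
    the series plus a ground-truth dict naming the planted residues.
    """
    if n_residues < 2 * coupled_pairs + 2:
        raise ValueError("need at least 2*coupled_pairs + 2 residues")
    rng = np.random.default_rng(seed)
    dt = frame_interval if frame_interval is not None else mean_waiting / 40.0
    emission = AngleEmissionSpec(state_centers=PROTEIN_CENTERS,
                                 angular_noise_sd=noise_sd,
                                 frame_interval=dt)
    records: list[TransitionRecord] = []
    truth: dict = {"couplings": [], "high_memory": None}

    def _key(i: int) -> ResidueKey:
        return ResidueKey("SYN", i + 1, "VAL", "protein")

    idx = 0
    for _ in range(coupled_pairs):
        master_spec = RenewalSpec(("exponential", mean_waiting), tau,
                                  key=_key(idx))
        slave_base = RenewalSpec(("exponential", 4.0 * mean_waiting), tau,
                                 key=_key(idx + 1))
        # lag of three frame intervals: short against the mean waiting time
        # but resolvable after frame discretization (a sub-frame lag would
        # put master and response in the same frame and hide the coupling)
        coupling = CouplingSpec(trigger_probability=1.0, lag=("fixed", 3 * dt))
        master, slave = generate_coupled_pair(master_spec, coupling,
                                              slave_baseline=slave_base,
                                              rng=rng)
        records += [master, slave]
        truth["couplings"].append({"master": str(master.key),
                                   "slave": str(slave.key)})
        idx += 2

    # bursty clock: two-exponential mixture with heavy long component
    bursty_spec = RenewalSpec(
        ("mixture", 0.1 * mean_waiting, 4.0 * mean_waiting, 0.8), tau,
        key=_key(idx))
    records.append(generate_renewal(bursty_spec, rng=rng))
    truth["high_memory"] = str(records[-1].key)
    idx += 1

    while idx < n_residues:
        spec = RenewalSpec(("exponential", mean_waiting), tau, key=_key(idx))
        records.append(generate_renewal(spec, rng=rng))
        idx += 1

    series = []
    for rec in records:
        seq = random_state_sequence(rec.n + 1, rng)
        series.append(emit_angle_series(rec, emission, seq, rng=rng))
    return series, truth
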