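"""Permutation significance for inter-residue conditional activities.

The null hypothesis is that X's transition timing is unrelated to Y's.
It is built by circularly shifting the influencing residue's record by a
uniformly random offset modulo the observation time: the shift preserves
Y's single-residue waiting-time statistics (up to the one interval that
wraps the boundary) while destroying any cross-timing with X.  The
p-value is the one-sided upper-tail probability
p = (1 + #{A_null >= A_observed}) / (n_permutations + 1), so its floor
is 1/(n+1) and it is never zero.

Raw p-values are reported by default; an optional Benjamini-Hochberg
pass is available for tables of many pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import conditional_activity
from .types import TransitionRecord

__all__ = ["PermutationResult", "circular_shift", "permutation_pvalue",
           "significance_table", "benjamini_hochberg"]


@dataclass
class PermutationResult:
    observed_a: float
    null_samples: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


def circular_shift(record: TransitionRecord, offset: float) -> TransitionRecord:
    """Shift all transition times by ``offset`` modulo tau and re-sort.

    Preserves N and the multiset of interior waiting times except at the
    wrap point.  A time that lands exactly on 0 is mapped to tau to stay
    inside (0, tau].
    """
    if not 0 <= offset < record.tau:
        raise ValueError("offset must lie in [0, tau)")
    if record.n == 0 or offset == 0:
        return record.with_times(record.times.copy())
    shifted = np.mod(record.times + offset, record.tau)
    shifted[shifted == 0.0] = record.tau
    return record.with_times(np.sort(shifted))


def permutation_pvalue(x: TransitionRecord, y: TransitionRecord,
                       n_permutations: int = 2000,
                       seed: int = 0) -> PermutationResult:
    """Empirical upper-tail p-value for A[X][Y] under circular shifts of Y."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    observed = conditional_activity(x, y)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        offset = rng.uniform(0.0, y.tau)
        null[k] = conditional_activity(x, circular_shift(y, offset))
    finite_null = null[np.isfinite(null)]
    n_ge = int(np.sum(finite_null >= observed)) if np.isfinite(observed) else n_permutations
    p = (1.0 + n_ge) / (n_permutations + 1.0)
    return PermutationResult(observed_a=float(observed), null_samples=null,
                             p_value=float(p),
                             n_permutations=n_permutations, seed=seed)


def significance_table(records, pairs=None, n_permutations: int = 2000,
                       seed: int = 0, fdr: bool = False) -> pd.DataFrame:
    """Long-format table (residue_X, residue_Y, A, p_value) for residue pairs.

    ``pairs`` is an iterable of (i, j) index pairs into ``records``;
    by default all ordered off-diagonal pairs are tested.  With
    ``fdr=True`` a Benjamini-Hochberg adjusted column is appended.
    """
    records = list(records)
    if pairs is None:
        pairs = [(i, j) for i in range(len(records))
                 for j in range(len(records)) if i != j]
    rng = np.random.default_rng(seed)
    rows = []
    for i, j in pairs:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = permutation_pvalue(records[i], records[j],
                                 n_permutations=n_permutations, seed=sub_seed)
        rows.append({"residue_X": str(records[i].key),
                     "residue_Y": str(records[j].key),
                     "A": res.observed_a, "p_value": res.p_value})
    table = pd.DataFrame(rows)
    if fdr and len(table):
        table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adjusted, 1.0)
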