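"""Coupling versus spatial separation: the fraction of residue pairs whose
conditional activity (or mutual information) exceeds a threshold, binned
by inter-residue distance.

The reference point of a residue is the center of geometry of its
dihedral quadruple's atoms on a time-averaged structure (selectable:
first frame, or a single representative atom).  Distances are in nm.
The distance-0 bin holds the self-pairs, i.e. the diagonal of the
activity matrix (dynamical memory against the same threshold).

Conditional activity is directional, so its curve counts ordered pairs;
MI is symmetric and its curve counts unordered pairs once.  The default
coupling threshold of 2 (natural-log units) corresponds to roughly 20%
of the largest inter-residue activity in well-sampled systems; the MI
curve has no stated absolute threshold, so it reuses the same fractional
rule — 20% of the maximum off-diagonal MI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DistanceProfile", "residue_positions", "fraction_correlated",
           "distance_profile_frame"]

ANGSTROM_TO_NM = 0.1


@dataclass
class DistanceProfile:
    """Fraction of coupled pairs per distance bin, with SEM over replicas."""

    bin_edges: np.ndarray      # nm, ascending; bin 0 is the self-pair bin
    fraction: np.ndarray       # NaN where a bin holds no pairs
    n_pairs: np.ndarray
    threshold: float
    sem: np.ndarray | None = None

    @property
    def bin_mid(self) -> np.ndarray:
        mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return np.concatenate(([0.0], mids))  # leading self-pair bin

    def to_frame(self) -> pd.DataFrame:
        data = {"bin_mid_nm": self.bin_mid, "fraction": self.fraction,
                "n_pairs": self.n_pairs}
        if self.sem is not None:
            data["sem"] = self.sem
        return pd.DataFrame(data)


def residue_positions(universe_or_series, series=None, mode: str = "average",
                      stride: int = 1) -> dict[str, np.ndarray]:
    """Per-residue reference coordinates in nm.

    For each dihedral series, the reference point is the center of
    geometry of its quadruple's atoms, on the time-averaged structure
    (``mode="average"``, the default) or the first frame
    (``mode="first"``).  Returns ``{residue-key string: xyz (nm)}``.
    """
    universe = universe_or_series
    out: dict[str, np.ndarray] = {}
    by_resid: dict[tuple[int, str], list[int]] = {}
    for s in series:
        if s.atom_quadruple is None:
            continue
        res = universe.select_atoms(f"resid {s.key.residue_number}").residues
        res = [r for r in res
               if str(r.resname).strip() == s.key.residue_name][:1]
        if not res:
            continue
        names = {n.replace("′", "'").replace("*", "'").upper()
                 for n in s.atom_quadruple}
        idx = [a.index for a in res[0].atoms
               if a.name.replace("′", "'").replace("*", "'").upper() in names]
        if idx:
            by_resid[str(s.key)] = idx
    if mode == "first":
        frames = [0]
    else:
        frames = range(0, len(universe.trajectory), stride)
    acc = {k: np.zeros(3) for k in by_resid}
    count = 0
    for f in frames:
        universe.trajectory[f]
        pos = universe.atoms.positions
        for k, idx in by_resid.items():
            acc[k] += pos[idx].mean(axis=0)
        count += 1
    for k in acc:
        out[k] = acc[k] / count * ANGSTROM_TO_NM
    return out


def fraction_correlated(matrix, positions: dict[str, np.ndarray],
                        threshold: float = 2.0, bin_width: float = 0.5,
                        max_distance: float = 10.0,
                        symmetric: bool = False) -> DistanceProfile:
    """Fraction of residue pairs with coupling >= threshold, per distance bin.

    ``matrix`` is a labelled square DataFrame (activity or MI).  Ordered
    off-diagonal pairs are counted unless ``symmetric=True`` (MI), in
    which case each unordered pair counts once.  The leading bin (distance
    0) is the diagonal.  Bins with no pairs get NaN, not 0.
    """
    labels = [l for l in matrix.index if l in positions]
    if not labels:
        raise ValueError("no residues shared between matrix and positions")
    sub = matrix.loc[labels, labels].to_numpy(dtype=float)
    xyz = np.array([positions[l] for l in labels])
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    n = len(labels)
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    n_bins = edges.size - 1
    frac = np.full(n_bins + 1, np.nan)
    counts = np.zeros(n_bins + 1, dtype=int)

    diag = np.diagonal(sub)
    defined = np.isfinite(diag)
    counts[0] = int(defined.sum())
    if counts[0]:
        frac[0] = float(np.mean(diag[defined] >= threshold))

    iu, ju = np.triu_indices(n, k=1)
    if symmetric:
        pair_i, pair_j = iu, ju
    else:
        pair_i = np.concatenate([iu, ju])
        pair_j = np.concatenate([ju, iu])
    values = sub[pair_i, pair_j]
    distances = dist[pair_i, pair_j]
    ok = np.isfinite(values)
    values, distances = values[ok], distances[ok]
    which = np.digitize(distances, edges) - 1
    for b in range(n_bins):
        mask = which == b
        counts[b + 1] = int(mask.sum())
        if counts[b + 1]:
            frac[b + 1] = float(np.mean(values[mask] >= threshold))
    return DistanceProfile(bin_edges=edges, fraction=frac, n_pairs=counts,
                           threshold=threshold)


def distance_profile_frame(profiles: list[DistanceProfile]) -> pd.DataFrame:
    """Mean and SEM over replica profiles, aligned on identical bins."""
    if not profiles:
        raise ValueError("no profiles")
    stack = np.array([p.fraction for p in profiles])
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        count = np.sum(np.isfinite(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(count >= 2, sd / np.sqrt(np.maximum(count, 1)), np.nan)
    out = profiles[0].to_frame()[["bin_mid_nm"]].copy()
    out["fraction"] = mean
    out["sem"] = sem
    out["n_pairs"] = np.sum([p.n_pairs for p in profiles], axis=0)
    return out
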