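"""Per-residue dihedral time series from MD trajectories.

Proteins contribute the first side-chain torsion chi1 (N-CA-CB-gamma;
glycine and alanine have no chi1 and are skipped).  DNA contributes the
glycosidic base-sugar torsion: O4'-C1'-N9-C4 for purines and
O4'-C1'-N1-C2 for pyrimidines, which separates the syn and anti base
orientations.  Angles are reported in degrees on [0, 360): the secondary
angle (raw + 360) is used for negative raw dihedrals, because the
rotamer / syn-anti state boundaries are defined on that range.

Reading topologies (PDB, PSF, PRMTOP, GRO, ...) and coordinates (DCD,
XTC, TRR, multi-model PDB, ...) and the dihedral geometry itself are
delegated to MDAnalysis.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np

from .types import DihedralSeries, ResidueKey

logger = logging.getLogger(__name__)

__all__ = [
    "CHI1_GAMMA_ATOM",
    "wrap_angle",
    "extract_chi1",
    "extract_glycosidic",
    "extract_all",
]

# Standard gamma heavy atom completing the chi1 quadruple N-CA-CB-gamma.
CHI1_GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "HSD": "CG", "HSE": "CG", "HSP": "CG",
    "HID": "CG", "HIE": "CG", "HIP": "CG",
    "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG", "PRO": "CG",
    "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG",
}
_NO_CHI1 = {"GLY", "ALA"}

_PURINES = {"DA", "DG", "ADE", "GUA", "A", "G", "DA5", "DG5", "DA3", "DG3"}
_PYRIMIDINES = {"DC", "DT", "CYT", "THY", "C", "T", "U",
                "DC5", "DT5", "DC3", "DT3"}


def wrap_angle(raw):
    """Map a raw dihedral in (-180, 180] to [0, 360).

    Negative angles take their secondary angle (raw + 360); non-negative
    angles are unchanged.  Vectorized; NaN (undefined geometry) passes
    through, infinities are rejected.
    """
    arr = np.asarray(raw, dtype=float)
    if np.isinf(arr).any():
        raise ValueError("non-finite dihedral angle")
    out = np.where(arr < 0, arr + 360.0, arr)
    # raw == 180 maps to itself; a raw of exactly 360 cannot occur
    out = np.where(out >= 360.0, out - 360.0, out)
    return out if arr.ndim else float(out)


def _strip_primes(name: str) -> str:
    """Normalize primed / apostrophe / star sugar-atom dialects (O4' == O4* == O4′)."""
    return name.replace("′", "'").replace("*", "'").upper()


def _find_atom(residue, wanted: str):
    wanted = _strip_primes(wanted)
    for atom in residue.atoms:
        if _strip_primes(atom.name) == wanted:
            return atom
    return None


def _quadruple_series(universe, index_quads, stride: int = 1) -> np.ndarray:
    """(n_frames, n_quadruples) wrapped dihedral angles for atom-index quadruples."""
    from MDAnalysis.lib.distances import calc_dihedrals

    idx = np.asarray(index_quads, dtype=int)
    rows = []
    for ts in universe.trajectory[::stride]:
        pos = universe.atoms.positions
        rad = calc_dihedrals(pos[idx[:, 0]], pos[idx[:, 1]],
                             pos[idx[:, 2]], pos[idx[:, 3]], box=None)
        with np.errstate(invalid="ignore"):
            rows.append(wrap_angle(np.degrees(rad)))
    return np.asarray(rows)


def _frame_interval(universe, stride: int) -> float:
    dt = getattr(universe.trajectory, "dt", None) or 1.0
    return float(dt) * stride


def _residue_key(res, polymer_class: str) -> ResidueKey:
    seg = getattr(res, "segid", "") or getattr(res, "chainID", "") or "SYSTEM"
    return ResidueKey(segment=str(seg).strip() or "SYSTEM",
                      residue_number=int(res.resid),
                      residue_name=str(res.resname).strip(),
                      polymer_class=polymer_class)


def extract_chi1(universe, selection: str = "protein",
                 stride: int = 1) -> list[DihedralSeries]:
    """chi1 (N-CA-CB-gamma) time series for every protein residue with one.

    Gly and Ala are skipped silently; residues missing any quadruple atom
    are skipped with a warning.  ``stride`` subsamples frames, scaling
    the frame interval accordingly.
    """
    group = universe.select_atoms(selection)
    keys, quads, groups = [], [], []
    for res in group.residues:
        resname = str(res.resname).strip().upper()
        if resname in _NO_CHI1:
            continue
        gamma = CHI1_GAMMA_ATOM.get(resname)
        if gamma is None:
            logger.warning("%s %d: unknown residue type, skipped",
                           resname, res.resid)
            continue
        atoms = [_find_atom(res, nm) for nm in ("N", "CA", "CB", gamma)]
        if any(at is None for at in atoms):
            missing = [nm for nm, at in zip(("N", "CA", "CB", gamma), atoms)
                       if at is None]
            logger.warning("%s %d: missing atoms %s, skipped",
                           resname, res.resid, missing)
            continue
        keys.append(_residue_key(res, "protein"))
        quads.append(("N", "CA", "CB", gamma))
        groups.append([at.index for at in atoms])
    if not groups:
        return []
    angles = _quadruple_series(universe, groups, stride=stride)
    dt = _frame_interval(universe, stride)
    return [DihedralSeries(key=k, angles=angles[:, i], frame_interval=dt,
                           atom_quadruple=q)
            for i, (k, q) in enumerate(zip(keys, quads))]


def extract_glycosidic(universe, selection: str = "nucleic",
                       stride: int = 1) -> list[DihedralSeries]:
    """Glycosidic dihedral time series for every DNA nucleotide.

    Purines (A, G) use O4'-C1'-N9-C4; pyrimidines (C, T) use
    O4'-C1'-N1-C2.  Primed, apostrophe and star sugar-atom naming
    dialects are all accepted.  Unknown base names are skipped with a
    warning.
    """
    group = universe.select_atoms(selection)
    keys, quads, groups = [], [], []
    for res in group.residues:
        resname = str(res.resname).strip().upper()
        if resname in _PURINES:
            names = ("O4'", "C1'", "N9", "C4")
        elif resname in _PYRIMIDINES:
            names = ("O4'", "C1'", "N1", "C2")
        else:
            logger.warning("%s %d: unknown base, skipped", resname, res.resid)
            continue
        atoms = [_find_atom(res, nm) for nm in names]
        if any(at is None for at in atoms):
            missing = [nm for nm, at in zip(names, atoms) if at is None]
            logger.warning("%s %d: missing atoms %s, skipped",
                           resname, res.resid, missing)
            continue
        keys.append(_residue_key(res, "dna"))
        quads.append(names)
        groups.append([at.index for at in atoms])
    if not groups:
        return []
    angles = _quadruple_series(universe, groups, stride=stride)
    dt = _frame_interval(universe, stride)
    return [DihedralSeries(key=k, angles=angles[:, i], frame_interval=dt,
                           atom_quadruple=q)
            for i, (k, q) in enumerate(zip(keys, quads))]


def extract_all(topology, *trajectories, protein_selection: str = "protein",
                dna_selection: str = "nucleic",
                stride: int = 1) -> list[DihedralSeries]:
    """chi1 + glycosidic series from a topology and optional coordinates.

    Each replica should be loaded separately — never concatenate
    trajectories, since a splice boundary would fabricate a transition.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = (mda.Universe(topology, *trajectories) if trajectories
                    else mda.Universe(topology))
    series = extract_chi1(universe, protein_selection, stride=stride)
    series += extract_glycosidic(universe, dna_selection, stride=stride)
    return series
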