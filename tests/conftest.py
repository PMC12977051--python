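"""Shared fixtures: toy transition records and tiny programmatic PDB
structures (text-only, built at test time)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from condact import ResidueKey, TransitionRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def toy_record() -> TransitionRecord:
    """Transitions at 1, 3, 7 over tau = 7: tau_p = 1.5, tau_xx = 8/7."""
    return TransitionRecord(key=ResidueKey("A", 1, "VAL"),
                            times=np.array([1.0, 3.0, 7.0]), tau=7.0)


def _pdb_atom(serial, name, resname, chain, resseq, xyz, element):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:>5d} {name_field:<4s}{resname:>4s} {chain}"
            f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00  0.00          {element:>2s}\n")


def make_pdb(frames: list[list[tuple]], path) -> str:
    """Write a multi-model PDB.

    Each frame is a list of (name, resname, chain, resseq, (x, y, z))
    tuples; every frame must list the same atoms in the same order.
    """
    lines = []
    for m, atoms in enumerate(frames, start=1):
        if len(frames) > 1:
            lines.append(f"MODEL     {m:>4d}\n")
        for serial, (name, resname, chain, resseq, xyz) in enumerate(atoms, 1):
            lines.append(_pdb_atom(serial, name, resname, chain, resseq, xyz,
                                   name[0]))
        if len(frames) > 1:
            lines.append("ENDMDL\n")
    lines.append("END\n")
    text = "".join(lines)
    path.write_text(text)
    return str(path)


def peptide_atoms(chi1_deg_by_res: dict[int, float]) -> list[tuple]:
    """Atoms of an Ala-Gly-Ser-Val-Lys peptide with prescribed chi1 angles.

    Each residue is placed on its own z-offset; the chi1 quadruple
    N-CA-CB-gamma is built so the dihedral equals the requested angle
    (standard sign convention), with CA-CB along +x and N off in +y.
    """
    residues = [(1, "ALA"), (2, "GLY"), (3, "SER"), (4, "VAL"), (5, "LYS")]
    gamma = {"SER": "OG", "VAL": "CG1", "LYS": "CG", "ALA": None, "GLY": None}
    atoms = []
    for resseq, resname in residues:
        z0 = 10.0 * resseq
        base = np.array([0.0, 0.0, z0])
        # quadruple: N at (0,1,z), CA at origin, CB at (1.5,0,z)
        atoms.append(("N", resname, "A", resseq, tuple(base + [0.0, 1.5, 0.0])))
        atoms.append(("CA", resname, "A", resseq, tuple(base)))
        if resname == "GLY":
            continue
        atoms.append(("CB", resname, "A", resseq, tuple(base + [1.5, 0.0, 0.0])))
        g = gamma[resname]
        if g is None:
            continue
        phi = np.radians(chi1_deg_by_res.get(resseq, 60.0))
        # the dihedral N-CA-CB-G then equals phi (right-handed convention)
        direction = np.array([0.0, np.cos(phi), np.sin(phi)])
        atoms.append((g, resname, "A", resseq,
                      tuple(base + np.array([1.5, 0.0, 0.0]) + 1.4 * direction)))
    return atoms


def dna_atoms(glyco_deg_by_res: dict[int, float]) -> list[tuple]:
    """One DG and one DT nucleotide with prescribed glycosidic dihedrals."""
    residues = [(11, "DG", ("O4'", "C1'", "N9", "C4")),
                (12, "DT", ("O4'", "C1'", "N1", "C2"))]
    atoms = []
    for resseq, resname, names in residues:
        z0 = 10.0 * resseq
        base = np.array([0.0, 0.0, z0])
        phi = np.radians(glyco_deg_by_res.get(resseq, 30.0))
        direction = np.array([0.0, np.cos(phi), np.sin(phi)])
        coords = [base + [0.0, 1.5, 0.0], base,
                  base + [1.5, 0.0, 0.0],
                  base + np.array([1.5, 0.0, 0.0]) + 1.4 * direction]
        for name, xyz in zip(names, coords):
            atoms.append((name, resname, "B", resseq, tuple(xyz)))
        # minimal extra atoms so MDAnalysis "nucleic" selection finds the residue
        atoms.append(("P", resname, "B", resseq, tuple(base + [-2.0, 0.0, 0.0])))
        atoms.append(("O3'", resname, "B", resseq,
                      tuple(base + [-1.0, -1.0, 0.0])))
    return atoms


def dihedral_oracle(p0, p1, p2, p3) -> float:
    """Independent dihedral computation (degrees in (-180, 180])."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))
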