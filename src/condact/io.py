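"""Delimited-text serialization shared by every stage.

Formats (all plain text, tab-delimited by default):

* angle matrix — rows = frames, columns = residues, header row of
  ``SEG:RESNAME:RESID`` keys; JSON sidecar (``<path>.meta.json``) with
  the frame interval and atom quadruples;
* transition records — one row per residue:
  key, replica, N, tau, comma-joined times;
* square matrices (activity, MI) — residue-key header row and column;
* long-format coupling table — residue_X, residue_Y, A, p_value.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import DihedralSeries, ResidueKey, TransitionRecord
from .kinetics import ActivityMatrix

__all__ = [
    "save_angle_matrix", "load_angle_matrix",
    "save_transition_records", "load_transition_records",
    "save_matrix", "load_matrix",
    "save_bfactor_pdb",
]


def save_angle_matrix(path, series: Sequence[DihedralSeries],
                      delimiter: str = "\t") -> None:
    if not series:
        raise ValueError("nothing to save")
    n = {s.n_frames for s in series}
    if len(n) != 1:
        raise ValueError("all series must have the same frame count")
    dt = {s.frame_interval for s in series}
    if len(dt) != 1:
        raise ValueError("all series must share the frame interval")
    frame = pd.DataFrame({str(s.key): s.angles for s in series})
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.6f")
    meta = {
        "frame_interval": series[0].frame_interval,
        "atom_quadruples": {str(s.key): list(s.atom_quadruple)
                            if s.atom_quadruple else None for s in series},
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_angle_matrix(path, delimiter: str = "\t",
                      frame_interval: float | None = None) -> list[DihedralSeries]:
    frame = pd.read_csv(path, sep=delimiter)
    meta_path = Path(str(path) + ".meta.json")
    quads = {}
    if frame_interval is None:
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            frame_interval = float(meta["frame_interval"])
            quads = meta.get("atom_quadruples") or {}
        else:
            frame_interval = 1.0
    out = []
    for col in frame.columns:
        q = quads.get(col)
        out.append(DihedralSeries(key=ResidueKey.from_string(col),
                                  angles=frame[col].to_numpy(dtype=float),
                                  frame_interval=frame_interval,
                                  atom_quadruple=tuple(q) if q else None))
    return out


def save_transition_records(path, records: Sequence[TransitionRecord],
                            delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(("key", "replica", "N", "tau", "times")) + "\n")
        for r in records:
            times = ",".join(f"{t:.9g}" for t in r.times)
            fh.write(delimiter.join((str(r.key), str(r.replica_id), str(r.n),
                                     f"{r.tau:.9g}", times)) + "\n")


def load_transition_records(path, delimiter: str = "\t") -> list[TransitionRecord]:
    frame = pd.read_csv(path, sep=delimiter, dtype=str).fillna("")
    out = []
    for _, row in frame.iterrows():
        times = (np.array([float(t) for t in row["times"].split(",")])
                 if row["times"] else np.empty(0))
        out.append(TransitionRecord(key=ResidueKey.from_string(row["key"]),
                                    times=times, tau=float(row["tau"]),
                                    replica_id=int(row["replica"])))
    return out


def save_matrix(path, matrix: ActivityMatrix | pd.DataFrame,
                delimiter: str = "\t") -> None:
    frame = matrix.to_frame() if isinstance(matrix, ActivityMatrix) else matrix
    frame.to_csv(path, sep=delimiter, float_format="%.6f",
                 index_label="residue")


def load_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, index_col=0)


def save_bfactor_pdb(reference_pdb, out_path, scores: dict[str, float]) -> None:
    """Write per-residue scores into the B-factor column of a reference PDB.

    ``scores`` maps ``SEG:RESNAME:RESID`` keys to values; residues absent
    from the map get 0.  Intended for sphere-size rendering of memory or
    eigenvector scores in molecular viewers.
    """
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(reference_pdb)
        u.add_TopologyAttr("tempfactors", np.zeros(len(u.atoms)))
        by_resid = {}
        for key, value in scores.items():
            by_resid[int(key.rsplit(":", 1)[1])] = value
        for res in u.residues:
            res.atoms.tempfactors = by_resid.get(int(res.resid), 0.0)
        u.atoms.write(str(out_path))
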