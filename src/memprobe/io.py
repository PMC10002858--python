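"""Structure/trajectory reading and analysis-product writing.

Reading goes through mdtraj (PDB including multi-MODEL, GRO including
concatenated multi-frame files, and — where the optional binary plug-ins are
available — XTC/DCD behind the same contract).  Coordinates are converted to
Å on read (mdtraj is nm-native).  Writing of PDB/GRO frames is provided for
the synthetic generator's fixtures; tabular products go to CSV and gridded
products to a JSON matrix container.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AtomRecord,
    LipidClass,
    MolecularSystem,
    SegmentKind,
    Trajectory,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RESIDUE_CLASS_TABLE",
    "TrajectorySource",
    "read_structure",
    "read_frames",
    "read_trajectory",
    "write_pdb",
    "write_gro",
    "write_table",
    "read_table",
    "write_grid",
    "read_grid",
]

_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP",
}
_SOLVENT = {"HOH", "TIP3", "SOL", "WAT", "SPC"}
_IONS = {"SOD", "CLA", "POT", "MG", "CAL", "ZN", "ZN2", "NA", "CL", "K"}

#: residue name -> lipid class; CHARMM36 tokens for the bilayer species this
#: package targets, plus common aliases.  Extendable via ``extra_classes``.
RESIDUE_CLASS_TABLE: dict[str, LipidClass] = {
    "CHL1": LipidClass.CHOL, "CHOL": LipidClass.CHOL,
    "POPC": LipidClass.PC, "DOPC": LipidClass.PC, "DPPC": LipidClass.PC,
    "POPE": LipidClass.PE, "DOPE": LipidClass.PE,
    "SOPS": LipidClass.PS, "POPS": LipidClass.PS, "DOPS": LipidClass.PS,
    "POPA": LipidClass.PA, "DOPA": LipidClass.PA,
    "PLPIP35": LipidClass.PIP, "SAPI": LipidClass.PIP, "PIP2": LipidClass.PIP,
    "CER160": LipidClass.CER, "CER": LipidClass.CER, "CER180": LipidClass.CER,
}


@dataclass
class TrajectorySource:
    """Where a trajectory lives on disk: a structure file plus frame file(s)."""

    structure_path: str
    frames_paths: list[str] = field(default_factory=list)
    format: str | None = None  # 'pdb' | 'gro' | 'compressed_trajectory' | None = infer

    def __post_init__(self):
        if not os.path.exists(self.structure_path):
            raise FileNotFoundError(self.structure_path)
        for p in self.frames_paths:
            if not os.path.exists(p):
                raise FileNotFoundError(p)


def _classify(residue_name: str, ligand_resnames: set[str], table: Mapping[str, LipidClass]):
    if residue_name in _AMINO:
        return SegmentKind.PROTEIN, None
    if residue_name in table:
        return SegmentKind.LIPID, table[residue_name]
    if residue_name in _SOLVENT:
        return SegmentKind.SOLVENT, None
    if residue_name in _IONS:
        return SegmentKind.ION, None
    if residue_name in ligand_resnames:
        return SegmentKind.LIGAND, None
    logger.warning("unknown residue name %r classified as 'other'", residue_name)
    return SegmentKind.OTHER, None


def read_structure(
    path: str,
    format: str | None = None,
    extra_classes: Mapping[str, LipidClass] | None = None,
    ligand_resnames: Sequence[str] = ("PMA", "BRY", "M27", "LIG"),
) -> MolecularSystem:
    """Read a PDB or GRO structure into a :class:`MolecularSystem`.

    Atoms are classified into protein/lipid/ligand/solvent/ion/other from a
    configurable residue-name table; unknown residue names are kept (as
    ``other``) with a warning.  GRO coordinates (nm) are converted to Å, but
    only coordinates' metadata matters here — the atom table is static.
    """
    import mdtraj as md

    table = dict(RESIDUE_CLASS_TABLE)
    if extra_classes:
        table.update(extra_classes)
    lig = set(ligand_resnames)

    if str(path).lower().endswith(".gro"):
        top = md.load(path).topology  # GRO has no frame-seek support
    else:
        top = md.load_frame(path, 0).topology
    atoms = []
    for a in top.atoms:
        kind, lipid_class = _classify(a.residue.name, lig, table)
        atoms.append(
            AtomRecord(
                atom_index=a.index,
                atom_name=a.name,
                residue_name=a.residue.name,
                residue_seq=a.residue.resSeq,
                segment_kind=kind,
                molecule_id=a.residue.index,
                lipid_class=lipid_class,
            )
        )
    return MolecularSystem(atoms, name=os.path.basename(path))


def read_frames(
    paths: str | Sequence[str],
    system: MolecularSystem,
    format: str | None = None,
    dt: float | None = None,
    time_offset: float = 0.0,
) -> Trajectory:
    """Read coordinate frames for *system* into a :class:`Trajectory`.

    ``paths`` may be one file (multi-model PDB / concatenated GRO / binary
    trajectory plus the structure as topology) or a list concatenated in
    order.  Frame times come from the file where the format carries them
    (GRO ``t=`` titles); otherwise they are synthesised as
    ``time_offset + dt * frame_index`` (``dt`` default 1 ns).  Times must be
    strictly increasing.
    """
    import mdtraj as md

    if isinstance(paths, (str, os.PathLike)):
        paths = [str(paths)]
    xyz, boxes, times = [], [], []
    n_frames_seen = 0
    for path in paths:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        if ext in ("pdb", "gro"):
            t = md.load(path)
        else:  # binary formats need an explicit topology
            t = md.load(path, top=md.load(paths[0]).topology)
        if t.n_atoms != system.n_atoms:
            raise ValueError(
                f"frame {n_frames_seen} (file {path!r}): atom count {t.n_atoms} "
                f"does not match system atom count {system.n_atoms}"
            )
        if t.unitcell_lengths is None:
            raise ValueError(f"{path!r} carries no periodic box (CRYST1/box line missing)")
        xyz.append(t.xyz * 10.0)  # nm -> Å
        boxes.append(t.unitcell_lengths * 10.0)
        times.append(np.asarray(t.time, dtype=float))
        n_frames_seen += t.n_frames

    coords = np.concatenate(xyz)
    boxes_a = np.concatenate(boxes)
    file_times = np.concatenate(times)
    if dt is not None:
        times_a = time_offset + dt * np.arange(len(coords))
    elif np.all(np.diff(file_times) > 0) and len(file_times) == len(coords):
        times_a = file_times + time_offset
    elif len(coords) == 1:
        times_a = np.array([time_offset])
    else:
        raise ValueError(
            "frame times from file are not strictly increasing; pass dt= to "
            "assign uniform times explicitly"
        )
    return Trajectory(system, coords, boxes_a, times_a)


def read_trajectory(source: TrajectorySource, **kwargs) -> Trajectory:
    """Convenience wrapper: read structure then frames from a source spec."""
    system = read_structure(source.structure_path, format=source.format)
    frames = source.frames_paths or [source.structure_path]
    return read_frames(frames, system, format=source.format, **kwargs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, het):
    if len(resname) > 4:
        raise ValueError(f"residue name {resname!r} exceeds the 4-character PDB field")
    rec = "HETATM" if het else "ATOM  "
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{rec}{serial % 100000:>5d} {nm:<4s} {resname:<4s}{chain:1s}"
        f"{resseq % 10000:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {_element_of(name):>2s}"
    )


def write_pdb(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB (CRYST1 + MODEL/ENDMDL)."""
    sys_ = traj.system
    lines = []
    b = traj.boxes[0]
    lines.append(
        f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}  90.00  90.00  90.00 P 1           1"
    )
    het = sys_.segment_kinds != SegmentKind.PROTEIN.value
    for m in range(traj.n_frames):
        lines.append(f"MODEL     {m + 1:>4d}")
        coords = traj.coordinates[m]
        for a in sys_.atoms:
            chain = "A" if not het[a.atom_index] else "B"
            x, y, z = coords[a.atom_index]
            lines.append(
                _pdb_atom_line(
                    a.atom_index + 1, a.atom_name, a.residue_name, chain,
                    a.residue_seq, x, y, z, bool(het[a.atom_index]),
                )
            )
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_gro(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a concatenated GRO file (nm units, t= titles)."""
    sys_ = traj.system
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"{sys_.name} t= {traj.times[m]:.4f}\n{sys_.n_atoms:5d}\n")
            coords = traj.coordinates[m] / 10.0
            for a in sys_.atoms:
                x, y, z = coords[a.atom_index]
                fh.write(
                    f"{a.residue_seq % 100000:>5d}{a.residue_name:<5s}"
                    f"{a.atom_name:>5s}{(a.atom_index + 1) % 100000:>5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            b = traj.boxes[m] / 10.0
            fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


def write_table(df: pd.DataFrame, path: str, metadata: Mapping[str, str] | None = None) -> None:
    """Write a tabular product as CSV; metadata (units etc.) as '#' header lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_grid(grid, path: str) -> None:
    """Write a gridded product (2D counts + bin edges) as a JSON container."""
    data = grid.to_dict() if hasattr(grid, "to_dict") else dict(grid)
    out = {}
    for k, v in data.items():
        out[k] = v.tolist() if isinstance(v, np.ndarray) else v
    with open(path, "w") as fh:
        json.dump(out, fh)


def read_grid(path: str) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    for k in ("counts", "x_edges", "y_edges", "depth_edges", "tilt_edges"):
        if k in data:
            data[k] = np.asarray(data[k])
    return data
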