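"""Shared data model for membrane protein-lipid trajectory analysis.

The model is deliberately minimal: a static atom table
(:class:`MolecularSystem`), coordinate frames with an orthorhombic periodic
box (:class:`Frame`, :class:`Trajectory`), named atom selections
(:class:`SelectionSpec`) and a per-leaflet membrane composition
(:class:`MembraneComposition`).  All coordinates are stored in Angstrom and
all times in nanoseconds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SegmentKind",
    "LipidClass",
    "AtomRecord",
    "MolecularSystem",
    "Frame",
    "Trajectory",
    "SelectionGroup",
    "SelectionSpec",
    "SelectionError",
    "MembraneComposition",
    "composition_from_frame",
    "resolve_selection",
    "leaflet_assign",
    "DEFAULT_HEADGROUP_ATOMS",
]


class SegmentKind(str, enum.Enum):
    """Broad classification of what kind of molecule an atom belongs to."""

    PROTEIN = "protein"
    LIPID = "lipid"
    LIGAND = "ligand"
    SOLVENT = "solvent"
    ION = "ion"
    OTHER = "other"


class LipidClass(str, enum.Enum):
    """Headgroup chemistry classes of the bilayer's lipid species."""

    CHOL = "CHOL"  # cholesterol
    PC = "PC"      # phosphatidylcholine
    PE = "PE"      # phosphatidylethanolamine
    PS = "PS"      # phosphatidylserine
    PA = "PA"      # phosphatidic acid
    PIP = "PIP"    # phosphatidylinositol phosphate
    CER = "CER"    # ceramide


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the static topology.

    ``molecule_id`` groups the atoms of one molecule (for lipids, one lipid
    molecule; for the protein, one residue) so that per-molecule analyses
    such as leaflet assignment and contact bookkeeping are well defined.
    """

    atom_index: int
    atom_name: str
    residue_name: str
    residue_seq: int
    segment_kind: SegmentKind
    molecule_id: int
    lipid_class: LipidClass | None = None


class SelectionError(KeyError):
    """Raised when a selection predicate matches no atom of the system."""


class MolecularSystem:
    """Ordered, validated atom table with fast lookup arrays.

    Parameters
    ----------
    atoms
        Atom records ordered by ``atom_index`` (0-based, contiguous).
    name
        Free-form system label.
    """

    def __init__(self, atoms: Sequence[AtomRecord], name: str = "system"):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("MolecularSystem requires at least one atom")
        for i, a in enumerate(atoms):
            if a.atom_index != i:
                raise ValueError(
                    f"atom_index must be contiguous from 0; got {a.atom_index} at position {i}"
                )
            if a.segment_kind is SegmentKind.LIPID and a.lipid_class is None:
                raise ValueError(
                    f"lipid atom {a.atom_name} ({a.residue_name} {a.residue_seq}) lacks lipid_class"
                )
        self.atoms: list[AtomRecord] = atoms
        self.name = name

        self.atom_names = np.array([a.atom_name for a in atoms])
        self.residue_names = np.array([a.residue_name for a in atoms])
        self.residue_seqs = np.array([a.residue_seq for a in atoms], dtype=np.int64)
        self.molecule_ids = np.array([a.molecule_id for a in atoms], dtype=np.int64)
        self.segment_kinds = np.array([a.segment_kind.value for a in atoms])
        self.lipid_classes = np.array(
            [a.lipid_class.value if a.lipid_class is not None else "" for a in atoms]
        )
        # molecule_id consistency: same residue_name and segment_kind throughout
        for mid in np.unique(self.molecule_ids):
            mask = self.molecule_ids == mid
            if len(set(self.residue_names[mask])) != 1 or len(set(self.segment_kinds[mask])) != 1:
                raise ValueError(f"molecule_id {mid} spans multiple residue names or segment kinds")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<MolecularSystem {self.name!r} with {self.n_atoms} atoms>"

    # -- lookups ---------------------------------------------------------

    def atom_indices(self, residue: str | int, atom_name: str) -> np.ndarray:
        """Indices of atoms matching a (residue_name | residue_seq, atom_name) predicate."""
        if isinstance(residue, (int, np.integer)):
            res_mask = self.residue_seqs == int(residue)
        else:
            res_mask = self.residue_names == residue
        return np.nonzero(res_mask & (self.atom_names == atom_name))[0]

    def lipid_molecules(self) -> dict[int, LipidClass]:
        """Map molecule_id -> lipid class for all lipid molecules."""
        out: dict[int, LipidClass] = {}
        lipid_mask = self.segment_kinds == SegmentKind.LIPID.value
        for mid, cls in zip(self.molecule_ids[lipid_mask], self.lipid_classes[lipid_mask]):
            out[int(mid)] = LipidClass(cls)
        return out

    def molecule_atoms(self, molecule_id: int) -> np.ndarray:
        return np.nonzero(self.molecule_ids == molecule_id)[0]


@dataclass
class Frame:
    """One snapshot: per-atom coordinates (Å), orthorhombic box (Å), time (ns)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (Lx, Ly, Lz)")


class Trajectory:
    """A molecular system plus an ordered stack of coordinate frames.

    Coordinates are held as one ``(n_frames, n_atoms, 3)`` float array in Å;
    ``boxes`` is ``(n_frames, 3)`` and ``times`` is ``(n_frames,)`` in ns.
    ``frames`` yields :class:`Frame` views for frame-at-a-time APIs.
    """

    def __init__(
        self,
        system: MolecularSystem,
        coordinates: np.ndarray,
        boxes: np.ndarray,
        times: np.ndarray,
    ):
        coordinates = np.asarray(coordinates, dtype=float)
        boxes = np.asarray(boxes, dtype=float)
        times = np.asarray(times, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if coordinates.shape[0] == 0:
            raise ValueError("Trajectory requires at least one frame")
        if coordinates.shape[1] != system.n_atoms:
            raise ValueError(
                f"coordinate atom count {coordinates.shape[1]} != system atom count {system.n_atoms}"
            )
        if boxes.shape != (coordinates.shape[0], 3) or np.any(boxes <= 0):
            raise ValueError("boxes must be (n_frames, 3) positive lengths")
        if times.shape != (coordinates.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.system = system
        self.coordinates = coordinates
        self.boxes = boxes
        self.times = times

    @classmethod
    def from_frames(cls, system: MolecularSystem, frames: Sequence[Frame]) -> "Trajectory":
        return cls(
            system,
            np.stack([f.coordinates for f in frames]),
            np.stack([f.box for f in frames]),
            np.array([f.time for f in frames]),
        )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def dt(self) -> float:
        """Nominal frame spacing in ns (mean spacing; exact when uniform)."""
        if self.n_frames < 2:
            return 0.0
        return float(np.mean(np.diff(self.times)))

    @property
    def duration(self) -> float:
        """Total spanned time in ns, counting one dt per frame."""
        return self.n_frames * self.dt if self.n_frames > 1 else 0.0

    @property
    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def __repr__(self) -> str:
        return (
            f"<Trajectory {self.system.name!r}: {self.n_frames} frames x "
            f"{self.system.n_atoms} atoms, dt={self.dt:g} ns>"
        )


class SelectionRole(str, enum.Enum):
    PROTEIN_PROBE = "protein_probe"
    LIPID_PROBE = "lipid_probe"
    REFERENCE = "reference"


@dataclass
class SelectionGroup:
    """Named atom group defined by (residue, atom_name) predicates.

    ``residue`` in a predicate is either a residue name (str) or a residue
    sequence number (int); a group may list several predicates (e.g. the
    S240 side-chain oxygen *and* backbone amide nitrogen — downstream
    distance code takes the minimum over the whole tracked set).
    """

    name: str
    role: SelectionRole
    predicates: list[tuple[str | int, str]]
    lipid_class: LipidClass | None = None

    def __post_init__(self):
        if isinstance(self.role, str):
            self.role = SelectionRole(self.role)
        if isinstance(self.lipid_class, str):
            self.lipid_class = LipidClass(self.lipid_class)


@dataclass
class SelectionSpec:
    """A set of named selection groups, loadable from YAML/JSON mappings."""

    groups: dict[str, SelectionGroup] = field(default_factory=dict)

    def add(self, group: SelectionGroup) -> None:
        self.groups[group.name] = group

    def by_role(self, role: SelectionRole | str) -> list[SelectionGroup]:
        role = SelectionRole(role)
        return [g for g in self.groups.values() if g.role is role]

    @classmethod
    def from_dict(cls, data: Mapping) -> "SelectionSpec":
        spec = cls()
        for name, g in data.items():
            preds = []
            for p in g["atoms"]:
                residue, atom = p
                if isinstance(residue, str) and residue.isdigit():
                    residue = int(residue)
                preds.append((residue, str(atom)))
            spec.add(
                SelectionGroup(
                    name=name,
                    role=SelectionRole(g["role"]),
                    predicates=preds,
                    lipid_class=LipidClass(g["lipid_class"]) if g.get("lipid_class") else None,
                )
            )
        return spec

    @classmethod
    def from_yaml(cls, path) -> "SelectionSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data["groups"] if "groups" in data else data)

    def to_dict(self) -> dict:
        return {
            "groups": {
                name: {
                    "role": g.role.value,
                    "atoms": [[r, a] for r, a in g.predicates],
                    **({"lipid_class": g.lipid_class.value} if g.lipid_class else {}),
                }
                for name, g in self.groups.items()
            }
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def resolve_selection(
    system: MolecularSystem, spec: SelectionSpec
) -> dict[str, np.ndarray]:
    """Resolve every group of *spec* to sorted atom indices of *system*.

    Each predicate must match at least one atom; otherwise a
    :class:`SelectionError` naming the group and the failing predicate is
    raised.  Resolution is deterministic (ascending atom_index) and
    idempotent.
    """
    out: dict[str, np.ndarray] = {}
    for name, group in spec.groups.items():
        hits: list[np.ndarray] = []
        for residue, atom in group.predicates:
            idx = system.atom_indices(residue, atom)
            if idx.size == 0:
                raise SelectionError(
                    f"selection group {name!r}: predicate (residue={residue!r}, "
                    f"atom={atom!r}) matches no atom of system {system.name!r}"
                )
            hits.append(idx)
        out[name] = np.unique(np.concatenate(hits))
    return out


#: Default headgroup atom names per lipid class, CHARMM36 tokens.  The
#: phosphate phosphorus marks glycerophospholipid headgroups; cholesterol's
#: hydroxyl oxygen is O3; ceramide's headgroup hydroxyl oxygens.  Entirely
#: overridable — these are conventions, not chemistry the code depends on.
DEFAULT_HEADGROUP_ATOMS: dict[LipidClass, tuple[str, ...]] = {
    LipidClass.CHOL: ("O3",),
    LipidClass.PC: ("P",),
    LipidClass.PE: ("P",),
    LipidClass.PS: ("P",),
    LipidClass.PA: ("P",),
    LipidClass.PIP: ("P",),
    LipidClass.CER: ("O3", "O1", "OG"),
}


def headgroup_atom_indices(
    system: MolecularSystem,
    headgroup_atoms: Mapping[LipidClass, tuple[str, ...]] | None = None,
) -> dict[int, np.ndarray]:
    """Map every lipid molecule_id to its headgroup atom indices.

    Raises :class:`SelectionError` for any lipid molecule in which none of
    the configured headgroup atom names is found.
    """
    table = dict(DEFAULT_HEADGROUP_ATOMS)
    if headgroup_atoms:
        table.update(headgroup_atoms)
    out: dict[int, np.ndarray] = {}
    for mid, cls in system.lipid_molecules().items():
        mol_atoms = system.molecule_atoms(mid)
        names = system.atom_names[mol_atoms]
        hit = mol_atoms[np.isin(names, table.get(cls, ()))]
        if hit.size == 0:
            res = system.residue_names[mol_atoms[0]]
            raise SelectionError(
                f"lipid molecule {mid} ({res}, class {cls.value}) has no headgroup "
                f"atom among {table.get(cls, ())}"
            )
        out[mid] = hit
    return out


def leaflet_assign(
    system: MolecularSystem,
    frame: Frame,
    headgroup_selection: Mapping[LipidClass, tuple[str, ...]] | None = None,
) -> dict[int, str]:
    """Assign each lipid molecule to the 'upper' or 'lower' leaflet.

    A lipid is *lower* iff the mean z of its headgroup atoms is below the
    membrane midplane, defined as the mean z of all lipid headgroup atoms in
    this frame.  Assignment is per-frame: lipids may flip between frames.
    """
    hg = headgroup_atom_indices(system, headgroup_selection)
    all_hg = np.concatenate(list(hg.values()))
    midplane = float(np.mean(frame.coordinates[all_hg, 2]))
    out: dict[int, str] = {}
    for mid, idx in hg.items():
        z = float(np.mean(frame.coordinates[idx, 2]))
        out[mid] = "lower" if z < midplane else "upper"
    return out


def composition_from_frame(
    system: MolecularSystem,
    frame: Frame,
    headgroup_selection: Mapping[LipidClass, tuple[str, ...]] | None = None,
) -> "MembraneComposition":
    """Per-leaflet class counts of a system as observed in one frame."""
    assign = leaflet_assign(system, frame, headgroup_selection)
    classes = system.lipid_molecules()
    upper: dict[str, int] = {}
    lower: dict[str, int] = {}
    for mid, leaflet in assign.items():
        d = upper if leaflet == "upper" else lower
        cls = classes[mid].value
        d[cls] = d.get(cls, 0) + 1
    return MembraneComposition(upper=upper, lower=lower)


@dataclass
class MembraneComposition:
    """Per-leaflet lipid counts, keyed by lipid class name."""

    upper: dict[str, int] = field(default_factory=dict)
    lower: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for leaflet in (self.upper, self.lower):
            for cls, n in leaflet.items():
                if n < 0:
                    raise ValueError(f"negative lipid count for {cls}: {n}")

    def total(self, leaflet: str) -> int:
        return sum(self.leaflet(leaflet).values())

    def leaflet(self, leaflet: str) -> dict[str, int]:
        if leaflet == "upper":
            return self.upper
        if leaflet == "lower":
            return self.lower
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")

    def percentages(self, leaflet: str) -> dict[str, int]:
        """Mole percentages per class, rounded to the nearest integer."""
        counts = self.leaflet(leaflet)
        total = self.total(leaflet)
        if total == 0:
            raise ValueError(f"{leaflet} leaflet is empty")
        # round-half-up, the convention of printed composition tables
        return {cls: int(np.floor(100.0 * n / total + 0.5)) for cls, n in counts.items()}
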