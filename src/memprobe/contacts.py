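"""Protein-lipid contact analysis: distances, occupancy, lifetimes, multivalency.

A *contact* is a distance criterion only: a protein probe group (e.g. the
side-chain amine nitrogen of a lysine) is bound to a lipid molecule in a
frame when the minimum distance between the group's tracked atoms and the
lipid's tracked atoms is within the cutoff (default 6 Å, inclusive).  Where
a residue tracks several atoms (e.g. a side-chain oxygen and the backbone
amide nitrogen), the minimum over the whole set is used.

Occupancy of a residue with a lipid *class* uses union semantics: the
residue is occupied in a frame if any molecule of that class is bound.
Interaction lifetimes are maximal runs of bound frames for one
residue-molecule pair, with unbound gaps up to a configurable tolerance
bridged; the transient/stable rule classifies a pair as transient when its
longest continuous interaction is below 10 ns or its total bound time is
below 50 ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    LipidClass,
    SelectionRole,
    SelectionSpec,
    Trajectory,
    resolve_selection,
)
from .geometry import min_image_displacement

__all__ = [
    "DEFAULT_CUTOFF",
    "ContactRecord",
    "LifetimeSet",
    "distance_series",
    "compute_contacts",
    "occupancy",
    "occupancy_per_molecule",
    "lifetimes",
    "classify_interaction",
    "multivalency",
    "MultivalencyResult",
]

#: contact cutoff in Å; the boundary is inclusive ("within <= 6 Å")
DEFAULT_CUTOFF = 6.0


def distance_series(
    traj: Trajectory,
    protein_atoms: Sequence[int],
    lipid_atoms: Sequence[int],
    use_min_image: bool = True,
) -> np.ndarray:
    """Per-frame minimum distance (Å) between two atom sets.

    For every frame, the minimum over all (protein atom, lipid atom) pairs
    of the minimum-image distance.  Vectorised over frames.
    """
    pa = np.asarray(protein_atoms, dtype=int)
    la = np.asarray(lipid_atoms, dtype=int)
    if pa.size == 0 or la.size == 0:
        raise ValueError("both atom sets must be non-empty")
    a = traj.coordinates[:, pa, :]  # (F, na, 3)
    b = traj.coordinates[:, la, :]  # (F, nb, 3)
    delta = a[:, :, None, :] - b[:, None, :, :]  # (F, na, nb, 3)
    if use_min_image:
        delta = min_image_displacement(delta, traj.boxes[:, None, None, :])
    d = np.sqrt(np.sum(delta * delta, axis=-1))
    return d.reshape(traj.n_frames, -1).min(axis=1)


@dataclass
class ContactRecord:
    """Distance/bound time series for one protein group vs one lipid molecule."""

    protein_group: str
    lipid_class: LipidClass
    lipid_molecule_id: int
    distance_series: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    dt: float = 1.0  # ns per frame

    def __post_init__(self):
        self.distance_series = np.asarray(self.distance_series, dtype=float)
        if isinstance(self.lipid_class, str):
            self.lipid_class = LipidClass(self.lipid_class)

    @property
    def bound_series(self) -> np.ndarray:
        return self.distance_series <= self.cutoff

    @property
    def n_frames(self) -> int:
        return len(self.distance_series)


def compute_contacts(
    traj: Trajectory,
    spec: SelectionSpec,
    cutoff: float = DEFAULT_CUTOFF,
    use_min_image: bool = True,
) -> list[ContactRecord]:
    """Build contact records for every protein probe group x lipid molecule.

    Protein probe groups come from *spec* (role ``protein_probe``); each
    lipid probe group (role ``lipid_probe``) must carry a ``lipid_class``
    and defines the tracked atoms of every molecule of that class.
    """
    resolved = resolve_selection(traj.system, spec)
    lipid_groups = spec.by_role(SelectionRole.LIPID_PROBE)
    protein_groups = spec.by_role(SelectionRole.PROTEIN_PROBE)
    if not protein_groups or not lipid_groups:
        return []

    mol_classes = traj.system.lipid_molecules()
    records: list[ContactRecord] = []
    for lg in lipid_groups:
        if lg.lipid_class is None:
            raise ValueError(f"lipid probe group {lg.name!r} lacks a lipid_class")
        tracked = resolved[lg.name]
        tracked_mids = traj.system.molecule_ids[tracked]
        for mid in sorted(m for m, c in mol_classes.items() if c is lg.lipid_class):
            mol_tracked = tracked[tracked_mids == mid]
            if mol_tracked.size == 0:
                continue
            for pg in protein_groups:
                d = distance_series(traj, resolved[pg.name], mol_tracked, use_min_image)
                records.append(
                    ContactRecord(pg.name, lg.lipid_class, int(mid), d, cutoff, traj.dt)
                )
    return records


def _check_common_length(records: Sequence[ContactRecord]) -> int:
    lengths = {r.n_frames for r in records}
    if len(lengths) > 1:
        raise ValueError(f"contact records differ in trajectory length: {sorted(lengths)}")
    return lengths.pop() if lengths else 0


def occupancy(
    records: Sequence[ContactRecord], replicate_id: int | str | None = None
) -> pd.DataFrame:
    """Class-level occupancy table: one row per (protein_group, lipid_class).

    ``occupancy_fraction`` is the fraction of frames in which *any* molecule
    of the class is bound to the group (union semantics).
    """
    n = _check_common_length(records)
    rows = []
    by_pair: dict[tuple[str, str], np.ndarray] = {}
    for r in records:
        key = (r.protein_group, r.lipid_class.value)
        acc = by_pair.setdefault(key, np.zeros(n, dtype=bool))
        acc |= r.bound_series
    for (group, cls), bound in sorted(by_pair.items()):
        rows.append(
            {
                "protein_group": group,
                "lipid_class": cls,
                "occupancy_fraction": float(bound.mean()) if n else 0.0,
                "replicate_id": replicate_id,
            }
        )
    return pd.DataFrame(rows, columns=["protein_group", "lipid_class", "occupancy_fraction", "replicate_id"])


def occupancy_per_molecule(
    records: Sequence[ContactRecord], replicate_id: int | str | None = None
) -> pd.DataFrame:
    """Per-molecule occupancy: one row per (protein_group, lipid molecule)."""
    _check_common_length(records)
    rows = [
        {
            "protein_group": r.protein_group,
            "lipid_class": r.lipid_class.value,
            "lipid_molecule_id": r.lipid_molecule_id,
            "occupancy_fraction": float(r.bound_series.mean()),
            "replicate_id": replicate_id,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_group", "lipid_class", "lipid_molecule_id", "occupancy_fraction", "replicate_id"],
    )


@dataclass
class LifetimeSet:
    """Durations (ns) of the bound segments of one contact pair."""

    segments: list[float] = field(default_factory=list)

    @property
    def total_bound(self) -> float:
        return float(sum(self.segments))

    @property
    def max_continuous(self) -> float:
        return float(max(self.segments)) if self.segments else 0.0


def lifetimes(
    record: ContactRecord | np.ndarray,
    gap_tolerance_frames: int = 0,
    dt: float | None = None,
) -> LifetimeSet:
    """Segment a bound series into interaction lifetimes.

    Maximal runs of bound frames become segments; unbound gaps of at most
    ``gap_tolerance_frames`` frames are bridged and their frames count
    toward the segment duration.  Duration = frames x dt.
    """
    if gap_tolerance_frames < 0:
        raise ValueError("gap_tolerance_frames must be >= 0")
    if isinstance(record, ContactRecord):
        bound = record.bound_series
        dt = record.dt if dt is None else dt
    else:
        bound = np.asarray(record, dtype=bool)
        if dt is None:
            raise ValueError("dt is required when passing a raw bound series")
    idx = np.nonzero(bound)[0]
    if idx.size == 0:
        return LifetimeSet([])
    breaks = np.nonzero(np.diff(idx) > gap_tolerance_frames + 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    segments = [(int(idx[e]) - int(idx[s]) + 1) * dt for s, e in zip(starts, ends)]
    return LifetimeSet(segments)


def classify_interaction(
    ls: LifetimeSet,
    continuous_threshold_ns: float = 10.0,
    total_threshold_ns: float = 50.0,
) -> str:
    """Transient/stable rule for one contact pair.

    *Transient* iff the longest continuous interaction is below the
    continuous threshold (default 10 ns) OR the total interaction time is
    below the total threshold (default 50 ns); *stable* otherwise.
    """
    if ls.max_continuous < continuous_threshold_ns or ls.total_bound < total_threshold_ns:
        return "transient"
    return "stable"


@dataclass
class MultivalencyResult:
    """Per-frame engagement counts in both directions, plus summaries.

    ``lipid_group_counts[mol_id][f]``: number of protein groups bound to
    that lipid molecule in frame f.  ``group_lipid_counts[group][f]``:
    number of lipid molecules bound to that group.  A frame is multivalent
    when either count reaches 2 anywhere.
    """

    lipid_group_counts: dict[int, np.ndarray]
    group_lipid_counts: dict[str, np.ndarray]
    multivalent_frames: np.ndarray
    any_bound_frames: np.ndarray

    @property
    def multivalent_fraction_of_frames(self) -> float:
        return float(self.multivalent_frames.mean()) if self.multivalent_frames.size else 0.0

    @property
    def multivalent_fraction_of_bound_frames(self) -> float:
        nb = int(self.any_bound_frames.sum())
        if nb == 0:
            return 0.0
        return float(self.multivalent_frames[self.any_bound_frames].sum() / nb)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "lipid_molecule", "key": str(mid), "max_count": int(c.max()),
             "frames_multivalent": int((c >= 2).sum())}
            for mid, c in sorted(self.lipid_group_counts.items())
        ] + [
            {"kind": "protein_group", "key": g, "max_count": int(c.max()),
             "frames_multivalent": int((c >= 2).sum())}
            for g, c in sorted(self.group_lipid_counts.items())
        ]
        return pd.DataFrame(rows, columns=["kind", "key", "max_count", "frames_multivalent"])


def multivalency(records: Sequence[ContactRecord]) -> MultivalencyResult:
    """Count simultaneous engagements across a set of contact records."""
    n = _check_common_length(records)
    lipid_counts: dict[int, np.ndarray] = {}
    group_counts: dict[str, np.ndarray] = {}
    any_bound = np.zeros(n, dtype=bool)
    for r in records:
        b = r.bound_series
        any_bound |= b
        lc = lipid_counts.setdefault(r.lipid_molecule_id, np.zeros(n, dtype=int))
        lc += b
        gc = group_counts.setdefault(r.protein_group, np.zeros(n, dtype=int))
        gc += b
    multi = np.zeros(n, dtype=bool)
    for c in lipid_counts.values():
        multi |= c >= 2
    for c in group_counts.values():
        multi |= c >= 2
    return MultivalencyResult(lipid_counts, group_counts, multi, any_bound)
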