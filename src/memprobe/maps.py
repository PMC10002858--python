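"""Lateral (x, y) localization-frequency maps of tracked lipid atoms.

Maps count, per frame, the lateral position of every tracked lipid atom
whose parent lipid currently sits in the chosen leaflet (default: the
protein-containing lower leaflet).  Positions are wrapped into the primary
box image each frame; optionally the map is recentered on the protein
centroid so that lateral protein drift does not smear the density.  Raw
counts are kept; frequency normalisation divides by the total count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LipidClass, Trajectory, headgroup_atom_indices
from .geometry import min_image_displacement

__all__ = ["HeatmapGrid", "lipid_heatmap", "mean_protein_positions"]


@dataclass
class HeatmapGrid:
    """2D lateral histogram with edges (Å) and optional protein overlay points."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    normalization: str = "counts"  # 'counts' | 'frequency'
    overlay_points: list[tuple[str, float, float]] = field(default_factory=list)

    def to_frequency(self) -> "HeatmapGrid":
        total = self.counts.sum()
        freq = self.counts / total if total > 0 else self.counts.astype(float)
        return HeatmapGrid(freq, self.x_edges, self.y_edges, "frequency", list(self.overlay_points))

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "x_edges": self.x_edges,
            "y_edges": self.y_edges,
            "normalization": self.normalization,
            "overlay_points": [[str(l), float(x), float(y)] for l, x, y in self.overlay_points],
            "units": {"x": "angstrom", "y": "angstrom"},
        }


def _lateral_positions(traj, atom_idx, recenter, center_atoms):
    """Wrapped per-frame lateral positions of the given atoms.

    Without recentering: coordinates wrapped into [0, L) per axis.  With
    recentering: minimum-image displacement from the per-frame centroid of
    ``center_atoms``, in [-L/2, L/2).
    """
    xy = traj.coordinates[:, atom_idx, :2]  # (F, n, 2)
    box = traj.boxes[:, None, :2]
    if recenter:
        if center_atoms is None or len(center_atoms) == 0:
            raise ValueError("recentering requires protein (center) atoms")
        center = traj.coordinates[:, np.asarray(center_atoms, dtype=int), :2].mean(axis=1)
        return min_image_displacement3(xy - center[:, None, :], box)
    return np.mod(xy, box)


def min_image_displacement3(delta, box):
    # thin alias keeping the 2D case readable
    return min_image_displacement(
        np.concatenate([delta, np.zeros_like(delta[..., :1])], axis=-1),
        np.concatenate([box, np.ones_like(box[..., :1])], axis=-1),
    )[..., :2]


def _default_edges(traj, recenter):
    lx, ly = traj.boxes[:, 0].mean(), traj.boxes[:, 1].mean()
    if recenter:
        x_edges = np.arange(-np.ceil(lx / 2), np.ceil(lx / 2) + 1.0, 1.0)
        y_edges = np.arange(-np.ceil(ly / 2), np.ceil(ly / 2) + 1.0, 1.0)
    else:
        x_edges = np.arange(0.0, np.ceil(lx) + 1.0, 1.0)
        y_edges = np.arange(0.0, np.ceil(ly) + 1.0, 1.0)
    return x_edges, y_edges


def lipid_heatmap(
    traj: Trajectory,
    tracked_atoms: Sequence[int],
    leaflet: str = "lower",
    x_edges: np.ndarray | None = None,
    y_edges: np.ndarray | None = None,
    recenter: bool = False,
    protein_atoms: Sequence[int] | None = None,
    headgroups: Mapping[LipidClass, tuple[str, ...]] | None = None,
) -> HeatmapGrid:
    """Bin tracked lipid atoms' lateral positions over all frames.

    Every tracked atom contributes one count per frame in which its parent
    lipid is assigned to *leaflet* (per-frame headgroup-z rule).  Positions
    outside the grid are clamped into the edge bins, so the total count
    equals the tracked-atom x in-leaflet frame tally exactly.
    """
    tracked_atoms = np.asarray(tracked_atoms, dtype=int)
    if x_edges is None or y_edges is None:
        xe, ye = _default_edges(traj, recenter)
        x_edges = xe if x_edges is None else np.asarray(x_edges, float)
        y_edges = ye if y_edges is None else np.asarray(y_edges, float)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)

    # per-frame leaflet membership of each tracked atom's parent molecule
    hg_map = headgroup_atom_indices(traj.system, headgroups)
    mids = np.array(sorted(hg_map))
    hg_atoms = np.concatenate([hg_map[m] for m in mids])
    owner = np.concatenate([np.full(len(hg_map[m]), m) for m in mids])
    hg_z = traj.coordinates[:, hg_atoms, 2]
    midplane = hg_z.mean(axis=1)
    mol_z = np.stack([hg_z[:, owner == m].mean(axis=1) for m in mids], axis=1)  # (F, n_mol)
    lower = mol_z < midplane[:, None]
    mid_of_atom = traj.system.molecule_ids[tracked_atoms]
    col = np.searchsorted(mids, mid_of_atom)
    in_leaflet = lower[:, col] if leaflet == "lower" else ~lower[:, col]  # (F, n_tracked)

    xy = _lateral_positions(traj, tracked_atoms, recenter, protein_atoms)
    xs = xy[..., 0][in_leaflet]
    ys = xy[..., 1][in_leaflet]
    eps = 1e-9
    xs = np.clip(xs, x_edges[0], x_edges[-1] - eps)
    ys = np.clip(ys, y_edges[0], y_edges[-1] - eps)
    counts, _, _ = np.histogram2d(xs, ys, bins=[x_edges, y_edges])

    overlay = []
    if protein_atoms is not None and len(protein_atoms):
        mp = mean_protein_positions(traj, protein_atoms, recenter=recenter,
                                    center_atoms=protein_atoms)
        overlay = [
            (str(int(r.residue_seq)), float(r.mean_x), float(r.mean_y))
            for r in mp.itertuples()
        ]
    return HeatmapGrid(counts.astype(int), x_edges, y_edges, "counts", overlay)


def mean_protein_positions(
    traj: Trajectory,
    ca_atoms: Sequence[int],
    recenter: bool = False,
    center_atoms: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-residue mean lateral position of the given (Cα) atoms.

    Uses the same wrapping/recentering convention as :func:`lipid_heatmap`
    so overlay points land in the same coordinate frame as the lipid map.
    """
    ca_atoms = np.asarray(ca_atoms, dtype=int)
    if ca_atoms.size == 0:
        raise ValueError("no atoms given")
    xy = _lateral_positions(traj, ca_atoms, recenter, center_atoms if center_atoms is not None else ca_atoms)
    mean_xy = xy.mean(axis=0)  # (n, 2)
    res = traj.system.residue_seqs[ca_atoms]
    return pd.DataFrame(
        {"residue_seq": res, "mean_x": mean_xy[:, 0], "mean_y": mean_xy[:, 1]}
    )
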