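"""Synthetic membrane-protein trajectories with known ground truth.

The generator emulates, at desk scale, the statistical structure the
analysis layer is built to measure: a two-leaflet bilayer of seven lipid
classes with lateral diffusion, a rigid pseudo-Cα protein scaffold placed
at a planted insertion depth and tilt with per-frame noise, and planted
two-state (bound/unbound) lipid-binding episodes with prescribed stationary
occupancy and mean lifetime.  Each lipid is one headgroup pseudo-atom and
the protein is one Cα per residue plus the tracked side-chain atoms, named
so the default selections resolve — the analysis only ever consumes tracked
atom positions, so full-atom realism buys nothing for verification.

Contact kinetics are a discrete-time two-state Markov chain with per-frame
switch probabilities ``q_off = dt / mean_lifetime`` and
``q_on = q_off * p / (1 - p)``, whose stationary bound probability is
exactly ``p`` and whose bound-run lengths are geometric with mean
``mean_lifetime / dt`` frames.  While bound, the designated lipid's
headgroup is placed uniformly in a 2-5.5 Å shell around the probe atom
(inside the 6 Å cutoff); while unbound it follows its random walk but is
kept beyond 8 Å of the probe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import (
    AtomRecord,
    LipidClass,
    MembraneComposition,
    MolecularSystem,
    SegmentKind,
    SelectionGroup,
    SelectionRole,
    SelectionSpec,
    Trajectory,
)

__all__ = [
    "PHORBOL_COMPOSITION",
    "BRYOSTATIN_COMPOSITION",
    "ContactPlan",
    "BridgePlan",
    "SyntheticParams",
    "GroundTruth",
    "build_composition",
    "build_system",
    "synthetic_selections",
    "simulate_trajectory",
    "worked_fixtures",
]

#: Per-leaflet lipid counts of the phorbol-complex membrane (upper/lower).
PHORBOL_COMPOSITION = MembraneComposition(
    upper={"CHOL": 14, "PC": 13, "PE": 18, "PS": 8, "PA": 2, "PIP": 4, "CER": 7},
    lower={"CHOL": 13, "PC": 12, "PE": 17, "PS": 7, "PA": 1, "PIP": 3, "CER": 6},
)

#: Per-leaflet lipid counts of the bryostatin/Merle27-complex membranes.
BRYOSTATIN_COMPOSITION = MembraneComposition(
    upper={"CHOL": 16, "PC": 15, "PE": 19, "PS": 8, "PA": 3, "PIP": 5, "CER": 7},
    lower={"CHOL": 16, "PC": 13, "PE": 18, "PS": 8, "PA": 2, "PIP": 4, "CER": 6},
)

# residue/atom tokens for the single-pseudo-atom lipids
_LIPID_TOKENS: dict[str, tuple[str, str]] = {
    "CHOL": ("CHL1", "O3"),
    "PC": ("POPC", "P"),
    "PE": ("POPE", "P"),
    "PS": ("SOPS", "P"),
    "PA": ("POPA", "P"),
    "PIP": ("SAPI", "P"),  # 4-char token (PDB resName field limit)
    "CER": ("CER", "O3"),
}

# tracked side-chain/backbone atoms of the probe residues (construct numbering)
_PROBE_ATOMS: dict[int, tuple[str, ...]] = {
    240: ("OG", "N"),   # serine side-chain oxygen or backbone amide nitrogen
    241: ("O", "N"),    # proline backbone carbonyl oxygen or amide nitrogen
    250: ("N",),        # leucine backbone amide nitrogen
    252: ("NE1",),      # tryptophan indole nitrogen
    256: ("NZ",),
    260: ("NZ",),
    271: ("NZ",),
    275: ("NZ",),
}

_RES3 = {
    233: "PRO", 239: "MET", 240: "SER", 241: "PRO", 246: "HIS", 250: "LEU",
    252: "TRP", 253: "GLY", 255: "VAL", 256: "LYS", 260: "LYS", 263: "ASP",
    271: "LYS", 275: "LYS", 276: "VAL",
}

_FIRST_RES, _LAST_RES = 230, 280
_UPPER_SET = (239, 241, 253, 255)
_LOWER_SET = (233, 246, 263, 276)
_AXIS_HALF = 15.0  # body-frame half length of the scaffold, Å


def build_composition(
    fractions: Mapping[str, float], leaflet_totals: tuple[int, int]
) -> MembraneComposition:
    """Integer per-leaflet counts from mole fractions by largest-remainder rounding.

    Each leaflet's counts sum exactly to its total; ties in the fractional
    remainders are broken by the order of the classes in *fractions*.
    """
    total_frac = sum(fractions.values())
    if abs(total_frac - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {total_frac}")
    n_upper, n_lower = leaflet_totals
    if n_upper <= 0 or n_lower <= 0:
        raise ValueError("leaflet totals must be positive")

    def one_leaflet(total: int) -> dict[str, int]:
        ideal = {c: p * total for c, p in fractions.items()}
        counts = {c: int(np.floor(v)) for c, v in ideal.items()}
        short = total - sum(counts.values())
        order = sorted(
            fractions, key=lambda c: (-(ideal[c] - counts[c]), list(fractions).index(c))
        )
        for c in order[:short]:
            counts[c] += 1
        return counts

    return MembraneComposition(upper=one_leaflet(n_upper), lower=one_leaflet(n_lower))


@dataclass
class ContactPlan:
    """A planted binding pair: one protein group vs one designated lipid."""

    protein_group: str
    lipid_class: str
    occupancy: float       # stationary bound probability p, exclusive (0, 1)
    mean_lifetime_ns: float

    def __post_init__(self):
        if not 0.0 < self.occupancy < 1.0:
            raise ValueError("planted occupancy must be in (0, 1) exclusive")


@dataclass
class BridgePlan:
    """A planted bivalent episode: one lipid engaging two protein groups at once."""

    protein_groups: tuple[str, str]
    lipid_class: str
    rate: float            # stationary fraction of frames bridged
    mean_lifetime_ns: float

    def __post_init__(self):
        if not 0.0 < self.rate < 1.0:
            raise ValueError("bridge rate must be in (0, 1) exclusive")


@dataclass
class SyntheticParams:
    """Everything the generator needs; defaults are the study conditions."""

    composition: MembraneComposition = field(default_factory=lambda: PHORBOL_COMPOSITION)
    box: tuple[float, float, float] = (60.0, 60.0, 90.0)
    n_frames: int = 1000
    dt: float = 0.1                   # ns per frame
    lipid_step_sigma: float = 0.4     # lateral random-walk step, Å/frame/axis
    z_jitter_sigma: float = 0.5       # headgroup z noise around the leaflet plane, Å
    half_thickness: float = 20.0      # headgroup planes at ±half_thickness, Å
    depth_mean: float = 8.0           # planted insertion depth, Å
    depth_sigma: float = 1.0
    tilt_mean: float = 48.0           # planted tilt from the membrane normal, deg
    tilt_sigma: float = 5.0
    protein_drift_per_frame: tuple[float, float] = (0.0, 0.0)  # lateral drift, Å
    contact_plan: list[ContactPlan] = field(default_factory=list)
    bridge_plan: list[BridgePlan] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for p in self.contact_plan:
            if p.mean_lifetime_ns <= self.dt:
                raise ValueError("mean_lifetime must exceed dt")


@dataclass
class GroundTruth:
    """What was planted, in recomputable form."""

    contact_states: dict[str, np.ndarray]        # key 'group|class|mol_id' -> bool (F,)
    realized_occupancy: dict[str, float]
    realized_lifetimes_ns: dict[str, list[float]]
    bridge_states: dict[str, np.ndarray]
    depth_series: np.ndarray
    tilt_series: np.ndarray
    leaflet_of_molecule: dict[int, str]
    contact_lipid_ids: dict[str, int]

    def to_json(self, path: str) -> None:
        payload = {
            "realized_occupancy": self.realized_occupancy,
            "realized_lifetimes_ns": self.realized_lifetimes_ns,
            "contact_lipid_ids": self.contact_lipid_ids,
            "depth_series": self.depth_series.tolist(),
            "tilt_series": self.tilt_series.tolist(),
            "leaflet_of_molecule": {str(k): v for k, v in self.leaflet_of_molecule.items()},
            "contact_states": {k: v.astype(int).tolist() for k, v in self.contact_states.items()},
            "bridge_states": {k: v.astype(int).tolist() for k, v in self.bridge_states.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _body_frame() -> dict[int, dict[str, np.ndarray]]:
    """Body-frame coordinates of every residue's atoms (protein long axis = z)."""
    corners = [(2.0, 2.0), (-2.0, 2.0), (2.0, -2.0), (-2.0, -2.0)]
    coords: dict[int, dict[str, np.ndarray]] = {}
    for r in range(_FIRST_RES, _LAST_RES + 1):
        if r in _UPPER_SET:
            x, y = corners[_UPPER_SET.index(r)]
            z = _AXIS_HALF
        elif r in _LOWER_SET:
            x, y = corners[_LOWER_SET.index(r)]
            z = -_AXIS_HALF
        else:
            ang = 0.7 * r
            x, y = 3.0 * np.cos(ang), 3.0 * np.sin(ang)
            z = (r - (_FIRST_RES + _LAST_RES) / 2) * (2 * _AXIS_HALF / (_LAST_RES - _FIRST_RES))
        ca = np.array([x, y, z])
        atoms = {"CA": ca}
        lateral = ca[:2]
        u = lateral / np.linalg.norm(lateral) if np.linalg.norm(lateral) > 0 else np.array([1.0, 0.0])
        for k, name in enumerate(_PROBE_ATOMS.get(r, ())):
            atoms[name] = ca + np.array([u[0] * 1.5, u[1] * 1.5, 0.4 * k])
        coords[r] = atoms
    return coords


def build_system(params: SyntheticParams) -> MolecularSystem:
    """Static atom table: protein scaffold, then upper- then lower-leaflet lipids."""
    records: list[AtomRecord] = []
    body = _body_frame()
    mol = 0
    idx = 0
    for r in range(_FIRST_RES, _LAST_RES + 1):
        resname = _RES3.get(r, "ALA")
        for name in body[r]:
            records.append(
                AtomRecord(idx, name, resname, r, SegmentKind.PROTEIN, mol)
            )
            idx += 1
        mol += 1
    seq = 1
    for leaflet in ("upper", "lower"):
        for cls_name, count in params.composition.leaflet(leaflet).items():
            resname, atom = _LIPID_TOKENS[cls_name]
            for _ in range(count):
                records.append(
                    AtomRecord(
                        idx, atom, resname, seq, SegmentKind.LIPID, mol,
                        lipid_class=LipidClass(cls_name),
                    )
                )
                idx += 1
                mol += 1
                seq += 1
    return MolecularSystem(records, name="synthetic-bilayer")


def synthetic_selections() -> SelectionSpec:
    """Selections matching the synthetic system's atom naming."""
    spec = SelectionSpec()
    for r in (256, 260, 271, 275):
        spec.add(SelectionGroup(f"K{r}", SelectionRole.PROTEIN_PROBE, [(r, "NZ")]))
    spec.add(SelectionGroup("L250", SelectionRole.PROTEIN_PROBE, [(250, "N")]))
    spec.add(SelectionGroup("W252", SelectionRole.PROTEIN_PROBE, [(252, "NE1")]))
    spec.add(SelectionGroup("S240", SelectionRole.PROTEIN_PROBE, [(240, "OG"), (240, "N")]))
    spec.add(SelectionGroup("P241", SelectionRole.PROTEIN_PROBE, [(241, "O"), (241, "N")]))
    for cls_name, (resname, atom) in _LIPID_TOKENS.items():
        spec.add(
            SelectionGroup(
                cls_name, SelectionRole.LIPID_PROBE, [(resname, atom)],
                lipid_class=LipidClass(cls_name),
            )
        )
    spec.add(SelectionGroup("G253_CA", SelectionRole.REFERENCE, [(253, "CA")]))
    return spec


def _rotation_y(theta_deg: np.ndarray) -> np.ndarray:
    """(F, 3, 3) rotations about y by theta (tilts +z toward +x)."""
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros((len(t), 3, 3))
    out[:, 0, 0] = c
    out[:, 0, 2] = s
    out[:, 1, 1] = 1.0
    out[:, 2, 0] = -s
    out[:, 2, 2] = c
    return out


def _two_state_chain(rng, n, p, q_off):
    """Simulate a stationary two-state chain; returns bool array (True = bound)."""
    q_on = q_off * p / (1.0 - p)
    if q_on >= 1.0 or q_off >= 1.0:
        raise ValueError("switch probabilities exceed 1; increase mean_lifetime or dt")
    state = np.empty(n, dtype=bool)
    u = rng.random(n)
    state[0] = u[0] < p
    for i in range(1, n):
        state[i] = (u[i] >= q_off) if state[i - 1] else (u[i] < q_on)
    return state


def _shell_offsets(rng, n, r_min=2.0, r_max=5.5):
    """n points uniform in direction, radius uniform in [r_min, r_max]."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(r_min, r_max, size=n)
    return v * r[:, None]


def simulate_trajectory(params: SyntheticParams) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory plus its ground truth.  Deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    system = build_system(params)
    n, box = params.n_frames, np.asarray(params.box, dtype=float)
    n_lipids_total = params.composition.total("upper") + params.composition.total("lower")
    min_area = 30.0 * n_lipids_total / 2  # ~30 Å² hard floor per lipid
    if box[0] * box[1] < min_area:
        raise ValueError(
            f"box {box[0]}x{box[1]} Å too small for {n_lipids_total} lipids"
        )

    body = _body_frame()
    # --- protein placement -------------------------------------------------
    tilt = np.clip(rng.normal(params.tilt_mean, params.tilt_sigma, n), 0.0, 90.0)
    depth = rng.normal(params.depth_mean, params.depth_sigma, n)
    rot = _rotation_y(tilt)  # (F, 3, 3)

    # --- lipids -------------------------------------------------------------
    lipid_atoms = np.nonzero(system.segment_kinds == SegmentKind.LIPID.value)[0]
    n_lip = len(lipid_atoms)
    leaflet_of_mol: dict[int, str] = {}
    plane = np.empty(n_lip)
    pos0 = rng.uniform(0.0, 1.0, size=(n_lip, 2)) * box[:2]
    i = 0
    for leaflet, zsign in (("upper", +1.0), ("lower", -1.0)):
        for cls_name, count in params.composition.leaflet(leaflet).items():
            for _ in range(count):
                mid = int(system.molecule_ids[lipid_atoms[i]])
                leaflet_of_mol[mid] = leaflet
                plane[i] = zsign * params.half_thickness
                i += 1
    steps = rng.normal(0.0, params.lipid_step_sigma, size=(n, n_lip, 2))
    steps[0] = 0.0
    xy = np.mod(pos0[None] + np.cumsum(steps, axis=0), box[:2])
    z = plane[None, :] + rng.normal(0.0, params.z_jitter_sigma, size=(n, n_lip))
    lipid_xyz = np.concatenate([xy, z[..., None]], axis=-1)  # (F, n_lip, 3)

    # --- realized PS phosphate plane of the lower leaflet (pre-contact) -----
    lower_ps = np.array(
        [
            j
            for j, a in enumerate(lipid_atoms)
            if system.lipid_classes[a] == "PS"
            and leaflet_of_mol[int(system.molecule_ids[a])] == "lower"
        ]
    )
    ps_plane_z = lipid_xyz[:, lower_ps, 2].mean(axis=1)

    # --- assemble protein world coordinates ---------------------------------
    g253_body = body[253]["CA"]
    drift = np.asarray(params.protein_drift_per_frame, dtype=float)
    center_xy = box[:2] / 2 + drift * np.arange(n)[:, None]
    z_anchor = ps_plane_z + depth - (rot @ g253_body)[:, 2]

    protein_atoms = np.nonzero(system.segment_kinds == SegmentKind.PROTEIN.value)[0]
    body_mat = np.stack(
        [body[system.residue_seqs[a]][system.atom_names[a]] for a in protein_atoms]
    )  # (n_prot, 3)
    prot_xyz = np.einsum("fij,aj->fai", rot, body_mat)
    prot_xyz[..., 0] += center_xy[:, None, 0]
    prot_xyz[..., 1] += center_xy[:, None, 1]
    prot_xyz[..., 2] += z_anchor[:, None]

    # probe atom world positions by group name
    sel = synthetic_selections()
    probe_pos: dict[str, np.ndarray] = {}
    name_to_row = {
        (int(system.residue_seqs[a]), system.atom_names[a]): k
        for k, a in enumerate(protein_atoms)
    }
    for g in sel.by_role(SelectionRole.PROTEIN_PROBE):
        r0, a0 = g.predicates[0]
        probe_pos[g.name] = prot_xyz[:, name_to_row[(int(r0), a0)], :]

    # --- planted contacts ----------------------------------------------------
    lipid_row_of_mol = {
        int(system.molecule_ids[a]): j for j, a in enumerate(lipid_atoms)
    }
    available = {
        cls: [
            m for m, lf in leaflet_of_mol.items()
            if lf == "lower" and system.lipid_classes[lipid_atoms[lipid_row_of_mol[m]]] == cls
        ]
        for cls in {p.lipid_class for p in params.contact_plan}
        | {b.lipid_class for b in params.bridge_plan}
    }
    def _wrap_xy(pts: np.ndarray) -> np.ndarray:
        # the bilayer is centred at z = 0: wrap laterally only, keep z signed
        pts = pts.copy()
        pts[..., :2] = np.mod(pts[..., :2], box[:2])
        return pts

    contact_states: dict[str, np.ndarray] = {}
    realized_occ: dict[str, float] = {}
    realized_lt: dict[str, list[float]] = {}
    bridge_states: dict[str, np.ndarray] = {}
    contact_ids: dict[str, int] = {}

    def _take_lipid(cls: str) -> int:
        pool = available.get(cls, [])
        if not pool:
            raise ValueError(f"no unassigned lower-leaflet lipid of class {cls} left")
        return pool.pop(0)

    def _keep_away(row: int, anchor: np.ndarray, state: np.ndarray, radius: float):
        """Push lipid `row` to >= radius Å from the anchor wherever unbound.

        The push is radial from the anchor, so a single anchor point (the
        probe, or the midpoint of a probe pair with an enlarged radius)
        guarantees clearance from everything within the anchor's vicinity.
        """
        d = lipid_xyz[:, row, :] - anchor
        d -= box * np.round(d / box)
        dist = np.linalg.norm(d, axis=1)
        viol = (~state) & (dist < radius - 0.5)
        if np.any(viol):
            unit = d[viol]
            zero = np.linalg.norm(unit, axis=1) == 0
            unit[zero] = [1.0, 0.0, 0.0]
            unit /= np.linalg.norm(unit, axis=1, keepdims=True)
            lipid_xyz[viol, row, :] = _wrap_xy(anchor[viol] + unit * radius)

    for plan in params.contact_plan:
        mol = _take_lipid(plan.lipid_class)
        row = lipid_row_of_mol[mol]
        q_off = params.dt / plan.mean_lifetime_ns
        state = _two_state_chain(rng, n, plan.occupancy, q_off)
        anchor = probe_pos[plan.protein_group]
        lipid_xyz[state, row, :] = _wrap_xy(
            anchor[state] + _shell_offsets(rng, int(state.sum()))
        )
        _keep_away(row, anchor, state, radius=9.0)
        key = f"{plan.protein_group}|{plan.lipid_class}|{mol}"
        contact_states[key] = state
        realized_occ[key] = float(state.mean())
        realized_lt[key] = _run_lengths_ns(state, params.dt)
        contact_ids[key] = mol

    for plan in params.bridge_plan:
        mol = _take_lipid(plan.lipid_class)
        row = lipid_row_of_mol[mol]
        q_off = params.dt / plan.mean_lifetime_ns
        state = _two_state_chain(rng, n, plan.rate, q_off)
        a = probe_pos[plan.protein_groups[0]]
        b = probe_pos[plan.protein_groups[1]]
        axis = b - a
        perp = np.cross(axis, np.array([0.0, 0.0, 1.0]))
        bad = np.linalg.norm(perp, axis=1) < 1e-9
        perp[bad] = [1.0, 0.0, 0.0]
        perp /= np.linalg.norm(perp, axis=1, keepdims=True)
        mid = (a + b) / 2 + 2.0 * perp
        lipid_xyz[state, row, :] = _wrap_xy(mid[state])
        # radius 9 Å beyond the pair midpoint clears both probes (few Å apart)
        _keep_away(row, (a + b) / 2, state, radius=9.0 + float(np.linalg.norm(axis, axis=1).max()))
        key = f"{plan.protein_groups[0]}+{plan.protein_groups[1]}|{plan.lipid_class}|{mol}"
        bridge_states[key] = state
        contact_ids[key] = mol

    # --- final assembly ------------------------------------------------------
    coords = np.empty((n, system.n_atoms, 3))
    coords[:, protein_atoms, :] = prot_xyz
    coords[:, lipid_atoms, :] = lipid_xyz
    boxes = np.tile(box, (n, 1))
    times = params.dt * np.arange(n)
    times[0] = 0.0
    traj = Trajectory(system, coords, boxes, times)
    gt = GroundTruth(
        contact_states=contact_states,
        realized_occupancy=realized_occ,
        realized_lifetimes_ns=realized_lt,
        bridge_states=bridge_states,
        depth_series=depth,
        tilt_series=tilt,
        leaflet_of_molecule=leaflet_of_mol,
        contact_lipid_ids=contact_ids,
    )
    return traj, gt


def _run_lengths_ns(state: np.ndarray, dt: float) -> list[float]:
    idx = np.nonzero(state)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [float((idx[e] - idx[s] + 1) * dt) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# hand-written worked fixtures
# ---------------------------------------------------------------------------

_THREE_ATOM_PDB = """\
CRYST1   60.000   60.000   90.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   SER A 240      10.000  11.000  12.000  1.00  0.00           N
ATOM      2  CA  SER A 240      11.200  11.500  12.300  1.00  0.00           C
ATOM      3  OG  SER A 240      12.400  12.000  13.000  1.00  0.00           O
END
"""


def worked_fixtures(out_dir) -> dict[str, str]:
    """Write the tiny hand-built PDB fixtures used in worked examples.

    Returns a name -> path map.  ``occupancy10``: one lysine probe and one
    PS pseudo-lipid at hand-picked distances {5,5,7,5,7,7,5,5,7,7} Å over
    10 frames (occupancy 0.5 at the 6 Å cutoff).  ``bridge``: one PS lipid
    within the cutoff of two lysines at once.  ``empty``: a system whose
    only lipid never comes near the probes.
    """
    import os

    from .io import write_pdb

    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    p = os.path.join(out_dir, "three_atom.pdb")
    with open(p, "w") as fh:
        fh.write(_THREE_ATOM_PDB)
    paths["three_atom"] = p

    def mini_system(lipid=True):
        recs = [
            AtomRecord(0, "CA", "LYS", 271, SegmentKind.PROTEIN, 0),
            AtomRecord(1, "NZ", "LYS", 271, SegmentKind.PROTEIN, 0),
            AtomRecord(2, "CA", "LYS", 275, SegmentKind.PROTEIN, 1),
            AtomRecord(3, "NZ", "LYS", 275, SegmentKind.PROTEIN, 1),
        ]
        if lipid:
            recs.append(
                AtomRecord(4, "P", "SOPS", 301, SegmentKind.LIPID, 2, LipidClass.PS)
            )
        return MolecularSystem(recs, name="fixture")

    box = np.array([60.0, 60.0, 90.0])

    # occupancy10: probe NZ(K271) at origin-ish; PS at planted distances
    dists = [5, 5, 7, 5, 7, 7, 5, 5, 7, 7]
    sysm = mini_system()
    coords = np.zeros((10, 5, 3))
    coords[:, 0] = [10.0, 10.0, 10.0]
    coords[:, 1] = [11.5, 10.0, 10.0]
    coords[:, 2] = [30.0, 30.0, 10.0]
    coords[:, 3] = [31.5, 30.0, 10.0]
    for f, d in enumerate(dists):
        coords[f, 4] = [11.5 + d, 10.0, 10.0]
    traj = Trajectory(sysm, coords, np.tile(box, (10, 1)), np.arange(10.0) + 1.0)
    p = os.path.join(out_dir, "occupancy10.pdb")
    write_pdb(traj, p)
    paths["occupancy10"] = p

    # bridge: PS within 6 Å of both lysine NZ atoms in a single frame
    sysm = mini_system()
    coords = np.zeros((1, 5, 3))
    coords[0, 0] = [10.0, 10.0, 10.0]
    coords[0, 1] = [11.5, 10.0, 10.0]   # NZ K271
    coords[0, 2] = [14.0, 10.0, 10.0]
    coords[0, 3] = [15.5, 10.0, 10.0]   # NZ K275, 4 Å from K271's NZ
    coords[0, 4] = [13.5, 12.0, 10.0]   # PS: ~2.83 Å from both NZ atoms
    traj = Trajectory(sysm, coords, box[None, :], np.array([0.0]))
    p = os.path.join(out_dir, "bridge.pdb")
    write_pdb(traj, p)
    paths["bridge"] = p

    # empty: the lone lipid stays ~40 Å from every probe
    sysm = mini_system()
    coords = np.zeros((5, 5, 3))
    coords[:, 0] = [10.0, 10.0, 10.0]
    coords[:, 1] = [11.5, 10.0, 10.0]
    coords[:, 2] = [14.0, 10.0, 10.0]
    coords[:, 3] = [15.5, 10.0, 10.0]
    coords[:, 4] = [13.0, 30.0, 50.0]
    traj = Trajectory(sysm, coords, np.tile(box, (5, 1)), np.arange(5.0) + 1.0)
    p = os.path.join(out_dir, "empty.pdb")
    write_pdb(traj, p)
    paths["empty"] = p
    return paths


def fixture_selections() -> SelectionSpec:
    """Selections for the worked fixtures (two lysines, PS pseudo-lipid)."""
    spec = SelectionSpec()
    spec.add(SelectionGroup("K271", SelectionRole.PROTEIN_PROBE, [(271, "NZ")]))
    spec.add(SelectionGroup("K275", SelectionRole.PROTEIN_PROBE, [(275, "NZ")]))
    spec.add(
        SelectionGroup("PS", SelectionRole.LIPID_PROBE, [("SOPS", "P")], lipid_class=LipidClass.PS)
    )
    return spec
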