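"""Contacts: distance semantics, occupancy, lifetimes, classification, multivalency."""

import numpy as np
import pytest

from memprobe.contacts import (
    ContactRecord,
    classify_interaction,
    compute_contacts,
    distance_series,
    lifetimes,
    multivalency,
    occupancy,
    occupancy_per_molecule,
)
from memprobe.core import (
    AtomRecord,
    LipidClass,
    MolecularSystem,
    SegmentKind,
    Trajectory,
)
from memprobe.geometry import min_image_distance
from memprobe.io import read_frames, read_structure
from memprobe.synthetic import (
    ContactPlan,
    SyntheticParams,
    simulate_trajectory,
)


def _toy_traj(probe_xyz, lipid_xyz, box=(60.0, 60.0, 90.0)):
    """n-frame trajectory: one probe atom set and one lipid atom set."""
    probe_xyz = np.asarray(probe_xyz, float)
    lipid_xyz = np.asarray(lipid_xyz, float)
    n_frames = probe_xyz.shape[0]
    na, nb = probe_xyz.shape[1], lipid_xyz.shape[1]
    records = [
        AtomRecord(i, f"N{i}", "LYS", 271, SegmentKind.PROTEIN, 0) for i in range(na)
    ] + [
        AtomRecord(na + j, f"O{j}", "SOPS", 301, SegmentKind.LIPID, 1, LipidClass.PS)
        for j in range(nb)
    ]
    sys_ = MolecularSystem(records)
    coords = np.concatenate([probe_xyz, lipid_xyz], axis=1)
    return Trajectory(sys_, coords, np.tile(np.asarray(box, float), (n_frames, 1)),
                      np.arange(n_frames, dtype=float))


class TestDistanceSeries:
    def test_constant_separation(self):
        probe = np.tile([[10.0, 10.0, 10.0]], (10, 1, 1))
        lipid = np.tile([[14.0, 10.0, 10.0]], (10, 1, 1))
        traj = _toy_traj(probe, lipid)
        d = distance_series(traj, [0], [1])
        assert d == pytest.approx(np.full(10, 4.0))

    def test_minimum_over_lipid_atoms(self):
        probe = np.array([[[10.0, 10.0, 10.0]]])
        lipid = np.array([[[15.0, 10.0, 10.0], [19.0, 10.0, 10.0]]])
        traj = _toy_traj(probe, lipid)
        assert distance_series(traj, [0], [1, 2])[0] == pytest.approx(5.0)

    def test_matches_exhaustive_pair_minimum(self, rng):
        probe = rng.uniform(0, 60, size=(20, 3, 3))
        lipid = rng.uniform(0, 60, size=(20, 4, 3))
        traj = _toy_traj(probe, lipid)
        d = distance_series(traj, [0, 1, 2], [3, 4, 5, 6])
        box = traj.boxes[0]
        for f in range(20):
            expected = min(
                min_image_distance(probe[f, i], lipid[f, j], box)
                for i in range(3)
                for j in range(4)
            )
            assert d[f] == pytest.approx(expected, abs=1e-9)

    def test_empty_set_errors(self, small_traj):
        traj, _ = small_traj
        with pytest.raises(ValueError):
            distance_series(traj, [], [0])


def _record(dists, cutoff=6.0, dt=1.0, group="K271", mol=1):
    return ContactRecord(group, LipidClass.PS, mol, np.asarray(dists, float), cutoff, dt)


class TestOccupancy:
    def test_hand_counted_ten_frames(self, fixture_paths, fixture_spec):
        """Planted distances {5,5,7,5,7,7,5,5,7,7} at 6 Å cutoff give 0.5."""
        system = read_structure(fixture_paths["occupancy10"])
        traj = read_frames(fixture_paths["occupancy10"], system, dt=1.0)
        records = compute_contacts(traj, fixture_spec)
        occ = occupancy(records)
        row = occ[(occ.protein_group == "K271") & (occ.lipid_class == "PS")]
        assert float(row.occupancy_fraction.iloc[0]) == pytest.approx(0.5)

    def test_never_bound_is_zero(self):
        occ = occupancy([_record([8, 9, 10])])
        assert float(occ.occupancy_fraction.iloc[0]) == 0.0

    def test_union_semantics_across_molecules(self):
        """Two lipids bound on disjoint 30% + 20% frame sets give 0.5."""
        n = 10
        d1 = np.full(n, 9.0)
        d1[:3] = 4.0
        d2 = np.full(n, 9.0)
        d2[3:5] = 4.0
        occ = occupancy([_record(d1, mol=1), _record(d2, mol=2)])
        assert len(occ) == 1
        assert float(occ.occupancy_fraction.iloc[0]) == pytest.approx(0.5)
        per_mol = occupancy_per_molecule([_record(d1, mol=1), _record(d2, mol=2)])
        assert sorted(per_mol.occupancy_fraction) == [pytest.approx(0.2), pytest.approx(0.3)]

    def test_monotone_in_cutoff(self, rng):
        d = rng.uniform(0, 12, size=200)
        fracs = [
            float(occupancy([_record(d, cutoff=c)]).occupancy_fraction.iloc[0])
            for c in np.linspace(1, 11, 11)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            occupancy([_record([1, 2, 3]), _record([1, 2], mol=2)])


def lifetimes_oracle(bound, gap, dt):
    """Independent enumeration of the bridging rule, frame by frame."""
    segments = []
    start = None
    gap_run = 0
    for i, b in enumerate(bound):
        if b:
            if start is None:
                start = i
            end = i
            gap_run = 0
        elif start is not None:
            gap_run += 1
            if gap_run > gap:
                segments.append((end - start + 1) * dt)
                start, gap_run = None, 0
    if start is not None:
        segments.append((end - start + 1) * dt)
    return segments


class TestLifetimes:
    def test_run_lengths(self):
        ls = lifetimes(np.array([1, 1, 1, 0, 1, 1], bool), 0, dt=2.0)
        assert ls.segments == [6.0, 4.0]
        assert ls.total_bound == 10.0
        assert ls.max_continuous == 6.0

    def test_all_unbound(self):
        ls = lifetimes(np.zeros(5, bool), 0, dt=1.0)
        assert ls.segments == [] and ls.max_continuous == 0.0

    def test_gap_bridging(self):
        ls = lifetimes(np.array([1, 1, 0, 1], bool), 1, dt=2.0)
        assert ls.segments == [8.0]

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            bound = rng.random(60) < 0.4
            gap = int(rng.integers(0, 4))
            ls = lifetimes(bound, gap, dt=0.5)
            assert ls.segments == pytest.approx(lifetimes_oracle(bound, gap, 0.5))

    def test_total_bound_bounded_by_duration(self, small_traj):
        traj, _ = small_traj
        from memprobe.synthetic import synthetic_selections

        for r in compute_contacts(traj, synthetic_selections()):
            ls = lifetimes(r)
            assert ls.total_bound <= traj.n_frames * traj.dt + 1e-9

    def test_occupancy_equals_total_bound_over_duration_single_molecule(self):
        d = np.array([4, 4, 9, 4, 9, 9, 4, 4.0])
        rec = _record(d, dt=2.0)
        ls = lifetimes(rec)
        occ = float(occupancy([rec]).occupancy_fraction.iloc[0])
        assert occ == pytest.approx(ls.total_bound / (len(d) * 2.0))


class TestClassifyInteraction:
    # transient iff max_continuous < 10 ns OR total_bound < 50 ns
    @pytest.mark.parametrize(
        "max_c, total, expected",
        [
            (9.9, 45, "transient"), (9.9, 50, "transient"), (9.9, 300, "transient"),
            (10, 45, "transient"), (10, 50, "stable"), (10, 300, "stable"),
            (15, 45, "transient"), (15, 50, "stable"), (15, 300, "stable"),
        ],
    )
    def test_boundary_truth_table(self, max_c, total, expected):
        assert classify_interaction(LifetimeSetStub(max_c, total)) == expected

    def test_worked_examples(self):
        assert classify_interaction(LifetimeSetStub(8, 40)) == "transient"
        assert classify_interaction(LifetimeSetStub(15, 45)) == "transient"
        assert classify_interaction(LifetimeSetStub(120, 300)) == "stable"


class LifetimeSetStub:
    """Direct (max_continuous, total_bound) pair for boundary-case tests."""

    def __init__(self, max_continuous, total_bound):
        self.max_continuous = float(max_continuous)
        self.total_bound = float(total_bound)


class TestMultivalency:
    def test_single_pair_counts_stay_below_two(self):
        res = multivalency([_record([4, 9, 4])])
        assert res.multivalent_fraction_of_frames == 0.0
        assert res.lipid_group_counts[1].max() == 1

    def test_bridge_fixture_counts_two_groups(self, fixture_paths, fixture_spec):
        system = read_structure(fixture_paths["bridge"])
        traj = read_frames(fixture_paths["bridge"], system, dt=1.0)
        records = compute_contacts(traj, fixture_spec)
        res = multivalency(records)
        mol = next(iter(res.lipid_group_counts))
        assert res.lipid_group_counts[mol][0] == 2
        assert res.multivalent_fraction_of_frames == 1.0

    def test_empty_fixture_gives_zero_tables(self, fixture_paths, fixture_spec):
        system = read_structure(fixture_paths["empty"])
        traj = read_frames(fixture_paths["empty"], system, dt=1.0)
        records = compute_contacts(traj, fixture_spec)
        occ = occupancy(records)
        assert (occ.occupancy_fraction == 0.0).all()
        res = multivalency(records)
        assert res.multivalent_fraction_of_frames == 0.0

    def test_planted_bridging_rate_recovered(self):
        """A planted bivalent episode rate is recovered within 3 SE."""
        from memprobe.synthetic import BridgePlan, synthetic_selections
        from memprobe.core import SelectionSpec

        params = SyntheticParams(
            n_frames=4000, seed=9,
            bridge_plan=[BridgePlan(("K271", "K275"), "PS", 0.3, 10.0)],
        )
        traj, gt = simulate_trajectory(params)
        spec = SelectionSpec()
        full = synthetic_selections()
        for name in ("K271", "K275", "PS"):
            spec.add(full.groups[name])
        key = next(iter(gt.bridge_states))
        state = gt.bridge_states[key]
        mol = gt.contact_lipid_ids[key]
        recs = [r for r in compute_contacts(traj, spec) if r.lipid_molecule_id == mol]
        res = multivalency(recs)
        # analysis agrees with the planted bridge state exactly...
        assert np.array_equal(res.lipid_group_counts[mol] == 2, state)
        assert res.multivalent_frames.mean() == pytest.approx(state.mean())
        # ...and the realized rate is statistically consistent with the plan
        p, n = 0.3, 4000
        q_off = 0.1 / 10.0
        rho = 1 - q_off - q_off * p / (1 - p)
        n_eff = n * (1 - rho) / (1 + rho)
        se = np.sqrt(p * (1 - p) / n_eff)
        assert abs(res.multivalent_fraction_of_frames - p) < 3 * se


class TestEstimatorRecovery:
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.8])
    def test_two_state_occupancy_recovery(self, p):
        """Planted stationary occupancy recovered within 3 SE (ESS-corrected)."""
        mean_lt, dt, n = 20.0, 0.1, 6000
        params = SyntheticParams(
            n_frames=n, seed=100 + int(10 * p),
            contact_plan=[ContactPlan("K271", "PS", p, mean_lt)],
        )
        traj, gt = simulate_trajectory(params)
        key = next(iter(gt.contact_states))
        mol = gt.contact_lipid_ids[key]
        from memprobe.synthetic import synthetic_selections

        recs = compute_contacts(traj, synthetic_selections())
        rec = [r for r in recs if r.protein_group == "K271" and r.lipid_molecule_id == mol][0]
        est = float(rec.bound_series.mean())
        assert est == pytest.approx(gt.realized_occupancy[key])
        q_off = dt / mean_lt
        rho = 1 - q_off - q_off * p / (1 - p)
        n_eff = n * (1 - rho) / (1 + rho)
        se = np.sqrt(p * (1 - p) / n_eff)
        assert abs(est - p) < 3 * se
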