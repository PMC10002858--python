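"""Insertion depth, tilt, topology histograms, area per lipid, stability checks."""

import numpy as np
import pytest

from memprobe.core import (
    AtomRecord,
    LipidClass,
    MembraneComposition,
    MolecularSystem,
    SegmentKind,
    Trajectory,
)
from memprobe.synthetic import PHORBOL_COMPOSITION, SyntheticParams, simulate_trajectory
from memprobe.topology import (
    TopologySeries,
    area_per_lipid,
    insertion_depth,
    stability_check,
    tilt_angle,
    topology_histogram,
    topology_series,
)


def _depth_system(n_ps=4):
    """Protein reference atom + PS lipids split over two leaflets."""
    records = [AtomRecord(0, "CA", "GLY", 253, SegmentKind.PROTEIN, 0)]
    for j in range(n_ps):
        records.append(
            AtomRecord(1 + j, "P", "SOPS", 301 + j, SegmentKind.LIPID, 1 + j, LipidClass.PS)
        )
    return MolecularSystem(records)


def _depth_traj(ref_z, lower_z=-20.0, upper_z=20.0, n_lower=2):
    sys_ = _depth_system(4)
    coords = np.zeros((1, 5, 3))
    coords[0, 0, 2] = ref_z
    for j in range(4):
        coords[0, 1 + j, 2] = lower_z if j < n_lower else upper_z
        coords[0, 1 + j, 0] = 10.0 * j
    return Trajectory(sys_, coords, np.array([[60.0, 60.0, 90.0]]), np.array([0.0])), sys_


class TestInsertionDepth:
    def test_zero_at_phosphate_plane(self):
        traj, sys_ = _depth_traj(ref_z=-20.0)
        depth, plane = insertion_depth(traj, [0], [1, 2, 3, 4])
        assert depth[0] == pytest.approx(0.0)
        assert plane[0] == pytest.approx(-20.0)

    def test_positive_toward_midplane(self):
        """Lower-leaflet plane at -20, ref at -12 => +8 Å (deeper insertion)."""
        traj, _ = _depth_traj(ref_z=-12.0)
        depth, _ = insertion_depth(traj, [0], [1, 2, 3, 4])
        assert depth[0] == pytest.approx(8.0)

    def test_negative_outside_membrane(self):
        traj, _ = _depth_traj(ref_z=-25.0)
        depth, _ = insertion_depth(traj, [0], [1, 2, 3, 4])
        assert depth[0] == pytest.approx(-5.0)

    def test_invariant_to_global_z_shift(self):
        traj, sys_ = _depth_traj(ref_z=-12.0)
        shifted = Trajectory(
            sys_, traj.coordinates + np.array([0.0, 0.0, 13.7]), traj.boxes, traj.times
        )
        d0, _ = insertion_depth(traj, [0], [1, 2, 3, 4])
        d1, _ = insertion_depth(shifted, [0], [1, 2, 3, 4])
        assert d1[0] == pytest.approx(d0[0])

    def test_empty_phosphate_selection_errors(self):
        traj, _ = _depth_traj(ref_z=-12.0)
        with pytest.raises(ValueError):
            insertion_depth(traj, [0], [])


def _tilt_traj(axis):
    """Two 4-residue centroid sets separated along ``axis``."""
    upper_res = (239, 241, 253, 255)
    lower_res = (233, 246, 263, 276)
    records = []
    for i, r in enumerate(upper_res + lower_res):
        records.append(AtomRecord(i, "CA", "GLY", r, SegmentKind.PROTEIN, i))
    sys_ = MolecularSystem(records)
    axis = np.asarray(axis, float)
    coords = np.zeros((1, 8, 3))
    spread = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
    coords[0, :4] = 10.0 * axis + spread  # lateral spread cancels in the centroid
    coords[0, 4:] = -10.0 * axis + spread
    return Trajectory(sys_, coords, np.array([[60.0, 60.0, 90.0]]), np.array([0.0]))


class TestTiltAngle:
    @pytest.mark.parametrize(
        "axis, expected",
        [
            ((0, 0, 1), 0.0),
            ((1, 0, 0), 90.0),
            ((1 / np.sqrt(2), 0, 1 / np.sqrt(2)), 45.0),
            ((0, 0, -1), 0.0),  # folded to [0, 90]
        ],
    )
    def test_closed_form_angles(self, axis, expected):
        traj = _tilt_traj(axis)
        assert tilt_angle(traj)[0] == pytest.approx(expected, abs=1e-9)

    def test_complementary_convention(self):
        traj = _tilt_traj((1 / np.sqrt(2), 0, 1 / np.sqrt(2)))
        assert tilt_angle(traj, convention="from_plane")[0] == pytest.approx(45.0)
        traj = _tilt_traj((0, 0, 1))
        assert tilt_angle(traj, convention="from_plane")[0] == pytest.approx(90.0)

    def test_invariant_to_translation_and_z_rotation(self):
        axis = np.array([0.5, 0.3, 0.81])
        axis /= np.linalg.norm(axis)
        traj = _tilt_traj(axis)
        base = tilt_angle(traj)[0]
        # translation
        t2 = Trajectory(traj.system, traj.coordinates + 7.0, traj.boxes, traj.times)
        assert tilt_angle(t2)[0] == pytest.approx(base, abs=1e-9)
        # rotation about the membrane normal
        th = 1.1
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        t3 = Trajectory(traj.system, traj.coordinates @ rot.T, traj.boxes, traj.times)
        assert tilt_angle(t3)[0] == pytest.approx(base, abs=1e-9)


class TestTopologyHistogram:
    def test_constant_series_single_bin(self):
        s = TopologySeries(np.full(50, 5.0), np.full(50, 38.0), np.zeros(50))
        hist = topology_histogram([s])
        assert hist.counts.sum() == 50
        assert (hist.counts > 0).sum() == 1
        assert hist.mean_depth == pytest.approx(5.0)
        assert hist.mean_tilt == pytest.approx(38.0)

    def test_pooling_is_additive(self):
        s1 = TopologySeries(np.full(30, 5.0), np.full(30, 38.0), np.zeros(30))
        s2 = TopologySeries(np.full(20, 8.0), np.full(20, 48.0), np.zeros(20))
        pooled = topology_histogram([s1, s2])
        h1 = topology_histogram([s1], pooled.depth_edges, pooled.tilt_edges)
        h2 = topology_histogram([s2], pooled.depth_edges, pooled.tilt_edges)
        assert np.array_equal(pooled.counts, h1.counts + h2.counts)

    def test_out_of_range_clamped_conserves_counts(self):
        s = TopologySeries(np.array([100.0, -100.0]), np.array([38.0, 38.0]), np.zeros(2))
        hist = topology_histogram([s])
        assert hist.counts.sum() == 2

    def test_planted_gaussian_recovery(self):
        """Planted depth 8±1 Å / tilt 48°±5° recovered within 3 SE, 5 pooled runs."""
        series, truths_d, truths_t = [], [], []
        for rep in range(5):
            params = SyntheticParams(n_frames=500, seed=300 + rep)
            traj, gt = simulate_trajectory(params)
            series.append(topology_series(traj))
            truths_d.append(gt.depth_series)
            truths_t.append(gt.tilt_series)
        hist = topology_histogram(series)
        n = 5 * 500
        # tilt is clipped to [0, 90], so compare against the realized truth too
        assert abs(hist.mean_depth - 8.0) < 3 * 1.0 / np.sqrt(n)
        assert hist.mean_depth == pytest.approx(np.concatenate(truths_d).mean(), abs=1e-6)
        assert abs(hist.mean_tilt - 48.0) < 3 * 5.0 / np.sqrt(n)
        assert hist.mean_tilt == pytest.approx(np.concatenate(truths_t).mean(), abs=1e-6)


class TestAreaPerLipid:
    def test_table_lower_leaflet_value(self, small_traj):
        """60x60 Å box over the 59 lower-leaflet lipids gives 61.02 Å²."""
        traj, _ = small_traj
        apl = area_per_lipid(traj, PHORBOL_COMPOSITION)
        assert apl["lower"][0] == pytest.approx(3600.0 / 59.0, abs=1e-6)
        assert apl["lower"][0] == pytest.approx(61.02, abs=0.01)
        assert np.ptp(apl["lower"]) == 0.0  # constant box -> constant series

    def test_proportional_to_box_area(self):
        comp = MembraneComposition(upper={"PC": 10}, lower={"PC": 10})
        sys_ = MolecularSystem(
            [AtomRecord(0, "P", "POPC", 1, SegmentKind.LIPID, 0, LipidClass.PC)]
        )
        coords = np.zeros((2, 1, 3))
        boxes = np.array([[60.0, 60.0, 90.0], [60.0 * np.sqrt(2), 60.0 * np.sqrt(2), 90.0]])
        traj = Trajectory(sys_, coords, boxes, np.array([0.0, 1.0]))
        apl = area_per_lipid(traj, comp)
        assert apl["upper"][1] == pytest.approx(2 * apl["upper"][0])

    def test_zero_lipids_errors(self, small_traj):
        traj, _ = small_traj
        with pytest.raises(ValueError):
            area_per_lipid(traj, MembraneComposition(upper={}, lower={"PC": 1}))


class TestStabilityCheck:
    def test_constant_series_stable(self):
        t = np.arange(100.0)
        v = stability_check(np.full(100, 5.0), t, window_ns=50.0)
        assert v.verdict == "stable" and v.slope == pytest.approx(0.0)

    def test_linear_drift_detected(self):
        t = np.arange(100.0)
        v = stability_check(5.0 + 1.0 * t, t, window_ns=50.0, tolerance=0.01)
        assert v.verdict == "drifting"
        assert v.slope == pytest.approx(1.0)

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            stability_check(np.ones(5), np.arange(5.0), window_ns=50.0)

    def test_ar1_noise_called_stable_in_most_replicates(self):
        """AR(1) fluctuation about a fixed mean: >= 95% of 200 runs stable."""
        rng = np.random.default_rng(20260928)
        phi, sigma = 0.9, 0.5
        times = 0.1 * np.arange(1000)
        n_stable = 0
        for _ in range(200):
            eps = rng.normal(0, sigma * np.sqrt(1 - phi**2), 1000)
            x = np.empty(1000)
            x[0] = rng.normal(0, sigma)
            for i in range(1, 1000):
                x[i] = phi * x[i - 1] + eps[i]
            v = stability_check(8.0 + x, times, window_ns=50.0)
            n_stable += v.verdict == "stable"
        assert n_stable >= 190


def test_depth_and_tilt_exact_against_planted_series():
    """With no planted contacts the analysis reproduces the generator's series."""
    params = SyntheticParams(n_frames=200, seed=15)
    traj, gt = simulate_trajectory(params)
    ts = topology_series(traj)
    assert ts.depth == pytest.approx(gt.depth_series, abs=1e-9)
    assert ts.tilt == pytest.approx(gt.tilt_series, abs=1e-9)
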