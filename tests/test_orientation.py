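import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from membind.errors import DegenerateGeometryError, UnknownLabelError
from membind.kinetics import DistanceSeries
from membind.orientation import (
    BindingMode,
    classify_refinement,
    com_z_distance_series,
    density_map,
    detect_modes,
    last_frame_reference,
    rereference,
    rotation_matrix,
    rzz_series,
    score_modes,
)
from membind.toysim import BilayerModel, build_bilayer, make_c2_like_body
from membind.toysim.state import Frame, Trajectory


def make_traj(body, poses, bilayer=None, lipid_xy=None):
    """poses: list of (com, Rotation)."""
    if bilayer is None:
        bilayer = build_bilayer(10, {"PC": 1.0}, seed=0, mode="mean-field")
    frames = [
        Frame(
            time=float(i),
            body_com=np.asarray(com, dtype=float),
            body_orientation=rot.as_quat(),
            lipid_xy=lipid_xy,
        )
        for i, (com, rot) in enumerate(poses)
    ]
    return Trajectory(body=body, bilayer=bilayer, frames=frames, frame_interval=1.0)


class TestRotationMatrix:
    def test_identity(self, body):
        r = rotation_matrix(body.bead_positions, body.bead_positions)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-12)

    def test_recovers_known_rotation(self, body):
        true = Rotation.from_euler("xyz", [20, -35, 110], degrees=True)
        coords = true.apply(body.bead_positions)
        r = rotation_matrix(body.bead_positions, coords)
        np.testing.assert_allclose(r, true.as_matrix(), atol=1e-9)

    def test_proper_rotation_enforced(self, body):
        true = Rotation.from_euler("y", 150, degrees=True)
        coords = true.apply(body.bead_positions)
        r = rotation_matrix(body.bead_positions, coords)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_rejected(self):
        line = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            rotation_matrix(line, line)

    def test_beats_random_rotations_on_noisy_coords(self, body):
        rng = np.random.default_rng(1)
        true = Rotation.from_euler("xyz", [30, 40, 50], degrees=True)
        coords = true.apply(body.bead_positions) + rng.normal(0, 0.02, (body.n_beads, 3))
        r = rotation_matrix(body.bead_positions, coords)
        coords_c = coords - coords.mean(axis=0)

        def rmsd(mat):
            return np.sqrt(((coords_c - body.bead_positions @ mat.T) ** 2).sum())

        best_fit = rmsd(r)
        random_rots = Rotation.random(10000, rng=rng).as_matrix()
        random_best = min(rmsd(m) for m in random_rots)
        assert best_fit <= random_best + 1e-12


class TestRzz:
    def test_same_orientation_is_one(self, body):
        traj = make_traj(body, [((0, 0, 3), Rotation.identity())])
        s = rzz_series(traj, body.bead_positions)
        assert s.rzz[0] == pytest.approx(1.0, abs=1e-12)

    def test_in_plane_flip_is_minus_one(self, body):
        traj = make_traj(body, [((0, 0, 3), Rotation.from_euler("x", 180, degrees=True))])
        s = rzz_series(traj, body.bead_positions)
        assert s.rzz[0] == pytest.approx(-1.0, abs=1e-12)

    def test_ninety_degree_tilt_is_zero(self, body):
        traj = make_traj(body, [((0, 0, 3), Rotation.from_euler("x", 90, degrees=True))])
        s = rzz_series(traj, body.bead_positions)
        assert s.rzz[0] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_z_rotations(self, body):
        # pre/post-composing with rotations about z leaves R_zz unchanged,
        # so an in-plane pre-fit is a no-op for rigid bodies
        base = Rotation.from_euler("xyz", [25, 40, 10], degrees=True)
        rz1 = Rotation.from_euler("z", 77, degrees=True)
        rz2 = Rotation.from_euler("z", -131, degrees=True)
        vals = []
        for rot in (base, rz1 * base, base * rz2, rz1 * base * rz2):
            traj = make_traj(body, [((0, 0, 3), rot)])
            vals.append(rzz_series(traj, body.bead_positions).rzz[0])
        assert np.abs(np.diff(vals)).max() < 1e-9


class TestComZSeries:
    def test_height_above_plane(self, body):
        bl = build_bilayer(10, {"PC": 1.0}, seed=0, mode="mean-field", plane_z=0.0)
        traj = make_traj(body, [((1, 1, 4.0), Rotation.identity())], bilayer=bl)
        assert com_z_distance_series(traj).values[0] == pytest.approx(4.0)

    def test_descending(self, body):
        poses = [((0, 0, z), Rotation.identity()) for z in (5.0, 4.0, 3.0)]
        traj = make_traj(body, poses)
        assert np.all(np.diff(com_z_distance_series(traj).values) < 0)

    def test_direct_recomputation_oracle(self, body):
        rng = np.random.default_rng(3)
        zs = rng.uniform(1, 6, size=10)
        traj = make_traj(body, [((0, 0, z), Rotation.identity()) for z in zs])
        np.testing.assert_allclose(com_z_distance_series(traj).values, zs)


class TestDensityMap:
    def test_single_cell(self):
        d = [DistanceSeries(np.arange(50.0), np.full(50, 3.33))]
        r = [_orient(np.full(50, 0.91))]
        m = density_map(d, r)
        prob = m.probability
        assert (prob > 0).sum() == 1
        assert prob.max() == pytest.approx(1.0)

    def test_unit_mass(self):
        rng = np.random.default_rng(0)
        d = [DistanceSeries(np.arange(500.0), rng.uniform(1, 6, 500))]
        r = [_orient(rng.uniform(-1, 1, 500))]
        m = density_map(d, r)
        dd = np.diff(m.distance_edges)[:, None] * np.diff(m.rzz_edges)[None, :]
        assert (m.density * dd).sum() == pytest.approx(1.0, abs=1e-9)

    def test_log_floor(self):
        d = [DistanceSeries(np.arange(100.0), np.full(100, 2.0))]
        r = [_orient(np.zeros(100))]
        assert density_map(d, r).log_floor == pytest.approx(1.0 / 1000.0)


def _orient(rzz):
    from membind.orientation import OrientationSeries

    return OrientationSeries(times=np.arange(float(len(rzz))), rzz=np.asarray(rzz))


def _bimodal_ensemble(rng, centers=((3.3, 0.9), (3.6, -0.8)), n=600):
    d, r = [], []
    dd = np.empty(n)
    rr = np.empty(n)
    for i in range(n):
        cd, cr = centers[i % len(centers)]
        dd[i] = cd + rng.normal(0, 0.02)
        rr[i] = np.clip(cr + rng.normal(0, 0.01), -1, 1)
    d.append(DistanceSeries(np.arange(float(n)), dd))
    r.append(_orient(rr))
    return d, r


class TestDetectModes:
    def test_unimodal(self):
        rng = np.random.default_rng(0)
        d, r = _bimodal_ensemble(rng, centers=((3.4, 0.7),))
        modes = detect_modes(density_map(d, r), d, r, distance_bound=5.0)
        assert len(modes) == 1
        assert modes[0].occupancy == pytest.approx(1.0)

    def test_bimodal_centers_within_one_bin(self):
        rng = np.random.default_rng(1)
        d, r = _bimodal_ensemble(rng)
        modes = detect_modes(density_map(d, r), d, r, distance_bound=5.0)
        assert len(modes) == 2
        found = sorted(m.center for m in modes)
        for (fd, fr), (td, tr) in zip(found, sorted([(3.3, 0.9), (3.6, -0.8)])):
            assert abs(fd - td) <= 0.1 + 1e-9
            assert abs(fr - tr) <= 0.05 + 1e-9

    def test_uniform_map_high_threshold_gives_none(self):
        rng = np.random.default_rng(2)
        n = 2000
        d = [DistanceSeries(np.arange(float(n)), rng.uniform(1, 5, n))]
        r = [_orient(rng.uniform(-1, 1, n))]
        modes = detect_modes(density_map(d, r), d, r, distance_bound=5.0,
                             min_occupancy=0.05)
        assert modes == []


class TestRereference:
    def _planted(self, body):
        rng = np.random.default_rng(5)
        rots = [
            Rotation.from_euler("xyz", rng.uniform(0, 40, 3), degrees=True)
            for _ in range(30)
        ]
        poses = [((0, 0, 3.0 + 0.01 * i), rot) for i, rot in enumerate(rots)]
        return make_traj(body, poses)

    def test_representative_frame_maps_to_one(self, body):
        traj = self._planted(body)
        mode = BindingMode(
            center=(3.0, 1.0), occupancy=0.5, representative_frame=(0, 7)
        )
        series = rereference([traj], mode)
        assert series[0].rzz[7] == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self, body):
        traj = self._planted(body)
        mode = BindingMode(center=(3.0, 1.0), occupancy=0.5, representative_frame=(0, 4))
        a = rereference([traj], mode)
        b = rereference([traj], mode)
        np.testing.assert_allclose(a[0].rzz, b[0].rzz, atol=1e-12)

    def test_matches_direct_recomputation(self, body):
        traj = self._planted(body)
        mode = BindingMode(center=(3.0, 1.0), occupancy=0.5, representative_frame=(0, 11))
        series = rereference([traj], mode)
        direct = rzz_series(traj, traj.bead_lab_positions(11))
        np.testing.assert_allclose(series[0].rzz, direct.rzz, atol=1e-12)


class TestScoreModes:
    def _bound_traj(self, body, flip=False):
        rot = Rotation.from_euler("x", 180, degrees=True) if flip else Rotation.identity()
        # identity: basic face down near the plane, termini up
        z = 1.0
        return make_traj(body, [((0, 0, z), rot)] * 3)

    def test_buried_termini_fail_physical(self, body):
        traj = self._bound_traj(body, flip=True)  # termini now buried below
        mode = BindingMode(center=(1.0, -1.0), occupancy=0.5, representative_frame=(0, 0))
        scored = score_modes([mode], [traj], physical_mask={"terminus": 0.5})
        assert scored[0].flags["physical"] is False

    def test_empty_masks_vacuously_true(self, body):
        traj = self._bound_traj(body)
        mode = BindingMode(center=(1.0, 1.0), occupancy=0.5, representative_frame=(0, 0))
        scored = score_modes([mode], [traj])
        assert scored[0].flags["physical"] and scored[0].flags["productive"]

    def test_flags_match_brute_force(self, body):
        traj = self._bound_traj(body)
        mode = BindingMode(center=(1.0, 1.0), occupancy=0.5, representative_frame=(0, 0))
        scored = score_modes(
            [mode], [traj], physical_mask={"terminus": 0.5},
            productive_mask={"basic": 0.8},
        )
        beads = traj.bead_lab_positions(0)
        term = [i for i, lab in enumerate(body.bead_labels) if lab == "terminus"]
        basic = [i for i, lab in enumerate(body.bead_labels) if lab == "basic"]
        assert scored[0].flags["physical"] == bool(
            min(beads[i, 2] for i in term) >= 0.5
        )
        assert scored[0].flags["productive"] == bool(
            min(beads[i, 2] for i in basic) <= 0.8
        )

    def test_unknown_label_rejected(self, body):
        traj = self._bound_traj(body)
        mode = BindingMode(center=(1.0, 1.0), occupancy=0.5, representative_frame=(0, 0))
        with pytest.raises(UnknownLabelError):
            score_modes([mode], [traj], physical_mask={"nonexistent": 0.5})

    def test_probable_threshold(self, body):
        traj = self._bound_traj(body)
        lo = BindingMode(center=(1.0, 1.0), occupancy=0.01, representative_frame=(0, 0))
        hi = BindingMode(center=(1.0, 1.0), occupancy=0.4, representative_frame=(0, 0))
        scored = score_modes([lo, hi], [traj], occupancy_threshold=0.02)
        assert scored[0].flags["probable"] is False
        assert scored[1].flags["probable"] is True


class TestClassifyRefinement:
    def _lipid_bilayer(self):
        return BilayerModel(
            box_xy=np.array([7.0, 7.0]),
            species_counts={"PC": 1},
            lipid_xy=np.array([[3.5, 3.5]]),
            lipid_species=["PC"],
        )

    def test_static_is_retained(self, body):
        bl = self._lipid_bilayer()
        traj = make_traj(
            body, [((3.5, 3.5, 1.0), Rotation.identity())] * 10, bilayer=bl,
            lipid_xy=bl.lipid_xy,
        )
        c = classify_refinement(traj)
        assert c.label == "retained"
        assert c.max_delta_distance == 0.0
        assert c.max_delta_angle == 0.0

    def test_in_place_rotation(self, body):
        bl = self._lipid_bilayer()
        poses = [((3.5, 3.5, 1.0), Rotation.identity())] * 5 + [
            ((3.5, 3.5, 1.0), Rotation.from_euler("y", 90, degrees=True))
        ] * 5
        traj = make_traj(body, poses, bilayer=bl, lipid_xy=bl.lipid_xy)
        c = classify_refinement(traj)
        assert c.label == "rotated"
        assert c.max_delta_angle == pytest.approx(90.0, abs=1e-6)

    def test_escape_is_unbound(self, body):
        bl = self._lipid_bilayer()
        poses = [((3.5, 3.5, 1.0), Rotation.identity())] * 3 + [
            ((3.5, 3.5, 8.0), Rotation.identity())
        ] * 7
        traj = make_traj(body, poses, bilayer=bl, lipid_xy=bl.lipid_xy)
        c = classify_refinement(traj)
        assert c.label == "unbound"
        assert c.max_delta_distance == pytest.approx(7.0)

    def test_ten_constructed_trajectories_match_manual_labels(self, body):
        bl = self._lipid_bilayer()
        rng = np.random.default_rng(9)
        cases = []
        for i in range(10):
            kind = ("retained", "rotated", "unbound")[i % 3]
            poses = []
            for j in range(12):
                if kind == "retained":
                    rot = Rotation.from_euler("z", rng.uniform(0, 359), degrees=True)
                    rot = Rotation.from_euler("x", rng.uniform(0, 20), degrees=True)
                    com = (3.5, 3.5, 1.0 + 0.05 * rng.standard_normal())
                elif kind == "rotated":
                    ang = 10.0 if j < 6 else 120.0
                    rot = Rotation.from_euler("x", ang, degrees=True)
                    com = (3.5, 3.5, 1.0)
                else:
                    rot = Rotation.identity()
                    com = (3.5, 3.5, 1.0 if j < 4 else 6.0)
                poses.append((com, rot))
            cases.append((kind, make_traj(body, poses, bilayer=bl, lipid_xy=bl.lipid_xy)))
        for kind, traj in cases:
            assert classify_refinement(traj).label == kind


def test_last_frame_reference(body):
    t1 = make_traj(body, [((0, 0, 3), Rotation.identity()),
                          ((0, 0, 3), Rotation.from_euler("x", 45, degrees=True))])
    t2 = make_traj(body, [((0, 0, 3), Rotation.identity())])
    ref = last_frame_reference([t1, t2])
    np.testing.assert_allclose(ref, t1.bead_lab_positions(1))
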