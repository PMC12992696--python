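"""Interaction detectors against exhaustive/brute-force oracles."""
import numpy as np
import pytest

from gpcrswitch.errors import GeometryError, SelectionError, TopologyError
from gpcrswitch.interactions import (InteractionSeries, InteractionSpec,
                                     detect_hbond, detect_hydrophobic_contact,
                                     detect_pi_stack, detect_salt_bridge,
                                     interaction_series, occupancy)
from gpcrswitch.presets import PAPER_PROFILE
from gpcrswitch.synthetic import PAPER_PROFILE_FIXTURES, build_fixture
from gpcrswitch.trajectory import Atom, Frame, Trajectory

from conftest import random_rigid


def _frame(coords, elements=None, names=None):
    n = len(coords)
    elements = elements or ["C"] * n
    names = names or [f"A{i}" for i in range(n)]
    atoms = [Atom(i + 1, names[i], "UNK", i + 1, "A", elements[i],
                  np.asarray(coords[i], dtype=float)) for i in range(n)]
    return Frame(0, 0.0, atoms)


def _hbond_frame(dist, ang_deg):
    """D at origin, H at (1,0,0); A placed at the requested D-A distance
    and D-H...A angle."""
    d = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    bend = np.radians(180.0 - ang_deg)
    direction = np.array([np.cos(bend), np.sin(bend), 0.0])
    b = 2.0 * np.dot(direction, h - d)
    disc = b * b - 4.0 * (1.0 - dist ** 2)
    r = (-b + np.sqrt(disc)) / 2.0
    a = h + r * direction
    return _frame([d, h, a], elements=["N", "H", "O"])


class TestHbond:
    def test_inside_both_cutoffs(self):
        ok, dist, ang = detect_hbond(_hbond_frame(2.8, 170.0), 0, 1, 2)
        assert ok and dist == pytest.approx(2.8) and ang == pytest.approx(170.0)

    def test_distance_too_long(self):
        ok, dist, _ = detect_hbond(_hbond_frame(5.0, 170.0), 0, 1, 2)
        assert not ok and dist == pytest.approx(5.0)

    def test_grid_matches_predicate_oracle(self):
        """Exhaustive (distance, angle) grid against the bare predicate."""
        for dist in np.arange(2.2, 5.01, 0.1):
            for ang in np.arange(100.0, 180.0, 2.5):
                ok, d, a = detect_hbond(_hbond_frame(dist, ang), 0, 1, 2)
                expected = (dist <= 3.5) and (ang >= 120.0)
                assert ok == expected, (dist, ang)
                assert d == pytest.approx(dist, abs=1e-9)
                assert a == pytest.approx(ang, abs=1e-6)

    def test_detached_hydrogen_rejected(self):
        fr = _frame([(0, 0, 0), (2.0, 0, 0), (3, 0, 0)], elements=["N", "H", "O"])
        with pytest.raises(TopologyError, match="covalent"):
            detect_hbond(fr, 0, 1, 2)


class TestSaltBridge:
    def test_near_and_far(self):
        fr = _frame([(0, 0, 0), (3.0, 0, 0)], elements=["N", "O"])
        assert detect_salt_bridge(fr, [0], [1]) == (True, pytest.approx(3.0))
        fr = _frame([(0, 0, 0), (6.0, 0, 0)], elements=["N", "O"])
        assert detect_salt_bridge(fr, [0], [1])[0] is False

    def test_random_groups_match_allpairs_oracle(self, rng):
        for _ in range(100):
            coords = rng.uniform(-6, 6, size=(7, 3))
            fr = _frame(coords, elements=["N"] * 3 + ["O"] * 4)
            ok, dmin = detect_salt_bridge(fr, [0, 1, 2], [3, 4, 5, 6])
            expected = min(np.linalg.norm(coords[i] - coords[j])
                           for i in range(3) for j in range(3, 7))
            assert dmin == pytest.approx(expected, abs=1e-12)
            assert ok == (expected <= 4.0)

    def test_empty_group(self):
        fr = _frame([(0, 0, 0)], elements=["N"])
        with pytest.raises(SelectionError):
            detect_salt_bridge(fr, [0], [])


class TestHydrophobic:
    def test_cutoff_edges(self):
        fr = _frame([(0, 0, 0), (4.0, 0, 0)])
        assert detect_hydrophobic_contact(fr, [0], [1])[0]
        fr = _frame([(0, 0, 0), (4.6, 0, 0)])
        assert not detect_hydrophobic_contact(fr, [0], [1])[0]

    def test_hydrogen_in_selection_rejected(self):
        fr = _frame([(0, 0, 0), (1, 0, 0)], elements=["C", "H"])
        with pytest.raises(SelectionError, match="hydrogen"):
            detect_hydrophobic_contact(fr, [0], [1])

    def test_random_matches_allpairs(self, rng):
        for _ in range(50):
            coords = rng.uniform(-8, 8, size=(6, 3))
            fr = _frame(coords)
            ok, dmin = detect_hydrophobic_contact(fr, [0, 1, 2], [3, 4, 5])
            expected = min(np.linalg.norm(coords[i] - coords[j])
                           for i in range(3) for j in range(3, 6))
            assert dmin == pytest.approx(expected, abs=1e-12)
            assert ok == (expected <= 4.5)


def _hexagon(center, normal, radius=1.4):
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return [np.asarray(center) + radius * (np.cos(t) * u + np.sin(t) * v)
            for t in np.linspace(0, 2 * np.pi, 6, endpoint=False)]


class TestPiStack:
    def test_parallel_offset_rings(self):
        ring_a = _hexagon((0, 0, 0), (0, 0, 1))
        ring_b = _hexagon((0.5, 0, 3.8), (0, 0, 1))
        fr = _frame(ring_a + ring_b)
        ok, dist, ang = detect_pi_stack(fr, list(range(6)), list(range(6, 12)))
        assert ok and ang == pytest.approx(0.0, abs=1e-9)

    def test_distant_centroids(self):
        fr = _frame(_hexagon((0, 0, 0), (0, 0, 1)) + _hexagon((8, 0, 0), (0, 0, 1)))
        assert not detect_pi_stack(fr, list(range(6)), list(range(6, 12)))[0]

    def test_tshaped_window(self):
        fr = _frame(_hexagon((0, 0, 0), (0, 0, 1)) + _hexagon((0, 0, 4.5), (1, 0, 0)))
        ok, _, ang = detect_pi_stack(fr, list(range(6)), list(range(6, 12)))
        assert ok and ang == pytest.approx(90.0, abs=1e-9)

    def test_intermediate_angle_rejected(self):
        tilt = (np.sin(np.radians(45)), 0, np.cos(np.radians(45)))
        fr = _frame(_hexagon((0, 0, 0), (0, 0, 1)) + _hexagon((0, 0, 4), tilt))
        ok, _, ang = detect_pi_stack(fr, list(range(6)), list(range(6, 12)))
        assert not ok and ang == pytest.approx(45.0, abs=1e-6)

    def test_nonplanar_ring_rejected(self, rng):
        ring = _hexagon((0, 0, 0), (0, 0, 1))
        ring[0] = ring[0] + np.array([0, 0, 1.0])
        fr = _frame(ring + _hexagon((0, 0, 4), (0, 0, 1)))
        with pytest.raises(GeometryError, match="planar"):
            detect_pi_stack(fr, list(range(6)), list(range(6, 12)))

    def test_plane_angles_match_svd_oracle(self, rng):
        for _ in range(25):
            na = rng.normal(size=3)
            nb = rng.normal(size=3)
            ring_a = _hexagon((0, 0, 0), na)
            ring_b = _hexagon((0, 0, 4), nb)
            fr = _frame(ring_a + ring_b)
            _, _, ang = detect_pi_stack(fr, list(range(6)), list(range(6, 12)))
            ua, ub = na / np.linalg.norm(na), nb / np.linalg.norm(nb)
            expected = np.degrees(np.arccos(abs(np.clip(np.dot(ua, ub), -1, 1))))
            assert ang == pytest.approx(expected, abs=1e-6)


class TestSeriesAndOccupancy:
    def test_series_matches_per_frame_detector_calls(self):
        """Composition oracle on a fixture with a known on/off pattern."""
        spec = PAPER_PROFILE_FIXTURES["trans1_thr160"]
        import dataclasses
        small = dataclasses.replace(spec, n_frames=40)
        traj, rmap, manifest = build_fixture(small)
        ispec = InteractionSpec(
            kind="hbond", label="n1h",
            donors=(("resname LIG and name N1", "resname LIG and name H1"),),
            acceptors=("resnum 160 and name OG1",))
        series = interaction_series(traj, [ispec])[0]
        from gpcrswitch.trajectory import select_atoms
        d = select_atoms(traj, "resname LIG and name N1")[0]
        h = select_atoms(traj, "resname LIG and name H1")[0]
        a = select_atoms(traj, "resnum 160 and name OG1")[0]
        singles = [detect_hbond(fr, d, h, a)[0] for fr in traj.frames]
        assert list(series.present) == singles
        assert int(series.present.sum()) == manifest.ground_truth["thr160_n1h"]["n_satisfied"]

    def test_empty_spec_list(self):
        traj, _, _ = build_fixture(
            PAPER_PROFILE_FIXTURES["trans1_thr160"].__class__(
                name="tiny", n_frames=2, seed=1, targets={}))
        assert interaction_series(traj, []) == []

    def test_occupancy_counting(self):
        spec = InteractionSpec(kind="salt_bridge", label="x", group_a="name A",
                               group_b="name B")
        pres = np.array([True] * 7 + [False] * 3)
        rep = occupancy(InteractionSeries(spec, pres, np.ones(10)))
        assert rep.occupancy_percent == 70.0
        rep = occupancy(InteractionSeries(spec, np.zeros(5, bool), np.ones(5)))
        assert rep.occupancy_percent == 0.0

    def test_occupancy_random_vectors_match_counting_oracle(self, rng):
        spec = InteractionSpec(kind="salt_bridge", label="x", group_a="a",
                               group_b="b")
        for _ in range(50):
            n = int(rng.integers(1, 400))
            pres = rng.random(n) < rng.random()
            rep = occupancy(InteractionSeries(spec, pres, np.ones(n)))
            assert rep.occupancy_percent == 100.0 * sum(bool(x) for x in pres) / n

    def test_occupancy_empty_series_rejected(self):
        spec = InteractionSpec(kind="salt_bridge", label="x", group_a="a",
                               group_b="b")
        with pytest.raises(ValueError):
            occupancy(InteractionSeries(spec, np.zeros(0, bool), np.zeros(0)))

    def test_occupancy_monotone_under_satisfying_appends(self, rng):
        spec = InteractionSpec(kind="salt_bridge", label="x", group_a="a",
                               group_b="b")
        pres = list(rng.random(50) < 0.5)
        base = occupancy(InteractionSeries(spec, np.array(pres), np.ones(50)))
        grown = occupancy(InteractionSeries(spec, np.array(pres + [True] * 10),
                                            np.ones(60)))
        assert grown.occupancy_percent >= base.occupancy_percent


class TestRigidMotionInvariance:
    def test_all_detectors_invariant(self, rng):
        for _ in range(10):
            rot, t = random_rigid(rng)
            fr = _hbond_frame(3.0, 150.0)
            moved = _frame([a.coordinates @ rot.T + t for a in fr.atoms],
                           elements=["N", "H", "O"])
            assert detect_hbond(fr, 0, 1, 2)[0] == detect_hbond(moved, 0, 1, 2)[0]
            assert detect_hbond(fr, 0, 1, 2)[1] == pytest.approx(
                detect_hbond(moved, 0, 1, 2)[1], abs=1e-9)
            ring = _hexagon((0, 0, 0), (0, 0, 1)) + _hexagon((0.5, 0, 3.8), (0, 0, 1))
            fr2 = _frame(ring)
            moved2 = _frame([c @ rot.T + t for c in ring])
            got = detect_pi_stack(fr2, list(range(6)), list(range(6, 12)))
            exp = detect_pi_stack(moved2, list(range(6)), list(range(6, 12)))
            assert got[0] == exp[0]
            assert got[1] == pytest.approx(exp[1], abs=1e-9)
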