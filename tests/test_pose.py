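"""Ligand-core RMSD, insertion depth, axis, moving average and KDE."""
import dataclasses
import warnings

import numpy as np
import pytest

from gpcrswitch.errors import AxisError
from gpcrswitch.pose import (CoreMapping, DepthAxis, depth_series,
                             fraction_below, insertion_depth, kde_1d,
                             moving_average, receptor_axis, rmsd_i_series)
from gpcrswitch.synthetic import (PAPER_PROFILE_FIXTURES, FixtureSpec,
                                  build_fixture, reference_state)

from conftest import random_rigid, scaffold_trajectory


@pytest.fixture(scope="module")
def reference():
    return reference_state()


@pytest.fixture(scope="module")
def core_mapping(reference):
    ref, rmap = reference
    return CoreMapping.from_reference(ref, rmap)


class TestRmsdISeries:
    def test_reference_pose_scores_zero(self, reference, core_mapping):
        ref, rmap = reference
        series = rmsd_i_series(ref, core_mapping, rmap)
        assert series[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_core_displacement_measured_exactly(self, core_mapping):
        spec = FixtureSpec(name="disp", n_frames=4, seed=9, rigid_motion=False,
                           targets={"rmsd_core": {"values": [True, True, False, False]}})
        traj, rmap, _ = build_fixture(spec)
        series = rmsd_i_series(traj, core_mapping, rmap)
        np.testing.assert_allclose(series, [0.5, 0.5, 3.0, 3.0], atol=1e-9)

    def test_invariant_under_per_frame_rigid_motion(self, core_mapping, rng):
        spec = FixtureSpec(name="disp", n_frames=6, seed=9, rigid_motion=True,
                           targets={"rmsd_core": {"fraction": 0.5}})
        traj, rmap, manifest = build_fixture(spec)
        series = rmsd_i_series(traj, core_mapping, rmap)
        assert sorted(np.round(series, 6).tolist()) == [0.5] * 3 + [3.0] * 3

    def test_matches_two_stage_oracle(self, reference, core_mapping, rng):
        """Composition oracle: explicit Kabsch on fit atoms, then RMSD."""
        from gpcrswitch.geometry import kabsch
        spec = FixtureSpec(name="o", n_frames=3, seed=13, rigid_motion=True,
                           targets={"rmsd_core": {"fraction": 0.5}})
        traj, rmap, _ = build_fixture(spec)
        series = rmsd_i_series(traj, core_mapping, rmap)
        fit_idx = list(core_mapping.fit_indices)
        core_idx = [rmap.ligand_atom_index(traj, n)
                    for n in core_mapping.ligand_core_atoms]
        for i, fr in enumerate(traj.frames):
            tf, _ = kabsch(fr.coords[fit_idx], core_mapping.reference_fit)
            moved = tf.apply(fr.coords[core_idx])
            expected = np.sqrt(((moved - core_mapping.reference_core) ** 2).sum()
                               / len(core_idx))
            assert series[i] == pytest.approx(expected, abs=1e-12)


class TestFractionBelow:
    def test_examples(self):
        assert fraction_below([1.0, 1.5, 3.0, 2.5], 2.0) == 50.0
        assert fraction_below([0.1, 0.2], 2.0) == 100.0

    def test_strict_inequality_at_boundary(self):
        assert fraction_below([2.0, 1.9], 2.0) == 50.0

    def test_random_series_match_counting_oracle(self, rng):
        for _ in range(50):
            s = rng.uniform(0, 4, size=int(rng.integers(1, 300)))
            thr = rng.uniform(0.5, 3.5)
            assert fraction_below(s, thr) == 100.0 * sum(v < thr for v in s) / len(s)

    def test_monotone_in_threshold(self, rng):
        s = rng.uniform(0, 4, size=200)
        vals = [fraction_below(s, t) for t in np.linspace(0, 5, 40)]
        assert vals == sorted(vals)
        assert all(0 <= v <= 100 for v in vals)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fraction_below([], 2.0)


class TestReceptorAxis:
    def test_bundle_axis_is_z_pointing_intracellular(self, reference):
        ref, rmap = reference
        ax = receptor_axis(ref, ref.frames[0], rmap)
        # extracellular is +z in the scaffold, so the depth axis is -z
        np.testing.assert_allclose(ax.direction, [0, 0, -1], atol=1e-9)

    def test_equivariant_under_rotation(self, reference, rng):
        ref, rmap = reference
        fr = ref.frames[0]
        ax = receptor_axis(ref, fr, rmap)
        rot, t = random_rigid(rng)
        moved, _ = scaffold_trajectory([fr.coords @ rot.T + t])
        ax2 = receptor_axis(moved, moved.frames[0], rmap)
        np.testing.assert_allclose(ax2.direction, rot @ ax.direction, atol=1e-9)

    def test_matches_covariance_eigenvector_oracle(self, reference):
        ref, rmap = reference
        fr = ref.frames[0]
        ax = receptor_axis(ref, fr, rmap)
        tm_idx = rmap.role_ca_indices(ref, "tm")
        cloud = fr.coords[tm_idx]
        cov = np.cov((cloud - cloud.mean(0)).T)
        w, v = np.linalg.eigh(cov)
        principal = v[:, np.argmax(w)]
        assert abs(np.dot(principal, ax.direction)) == pytest.approx(1.0, abs=1e-9)

    def test_planar_cloud_rejected(self, reference):
        ref, rmap = reference
        coords = ref.frames[0].coords.copy()
        tm_idx = rmap.role_ca_indices(ref, "tm")
        coords[tm_idx, 2] = 0.0  # flatten the bundle
        flat, _ = scaffold_trajectory([coords])
        with pytest.raises(AxisError):
            receptor_axis(flat, flat.frames[0], rmap)


class TestInsertionDepth:
    def test_translation_invariance_and_projection(self, reference, rng):
        ref, rmap = reference
        fr = ref.frames[0]
        ax = receptor_axis(ref, fr, rmap)
        d0 = insertion_depth(ref, fr, rmap, ax)
        shift = rng.uniform(-10, 10, 3)
        moved, _ = scaffold_trajectory([fr.coords + shift])
        ax2 = receptor_axis(moved, moved.frames[0], rmap)
        assert insertion_depth(moved, moved.frames[0], rmap, ax2) == \
            pytest.approx(d0, abs=1e-9)

    def test_displacement_along_axis_changes_depth_linearly(self, reference):
        ref, rmap = reference
        fr = ref.frames[0]
        ax = receptor_axis(ref, fr, rmap)
        d0 = insertion_depth(ref, fr, rmap, ax)
        coords = fr.coords.copy()
        lig_idx = [rmap.ligand_atom_index(ref, n)
                   for n in rmap.ligand_atoms_by_role("core")]
        coords[lig_idx] += 3.0 * ax.direction
        deeper, _ = scaffold_trajectory([coords])
        assert insertion_depth(deeper, deeper.frames[0], rmap, ax) == \
            pytest.approx(d0 + 3.0, abs=1e-9)

    def test_matches_dot_product_oracle(self, reference, rng):
        ref, rmap = reference
        fr = ref.frames[0]
        for _ in range(20):
            origin = rng.normal(size=3, scale=5)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            ax = DepthAxis(origin, direction)
            lig_idx = [rmap.ligand_atom_index(ref, n)
                       for n in rmap.ligand_atoms_by_role("core")]
            centroid = fr.coords[lig_idx].mean(axis=0)
            expected = float(np.dot(centroid - origin, direction))
            assert insertion_depth(ref, fr, rmap, ax) == pytest.approx(expected)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(moving_average([2.5] * 30, 20), [2.5] * 30)

    def test_ramp_window_20(self):
        out = moving_average(np.arange(1.0, 101.0), 20)
        assert out[19] == pytest.approx(10.5)  # mean(1..20)
        assert out[0] == 1.0
        assert len(out) == 100

    def test_matches_naive_loop_oracle(self, rng):
        s = rng.normal(size=137)
        for window in (1, 5, 20, 200):
            got = moving_average(s, window)
            expected = [np.mean(s[max(0, i - window + 1):i + 1])
                        for i in range(len(s))]
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            moving_average([1.0], 0)


class TestKde:
    def test_unimodal_peak_at_cluster(self, rng):
        samples = rng.normal(3.0, 0.1, size=500)
        grid, dens = kde_1d(samples)
        assert grid[np.argmax(dens)] == pytest.approx(3.0, abs=0.05)
        assert (dens >= 0).all()

    def test_two_equal_clusters_symmetric_bimodal(self, rng):
        offsets = rng.normal(0.0, 0.05, 400)
        samples = np.concatenate([2.0 + offsets, 4.0 - offsets])
        grid, dens = kde_1d(samples, grid=np.linspace(1, 5, 801), bandwidth=0.1)
        mid = 400  # grid point at 3.0
        np.testing.assert_allclose(dens[:mid], dens[:mid:-1], atol=1e-10)
        assert dens[100] > dens[mid] < dens[700]  # two modes, dip between

    def test_normalises_to_one(self, rng):
        grid, dens = kde_1d(rng.normal(3, 0.7, size=300))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_matches_direct_kernel_sum_oracle(self, rng):
        samples = rng.uniform(2, 5, size=50)
        grid = np.linspace(0, 7, 100)
        h = 0.3
        _, dens = kde_1d(samples, grid=grid, bandwidth=h)
        expected = np.zeros_like(grid)
        for s in samples:
            expected += np.exp(-0.5 * ((grid - s) / h) ** 2)
        expected /= len(samples) * h * np.sqrt(2 * np.pi)
        np.testing.assert_allclose(dens, expected, atol=1e-12)

    def test_matches_scipy_gaussian_kde(self, rng):
        """Cross-check against the scipy implementation with the same
        absolute bandwidth."""
        from scipy.stats import gaussian_kde
        samples = rng.normal(3, 0.8, size=200)
        h = 0.25
        grid = np.linspace(0, 6, 200)
        _, dens = kde_1d(samples, grid=grid, bandwidth=h)
        sk = gaussian_kde(samples, bw_method=h / samples.std(ddof=1))
        np.testing.assert_allclose(dens, sk(grid), atol=1e-6)

    def test_zero_variance_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="bandwidth"):
            grid, dens = kde_1d([3.0, 3.0, 3.0], bandwidth="scott")
        assert grid[np.argmax(dens)] == pytest.approx(3.0, abs=0.01)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kde_1d([1.0])


def test_depth_series_constant_on_demo_fixture():
    spec = dataclasses.replace(PAPER_PROFILE_FIXTURES["demo_combined"], n_frames=20)
    spec = dataclasses.replace(spec, targets={
        k: (v if "values" not in v else {"values": v["values"][:20]})
        for k, v in spec.targets.items()})
    traj, rmap, _ = build_fixture(spec)
    depths = depth_series(traj, rmap)
    # the ligand never moves along the bundle axis except the 0.5/3.0 A
    # pose displacements, whose axial component is bounded by their norm
    assert np.all(np.isfinite(depths))
    assert depths.std() < 1.5
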