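import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisphere.uas import (
    N_PHI,
    N_THETA,
    SpherePoint,
    bin_index,
    compute_bin_grid,
    hemisphere_view,
    load_grid,
    project_to_uas,
    save_grid,
    spherical_to_cartesian,
    to_spherical,
)
from tests.conftest import make_recording


class TestToSpherical:
    def test_standing_maps_to_south_pole(self):
        p = to_spherical(np.array([0.0, -1.0, 0.0]))
        assert p.rho == pytest.approx(1.0)
        assert p.theta == pytest.approx(-np.pi / 2)

    def test_plus_x_maps_to_equator_left(self):
        p = to_spherical(np.array([1.0, 0.0, 0.0]))
        assert p.rho == pytest.approx(1.0)
        assert p.theta == pytest.approx(0.0)
        assert p.phi == pytest.approx(np.pi / 2)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            to_spherical(np.zeros(3))

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**16))
    def test_round_trip_recovers_cartesian(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(100, 3))
        v = v[np.linalg.norm(v, axis=1) > 1e-6]
        back = spherical_to_cartesian(to_spherical(v))
        np.testing.assert_allclose(back, v, atol=1e-12)

    def test_angle_ranges(self):
        rng = np.random.default_rng(3)
        p = to_spherical(rng.normal(size=(10_000, 3)))
        assert np.all(np.abs(p.theta) <= np.pi / 2)
        assert np.all(np.abs(p.phi) <= np.pi)


class TestProjection:
    def test_projection_sets_unit_radius(self):
        p = project_to_uas(SpherePoint(2.0, -np.pi / 2, 0.0))
        assert p.rho == pytest.approx(1.0)
        assert p.theta == pytest.approx(-np.pi / 2)

    def test_projection_is_idempotent_and_unit(self):
        rng = np.random.default_rng(0)
        pts = to_spherical(rng.normal(size=(10_000, 3)))
        proj = project_to_uas(pts)
        assert np.all(proj.rho == 1.0)
        again = project_to_uas(proj)
        np.testing.assert_array_equal(again.theta, proj.theta)


def brute_force_bin(phi, theta):
    """Independent oracle: scan the 1-degree edge arrays directly."""
    phi_edges = np.linspace(-np.pi, np.pi, N_PHI + 1)
    theta_edges = np.linspace(-np.pi / 2, np.pi / 2, N_THETA + 1)
    i = int(np.searchsorted(phi_edges, phi, side="right"))
    j = int(np.searchsorted(theta_edges, theta, side="right"))
    return min(max(i, 1), N_PHI), min(max(j, 1), N_THETA)


class TestBinIndex:
    @pytest.mark.parametrize(
        "phi,theta,expected",
        [
            (-np.pi, -np.pi / 2, (1, 1)),
            (np.pi, np.pi / 2, (360, 180)),
            (0.0, 0.0, (181, 91)),
        ],
    )
    def test_corner_and_center_bins(self, phi, theta, expected):
        i, j = bin_index(SpherePoint(1.0, theta, phi))
        assert (int(i), int(j)) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_index(SpherePoint(1.0, 2.0, 0.0))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        phi = rng.uniform(-np.pi, np.pi, 100_000)
        theta = rng.uniform(-np.pi / 2, np.pi / 2, 100_000)
        # include all exact bin boundaries
        phi = np.concatenate([phi, np.linspace(-np.pi, np.pi, N_PHI + 1)])
        theta = np.concatenate(
            [theta, np.linspace(-np.pi / 2, np.pi / 2, N_PHI + 1)]
        )
        i, j = bin_index(SpherePoint(np.ones_like(phi), theta, phi))
        for k in rng.integers(0, phi.size, 500):
            assert (int(i[k]), int(j[k])) == brute_force_bin(phi[k], theta[k])

    def test_every_sample_lands_in_exactly_one_bin(self):
        rng = np.random.default_rng(4)
        phi = rng.uniform(-np.pi, np.pi, 10_000)
        theta = rng.uniform(-np.pi / 2, np.pi / 2, 10_000)
        i, j = bin_index(SpherePoint(np.ones_like(phi), theta, phi))
        assert np.all((i >= 1) & (i <= N_PHI) & (j >= 1) & (j <= N_THETA))


class TestBinGrid:
    def test_single_orientation_concentrates_probability(self, still_standing):
        grid = compute_bin_grid(still_standing)
        assert (grid.counts > 0).sum() == 1
        assert grid.prob.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.nanmax(grid.mean_a) == pytest.approx(1.0)
        assert np.nanmax(grid.sd_a) == 0.0

    def test_two_sample_bin_statistics(self):
        rec = make_recording([[0, -0.9, 0], [0, -1.1, 0]])
        grid = compute_bin_grid(rec)
        i, j = bin_index(to_spherical(np.array([0.0, -1.0, 0.0])))
        assert grid.mean_a[i - 1, j - 1] == pytest.approx(1.0)
        assert grid.sd_a[i - 1, j - 1] == pytest.approx(0.1)

    def test_matches_naive_accumulation_oracle(self):
        rng = np.random.default_rng(8)
        accel = rng.normal(0, 1, (100_000, 3))
        accel += np.array([0, -0.5, 0])
        rec = make_recording(accel)
        grid = compute_bin_grid(rec)

        # naive per-sample accumulation into dictionaries
        sp = to_spherical(accel)
        i, j = bin_index(sp)
        bins: dict[tuple[int, int], list[float]] = {}
        for ii, jj, m in zip(i, j, np.asarray(sp.rho)):
            bins.setdefault((int(ii), int(jj)), []).append(m)
        assert grid.n_total == 100_000
        for (ii, jj), mags in bins.items():
            assert grid.counts[ii - 1, jj - 1] == len(mags)
            np.testing.assert_allclose(
                grid.mean_a[ii - 1, jj - 1], np.mean(mags), rtol=1e-10
            )
            np.testing.assert_allclose(
                grid.sd_a[ii - 1, jj - 1], np.std(mags), rtol=1e-6, atol=1e-9
            )
        assert grid.counts.sum() == grid.n_total
        assert grid.prob.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_recording_rejected(self):
        rec = make_recording(np.zeros((0, 3)))
        with pytest.raises(ValueError):
            compute_bin_grid(rec)

    def test_magnitude_distribution_is_rotation_invariant(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        accel = rng.normal(0, 0.3, (5000, 3)) + np.array([0, -1, 0])
        rot = Rotation.from_euler("xyz", [30, 45, 60], degrees=True)
        rec_a = make_recording(accel)
        rec_b = make_recording(rot.apply(accel))
        np.testing.assert_allclose(
            np.sort(rec_a.magnitude()), np.sort(rec_b.magnitude()), atol=1e-12
        )


class TestHemisphereView:
    def test_south_pole_mass_appears_centrally(self, still_standing):
        grid = compute_bin_grid(still_standing)
        south = hemisphere_view(grid, "south", "prob")
        north = hemisphere_view(grid, "north", "prob")
        assert south.count() == 1  # one unmasked cell
        assert north.count() == 0
        # the unmasked cell sits at the pole (radial column 0)
        assert np.unravel_index(np.argmax(south.filled(0)), south.shape)[1] == 0

    def test_mirror_symmetry_under_phi_flip(self):
        rng = np.random.default_rng(6)
        accel = rng.normal(0, 0.2, (5000, 3)) + np.array([0, -1, 0])
        mirrored = accel.copy()
        mirrored[:, 0] *= -1
        both = np.concatenate([accel, mirrored])
        grid = compute_bin_grid(make_recording(both))
        view = hemisphere_view(grid, "south", "prob").filled(0)
        np.testing.assert_allclose(view, view[::-1, :], atol=1e-12)

    def test_log_scale_masks_zero_probability(self, still_standing):
        grid = compute_bin_grid(still_standing)
        view = hemisphere_view(grid, "south", "prob", log_scale=True)
        assert np.all(np.isfinite(view.compressed()))
        with pytest.raises(ValueError):
            hemisphere_view(grid, "south", "mean", log_scale=True)

    def test_grid_round_trips_through_hdf5(self, tmp_path, still_standing):
        grid = compute_bin_grid(still_standing)
        save_grid(grid, tmp_path / "g.h5")
        back = load_grid(tmp_path / "g.h5")
        np.testing.assert_array_equal(back.counts, grid.counts)
        assert back.n_total == grid.n_total
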