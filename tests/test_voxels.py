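import numpy as np
import pytest

from ppv3d import (
    ConfigurationError,
    PPVVolume,
    Segment,
    TrackPoint,
    clip_vertical,
    contains,
    default_extent,
    ellipsoid_params,
    make_grid,
    ppv_trajectory,
    ppv_union,
    rasterize_segment,
    segments,
    volume_size,
)
from ppv3d.voxels import contains_block
from conftest import make_traj


def seg(p0, p1, dt):
    return Segment(TrackPoint(*p0, 0.0), TrackPoint(*p1, float(dt)))


def exhaustive_rasterize(grid, params):
    """Unpruned all-voxel sweep: the oracle for the bbox-pruned rasterizer."""
    pts = np.stack(
        np.meshgrid(*(grid.axis_centers(i) for i in range(3)), indexing="ij"),
        axis=-1,
    )
    return contains_block(params, pts)


class TestMakeGrid:
    @pytest.mark.parametrize(
        "lo,hi,edge,dims",
        [
            ((0, 0, 0), (10, 10, 10), 1.0, (10, 10, 10)),
            ((0, 0, 0), (10, 10, 10), 3.0, (4, 4, 4)),
            ((0, 0, 0), (1, 2, 3), 1.0, (1, 2, 3)),
        ],
    )
    def test_ceiling_rule(self, lo, hi, edge, dims):
        assert make_grid(lo, hi, edge).dims == dims

    def test_degenerate_extent_errors(self):
        with pytest.raises(ConfigurationError):
            make_grid((0, 0, 0), (0, 1, 1), 1.0)

    def test_voxel_center_convention(self):
        g = make_grid((10, 0, 0), (20, 1, 1), 1.0)
        assert g.axis_centers(0)[0] == pytest.approx(10.5)


class TestDefaultExtent:
    def test_single_segment_padding(self):
        tr = make_traj([[0, 0, 0], [100, 0, 0]], [0, 10])
        lo, hi = default_extent([tr], 20.0)  # a = 100
        np.testing.assert_allclose(lo, [-100, -100, -100])
        np.testing.assert_allclose(hi, [200, 100, 100])

    def test_padding_never_clips(self):
        """Enlarging the padded extent (grid-aligned) adds no occupied voxel."""
        from ppv3d import CRWConfig, estimate_vmax, segment_speeds, simulate_crw3d

        for s in range(3):
            tr = simulate_crw3d(CRWConfig(n_steps=15, seed=s))
            vmax = estimate_vmax(segment_speeds(tr))
            lo, hi = default_extent([tr], vmax)
            edge = float((hi - lo).max() / 40)
            count = ppv_trajectory(tr, vmax, make_grid(lo, hi, edge)).occupancy.sum()
            bigger = make_grid(lo - 3 * edge, hi + 3 * edge, edge)
            count_big = ppv_trajectory(tr, vmax, bigger).occupancy.sum()
            assert count_big == count


class TestRasterize:
    def test_pruned_equals_exhaustive_on_random_ellipsoids(self):
        rng = np.random.default_rng(21)
        grid = make_grid((-100, -100, -100), (100, 100, 100), 5.0)
        for _ in range(20):
            p0 = rng.uniform(-60, 60, 3)
            p1 = p0 + rng.uniform(-40, 40, 3)
            dt = rng.uniform(5, 50)
            d = np.linalg.norm(p1 - p0)
            vmax = max(d, 5.0) / dt * rng.uniform(1.1, 2.0)
            params = ellipsoid_params(seg(p0, p1, dt), vmax)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                pruned = rasterize_segment(grid, params)
            assert np.array_equal(pruned, exhaustive_rasterize(grid, params))

    def test_ellipsoid_outside_grid_warns_all_zero(self):
        grid = make_grid((0, 0, 0), (10, 10, 10), 1.0)
        params = ellipsoid_params(seg((100, 100, 100), (105, 100, 100), 10), 2.0)
        with pytest.warns(UserWarning, match="does not occupy"):
            occ = rasterize_segment(grid, params)
        assert not occ.any()

    def test_sphere_volume_convergence(self):
        """Voxelized volume converges to (4/3) pi a b^2 as the edge shrinks."""
        params = ellipsoid_params(seg((0.3, -0.2, 0.15), (100.3, -0.2, 0.15), 10), 20.0)
        analytic = 4 / 3 * np.pi * params.a * params.b**2
        errors = []
        for div in (5, 10, 20):
            edge = params.b / div
            lo, hi = params.center - params.a - edge, params.center + params.a + edge
            grid = make_grid(lo, hi, edge)
            occ = rasterize_segment(grid, params)
            vol = occ.sum() * grid.voxel_volume
            errors.append(abs(vol - analytic) / analytic)
        assert errors[-1] < 0.02
        assert errors[-1] < errors[0]


class TestTrajectoryVolume:
    def test_single_segment_union_is_rasterize(self):
        tr = make_traj([[0, 0, 0], [100, 0, 0]], [0, 10])
        grid = make_grid((-120, -120, -120), (220, 120, 120), 10.0)
        vol = ppv_trajectory(tr, 20.0, grid)
        params = ellipsoid_params(segments(tr)[0], 20.0)
        assert np.array_equal(vol.occupancy, rasterize_segment(grid, params))

    def test_slow_middle_segment_is_wider_and_union_superset(self):
        # three collinear segments; the middle one is slower
        tr = make_traj([[0, 0, 0], [100, 0, 0], [150, 0, 0], [250, 0, 0]],
                       [0, 100, 200, 300])
        vmax = 1.5
        segs = segments(tr)
        params = [ellipsoid_params(s, vmax) for s in segs]
        assert params[1].b > params[0].b and params[1].b > params[2].b
        grid = make_grid((-100, -100, -100), (350, 100, 100), 5.0)
        union = ppv_trajectory(tr, vmax, grid)
        for p in params:
            assert (union.occupancy >= rasterize_segment(grid, p)).all()

    def test_fixes_lie_in_occupied_voxels(self):
        from ppv3d import CRWConfig, estimate_vmax, segment_speeds, simulate_crw3d

        tr = simulate_crw3d(CRWConfig(n_steps=10, seed=2))
        vmax = estimate_vmax(segment_speeds(tr))
        params = [ellipsoid_params(s, vmax) for s in segments(tr)]
        b_min = min(p.b for p in params)
        lo, hi = default_extent([tr], vmax)
        grid = make_grid(lo, hi, b_min / 2)
        vol = ppv_trajectory(tr, vmax, grid)
        idx = np.floor((tr.xyz - grid.origin) / grid.voxel_size).astype(int)
        assert vol.occupancy[idx[:, 0], idx[:, 1], idx[:, 2]].all()


class TestUnionClipSize:
    def _vol(self, occ, grid, z_scale=1.0):
        return PPVVolume(grid=grid, occupancy=occ, z_scale=z_scale)

    def test_union_boolean_algebra(self):
        grid = make_grid((0, 0, 0), (4, 4, 4), 1.0)
        rng = np.random.default_rng(1)
        a = self._vol(rng.random(grid.dims) < 0.3, grid)
        b = self._vol(rng.random(grid.dims) < 0.3, grid)
        zero = self._vol(np.zeros(grid.dims, dtype=bool), grid)
        u = ppv_union([a, b])
        assert np.array_equal(ppv_union([a, zero]).occupancy, a.occupancy)
        assert np.array_equal(u.occupancy, ppv_union([b, a]).occupancy)
        assert np.array_equal(ppv_union([u, a]).occupancy, u.occupancy)
        assert max(a.occupancy.sum(), b.occupancy.sum()) <= u.occupancy.sum()
        assert u.occupancy.sum() <= a.occupancy.sum() + b.occupancy.sum()

    def test_union_mismatched_grids_error(self):
        g1 = make_grid((0, 0, 0), (4, 4, 4), 1.0)
        g2 = make_grid((0, 0, 0), (4, 4, 4), 2.0)
        with pytest.raises(ConfigurationError):
            ppv_union([
                self._vol(np.zeros(g1.dims, bool), g1),
                self._vol(np.zeros(g2.dims, bool), g2),
            ])

    def test_clip_vertical(self):
        grid = make_grid((0, 0, 0), (4, 4, 10), 1.0)
        full = self._vol(np.ones(grid.dims, dtype=bool), grid)
        assert np.array_equal(
            clip_vertical(full, 0, 10).occupancy, full.occupancy
        )
        assert not clip_vertical(full, 20, 30).occupancy.any()
        clipped = clip_vertical(full, 0, 5)
        assert clipped.occupancy.sum() <= full.occupancy.sum()
        # centers at 0.5..9.5; [0, 5] keeps k = 0..4
        assert clipped.occupancy.sum() == 4 * 4 * 5

    def test_volume_size_units_and_z_scale(self):
        grid = make_grid((0, 0, 0), (1000, 1000, 1000), 100.0)
        occ = np.zeros(grid.dims, dtype=bool)
        occ.flat[:1000] = True  # grid only has 1000 voxels; all of them
        vol = self._vol(occ, grid)
        assert volume_size(vol) == pytest.approx(1.0)  # 1000 * 1e6 m^3 = 1 km^3
        vol4 = self._vol(occ, grid, z_scale=4.0)
        assert volume_size(vol4) == pytest.approx(0.25)
        empty = self._vol(np.zeros(grid.dims, bool), grid)
        assert volume_size(empty) == 0.0
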