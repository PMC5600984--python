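import numpy as np
import pytest

from ldpo import (Volume, PhantomSpec, initialize_potential, solve_laplace,
                  make_slab_phantom, trace_to_gm, trace_to_wm, width_at,
                  compute_width_map, region_stats)
from ldpo.labeling import LABEL_GM, LABEL_GWB, LABEL_WM
from ldpo.tracing import WidthMap, STATUS_CODES
from ldpo.exceptions import ContractError, EmptyRegionError, GeometryError


@pytest.fixture
def column_field(column_labels):
    return solve_laplace(column_labels, rel_tol=1e-10, max_iter=5000)


class TestTraceColumn:
    def test_descent_to_gm(self, column_field, column_labels):
        r = trace_to_gm(column_field, column_labels, (0, 0, 2))
        assert r.status == "ok"
        assert r.gm_endpoint == (0, 0, 0)
        assert len(r.path) - 1 == 2  # two steps from the middle voxel

    def test_ascent_to_wm(self, column_field, column_labels):
        r = trace_to_wm(column_field, column_labels, (0, 0, 2))
        assert r.status == "ok"
        assert r.wm_endpoint == (0, 0, 4)

    def test_adjacent_origin_single_step(self, column_field, column_labels):
        r = trace_to_wm(column_field, column_labels, (0, 0, 3))
        assert r.status == "ok" and len(r.path) - 1 == 1

    def test_origin_not_gwb_rejected(self, column_field, column_labels):
        with pytest.raises(ContractError):
            trace_to_gm(column_field, column_labels, (0, 0, 0))


class TestTraceNeighbourhoodSelection:
    def test_steps_to_smallest_potential_neighbour(self):
        # a 3x3 window where 67 is the smallest candidate value
        lab = np.full((3, 3, 1), LABEL_GWB, np.uint8)
        labv = Volume(lab, role="label")
        field = initialize_potential(labv, 40, 100, 150)
        psi = np.array([[98.0, 84.0, 92.0],
                        [88.0, 98.0, 95.0],
                        [67.0, 90.0, 99.0]])[..., None]
        field.psi.data = psi
        r = trace_to_gm(field, labv, (1, 1, 0))
        assert r.path[1] == (2, 0, 0)  # the 67-valued voxel

    def test_ascent_visits_increasing_values_to_wm(self):
        lab = np.full((1, 1, 4), LABEL_GWB, np.uint8)
        lab[0, 0, 3] = LABEL_WM
        labv = Volume(lab, role="label")
        field = initialize_potential(labv, 50, 100, 150)
        field.psi.data = np.array([[[98.0, 126.0, 140.0, 150.0]]])
        r = trace_to_wm(field, labv, (0, 0, 0))
        assert [tuple(p) for p in r.path] == [(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)]
        assert r.status == "ok"

    def test_plateau_is_unreachable(self):
        lab = np.full((3, 3, 3), LABEL_GWB, np.uint8)
        labv = Volume(lab, role="label")
        field = initialize_potential(labv, 50, 100, 150)  # all-GWB: flat at 100
        r = trace_to_gm(field, labv, (1, 1, 1))
        assert r.status == "gm_unreachable"
        r2 = trace_to_wm(field, labv, (1, 1, 1))
        assert r2.status == "wm_unreachable"

    def test_monotone_potential_along_paths(self, rng):
        spec = PhantomSpec(shape=(12, 12, 12), gwb_thickness_mm=4.0, seed=0)
        b = make_slab_phantom(spec)
        f = solve_laplace(b.truth_labels, rel_tol=1e-9, max_iter=5000)
        psi = f.psi.data
        lab = b.truth_labels
        for origin in map(tuple, np.argwhere(lab.data == LABEL_GWB)[::7]):
            r = trace_to_gm(f, lab, origin)
            assert r.status == "ok"
            vals = [psi[p] for p in r.path]
            assert np.all(np.diff(vals) < 0)  # strictly decreasing toward GM
            r = trace_to_wm(f, lab, origin)
            vals = [psi[p] for p in r.path]
            assert np.all(np.diff(vals) > 0)  # strictly increasing toward WM


class TestWidthAt:
    def test_collinear_unit_grid(self):
        assert width_at((0, 0, 1), (0, 0, 0), (0, 0, 2), (1, 1, 1)) == pytest.approx(2.0)

    def test_halfpath_mean_mode(self):
        w = width_at((0, 0, 1), (0, 0, 0), (0, 0, 2), (1, 1, 1), mode="halfpath-mean")
        assert w == pytest.approx(1.0)

    def test_anisotropic_world_distance(self):
        # oracle: direct world-coordinate distance through the affine
        sp = (0.8594, 0.8594, 0.9)
        w = width_at((0, 0, 0), (1, 1, 1), (2, 2, 2), sp)
        assert w == pytest.approx(np.sqrt(0.8594 ** 2 + 0.8594 ** 2 + 0.9 ** 2), abs=1e-6)
        assert w == pytest.approx(1.511, abs=2e-3)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(GeometryError):
            width_at((0, 0, 1), (0, 0, 0), (0, 0, 0), (1, 1, 1))


class TestComputeWidthMap:
    def test_slab_interior_width(self):
        spec = PhantomSpec(shape=(16, 16, 12), gwb_thickness_mm=3.0, seed=0)
        b = make_slab_phantom(spec)
        f = solve_laplace(b.truth_labels, rel_tol=1e-9, max_iter=5000)
        wm = compute_width_map(f, b.truth_labels)
        band = b.truth_width.data > 0
        interior = np.zeros_like(band)
        interior[2:-2, 2:-2, :] = True
        vals = wm.width.data[band & interior]
        assert np.allclose(vals, 4.0)  # GM voxel through 3 GWB voxels to WM voxel

    def test_thickened_patch_is_wider(self):
        from ldpo import LesionSpec
        spec = PhantomSpec(shape=(24, 24, 20), gwb_thickness_mm=3.0,
                           lesion=LesionSpec(center=(12, 12, 0), radius_mm=6.0,
                                             thickness_multiplier=2.0), seed=0)
        b = make_slab_phantom(spec)
        f = solve_laplace(b.truth_labels, rel_tol=1e-9, max_iter=8000)
        wm = compute_width_map(f, b.truth_labels)
        W = wm.width.data
        les = b.lesion_mask.data > 0
        non = (b.truth_width.data > 0) & ~les
        assert W[les & (W > 0)].mean() > W[non & (W > 0)].mean()

    def test_empty_gwb_gives_zero_map(self, column_labels, column_field):
        lab = Volume(np.full((2, 2, 2), LABEL_GM, np.uint8), role="label")
        wm = compute_width_map(column_field, lab)
        assert not wm.width.data.any() and wm.stats is None

    def test_width_zero_outside_gwb(self, column_field, column_labels):
        wm = compute_width_map(column_field, column_labels)
        outside = column_labels.data != LABEL_GWB
        assert not wm.width.data[outside].any()

    def test_deterministic(self, column_field, column_labels):
        a = compute_width_map(column_field, column_labels)
        b = compute_width_map(column_field, column_labels)
        assert np.array_equal(a.width.data, b.width.data)
        assert np.array_equal(a.status_map.data, b.status_map.data)

    def test_six_neighbourhood_supported(self, column_field, column_labels):
        wm = compute_width_map(column_field, column_labels, neighborhood=6)
        assert np.allclose(wm.width.data[0, 0, 1:4], 4.0)

    def test_rotated_slab_width_close_to_axis_aligned(self):
        n, w = 40, 5.0
        idx = np.indices((n, n, n)).astype(float)
        proj = (idx[0] + idx[1]) / np.sqrt(2)
        c = proj.mean()
        lab = np.full((n, n, n), LABEL_GM, np.uint8)
        lab[proj >= c + w / 2] = LABEL_WM
        lab[(proj > c - w / 2) & (proj < c + w / 2)] = LABEL_GWB
        labv = Volume(lab, role="label")
        f = solve_laplace(labv, rel_tol=1e-8, max_iter=8000)
        wm = compute_width_map(f, labv)
        W = wm.width.data
        interior = np.zeros_like(W, dtype=bool)
        interior[6:-6, 6:-6, 6:-6] = True
        rotated_mean = W[(lab == LABEL_GWB) & interior & (W > 0)].mean()
        assert abs(rotated_mean - 6.0) / 6.0 < 0.15  # vs the axis-aligned value w+1


class TestRegionStats:
    def _width_map(self, values):
        w = np.zeros((1, 1, len(values)), np.float32)
        w[0, 0, :] = values
        wv = Volume(w, role="width")
        sv = Volume(np.zeros_like(w, dtype=np.uint8), role="label")
        return WidthMap(wv, sv, None)

    def test_hand_statistics(self):
        wm = self._width_map([2.0, 2.0, 4.0])
        region = Volume(np.ones((1, 1, 3), np.uint8), role="mask")
        s = region_stats(wm, region)
        assert s.mean == pytest.approx(8 / 3)
        assert (s.min, s.max, s.mode, s.n_voxels) == (2.0, 4.0, 2.0, 3)

    def test_disjoint_region_rejected(self):
        wm = self._width_map([2.0, 2.0, 4.0])
        region = Volume(np.zeros((1, 1, 3), np.uint8), role="mask")
        with pytest.raises(EmptyRegionError):
            region_stats(wm, region)

    def test_stats_ignore_outside_region(self):
        wm = self._width_map([2.0, 9.0, 4.0])
        region = Volume(np.array([[[1, 0, 1]]], np.uint8), role="mask")
        s = region_stats(wm, region)
        assert s.max == 4.0 and s.mean == pytest.approx(3.0)

    def test_mode_tie_goes_to_smallest(self):
        wm = self._width_map([2.0, 2.0, 4.0, 4.0])
        region = Volume(np.ones((1, 1, 4), np.uint8), role="mask")
        assert region_stats(wm, region).mode == 2.0
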