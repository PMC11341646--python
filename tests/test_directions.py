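"""Direction detection, pruning cascade and the vector-field smoother."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from scipy.sparse.linalg import spsolve

from penna3d.core import (
    DirectionField,
    MaskVolume,
    PruneParams,
    SmoothParams,
    Volume,
    folded_angle_deg,
)
from penna3d.directions import (
    MuscleFrame,
    canonical_sign,
    direction_field,
    fascicle_mask,
    fill_muscle,
    muscle_frame,
    prune_endpoints,
    rotate_mask,
    rotate_volume,
    scale_and_prune_lengths,
    smooth_field,
    smoothn,
)

from conftest import make_cylinder_volume


# ---------------------------------------------------------------------------
# muscle frame

def cuboid_mask(shape=(12, 20, 40), sub=None):
    m = np.zeros(shape, dtype=bool)
    sub = sub or (slice(2, -2), slice(2, -2), slice(2, -2))
    m[sub] = True
    return MaskVolume(m)


class TestMuscleFrame:
    def test_axis_aligned_cuboid_identity(self):
        frame = muscle_frame(cuboid_mask())
        # z is the long axis, y the second: rotation is the identity
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-9)

    def test_rotated_cuboid_recovered(self):
        # rotate an anisotropic point cloud 25 degrees about x and check
        # the recovered axes against the closed-form covariance eigenvectors
        a = np.radians(25)
        R = np.array([[1, 0, 0],
                      [0, np.cos(a), -np.sin(a)],
                      [0, np.sin(a), np.cos(a)]])
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (4000, 3)) * np.array([2.0, 5.0, 20.0]) @ R.T
        # embed as a mask by binning points into a fine grid
        spacing = 0.5
        idx = np.round((pts - pts.min(axis=0)) / spacing).astype(int)
        shape = tuple(idx.max(axis=0) + 1)
        m = np.zeros(shape, dtype=bool)
        m[tuple(idx.T)] = True
        frame = muscle_frame(MaskVolume(m, (spacing,) * 3))
        long_axis = frame.rotation[:, 2]
        expected = R @ np.array([0, 0, 1.0])
        assert folded_angle_deg(long_axis, expected) < 1.0

    def test_spherical_mask_errors(self):
        n = 21
        x = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        ball = X ** 2 + Y ** 2 + Z ** 2 <= 8 ** 2
        with pytest.raises(ValueError, match="degenerate"):
            muscle_frame(MaskVolume(ball))
        muscle_frame(MaskVolume(ball), allow_degenerate=True)  # documented escape

    def test_too_few_voxels_errors(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[0, 0, 0] = True
        with pytest.raises(ValueError):
            muscle_frame(MaskVolume(m))


class TestRotateVolume:
    def test_identity_frame_bitwise(self, rng):
        vol = Volume(rng.uniform(0, 255, (10, 10, 10)))
        frame = MuscleFrame(np.eye(3), np.zeros(3))
        out = rotate_volume(vol, frame)
        assert np.array_equal(out.data, vol.data)

    def test_round_trip_smooth_content(self):
        # a smooth Gaussian ball rotated forth and back: the composition
        # is a pure grid translation, recovered from the centers of mass
        from scipy.ndimage import center_of_mass, map_coordinates
        n = 31
        x = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        ball = 200.0 * np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / (2 * 6.0 ** 2))
        vol = Volume(ball)
        a = np.radians(20)
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0],
                      [0, 0, 1]])
        centroid = vol.world_coords(np.array([n // 2] * 3, dtype=float))
        rot = rotate_volume(vol, MuscleFrame(R, centroid))
        back = rotate_volume(rot, MuscleFrame(R.T, centroid))
        shift = np.array(center_of_mass(back.data)) - np.array(
            center_of_mass(vol.data))
        core = np.argwhere(np.ones((15, 15, 15), bool)).reshape(15, 15, 15, 3) + 8
        src = core + shift
        got = map_coordinates(back.data, [src[..., 0], src[..., 1], src[..., 2]],
                              order=1)
        ref = vol.data[8:-8, 8:-8, 8:-8]
        assert np.mean(np.abs(got - ref)) < 2.0

    def test_mask_count_roughly_conserved(self):
        mask = cuboid_mask((24, 18, 30))
        a = np.radians(30)
        R = np.array([[1, 0, 0],
                      [0, np.cos(a), -np.sin(a)],
                      [0, np.sin(a), np.cos(a)]])
        frame = MuscleFrame(R, np.array([11.5, 8.5, 14.5]))
        rot = rotate_mask(mask, frame)
        assert abs(rot.count() - mask.count()) / mask.count() < 0.01


class TestDirectionField:
    def test_cylinder_along_z(self):
        vol, d = make_cylinder_volume(direction=(0, 0, 1))
        field = direction_field(vol, hessian_sigma=2.0)
        center = field.vectors[20, 20, 25:35]
        errs = folded_angle_deg(center, d)
        assert np.all(errs < 1.0)

    def test_cylinder_tilted_30deg_in_yz(self):
        vol, d = make_cylinder_volume(direction=(0, np.sin(np.radians(30)),
                                                 np.cos(np.radians(30))))
        field = direction_field(vol, hessian_sigma=2.0)
        center = field.vectors[20, 20, 28:32]
        errs = folded_angle_deg(center, d)
        assert np.all(errs < 1.0)

    def test_isotropic_blob_flagged_degenerate(self):
        n = 31
        x = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        blob = 200 * np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / (2 * 4.0 ** 2))
        field = direction_field(Volume(blob), hessian_sigma=2.0)
        assert field.degenerate[n // 2, n // 2, n // 2]

    def test_signed_mode_differs_on_tube(self):
        vol, d = make_cylinder_volume(direction=(0, 0, 1))
        literal = direction_field(vol, hessian_sigma=2.0, mode="signed")
        v = literal.vectors[20, 20, 30]
        # the signed-minimum eigenvector lies across, not along, the tube
        assert folded_angle_deg(v, d) > 45.0

    def test_sign_canonicalization(self, rng):
        v = rng.normal(size=(100, 3))
        out = canonical_sign(v, (0, 0, 1))
        assert np.all(out[:, 2] >= -1e-12)
        # axial equivalence: flipping inputs changes nothing
        np.testing.assert_allclose(canonical_sign(-v, (0, 0, 1)), out)


class TestFascicleMask:
    def test_threshold_is_fraction_of_max(self):
        data = np.zeros((8, 8, 8))
        data[2, 2, 2] = 200.0
        data[3, 3, 3] = 20.0   # exactly 10% of max: kept (inclusive)
        data[4, 4, 4] = 19.99
        vol = Volume(data)
        comp = MaskVolume(np.ones((8, 8, 8), dtype=bool))
        p = PruneParams(shrink_voxels=0)
        out = fascicle_mask(vol, comp, p)
        assert out.data[2, 2, 2] and out.data[3, 3, 3]
        assert not out.data[4, 4, 4]

    def test_shrink_zero_leaves_compartment(self):
        data = np.full((6, 6, 6), 100.0)
        comp_arr = np.zeros((6, 6, 6), dtype=bool)
        comp_arr[1:5, 1:5, 1:5] = True
        out = fascicle_mask(Volume(data), MaskVolume(comp_arr),
                            PruneParams(shrink_voxels=0))
        np.testing.assert_array_equal(out.data, comp_arr)

    def test_shrink_erodes_compartment(self):
        data = np.full((8, 8, 8), 100.0)
        comp_arr = np.zeros((8, 8, 8), dtype=bool)
        comp_arr[1:7, 1:7, 1:7] = True
        out = fascicle_mask(Volume(data), MaskVolume(comp_arr),
                            PruneParams(shrink_voxels=1))
        inner = np.zeros_like(comp_arr)
        inner[2:6, 2:6, 2:6] = True
        np.testing.assert_array_equal(out.data, inner)

    def test_all_zero_volume_errors(self):
        with pytest.raises(ValueError):
            fascicle_mask(Volume(np.zeros((6, 6, 6))),
                          MaskVolume(np.ones((6, 6, 6), dtype=bool)),
                          PruneParams())


def uniform_field(shape, vec, spacing=(1.0, 1.0, 1.0)):
    v = np.tile(np.asarray(vec, dtype=float), shape + (1,))
    return DirectionField(v, spacing)


class TestScaleAndPrune:
    def test_scaling_by_voxel_sizes(self):
        # a unit +z vector picks up the slice distance as its length
        f = uniform_field((4, 4, 4), (0, 0, 1))
        mask = MaskVolume(np.ones((4, 4, 4), dtype=bool))
        out = scale_and_prune_lengths(f, mask, (0.17, 0.17, 0.66), 0.5)
        assert out.n_support() == 64  # all survive, then re-normalized
        np.testing.assert_allclose(out.vectors[0, 0, 0], [0, 0, 1], atol=1e-12)

    def test_orientation_dependent_removal(self):
        # in-plane unit vectors scale to 0.17 < 0.5*0.66 and are removed
        vecs = np.tile(np.array([0.0, 0.0, 1.0]), (4, 4, 4, 1))
        vecs[0, :, :] = (1.0, 0.0, 0.0)
        f = DirectionField(vecs)
        mask = MaskVolume(np.ones((4, 4, 4), dtype=bool))
        out = scale_and_prune_lengths(f, mask, (0.17, 0.17, 0.66), 0.5)
        assert not out.support[0].any()
        assert out.support[1:].all()

    def test_isotropic_spacing_keeps_all(self, rng):
        v = rng.normal(size=(5, 5, 5, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        f = DirectionField(v)
        mask = MaskVolume(np.ones((5, 5, 5), dtype=bool))
        out = scale_and_prune_lengths(f, mask, (1, 1, 1), 0.5)
        assert out.n_support() == 125

    def test_never_increases_support(self, rng):
        v = np.full((6, 6, 6, 3), np.nan)
        sel = rng.random((6, 6, 6)) < 0.5
        v[sel] = (0, 0, 1)
        f = DirectionField(v)
        mask = MaskVolume(np.ones((6, 6, 6), dtype=bool))
        out = scale_and_prune_lengths(f, mask, (0.14, 0.14, 0.37), 0.5)
        assert np.all(out.support <= f.support)


class TestPruneEndpoints:
    def test_dense_interior_kept_isolated_removed(self):
        v = np.full((5, 5, 5, 3), np.nan)
        v[1:4, 1:4, 1:4] = (0, 0, 1)  # dense block: center has 26 neighbors
        v[0, 0, 0] = (0, 0, 1)        # isolated corner voxel
        out = prune_endpoints(DirectionField(v), 18)
        assert out.support[2, 2, 2]
        assert not out.support[0, 0, 0]

    def test_exactly_threshold_neighbors_kept(self):
        # build a voxel with exactly 18 non-missing neighbors
        v = np.full((3, 3, 3, 3), np.nan)
        neigh = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)
                 if (i, j, k) != (1, 1, 1)]
        for (i, j, k) in neigh[:18]:
            v[i, j, k] = (0, 0, 1)
        v[1, 1, 1] = (0, 0, 1)
        out = prune_endpoints(DirectionField(v), 18)
        assert out.support[1, 1, 1]
        # with one neighbor fewer it must be removed
        v[tuple(neigh[17])] = np.nan
        out17 = prune_endpoints(DirectionField(v), 18)
        assert not out17.support[1, 1, 1]

    def test_simultaneous_not_sequential(self):
        # a full 3x3x3 block: faces lose support but the update must use
        # the input field, so the center sees all 26 original neighbors
        v = np.full((3, 3, 3, 3), np.nan)
        v[:, :, :] = (0, 0, 1)
        out = prune_endpoints(DirectionField(v), 18)
        assert out.support[1, 1, 1]
        assert out.n_support() == 1

    @given(st.integers(0, 26))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_support_never_grows(self, thresh):
        rng = np.random.default_rng(thresh)
        v = np.full((6, 6, 6, 3), np.nan)
        sel = rng.random((6, 6, 6)) < 0.6
        v[sel] = (0, 0, 1)
        f = DirectionField(v)
        out = prune_endpoints(f, thresh)
        assert np.all(out.support <= f.support)


# ---------------------------------------------------------------------------
# smoother: independent dense oracle

def lap1(n):
    L = sp.diags([np.ones(n - 1), -2 * np.ones(n), np.ones(n - 1)],
                 [-1, 0, 1]).tolil()
    L[0, 0] = -1
    L[-1, -1] = -1
    return L.tocsr()


def lap_nd(shape):
    mats = [lap1(n) for n in shape]
    eyes = [sp.identity(n) for n in shape]
    total = None
    for ax in range(len(shape)):
        term = None
        for k in range(len(shape)):
            m = mats[k] if k == ax else eyes[k]
            term = m if term is None else sp.kron(term, m)
        total = term if total is None else total + term
    return total.tocsr()


def dense_penalized_solve(y, s):
    """Oracle: solve (W + s L'L) z = W y directly with sparse algebra."""
    shape = y.shape
    L = lap_nd(shape)
    w = np.isfinite(y).ravel().astype(float)
    W = sp.diags(w)
    A = (W + s * (L.T @ L)).tocsc()
    rhs = w * np.nan_to_num(y).ravel()
    return spsolve(A, rhs).reshape(shape)


class TestSmoothn:
    def test_s_zero_identity(self, rng):
        y = rng.normal(size=(6, 5, 4))
        np.testing.assert_allclose(smoothn(y, 0.0), y, atol=1e-10)

    def test_constant_invariant(self):
        y = np.full((8, 8, 8), 3.7)
        np.testing.assert_allclose(smoothn(y, 35.0), y, atol=1e-9)

    @pytest.mark.parametrize("s", [0.5, 5.0, 35.0])
    def test_matches_dense_solve_full_data(self, rng, s):
        y = rng.normal(size=(7, 6, 5))
        np.testing.assert_allclose(smoothn(y, s), dense_penalized_solve(y, s),
                                   atol=1e-8)

    @pytest.mark.parametrize("s", [0.5, 35.0])
    def test_matches_dense_solve_with_missing(self, rng, s):
        y = rng.normal(size=(8, 7, 6))
        miss = rng.random(y.shape) < 0.2
        y[miss] = np.nan
        z = smoothn(y, s, max_iter=50000, tol=1e-14)
        np.testing.assert_allclose(z, dense_penalized_solve(y, s), atol=1e-8)

    def test_1d_ramp_interior_fill_between_neighbors(self):
        y = np.linspace(0.0, 10.0, 11).reshape(11, 1, 1)
        y[5] = np.nan
        z = smoothn(y, 0.1, max_iter=5000, tol=1e-12)
        assert y[4] < z[5, 0, 0] < y[6]

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            smoothn(np.full((4, 4, 4), np.nan), 1.0)


class TestSmoothField:
    def test_s_zero_identity_no_missing(self, rng):
        v = rng.normal(size=(5, 5, 5, 3))
        f = DirectionField(v)
        out = smooth_field(f, 0.0)
        np.testing.assert_allclose(out.vectors, v, atol=1e-10)

    def test_constant_field_unchanged(self):
        f = uniform_field((6, 6, 6), (0.0, 0.6, 0.8))
        out = smooth_field(f, 35.0)
        np.testing.assert_allclose(out.vectors, f.vectors, atol=1e-8)

    def test_extrapolates_missing(self):
        v = np.full((6, 6, 6, 3), np.nan)
        v[1:5, 1:5, 1:5] = (0.0, 0.0, 1.0)
        out = smooth_field(DirectionField(v), 1.0)
        assert np.isfinite(out.vectors).all()


class TestFillMuscle:
    def test_uniform_field_fills_uniformly(self):
        v = np.full((8, 8, 8, 3), np.nan)
        rng = np.random.default_rng(1)
        sel = rng.random((8, 8, 8)) < 0.3
        sel[0, 0, 0] = sel[7, 7, 7] = sel[0, 7, 3] = sel[7, 0, 4] = True
        v[sel] = (0.0, 0.0, 1.0)
        mask = MaskVolume(np.ones((8, 8, 8), dtype=bool))
        out = fill_muscle(DirectionField(v), mask, SmoothParams())
        assert out.n_support() == 512
        np.testing.assert_allclose(out.vectors[..., 2], 1.0, atol=1e-6)

    def test_linear_component_exact_in_hull(self):
        # a linearly varying y-component is reproduced exactly by linear
        # interpolation inside the support's convex hull
        n = 10
        v = np.full((n, n, n, 3), np.nan)
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        comp_y = 0.01 * ii + 0.02 * jj + 0.03 * kk
        rng = np.random.default_rng(2)
        sel = rng.random((n, n, n)) < 0.4
        for c in [(0, 0, 0), (0, 0, n - 1), (0, n - 1, 0), (n - 1, 0, 0),
                  (n - 1, n - 1, n - 1), (n - 1, n - 1, 0), (n - 1, 0, n - 1),
                  (0, n - 1, n - 1)]:
            sel[c] = True
        vy = comp_y[sel]
        v[sel] = 0.0
        v[sel, 1] = vy
        v[sel, 2] = 1.0
        mask = MaskVolume(np.ones((n, n, n), dtype=bool))
        out = fill_muscle(DirectionField(v), mask, SmoothParams())
        # compare the (renormalized) ratio y/z which is invariant to norm
        ratio = out.vectors[..., 1] / out.vectors[..., 2]
        np.testing.assert_allclose(ratio, comp_y, atol=1e-6)

    def test_every_mask_voxel_filled(self):
        v = np.full((9, 9, 9, 3), np.nan)
        v[3:6, 3:6, 3:6] = (0.0, 0.1, 0.9)
        mask_arr = np.zeros((9, 9, 9), dtype=bool)
        mask_arr[1:8, 1:8, 1:8] = True
        out = fill_muscle(DirectionField(v), MaskVolume(mask_arr), SmoothParams())
        assert np.all(out.support[mask_arr])
        assert not out.support[~mask_arr].any()
        norms = np.linalg.norm(out.vectors[mask_arr], axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_insufficient_support_errors(self):
        v = np.full((6, 6, 6, 3), np.nan)
        v[0, 0, 0] = v[1, 1, 0] = v[2, 2, 0] = v[3, 3, 0] = (0, 0, 1)  # coplanar
        with pytest.raises(ValueError, match="support"):
            fill_muscle(DirectionField(v),
                        MaskVolume(np.ones((6, 6, 6), dtype=bool)), SmoothParams())
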