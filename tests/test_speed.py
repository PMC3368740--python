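"""Speed-function tests: gates, neighbor selection, trace similarity.

The per-pair summand FA(r) FA(n) tr(D D') / (tr D tr D') must lie in
[0, 1] for PSD tensors since tr(D D') <= tr D * tr D' and FA <= 1.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccdtiseg.dti_io import TensorVolume
from ccdtiseg.levelset import LevelSetState
from ccdtiseg.phantom import PhantomSpec, generate_cc_phantom
from ccdtiseg.speed import (
    NEIGHBOR_OFFSETS,
    SpeedParams,
    collinear_neighbors,
    compute_speed_field,
    gate,
    similarity_speed,
    surface_normals,
)
from ccdtiseg.tensor_features import FAField, PDDField, compute_feature_fields


def prolate(direction, l1=1.7e-3, l2=0.3e-3):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return (l1 - l2) * np.outer(d, d) + l2 * np.eye(3)


class TestSpeedParams:
    def test_defaults_are_the_operating_point(self):
        p = SpeedParams()
        assert (p.pdd_x_threshold, p.collinearity_threshold) == (0.55, 0.7)
        assert (p.fa_threshold, p.f_threshold) == (0.1, 0.05)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            SpeedParams(pdd_x_threshold=1.5)
        with pytest.raises(ValueError):
            SpeedParams(f_threshold=-0.1)


class TestSurfaceNormals:
    def test_sphere_normals_radial(self):
        g = np.meshgrid(*[np.arange(30, dtype=float)] * 3, indexing="ij")
        phi = np.sqrt(sum((x - 15.0) ** 2 for x in g)) - 8.0
        vox = np.argwhere(np.abs(phi) < 0.5)
        normals = surface_normals(phi, vox)
        radial = (vox - 15.0) / np.linalg.norm(vox - 15.0, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", normals, radial)
        assert dots.min() > 1.0 - 1e-2

    def test_plane_normal_exact(self):
        x = np.arange(20, dtype=float)
        phi = np.broadcast_to((x - 10.0)[:, None, None], (20, 20, 20)).copy()
        n = surface_normals(phi, np.array([[10, 10, 10]]))
        assert np.allclose(n, [[1, 0, 0]])

    def test_flat_phi_skipped(self):
        n = surface_normals(np.zeros((5, 5, 5)), np.array([[2, 2, 2]]))
        assert np.allclose(n, 0.0)


class TestCollinearNeighbors:
    def test_positive_x_default_cone_has_nine(self):
        # face +x, its 4 edge diagonals, and 4 corner diagonals (1/sqrt(3)
        # = 0.577 > 0.5) minus the 4 edge diagonals outside... enumerate:
        nbrs = collinear_neighbors((5, 5, 5), np.array([1.0, 0, 0]), SpeedParams())
        offsets = nbrs - np.array([5, 5, 5])
        # oracle: brute-force the rule over all 26 offsets
        expected = []
        for o in NEIGHBOR_OFFSETS:
            u = o / np.linalg.norm(o)
            if u[0] > 0.5:
                expected.append(tuple(o))
        assert sorted(map(tuple, offsets)) == sorted(expected)
        assert len(offsets) == 9

    def test_strict_cone_keeps_only_face_neighbor(self):
        p = SpeedParams(normal_collinearity_cos=0.99)
        nbrs = collinear_neighbors((5, 5, 5), np.array([1.0, 0, 0]), p)
        assert np.array_equal(nbrs, [[6, 5, 5]])

    def test_grid_face_bounds(self):
        nbrs = collinear_neighbors(
            (0, 0, 0), np.array([-1.0, 0, 0]), SpeedParams(), grid_shape=(5, 5, 5)
        )
        assert len(nbrs) == 0


def _fields_from(tensors):
    tv = TensorVolume(tensors=tensors)
    fa, pdd = compute_feature_fields(tv)
    return tv, fa, pdd


class TestGate:
    def setup_method(self):
        t = np.zeros((3, 3, 3, 3, 3))
        t[...] = prolate([1, 0, 0])
        self.tv, self.fa, self.pdd = _fields_from(t)

    def test_identical_left_right_tensors_pass(self):
        assert gate((1, 1, 1), (2, 1, 1), self.fa, self.pdd, SpeedParams())

    def test_orthogonal_pdds_fail_collinearity(self):
        t = np.zeros((3, 3, 3, 3, 3))
        t[...] = prolate([1, 0, 0])
        t[2, 1, 1] = prolate([0, 1, 0])
        _, fa, pdd = _fields_from(t)
        assert not gate((1, 1, 1), (2, 1, 1), fa, pdd, SpeedParams())

    def test_oblique_pdd_fails_x_gate_regardless_of_neighbor(self):
        t = np.zeros((3, 3, 3, 3, 3))
        t[...] = prolate([0.5, 0.87, 0])  # |PDD_x| = 0.5 < 0.55
        _, fa, pdd = _fields_from(t)
        for off in ((2, 1, 1), (1, 2, 1), (0, 1, 1)):
            assert not gate((1, 1, 1), off, fa, pdd, SpeedParams())

    def test_undefined_pdd_fails(self):
        t = np.zeros((3, 3, 3, 3, 3))
        t[1, 1, 1] = prolate([1, 0, 0])
        _, fa, pdd = _fields_from(t)
        assert not gate((1, 1, 1), (2, 1, 1), fa, pdd, SpeedParams())


class TestSimilaritySpeed:
    def test_rank_one_unit_tensor_pair_sums_to_one(self):
        t = np.zeros((3, 3, 3, 3, 3))
        t[...] = np.zeros((3, 3))
        t[1, 1, 1] = np.outer([1, 0, 0], [1, 0, 0])  # rank-1, unit eigenvalue
        t[2, 1, 1] = np.outer([1, 0, 0], [1, 0, 0])
        tv, fa, _ = _fields_from(t)
        val = similarity_speed((1, 1, 1), [(2, 1, 1)], tv, fa, SpeedParams())
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_tensors_give_zero(self):
        t = np.tile(0.8e-3 * np.eye(3), (3, 3, 3, 1, 1))
        tv, fa, _ = _fields_from(t)
        assert similarity_speed((1, 1, 1), [(2, 1, 1)], tv, fa, SpeedParams()) == 0.0

    def test_f_threshold_floors_small_speeds(self):
        t = np.tile(prolate([1, 0, 0]), (3, 3, 3, 1, 1))
        tv, fa, _ = _fields_from(t)
        raw = similarity_speed((1, 1, 1), [(2, 1, 1)], tv, fa, SpeedParams(f_threshold=0.0))
        assert raw > 0
        floored = similarity_speed(
            (1, 1, 1), [(2, 1, 1)], tv, fa, SpeedParams(f_threshold=raw + 0.01)
        )
        assert floored == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_summand_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        t = np.zeros((3, 3, 3, 3, 3))
        t[1, 1, 1] = a @ a.T
        t[2, 1, 1] = b @ b.T
        tv, fa, _ = _fields_from(t)
        val = similarity_speed(
            (1, 1, 1), [(2, 1, 1)], tv, fa, SpeedParams(f_threshold=0.0)
        )
        assert 0.0 <= val <= 1.0 + 1e-12

    def test_summand_symmetric_in_pair(self):
        rng = np.random.default_rng(77)
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        t = np.zeros((3, 3, 3, 3, 3))
        t[1, 1, 1] = a @ a.T
        t[2, 1, 1] = b @ b.T
        tv, fa, _ = _fields_from(t)
        p = SpeedParams(f_threshold=0.0)
        assert similarity_speed((1, 1, 1), [(2, 1, 1)], tv, fa, p) == pytest.approx(
            similarity_speed((2, 1, 1), [(1, 1, 1)], tv, fa, p), abs=1e-14
        )


class TestComputeSpeedField:
    @pytest.fixture(scope="class")
    def phantom(self):
        truth = generate_cc_phantom(PhantomSpec(grid_shape=(48, 72, 48)))
        fa, pdd = compute_feature_fields(truth.tensors)
        return truth, fa, pdd

    def _state_around(self, truth, point, radius=2.0):
        g = np.meshgrid(
            *[np.arange(s, dtype=float) for s in truth.tensors.shape], indexing="ij"
        )
        phi = np.sqrt(sum((x - c) ** 2 for x, c in zip(g, point))) - radius
        return LevelSetState(phi=phi)

    def test_positive_inside_bundle(self, phantom):
        truth, fa, pdd = phantom
        seed = truth.seeds_suggested.points[len(truth.seeds_suggested.points) // 2]
        state = self._state_around(truth, seed)
        field = compute_speed_field(state, truth.tensors, fa, pdd, SpeedParams())
        assert field.values.max() > 0

    def test_zero_toward_isotropic_background(self, phantom):
        truth, fa, pdd = phantom
        state = self._state_around(truth, (8.0, 10.0, 10.0))  # background corner
        field = compute_speed_field(state, truth.tensors, fa, pdd, SpeedParams())
        assert field.values.max() == 0.0

    def test_zero_at_cingulum_interface(self, phantom):
        truth, fa, pdd = phantom
        # sphere around a cingulum voxel: orthogonal PDD everywhere nearby
        cing = np.argwhere(truth.distractor_labels == 1)
        center = cing.mean(axis=0)
        state = self._state_around(truth, center)
        field = compute_speed_field(state, truth.tensors, fa, pdd, SpeedParams())
        cing_mask = truth.distractor_labels == 1
        assert field.values[cing_mask].max() == 0.0

    def test_empty_band_halts(self, phantom):
        truth, fa, pdd = phantom
        state = LevelSetState(phi=np.full(truth.tensors.shape, 10.0))
        field = compute_speed_field(state, truth.tensors, fa, pdd, SpeedParams())
        assert field.values.max() == 0.0

    def test_speed_bounded_by_neighborhood_size(self, phantom):
        truth, fa, pdd = phantom
        seed = truth.seeds_suggested.points[0]
        state = self._state_around(truth, seed, radius=3.0)
        field = compute_speed_field(state, truth.tensors, fa, pdd, SpeedParams())
        assert field.values.max() <= 26.0
        assert field.values.min() >= 0.0
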