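import numpy as np
import pytest

from porescope import (DensityVolume, PointModel, RigidTransform, cam_score,
                       fit_significance, global_fit, local_optimize,
                       overlap_score, simulate_map_from_model, subtract_density)
from porescope.fitting import FitResult, read_point_model
from porescope._transforms import rotation_angle_between
from porescope.errors import (DegenerateDistributionError,
                              DegenerateOverlapError, ParameterError)


def _model(points, weights=None):
    points = np.asarray(points, dtype=float)
    w = np.ones(len(points)) if weights is None else np.asarray(weights)
    return PointModel(points, np.array(["A"] * len(points)), w)


@pytest.fixture(scope="module")
def spiral_model():
    """Compact conical spiral: asymmetric, smooth orientation landscape."""
    t = np.linspace(0, 4.2, 16)
    pts = np.column_stack([(25 + 9 * t) * np.cos(t), (25 + 9 * t) * np.sin(t),
                           16 * t - 35])
    return _model(pts)


@pytest.fixture(scope="module")
def spiral_map(spiral_model):
    return simulate_map_from_model(spiral_model, 25.0, (48, 48, 48), 4.0)


class TestSimulateMap:
    def test_unit_point_normalization_and_peak(self):
        m = _model([[0.0, 0.0, 0.0]])
        v = simulate_map_from_model(m, 20.0, (32, 32, 32), 2.0)
        integral = v.data.sum() * 2.0 ** 3
        assert integral == pytest.approx(1.0, abs=0.01)
        assert np.unravel_index(np.argmax(v.data), v.shape) == (16, 16, 16)

    def test_mirrored_points_give_a_mirror_symmetric_map(self):
        m = _model([[12.0, 0.0, 0.0], [-12.0, 0.0, 0.0]])
        v = simulate_map_from_model(m, 20.0, (33, 33, 33), 2.0)
        assert np.allclose(v.data, v.data[::-1, :, :], atol=1e-7)

    def test_doubling_resolution_scales_the_peak_by_eight(self):
        m = _model([[0.0, 0.0, 0.0]])
        fine = simulate_map_from_model(m, 20.0, (48, 48, 48), 2.0)
        coarse = simulate_map_from_model(m, 40.0, (48, 48, 48), 2.0)
        assert fine.data.max() / coarse.data.max() == pytest.approx(8.0, rel=0.02)

    def test_empty_model_and_undersampling_rejected(self):
        with pytest.raises(ParameterError):
            simulate_map_from_model(_model([[0, 0, 0]]), 2.0, (16,) * 3, 4.0)


class TestScores:
    def test_cam_of_identical_maps_is_one(self, spiral_map):
        assert cam_score(spiral_map, spiral_map) == pytest.approx(1.0, abs=1e-7)

    def test_cam_of_negated_map_is_minus_one(self, spiral_map):
        neg = spiral_map.copy_with(-spiral_map.data)
        assert cam_score(neg, spiral_map) == pytest.approx(-1.0, abs=1e-7)

    def test_cam_against_noise_is_small(self, spiral_map, rng):
        noise = spiral_map.copy_with(
            rng.normal(size=spiral_map.shape).astype(np.float32))
        n = int((spiral_map.data > 0).sum())
        assert abs(cam_score(noise, spiral_map)) < 3.0 / np.sqrt(n)

    def test_cam_is_invariant_under_affine_intensity_rescaling(self, spiral_map, rng):
        target = spiral_map.copy_with(
            spiral_map.data + 0.2 * rng.normal(size=spiral_map.shape).astype(np.float32))
        base = cam_score(target, spiral_map)
        scaled = target.copy_with((3.7 * target.data + 1.2).astype(np.float32))
        assert abs(cam_score(scaled, spiral_map) - base) < 1e-6

    def test_cam_needs_a_region(self, spiral_map):
        tiny = spiral_map.copy_with(np.zeros(spiral_map.shape, dtype=np.float32))
        with pytest.raises(DegenerateOverlapError):
            cam_score(spiral_map, tiny)

    def test_overlap_inside_outside_and_half(self):
        shape, vox = (40, 40, 40), 2.0
        blob_a = simulate_map_from_model(_model([[-20.0, 0, 0]]), 16.0, shape, vox)
        blob_b = simulate_map_from_model(_model([[20.0, 0, 0]]), 16.0, shape, vox)
        model_map = blob_a.copy_with(blob_a.data + blob_b.data)
        ones = blob_a.copy_with(np.ones(shape, dtype=np.float32))
        assert overlap_score(ones, model_map, 0.5) == pytest.approx(1.0)
        zeros = blob_a.copy_with(np.zeros(shape, dtype=np.float32))
        assert overlap_score(zeros, model_map, 0.5) == pytest.approx(0.0)
        # target covers only the half-space holding one of two equal blobs
        half = np.zeros(shape, dtype=np.float32)
        half[:20] = 1.0
        assert overlap_score(blob_a.copy_with(half), model_map, 0.5) == \
            pytest.approx(0.5, abs=0.02)

    def test_overlap_requires_model_mass(self, spiral_map):
        empty = spiral_map.copy_with(np.zeros(spiral_map.shape, dtype=np.float32))
        with pytest.raises(DegenerateOverlapError):
            overlap_score(spiral_map, empty, 0.5)


class TestLocalOptimize:
    def test_optimum_is_a_fixed_point(self, spiral_map, spiral_model):
        res = local_optimize(spiral_map, spiral_model, RigidTransform())
        assert res.cam >= cam_score(
            spiral_map, simulate_map_from_model(spiral_model, 25.0,
                                                spiral_map.shape, 4.0)) - 1e-9
        assert rotation_angle_between(np.eye(3), res.transform.matrix) < 1.0

    def test_displaced_start_converges_back(self, spiral_map, spiral_model):
        init = RigidTransform((0.0, 0.0, 0.0), (12.0, -4.0, 8.0))  # 3 voxels off
        res = local_optimize(spiral_map, spiral_model, init, max_steps=600)
        assert np.linalg.norm(res.transform.translation) < 2.0  # within 0.5 voxel
        assert res.cam > 0.99

    def test_start_outside_the_map_raises(self, spiral_map, spiral_model):
        init = RigidTransform((0.0, 0.0, 0.0), (500.0, 500.0, 500.0))
        with pytest.raises(DegenerateOverlapError):
            local_optimize(spiral_map, spiral_model, init)


class TestGlobalFit:
    def test_single_placement_returns_one_cluster(self, spiral_map, spiral_model):
        clusters = global_fit(spiral_map, spiral_model, 1, seed=3)
        assert len(clusters) == 1

    def test_self_fit_recovers_identity_across_seeds(self, spiral_map, spiral_model):
        for seed in (7, 11, 23):
            clusters = global_fit(spiral_map, spiral_model, 400, seed=seed)
            top = clusters[0]
            assert top.cam > 0.99
            assert rotation_angle_between(np.eye(3), top.transform.matrix) < 3.0
            assert np.linalg.norm(top.transform.translation) < 4.0  # one voxel

    def test_c2_symmetric_model_scores_degenerately(self, spiral_model):
        """For a model with an exact C2 axis the two symmetry-related fits
        are score-degenerate."""
        pts = np.vstack([spiral_model.points,
                         spiral_model.points @ np.diag([-1.0, -1.0, 1.0])])
        model = _model(pts)  # exact C2 about z
        target = simulate_map_from_model(model, 25.0, (48, 48, 48), 4.0)
        clusters = global_fit(target, model, 200, seed=5)
        top = clusters[0]
        mate = RigidTransform((180.0, 0.0, 0.0), (0.0, 0.0, 0.0)).compose(
            top.transform)
        polished_mate = local_optimize(target, model, mate)
        assert abs(top.cam - polished_mate.cam) < 1e-3

    def test_invalid_count_rejected(self, spiral_map, spiral_model):
        with pytest.raises(ParameterError):
            global_fit(spiral_map, spiral_model, 0, seed=1)


class TestSignificance:
    def _clusters(self, scores):
        return [FitResult(RigidTransform(), cam, 0.0) for cam in scores]

    def test_two_clusters_give_unit_z_scores(self):
        out = fit_significance(self._clusters([0.9, 0.4]))
        assert out[0].z == pytest.approx(1.0)
        assert out[1].z == pytest.approx(-1.0)
        assert out[0].p == pytest.approx(0.3173, abs=1e-3)

    def test_bh_step_up_hand_example(self):
        # p = (0.005, 0.04, 0.2) -> q = (0.015, 0.06, 0.2)
        from statsmodels.stats.multitest import multipletests
        q = multipletests([0.005, 0.04, 0.2], method="fdr_bh")[1]
        assert np.allclose(q, [0.015, 0.06, 0.2])

    def test_bh_matches_brute_force_step_up(self, rng):
        """Benjamini-Hochberg as used in fit_significance equals the step-up
        definition computed directly."""
        for _ in range(20):
            m = rng.integers(2, 15)
            scores = rng.uniform(0, 1, m)
            while np.std(scores) == 0:
                scores = rng.uniform(0, 1, m)
            out = fit_significance(self._clusters(list(scores)))
            p = np.array([r.p for r in out])
            # brute force step-up: q_(i) = min_{j>=i} ( m p_(j) / j )
            order = np.argsort(p)
            ranked = p[order]
            q_sorted = np.minimum.accumulate(
                (len(p) * ranked / np.arange(1, len(p) + 1))[::-1])[::-1]
            q_expected = np.empty_like(q_sorted)
            q_expected[order] = np.clip(q_sorted, 0, 1)
            q_actual = np.array([r.q for r in out])
            assert np.allclose(q_actual, q_expected, atol=1e-12)
            assert (q_actual >= p - 1e-12).all()

    def test_equal_scores_are_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            fit_significance(self._clusters([0.5, 0.5, 0.5]))


class TestSubtractDensity:
    def test_zero_radius_changes_nothing(self, spiral_map, spiral_model):
        out = subtract_density(spiral_map, spiral_model, 0.0)
        assert np.array_equal(out.data, spiral_map.data)

    def test_huge_radius_blanks_the_map(self, spiral_map, spiral_model):
        out = subtract_density(spiral_map, spiral_model, 1000.0)
        assert not out.data.any()

    def test_zeroed_count_matches_the_voxelized_sphere(self):
        v = DensityVolume(np.ones((40, 40, 40), dtype=np.float32), 2.0)
        out = subtract_density(v, _model([[0.0, 0.0, 0.0]]), 12.0)  # 6 voxels
        n_zeroed = int((out.data == 0).sum())
        r = 6.0
        expected = 4.0 / 3.0 * np.pi * r ** 3
        surface = 4.0 * np.pi * r ** 2
        assert abs(n_zeroed - expected) <= surface

    def test_negative_radius_rejected(self, spiral_map, spiral_model):
        with pytest.raises(ParameterError):
            subtract_density(spiral_map, spiral_model, -1.0)


def test_point_model_text_round_trip(tmp_path):
    path = tmp_path / "model.txt"
    path.write_text("# x y z w chain\n0 0 0 1.0 A\n10 5 -3 2.0 B\n")
    m = read_point_model(path)
    assert len(m) == 2
    assert m.weights.tolist() == [1.0, 2.0]
    assert m.chains.tolist() == ["A", "B"]
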