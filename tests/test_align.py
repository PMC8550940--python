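import numpy as np
import pytest
from scipy import ndimage

from porescope import (AlignConfig, SimParams, align_particle, apply_symmetry,
                       average_particles, constrained_cc, iterative_align,
                       simulate_particles, wedge_mask)
from porescope.tables import new_table
from porescope._transforms import (euler_to_matrix, radius_grid,
                                   transform_volume, untransform_volume)
from porescope.errors import DegenerateOverlapError, ParameterError


class TestWedgeMask:
    def test_coverage_fraction_matches_tilt_span(self):
        w = wedge_mask(-52.0, 68.0, (64, 64, 64))
        assert w.coverage_fraction() == pytest.approx(120.0 / 180.0, abs=0.01)

    def test_full_tilt_range_covers_nearly_everything(self):
        # the kx = 0 plane is only sampled at exactly +/-90 degrees, so on a
        # grid the fraction approaches 1 minus one voxel plane
        w = wedge_mask(-89.9, 89.9, (32, 32, 32))
        assert w.coverage_fraction() > 0.95
        assert w.coverage_fraction() > wedge_mask(-52, 68, (32, 32, 32)).coverage_fraction()

    def test_friedel_symmetry_is_exact(self):
        # odd grid: every frequency has a conjugate partner (no unpaired
        # Nyquist planes)
        w = wedge_mask(-52.0, 68.0, (33, 33, 33)).fft_order()
        flipped = np.roll(w[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
        assert np.array_equal(w, flipped)

    def test_invalid_tilt_range_rejected(self):
        with pytest.raises(ParameterError):
            wedge_mask(60.0, -50.0, (16, 16, 16))


class TestConstrainedCC:
    def test_self_correlation_is_one_at_zero_shift(self, rng):
        a = ndimage.gaussian_filter(rng.normal(size=(32, 32, 32)), 2)
        score, shift = constrained_cc(a, a, None, None)
        assert score == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(shift, 0.0, atol=1e-6)

    def test_circular_shift_is_recovered(self, rng):
        a = ndimage.gaussian_filter(rng.normal(size=(32, 32, 32)), 2)
        b = np.roll(a, 3, axis=0)
        score, shift = constrained_cc(a, b, None, None)
        assert score == pytest.approx(1.0, abs=1e-6)
        assert shift == pytest.approx([3.0, 0.0, 0.0], abs=1e-3)

    def test_white_noise_pair_scores_near_zero(self, rng):
        a = rng.normal(size=(48, 48, 48))
        b = rng.normal(size=(48, 48, 48))
        w = wedge_mask(-52.0, 68.0, a.shape)
        score, _ = constrained_cc(a, b, w, w, max_shift=0)
        n_overlap = (w.fft_order() >= 0.5).sum()
        assert abs(score) < 3.0 / np.sqrt(n_overlap)

    def test_equals_plain_cc_under_full_wedges(self, rng):
        """Wedge-constrained CC with full coverage reduces to the ordinary
        mean-removed normalized correlation."""
        a = rng.normal(size=(32, 32, 32))
        b = a + 0.5 * rng.normal(size=(32, 32, 32))
        score, _ = constrained_cc(a, b, None, None, max_shift=0)
        da, db = a - a.mean(), b - b.mean()
        plain = (da * db).sum() / np.sqrt((da ** 2).sum() * (db ** 2).sum())
        assert score == pytest.approx(plain, abs=1e-6)

    def test_empty_overlap_region_raises(self, rng):
        a = rng.normal(size=(16, 16, 16))
        with pytest.raises(DegenerateOverlapError):
            constrained_cc(np.zeros_like(a), a, None, None)


class TestAlignParticle:
    CFG = AlignConfig(angular_step=5.0, rot_range=0.0, tilt_range=0.0,
                      psi_range=None, symmetry=8, max_shift=3.0)

    def test_in_plane_rotation_recovered_within_refined_step(self, mini_phantom):
        ref = mini_phantom.data
        part = transform_volume(ref, euler_to_matrix(0, 0, 33.0), order=3)
        euler, shift, score = align_particle(part, ref, None, self.CFG)
        assert abs(euler[2] - 33.0) <= 1.25  # angular_step / refinement_factor
        assert score > 0.99
        assert np.allclose(shift, 0.0, atol=0.3)

    def test_identity_particle_gives_identity_pose(self, mini_phantom):
        euler, shift, score = align_particle(mini_phantom.data,
                                             mini_phantom.data, None, self.CFG)
        assert euler == (0.0, 0.0, 0.0)
        assert np.allclose(shift, 0.0, atol=1e-6)
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_result_beats_every_coarse_grid_node(self, mini_phantom):
        """Exhaustive-search consistency: the returned pose scores at least
        as well as each node of the coarse angular grid."""
        ref = mini_phantom.data
        w = wedge_mask(-52, 68, ref.shape)
        part = np.fft.ifftn(
            np.fft.fftn(transform_volume(ref, euler_to_matrix(0, 0, 17.0),
                                         (1.0, -1.0, 0.5), order=3))
            * w.fft_order()).real
        euler, shift, best = align_particle(part, ref, w, self.CFG)
        for psi in np.arange(0.0, 45.0, 5.0):
            rotated = transform_volume(ref, euler_to_matrix(0, 0, psi), order=1)
            node, _ = constrained_cc(rotated, part, None, w, max_shift=3.0)
            assert best >= node - 1e-9

    def test_empty_grid_is_a_config_error(self, mini_phantom):
        cfg = AlignConfig(angular_step=-1.0)
        with pytest.raises(ParameterError):
            align_particle(mini_phantom.data, mini_phantom.data, None, cfg)


class TestAverageParticles:
    def test_two_identity_particles_average_to_their_mean(self, rng):
        a = rng.normal(size=(24, 24, 24)).astype(np.float32)
        b = rng.normal(size=(24, 24, 24)).astype(np.float32)
        table = new_table(2)
        res = average_particles([a, b], table, None, order=1)
        assert np.allclose(res.merged.data, (a + b) / 2.0, atol=1e-4)

    def test_single_particle_keeps_its_wedge_region_only(self, mini_phantom, rng):
        w = wedge_mask(-52, 68, mini_phantom.shape)
        part = np.fft.ifftn(np.fft.fftn(mini_phantom.data) * w.fft_order()).real
        table = new_table(2)  # both half sets must be populated
        res = average_particles([part, part], table, w, order=1)
        f = np.fft.fftn(res.merged.data.astype(np.float64))
        out_wedge = w.fft_order() < 0.5
        # single-precision storage leaks ~1e-5 of the peak back into the gap
        assert np.abs(f[out_wedge]).max() < 1e-4 * np.abs(f).max()
        assert np.abs(res.merged.data - part).max() < 1e-3 * np.abs(part).max()

    def test_complementary_wedges_compensate_amplitude(self, mini_phantom):
        """Two particles whose wedges cover complementary regions average to a
        map without systematic spectral loss inside either wedge."""
        w = wedge_mask(-52, 68, mini_phantom.shape)
        # particle 2 is tilted 90 degrees, so its wedge fills the other's gap
        poses = [(0.0, 0.0, 0.0), (0.0, 90.0, 0.0)]
        parts = []
        for rot, tilt, psi in poses:
            moved = transform_volume(mini_phantom.data,
                                     euler_to_matrix(rot, tilt, psi), order=3)
            parts.append(np.fft.ifftn(np.fft.fftn(moved) * w.fft_order()).real)
        table = new_table(2)
        table.loc[1, ["rot", "tilt", "psi"]] = poses[1]
        res = average_particles(parts, table, w, order=3)
        f2 = np.abs(np.fft.fftn(res.merged.data.astype(np.float64))) ** 2
        ref2 = np.abs(np.fft.fftn(mini_phantom.data.astype(np.float64))) ** 2
        in_wedge = w.fft_order() >= 0.5
        shells = radius_grid(mini_phantom.shape)
        band = (np.fft.ifftshift(shells) > 2) & (np.fft.ifftshift(shells) < 12)
        ratio_in = f2[in_wedge & band].sum() / ref2[in_wedge & band].sum()
        ratio_out = f2[~in_wedge & band].sum() / ref2[~in_wedge & band].sum()
        assert 0.8 <= ratio_in / max(ratio_out, 1e-12) <= 1.25

    def test_empty_half_set_raises(self, rng):
        table = new_table(2)
        table["half_set"] = "A"
        with pytest.raises(Exception):
            average_particles([rng.normal(size=(16,) * 3)] * 2, table, None)


class TestApplySymmetry:
    def test_order_one_is_identity(self, rng):
        a = rng.normal(size=(16, 16, 16))
        assert np.array_equal(apply_symmetry(a, 1), a.astype(np.float32))

    def test_idempotence_on_compact_smooth_input(self, mini_phantom):
        s1 = apply_symmetry(mini_phantom.data, 8)
        s2 = apply_symmetry(s1, 8)
        assert np.abs(s2 - s1).max() / np.abs(s1).max() < 0.01

    def test_symmetrization_suppresses_forbidden_harmonics(self, rng):
        """After C8 averaging the m=3 azimuthal harmonic on an equatorial
        ring nearly vanishes while m=8 survives."""
        vol = ndimage.gaussian_filter(rng.normal(size=(48, 48, 48)), 2.0)
        sym = apply_symmetry(vol, 8)
        angles = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        r, c = 12.0, 24.0
        coords = np.stack([c + r * np.cos(angles), c + r * np.sin(angles),
                           np.full_like(angles, c)])
        def harmonics(data):
            ring = ndimage.map_coordinates(data.astype(np.float64), coords, order=3)
            return np.abs(np.fft.rfft(ring)) ** 2
        h_before, h_after = harmonics(vol), harmonics(sym)
        assert h_after[3] < 0.01 * max(h_after[0], h_after[8])
        assert h_after[8] > 0.5 * h_before[8]  # preserved up to interpolation

    def test_rotation_by_symmetry_angle_commutes(self, mini_phantom):
        from porescope._transforms import rotate_about_z
        sym = apply_symmetry(mini_phantom.data, 8)
        rotated = rotate_about_z(sym, 45.0, order=3)
        assert np.abs(rotated - sym).max() / np.abs(sym).max() < 0.02

    def test_invalid_order_rejected(self, rng):
        with pytest.raises(ParameterError):
            apply_symmetry(rng.normal(size=(8, 8, 8)), 0)


class TestIterativeAlign:
    CFG = AlignConfig(angular_step=7.5, binnings=(1,), n_iterations=(2,),
                      tilt_range=0.0, psi_range=None, symmetry=8, max_shift=3.0)

    def _noise_free_stack(self, phantom, n=8, seed=4):
        sim = SimParams(n_particles=n, snr=1e9, pose_jitter=2.0, wobble=10.0,
                        seed=seed)
        return simulate_particles(phantom, sim)

    def test_recovers_wedge_compensated_phantom(self, mini_phantom):
        # random azimuths, true starting poses: the template is crisp from
        # the first average, so alignment must preserve and refine it
        particles, truth = self._noise_free_stack(mini_phantom, n=12)
        w = wedge_mask(-52, 68, mini_phantom.shape)
        res = iterative_align(particles, truth, w, self.CFG)
        # oracle: phantom filtered by the coverage the final poses produced
        oracle = np.fft.ifftn(np.fft.fftn(mini_phantom.data)
                              * res.coverage).real
        oracle = apply_symmetry(oracle, 8)
        sphere = radius_grid(mini_phantom.shape) <= 0.4 * min(mini_phantom.shape)
        cc = np.corrcoef(res.merged.data[sphere], oracle[sphere])[0, 1]
        # ceiling set by the interpolation chain (simulate, back-rotate,
        # symmetrize) on this coarse grid
        assert cc > 0.97

    def test_mean_cc_non_decreasing_on_noise_free_input(self, mini_phantom):
        from porescope.phantom import prealign_poses
        particles, truth = self._noise_free_stack(mini_phantom)
        w = wedge_mask(-52, 68, mini_phantom.shape)
        res = iterative_align(particles, prealign_poses(truth), w, self.CFG)
        ccs = [e["mean_cc"] for e in res.log]
        assert all(b >= a - 0.01 for a, b in zip(ccs, ccs[1:]))
        assert not res.early_stop

    def test_zero_iterations_returns_initial_reference(self, mini_phantom):
        from porescope.phantom import prealign_poses
        import dataclasses
        particles, truth = self._noise_free_stack(mini_phantom, n=4)
        w = wedge_mask(-52, 68, mini_phantom.shape)
        cfg = dataclasses.replace(self.CFG, n_iterations=(0,))
        table = prealign_poses(truth)
        res = iterative_align(particles, table, w, cfg)
        init = average_particles(particles, table, w, order=3)
        expected = apply_symmetry(init.merged.data, 8)
        assert np.allclose(res.merged.data, expected, atol=1e-5)

    def test_seeded_noisy_run_is_deterministic(self, mini_phantom):
        from porescope.phantom import prealign_poses
        sim = SimParams(n_particles=4, snr=0.5, seed=9)
        particles, truth = simulate_particles(mini_phantom, sim)
        w = wedge_mask(-52, 68, mini_phantom.shape)
        cfg = AlignConfig(angular_step=15.0, binnings=(1,), n_iterations=(1,),
                          tilt_range=0.0, psi_range=None, symmetry=8)
        r1 = iterative_align(particles, prealign_poses(truth), w, cfg)
        r2 = iterative_align(particles, prealign_poses(truth), w, cfg)
        assert np.array_equal(r1.merged.data, r2.merged.data)
        assert r1.table.equals(r2.table)
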