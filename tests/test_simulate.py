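"""Simulator: placement, rasterization, Perlin background, PSF, noise, datasets."""

import math
from dataclasses import replace

import numpy as np
import pytest

import upunet as u
from upunet.simulate import (
    BackgroundParams,
    DatasetSpec,
    NoiseParams,
    ParticleField,
    PlacementError,
    VolumeSpec,
    _normalize01,
    gaussian_kernel,
    perlin_octave,
    render_scene,
)
from conftest import make_tiny_spec


# ---------------------------------------------------------------------------
# Particle placement
# ---------------------------------------------------------------------------

class TestPlaceParticles:
    def test_zero_count_gives_empty_field(self, paper_volume):
        field = u.place_particles(paper_volume, (0, 0), 2.0, seed=0)
        assert field.count == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_study_setting_counts_and_separation(self, paper_volume, seed):
        """10-15 beads of 2 um radius in 76x76x5 um, no pairwise intersection."""
        field = u.place_particles(paper_volume, (10, 15), 2.0, seed=seed)
        assert 10 <= field.count <= 15
        # exhaustive O(p^2) pairwise oracle
        for i in range(field.count):
            for j in range(i + 1, field.count):
                d = np.linalg.norm(field.centers[i] - field.centers[j])
                assert d >= field.radii[i] + field.radii[j]

    def test_centers_inside_volume(self, paper_volume):
        field = u.place_particles(paper_volume, (10, 15), 2.0, seed=5)
        lo = field.centers.min(axis=0)
        hi = field.centers.max(axis=0)
        assert (lo >= 0).all()
        assert (hi <= [paper_volume.Dx, paper_volume.Dy, paper_volume.Dz]).all()

    def test_crowded_volume_raises(self):
        vol = VolumeSpec(Dx=10.0, Dy=10.0, Dz=4.0, n=32, nz=4)
        with pytest.raises(PlacementError, match="crowded"):
            u.place_particles(vol, (50, 50), 2.0, seed=0, max_tries=50)

    def test_radius_range_sampled_within_bounds(self, paper_volume):
        field = u.place_particles(paper_volume, (15, 15), (0.5, 4.0), seed=2)
        assert (field.radii >= 0.5).all() and (field.radii <= 4.0).all()
        assert field.radii.std() > 0


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

class TestRasterizeSlice:
    def test_particle_off_slice_contributes_nothing(self, paper_volume):
        z_slice = (3 + 0.5) * paper_volume.dz
        field = ParticleField(centers=[[38.0, 38.0, z_slice + 2.5]], radii=[2.0])
        img, truth = u.rasterize_slice(field, paper_volume, 3)
        assert not img.any()
        assert truth == ()

    def test_equatorial_disc_radius_and_value(self, paper_volume):
        """Bead centered on the slice plane: analytic profile radius r/dx."""
        z_slice = (10 + 0.5) * paper_volume.dz
        field = ParticleField(centers=[[38.0, 38.0, z_slice]], radii=[2.0])
        img, truth = u.rasterize_slice(field, paper_volume, 10)
        assert len(truth) == 1
        assert truth[0].radius_px == pytest.approx(2.0 / paper_volume.dx)
        on = img > 0
        assert np.all(img[on] == 229.5)
        # every in-disc pixel center (strictly inside) is set: brute-force check
        n = paper_volume.n
        xs = (np.arange(n) + 0.5) * paper_volume.dx
        expected = (xs[None, :] - 38.0) ** 2 + (xs[:, None] - 38.0) ** 2 < 4.0
        np.testing.assert_array_equal(on, expected)

    def test_half_radius_offset_chord(self, paper_volume):
        """|z_c - z_slice| = r/2 gives profile radius r*sqrt(3)/2."""
        r = 2.0
        z_slice = (5 + 0.5) * paper_volume.dz
        field = ParticleField(centers=[[30.0, 40.0, z_slice + r / 2]], radii=[r])
        _, truth = u.rasterize_slice(field, paper_volume, 5)
        assert truth[0].radius_px == pytest.approx(r * math.sqrt(3) / 2 / paper_volume.dx)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_agrees_with_bruteforce_3d_distance(self, paper_volume, seed):
        field = u.place_particles(paper_volume, (10, 15), 2.0, seed=seed)
        z_index = 4
        img, _ = u.rasterize_slice(field, paper_volume, z_index)
        n = paper_volume.n
        z = (z_index + 0.5) * paper_volume.dz
        brute = np.zeros((n, n))
        for row in range(n):
            for col in range(n):
                p = np.array([(col + 0.5) * paper_volume.dx,
                              (row + 0.5) * paper_volume.dy, z])
                if any(np.linalg.norm(p - c) < r
                       for c, r in zip(field.centers, field.radii)):
                    brute[row, col] = 229.5
        np.testing.assert_array_equal(img, brute)

    def test_z_index_out_of_range(self, paper_volume, default_field):
        with pytest.raises(ValueError):
            u.rasterize_slice(default_field, paper_volume, paper_volume.nz)

    def test_truth_positions_in_pixel_coordinates(self, paper_volume):
        # bead at the center of pixel (row 20, col 50)
        cx = (50 + 0.5) * paper_volume.dx
        cy = (20 + 0.5) * paper_volume.dy
        z_slice = (2 + 0.5) * paper_volume.dz
        field = ParticleField(centers=[[cx, cy, z_slice]], radii=[2.0])
        _, truth = u.rasterize_slice(field, paper_volume, 2)
        assert truth[0].cx_px == pytest.approx(50.0)
        assert truth[0].cy_px == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# Perlin background
# ---------------------------------------------------------------------------

class TestPerlin:
    def test_single_octave_vanishes_on_lattice(self):
        """With frequency f dividing n, pixels on lattice nodes are exactly 0."""
        n, f = 64, 4
        field = perlin_octave((n, n), f, np.random.default_rng(3))
        step = n // f
        lattice = field[::step, ::step]
        np.testing.assert_allclose(lattice, 0.0, atol=1e-12)

    def test_octave_amplitudes_follow_persistence(self):
        """The k-th octave enters with amplitude persistence**(k-1)."""
        shape = (64, 64)
        seed = 9
        bg2 = BackgroundParams(octaves=2, persistence=0.5, seed=seed)
        field2 = u.perlin_field(shape, bg2)
        # rebuild from the primitive: same generator stream, explicit weights
        rng = np.random.default_rng(seed)
        o1 = perlin_octave(shape, 1, rng)
        o2 = perlin_octave(shape, 2, rng)
        np.testing.assert_allclose(field2, o1 + 0.5 * o2, rtol=0, atol=1e-12)

    def test_amplitude_bound(self):
        """|field| <= (sqrt(2)/2) * sum of octave amplitudes (2D Perlin bound)."""
        bg = BackgroundParams(octaves=8, persistence=0.5, seed=11)
        field = u.perlin_field((128, 128), bg)
        bound = (math.sqrt(2) / 2) * sum(0.5 ** k for k in range(8))
        assert np.abs(field).max() <= bound

    def test_seed_determinism(self):
        bg = BackgroundParams(seed=21)
        f1 = u.perlin_field((64, 64), bg)
        f2 = u.perlin_field((64, 64), bg)
        f3 = u.perlin_field((64, 64), replace(bg, seed=22))
        np.testing.assert_array_equal(f1, f2)
        assert (f1 != f3).any()

    def test_base_amplitude_scales_linearly(self):
        bg1 = BackgroundParams(base_amplitude=1.0, seed=5)
        bg3 = BackgroundParams(base_amplitude=3.0, seed=5)
        f1 = u.perlin_field((32, 32), bg1)
        f3 = u.perlin_field((32, 32), bg3)
        np.testing.assert_allclose(f3, 3.0 * f1, rtol=1e-12)


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------

class TestApplyPsf:
    def test_constant_image_preserved(self):
        img = np.full((40, 40), 7.5)
        np.testing.assert_allclose(u.apply_psf(img, 2.0), img, rtol=1e-12)

    def test_impulse_reproduces_kernel(self):
        """Centered impulse on a large frame returns the normalized kernel."""
        sigma = 2.0
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = u.apply_psf(img, sigma)
        k1 = gaussian_kernel(sigma)
        expected = np.outer(k1, k1)
        r = len(k1) // 2
        np.testing.assert_allclose(out[32 - r:32 + r + 1, 32 - r:32 + r + 1],
                                   expected, atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(out.argmax(), out.shape) == (32, 32)

    def test_output_shape_matches_input(self):
        img = np.random.default_rng(0).random((33, 47))
        assert u.apply_psf(img, 2.0).shape == (33, 47)


# ---------------------------------------------------------------------------
# Statistical noise
# ---------------------------------------------------------------------------

class TestGaussianNoise:
    def test_zero_level_is_identity(self, rng):
        g = rng.random((32, 32)) * 200
        np.testing.assert_array_equal(u.add_gaussian_noise(g, 0.0, seed=1), g)

    @pytest.mark.parametrize("sigma_n", [0.03, 0.1])
    def test_relative_frobenius_level_exact(self, rng, sigma_n):
        g = rng.random((64, 64)) * 200
        gn = u.add_gaussian_noise(g, sigma_n, seed=2)
        ratio = np.linalg.norm(gn - g) / np.linalg.norm(g)
        assert ratio == pytest.approx(sigma_n, abs=1e-12)

    def test_zero_image_warns_and_passes_through(self):
        g = np.zeros((8, 8))
        with pytest.warns(UserWarning, match="zero-norm"):
            gn = u.add_gaussian_noise(g, 0.03, seed=0)
        np.testing.assert_array_equal(gn, g)


class TestPoissonNoise:
    def test_zero_image_stays_zero(self):
        assert not u.add_poisson_noise(np.zeros((16, 16)), 1.0, seed=0).any()

    @pytest.mark.parametrize("v,gamma", [(8.0, 1.0), (5.0, 2.0)])
    def test_moments(self, v, gamma):
        """Sample mean near v, variance near v/gamma (Poisson(gamma v)/gamma)."""
        n = 10_000
        g = np.full(n, v)
        gn = u.add_poisson_noise(g, gamma, seed=3)
        se = math.sqrt(v / gamma / n)
        assert abs(gn.mean() - v) < 4 * se
        assert abs(gn.var() - v / gamma) < 0.1 * (v / gamma)

    def test_high_photon_limit(self):
        g = np.full((32, 32), 100.0)
        gn = u.add_poisson_noise(g, 1e6, seed=4)
        assert np.abs(gn - g).max() < 1.0

    def test_negative_values_clamped(self):
        g = np.array([-5.0, 10.0])
        gn = u.add_poisson_noise(g, 1e6, seed=5)
        assert gn[0] == 0.0


# ---------------------------------------------------------------------------
# Frame pairs
# ---------------------------------------------------------------------------

class TestRenderPair:
    def test_no_background_means_identical_pair(self, tiny_volume):
        field = u.place_particles(tiny_volume, (2, 2), 2.0, seed=1)
        bg = BackgroundParams(amplitude=0.0, seed=0)
        pair = u.render_pair(field, tiny_volume, 3, bg, NoiseParams(seed=7))
        np.testing.assert_array_equal(pair.input_frame, pair.target_frame)

    def test_null_scene_is_all_zero(self, tiny_volume):
        field = ParticleField(centers=np.empty((0, 3)), radii=[])
        bg = BackgroundParams(amplitude=0.0, seed=0)
        noise = NoiseParams(gaussian_level=0.0, poisson_gamma=math.inf, seed=0)
        pair = u.render_pair(field, tiny_volume, 0, bg, noise)
        assert not pair.input_frame.any()
        assert not pair.target_frame.any()

    def test_frames_nonnegative_and_same_shape(self, tiny_volume):
        field = u.place_particles(tiny_volume, (2, 3), 2.0, seed=2)
        pair = u.render_pair(field, tiny_volume, 4, BackgroundParams(seed=3),
                             NoiseParams(seed=4))
        assert pair.input_frame.shape == pair.target_frame.shape == (32, 32)
        assert (pair.input_frame >= 0).all()
        assert (pair.target_frame >= 0).all()

    def test_matches_step_by_step_pipeline(self, tiny_volume):
        """Composition oracle: rebuild both frames from the primitive ops."""
        field = u.place_particles(tiny_volume, (2, 3), 2.0, seed=5)
        bg = BackgroundParams(seed=6)
        noise = NoiseParams(seed=8)
        z = 2
        pair = u.render_pair(field, tiny_volume, z, bg, noise)

        raster, truth = u.rasterize_slice(field, tiny_volume, z)
        assert truth == pair.truth
        perlin = u.perlin_field((32, 32), bg)
        bg_img = bg.amplitude * _normalize01(perlin)
        ss = np.random.SeedSequence(noise.seed)
        g_seed, p_seed = ss.spawn(2)
        eta = np.random.default_rng(g_seed).standard_normal((32, 32))
        for pre, got in ((raster + bg_img, pair.input_frame),
                         (raster, pair.target_frame)):
            g = u.apply_psf(pre, noise.psf_sigma)
            g = u.add_gaussian_noise(g, noise.gaussian_level, eta=eta)
            g = u.add_poisson_noise(g, noise.poisson_gamma,
                                    seed=np.random.default_rng(p_seed))
            np.testing.assert_array_equal(got, g)

    def test_gaussian_stage_satisfies_relative_norm(self, tiny_volume):
        """The read-noise stage keeps ||g_n - g||_F / ||g||_F = sigma_n to 1e-10."""
        field = u.place_particles(tiny_volume, (2, 3), 2.0, seed=5)
        bg = BackgroundParams(seed=6)
        noise = NoiseParams(seed=8)
        raster, _ = u.rasterize_slice(field, tiny_volume, 2)
        blurred = u.apply_psf(raster + bg.amplitude * _normalize01(
            u.perlin_field((32, 32), bg)), noise.psf_sigma)
        ss = np.random.SeedSequence(noise.seed)
        g_seed, _ = ss.spawn(2)
        eta = np.random.default_rng(g_seed).standard_normal((32, 32))
        before_poisson = u.add_gaussian_noise(blurred, noise.gaussian_level, eta=eta)
        ratio = np.linalg.norm(before_poisson - blurred) / np.linalg.norm(blurred)
        assert ratio == pytest.approx(0.03, abs=1e-10)

    def test_poisson_then_gaussian_order(self, tiny_volume):
        field = u.place_particles(tiny_volume, (2, 3), 2.0, seed=5)
        noise = NoiseParams(seed=8, noise_order="poisson_then_gaussian")
        pair = u.render_pair(field, tiny_volume, 2, BackgroundParams(seed=6), noise)
        assert (pair.input_frame >= 0).all()


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

class TestGenerateDataset:
    def test_study_split_sizes(self):
        spec = make_tiny_spec(n_images=500, split=(0.9, 0.05, 0.05), seed=1)
        ds = u.generate_dataset(spec)
        assert (len(ds.train), len(ds.val), len(ds.test)) == (450, 25, 25)

    def test_determinism(self):
        spec = make_tiny_spec(n_images=4, seed=3)
        d1 = u.generate_dataset(spec)
        d2 = u.generate_dataset(spec)
        for p1, p2 in zip(d1, d2):
            np.testing.assert_array_equal(p1.input_frame, p2.input_frame)
            np.testing.assert_array_equal(p1.target_frame, p2.target_frame)
            assert p1.truth == p2.truth

    def test_variable_radius_preset_respects_ranges(self):
        spec = DatasetSpec(n_images=5, split=(0.6, 0.2, 0.2), count_range=(0, 15),
                           radius=(0.5, 4.0), volume=VolumeSpec(n=256), seed=4)
        ds = u.generate_dataset(spec)
        max_px = 4.0 / ds.spec.volume.dx
        for pair in ds:
            assert len(pair.truth) <= 15
            for t in pair.truth:
                assert 0 < t.radius_px <= max_px + 1e-9

    def test_render_scene_is_seed_pure(self):
        spec = make_tiny_spec()
        p1 = render_scene(spec, 77)
        p2 = render_scene(spec, 77)
        np.testing.assert_array_equal(p1.input_frame, p2.input_frame)
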