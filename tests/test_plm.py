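import numpy as np
import pytest

from cartoptics.plm import (
    PLMStack,
    analyze_stack,
    depth_profile,
    fit_pixel_harmonics,
    zone_fractions,
)
from cartoptics.synthetic import (
    PLM_ANGLES_DEG,
    SyntheticFiberProfile,
    gen_plm_stack,
)


class _ConstantProfile:
    def __init__(self, angle):
        self.angle = angle

    def angle_at(self, z):
        return np.full_like(np.asarray(z, dtype=float), float(self.angle))


def _stack(frames):
    return PLMStack(frames=frames)


class TestHarmonicFit:
    def test_noiseless_angle_recovery(self):
        stack = gen_plm_stack(_ConstantProfile(30.0), image_shape=(8, 8), offset=0.0)
        omap = fit_pixel_harmonics(_stack(stack))
        assert np.allclose(omap.phi_deg, 30.0, atol=1e-6)
        assert np.allclose(omap.pi_index, 1.0, atol=1e-9)

    def test_uniform_intensity_has_no_modulation(self):
        frames = np.full((21, 8, 8), 3.0)
        omap = fit_pixel_harmonics(_stack(frames))
        assert np.allclose(omap.pi_index, 0.0, atol=1e-9)
        assert not omap.valid.any()

    def test_exact_harmonic_signal(self):
        theta = np.radians(PLM_ANGLES_DEG)
        signal = 2.0 + np.cos(4.0 * theta)
        frames = np.broadcast_to(signal[:, None, None], (21, 4, 4)).copy()
        omap = fit_pixel_harmonics(_stack(frames))
        assert np.allclose(omap.s0, 2.0, atol=1e-9)
        assert np.allclose(np.hypot(omap.s1, omap.s2), 1.0, atol=1e-9)
        assert np.allclose(omap.pi_index, 0.5, atol=1e-9)

    def test_extinction_occurs_at_recovered_angle(self):
        # minimum of the fitted curve must sit at theta = phi (mod 90)
        for true_phi in (10.0, 40.0, 70.0):
            stack = gen_plm_stack(
                _ConstantProfile(true_phi), image_shape=(4, 4), offset=0.2
            )
            omap = fit_pixel_harmonics(_stack(stack))
            assert np.allclose(np.mod(omap.phi_deg, 90.0), true_phi, atol=1e-6)

    def test_gain_invariance_of_phi_offset_changes_pi_only(self):
        base = gen_plm_stack(_ConstantProfile(25.0), image_shape=(6, 6), offset=0.0)
        omap0 = fit_pixel_harmonics(_stack(base))
        omap_gain = fit_pixel_harmonics(_stack(base * 7.0))
        omap_off = fit_pixel_harmonics(_stack(base + 1.0))
        assert np.allclose(omap_gain.phi_deg, omap0.phi_deg, atol=1e-9)
        assert np.allclose(omap_gain.pi_index, omap0.pi_index, atol=1e-9)
        assert np.allclose(omap_off.phi_deg, omap0.phi_deg, atol=1e-9)
        assert np.all(omap_off.pi_index < omap0.pi_index)

    def test_90_degree_ambiguity_by_construction(self):
        a = gen_plm_stack(_ConstantProfile(20.0), image_shape=(4, 4))
        b = gen_plm_stack(_ConstantProfile(110.0), image_shape=(4, 4))
        assert np.allclose(a, b, atol=1e-12)

    def test_frame_count_enforced(self):
        with pytest.raises(ValueError, match="21"):
            PLMStack(frames=np.zeros((20, 8, 8)))


class TestDepthProfile:
    def test_constant_angle_gives_flat_profile(self):
        stack = gen_plm_stack(_ConstantProfile(70.0), image_shape=(32, 8))
        omap = fit_pixel_harmonics(_stack(stack))
        depth, ang = depth_profile(omap, n_bins=8)
        assert np.allclose(ang, 70.0, atol=1e-6)
        assert depth[0] > 0 and depth[-1] < 1

    def test_wraparound_circular_mean(self):
        # 85 and 5 degrees straddle the period: the mean is 0, not 45
        from cartoptics.plm import _circular_mean_90

        assert _circular_mean_90(np.array([85.0, 5.0])) == pytest.approx(0.0, abs=1e-9)

    def test_logistic_profile_recovery_under_noise(self):
        profile = SyntheticFiberProfile()
        stack = gen_plm_stack(
            profile, image_shape=(192, 48), noise_sd=0.01, seed=17
        )
        omap = fit_pixel_harmonics(_stack(stack))
        depth, ang = depth_profile(omap, n_bins=48)
        truth = profile.angle_at(depth)
        rmse = float(np.sqrt(np.mean((ang - truth) ** 2)))
        assert rmse < 3.0

    def test_replicate_averaging_reduces_noise(self):
        profile = SyntheticFiberProfile()
        single_rmse = []
        stacks = []
        for rep in range(6):
            stack = gen_plm_stack(
                profile, image_shape=(96, 24), noise_sd=0.05, seed=100 + rep
            )
            stacks.append(stack)
            omap = fit_pixel_harmonics(_stack(stack))
            depth, ang = depth_profile(omap, n_bins=24)
            truth = profile.angle_at(depth)
            single_rmse.append(np.sqrt(np.mean((ang - truth) ** 2)))
        omap = fit_pixel_harmonics(_stack(np.mean(stacks, axis=0)))
        depth, ang = depth_profile(omap, n_bins=24)
        truth = profile.angle_at(depth)
        avg_rmse = float(np.sqrt(np.mean((ang - truth) ** 2)))
        assert avg_rmse < 0.6 * float(np.mean(single_rmse))


class TestZoneFractions:
    def test_constant_deep_profile(self):
        depth = np.linspace(0.01, 0.99, 50)
        fracs, _ = zone_fractions(depth, np.full(50, 70.0))
        assert fracs == pytest.approx((0.0, 0.0, 1.0), abs=0.02)

    def test_linear_ramp_gives_equal_thirds(self):
        depth = np.linspace(0.0, 1.0, 1001)
        fracs, _ = zone_fractions(depth, 90.0 * depth)
        assert fracs[0] == pytest.approx(1 / 3, abs=0.01)
        assert fracs[1] == pytest.approx(1 / 3, abs=0.01)
        assert fracs[2] == pytest.approx(1 / 3, abs=0.01)

    def test_fractions_sum_to_one(self):
        depth = np.linspace(0.0, 1.0, 101)
        ang = 90.0 / (1.0 + np.exp(-8.0 * (depth - 0.3)))
        fracs, bounds = zone_fractions(depth, ang)
        assert sum(fracs) == pytest.approx(1.0, abs=1e-9)
        assert bounds[0] <= bounds[1]

    def test_calibrated_profile_recovers_zone_shares(self):
        """The 8/21/71% depth-share profile survives the full reduction."""
        profile = SyntheticFiberProfile()
        stack = gen_plm_stack(
            profile, image_shape=(192, 48), noise_sd=0.01, seed=23
        )
        dp = analyze_stack(PLMStack(frames=stack), n_bins=48)
        assert dp.zone_fractions[0] == pytest.approx(0.08, abs=0.02)
        assert dp.zone_fractions[1] == pytest.approx(0.21, abs=0.02)
        assert dp.zone_fractions[2] == pytest.approx(0.71, abs=0.02)


def test_tiff_round_trip(tmp_path):
    from cartoptics.plm import read_plm_stack, write_plm_stack

    frames = gen_plm_stack(SyntheticFiberProfile(), image_shape=(16, 8))
    p = tmp_path / "stack.tif"
    write_plm_stack(frames, p)
    stack = read_plm_stack(p)
    assert stack.frames.shape == (21, 16, 8)
    assert np.allclose(stack.frames, frames, atol=1e-6)
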