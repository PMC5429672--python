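"""Forward model: Stokes–Einstein, diffusion solver vs closed form, rendering, leaks."""

import numpy as np
import pytest

from permchip import (
    SimulationConfig,
    inject_focal_leak,
    render_stack,
    robin_halfspace_solution,
    simulate_device,
    solve_diffusion,
    stokes_einstein_D,
)
from permchip.simulate import LeakSpec, NoiseModel


class TestStokesEinstein:
    def test_reference_value(self):
        # k_B·298 / (3π·8.9e-4·1e-9) evaluated directly: 4.62e-10 m²/s
        assert stokes_einstein_D(1.0, 298.0, 8.9e-4) == pytest.approx(4.905e-6, rel=1e-3)

    def test_inverse_proportionality(self):
        assert stokes_einstein_D(40.0) == pytest.approx(stokes_einstein_D(20.0) / 2)

    def test_determinism(self):
        assert stokes_einstein_D(37.0) == stokes_einstein_D(37.0)

    @pytest.mark.parametrize("args", [(-1.0, 300.0, 1e-3), (10.0, 0.0, 1e-3), (10.0, 300.0, 0.0)])
    def test_invalid(self, args):
        with pytest.raises(ValueError):
            stokes_einstein_D(*args)


class TestSolver:
    def test_impermeable_membrane(self):
        cfg = SimulationConfig(Pd_true=0.0, duration=300.0)
        f = solve_diffusion(cfg)
        assert not f.C.any()

    def test_mass_conservation(self, fast_field):
        """Gel mass equals the time-integral of membrane flux within 1%."""
        mass = fast_field.gel_mass()
        np.testing.assert_allclose(mass[1:], fast_field.influx[1:], rtol=0.01)

    def test_equilibration_to_lumen_concentration(self):
        # small gel, leaky membrane, long run: the gel fills uniformly to C_lumen
        cfg = SimulationConfig(
            Pd_true=1e-3, gel_half_width=50.0, duration=600.0, fill_time=0.0, n_monolayers=1
        )
        f = solve_diffusion(cfg)
        np.testing.assert_allclose(f.C[-1], cfg.C_lumen, rtol=0.01)

    def test_matches_robin_closed_form(self):
        """FD solution vs the surface-resistance half-space solution, <1% L2."""
        cfg = SimulationConfig(
            gel_half_width=1500.0, duration=300.0, fill_time=0.0, n_monolayers=1
        )
        f = solve_diffusion(cfg)
        for k in (len(f.times) // 2, len(f.times) - 1):
            ana = robin_halfspace_solution(f.y, f.times[k], cfg.D_um2_s, cfg.Pd_um_s, cfg.C_lumen)
            err = np.linalg.norm(f.C[k] - ana) / np.linalg.norm(ana)
            assert err < 0.01

    def test_grid_convergence(self):
        """Halving grid_dx changes the solved field by <0.5%."""
        base = dict(gel_half_width=200.0, duration=300.0, fill_time=0.0, n_monolayers=1)
        coarse = solve_diffusion(SimulationConfig(grid_dx=4.0, pixel_size=4.0, **base))
        fine = solve_diffusion(SimulationConfig(grid_dx=2.0, pixel_size=2.0, **base))
        fine_on_coarse = np.interp(coarse.y, fine.y, fine.C[-1])
        err = np.linalg.norm(coarse.C[-1] - fine_on_coarse) / np.linalg.norm(fine_on_coarse)
        assert err < 0.005

    def test_concentrations_bounded(self, fast_field, fast_config):
        assert np.all(fast_field.C >= 0)
        assert np.all(fast_field.C <= fast_config.C_lumen * (1 + 1e-9))


class TestRender:
    def test_zero_gain_zero_read_noise_gives_offset(self):
        cfg = SimulationConfig(
            duration=90.0, noise=NoiseModel(photon_gain=0.0, read_noise_sd=0.0, offset=7.0)
        )
        truth = simulate_device(cfg)
        assert (truth.stack.frames == 7.0).all()

    def test_seed_reproducibility(self, fast_config, fast_field):
        a = render_stack(fast_field, fast_config, seed=3).stack.frames
        b = render_stack(fast_field, fast_config, seed=3).stack.frames
        np.testing.assert_array_equal(a, b)
        c = render_stack(fast_field, fast_config, seed=4).stack.frames
        assert not np.array_equal(a, c)

    def test_noise_free_is_expectation(self, tiny_config):
        """Mean over seeds of a noisy pixel approaches its noise-free value."""
        field = solve_diffusion(tiny_config)
        nf = render_stack(field, tiny_config, seed=0).noise_free_stack.frames
        k, r, c = 10, tiny_config.lumen_px + 5, tiny_config.frame_width_px // 2
        n = 200
        vals = [render_stack(field, tiny_config, seed=s).stack.frames[k, r, c] for s in range(n)]
        lam = nf[k, r, c] - tiny_config.noise.offset
        se = np.sqrt(lam + tiny_config.noise.read_noise_sd**2) / np.sqrt(n)
        assert abs(np.mean(vals) - nf[k, r, c]) < 3 * se

    def test_true_t0_frame(self):
        assert SimulationConfig(fill_time=60.0, frame_interval=30.0).true_t0_frame == 2
        assert SimulationConfig(fill_time=45.0, frame_interval=30.0).true_t0_frame == 2
        assert SimulationConfig(fill_time=0.0, frame_interval=30.0).true_t0_frame == 0

    def test_pre_frames_are_background_only(self):
        cfg = SimulationConfig(duration=90.0, n_pre_frames=2, noise=NoiseModel(500.0, 0.0, 50.0))
        truth = simulate_device(cfg)
        assert (truth.noise_free_stack.frames[:2] == 50.0).all()
        assert truth.true_t0_frame == 4


class TestLeak:
    def test_multiplier_one_is_identity(self, fast_config):
        leaky = inject_focal_leak(fast_config, multiplier=1.0)
        a = simulate_device(leaky, seed=9).stack.frames
        b = simulate_device(fast_config, seed=9).stack.frames
        np.testing.assert_array_equal(a, b)

    def test_leak_brightens_interface_profile(self, fast_config):
        """10× leak over 10% of a gap: the interface profile averaged over
        the 10 min after filling shows max/median > 2 (the contrast is
        strongest early, before the intact membrane loads the gel)."""
        leaky = inject_focal_leak(fast_config, gap_index=0, multiplier=10.0, width_frac=0.1)
        truth = simulate_device(leaky)
        geom = leaky.device_geometry()
        m = geom.monolayer_positions[0]
        g0, g1 = geom.post_gaps[0]
        k0 = truth.true_t0_frame
        k1 = min(truth.noise_free_stack.n_frames, k0 + 20)
        prof = truth.noise_free_stack.frames[k0:k1, m, g0:g1].mean(axis=0) - leaky.noise.offset
        assert prof.max() / np.median(prof) > 2.0

    def test_leak_position_shifts_peak(self, fast_config):
        geom = fast_config.device_geometry()
        g0, g1 = geom.post_gaps[0]
        m = geom.monolayer_positions[0]
        peaks = []
        for start in (0.1, 0.7):
            leaky = inject_focal_leak(fast_config, gap_index=0, start_frac=start, width_frac=0.1)
            truth = simulate_device(leaky)
            k = truth.true_t0_frame + 10
            prof = truth.noise_free_stack.frames[k, m, g0:g1]
            peaks.append(int(np.argmax(prof)))
        assert peaks[1] - peaks[0] > 0.4 * (g1 - g0)

    def test_invalid_leak_spec(self):
        with pytest.raises(ValueError):
            LeakSpec(width_frac=0.0)
        with pytest.raises(ValueError):
            LeakSpec(start_frac=0.95, width_frac=0.1)
        with pytest.raises(ValueError):
            LeakSpec(multiplier=0.5)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimulationConfig(Pd_true=2e-5, seed=5)
        p = tmp_path / "sim.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        back = SimulationConfig.from_yaml(p)
        assert back == cfg

    def test_pixel_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(grid_dx=2.0, pixel_size=3.0)

    def test_device_geometry_matches_frames(self, fast_config, fast_truth):
        geom = fast_config.device_geometry()
        H, W = fast_truth.stack.frame_shape
        assert geom.gel_span[1] + fast_config.lumen_px == H
        assert all(g1 <= W for _, g1 in geom.post_gaps)
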