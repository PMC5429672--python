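"""t0 detection, slope fitting, the permeability formula and QC."""

import numpy as np
import pytest

from permchip import (
    BackgroundModel,
    ImageStack,
    IntensityTrace,
    MeasureConfig,
    compute_pd,
    detect_t0,
    extract_traces,
    fit_initial_slope,
    measure_device,
)
from permchip.permeability import measure_triple, measurements_to_frame
from permchip import SimulationConfig
from permchip.recover import recover_once
from permchip.roi import build_roi_triples


def make_trace(I_gel, I_lum=None, I_y0=None, t0=0, dt=30.0):
    I_gel = np.asarray(I_gel, dtype=float)
    n = I_gel.size
    return IntensityTrace(
        times=np.arange(n) * dt,
        I_ave_gel=I_gel,
        I_lumen=np.full(n, 1000.0) if I_lum is None else np.asarray(I_lum, float),
        I_y0=np.zeros(n) if I_y0 is None else np.asarray(I_y0, float),
        t0_index=t0,
    )


class TestDetectT0:
    def test_already_at_plateau(self):
        assert detect_t0(np.full(6, 500.0)) == 0

    def test_step_trace(self):
        assert detect_t0(np.array([0, 0, 100, 100, 100.0])) == 2

    def test_never_fills(self):
        with pytest.raises(ValueError):
            detect_t0(np.zeros(5))

    def test_too_short(self):
        with pytest.raises(ValueError):
            detect_t0(np.array([1.0]))

    def test_simulated_fill_schedule(self, fast_truth, fast_config):
        """Detected filling frame matches the simulation schedule within 1."""
        geom = fast_config.device_geometry()
        triple = build_roi_triples(geom, gel_depth=200.0)[0]
        bg = BackgroundModel(mode="scalar", value=fast_config.noise.offset)
        trace = extract_traces(fast_truth.stack, triple, bg)
        assert abs(trace.t0_index - fast_truth.true_t0_frame) <= 1


class TestSlopeFit:
    def test_exact_line(self):
        t = np.arange(12) * 30.0
        slope, r2 = fit_initial_slope(make_trace(5.0 + 2.0 * t), fit_window=10)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_trace(self):
        slope, _ = fit_initial_slope(make_trace(np.full(12, 3.0)), fit_window=10)
        assert slope == pytest.approx(0.0)

    def test_window_beyond_acquisition(self):
        with pytest.raises(ValueError):
            fit_initial_slope(make_trace(np.arange(5.0)), fit_window=10)

    def test_window_too_small(self):
        with pytest.raises(ValueError):
            fit_initial_slope(make_trace(np.arange(12.0)), fit_window=2)


class TestComputePd:
    def test_zero_slope(self):
        assert compute_pd(0.0, 1000.0, 1e4, 100.0) == 0.0

    def test_unit_arithmetic(self):
        # 1 intensity/s · 10⁴ µm² / (100 µm · 1000 intensity) = 0.1 µm/s = 1e-5 cm/s
        assert compute_pd(1.0, 1000.0, 1e4, 100.0) == pytest.approx(1e-5)

    @pytest.mark.parametrize("dI,A,w", [(0.0, 1e4, 100.0), (-5.0, 1e4, 100.0), (10.0, 0.0, 100.0), (10.0, 1e4, -1.0)])
    def test_invalid_inputs(self, dI, A, w):
        with pytest.raises(ValueError):
            compute_pd(1.0, dI, A, w)


class TestExtractTraces:
    def test_all_zero_stack_never_fills(self, fast_config):
        triple = build_roi_triples(fast_config.device_geometry(), gel_depth=30.0)[0]
        stack = ImageStack(np.zeros((6, 800, 300)), pixel_size=2.0, frame_interval=30.0)
        with pytest.raises(ValueError):
            extract_traces(stack, triple)

    def test_background_equal_stack_gives_zero_traces(self, fast_config):
        triple = build_roi_triples(fast_config.device_geometry(), gel_depth=30.0)[0]
        stack = ImageStack(np.full((6, 800, 300), 100.0), pixel_size=2.0, frame_interval=30.0)
        bg = BackgroundModel(mode="scalar", value=100.0)
        trace = extract_traces(stack, triple, bg, t0_index=0)
        assert not trace.I_ave_gel.any() and not trace.I_lumen.any()

    def test_gel_signal_rises_after_t0(self, fast_truth, fast_config):
        triple = build_roi_triples(fast_config.device_geometry(), gel_depth=400.0)[0]
        bg = BackgroundModel(mode="scalar", value=fast_config.noise.offset)
        trace = extract_traces(fast_truth.noise_free_stack, triple, bg)
        after = trace.I_ave_gel[trace.t0_index :]
        assert np.all(np.diff(after) > -1e-9)


class TestPipeline:
    def test_one_measurement_per_triple(self, fast_truth, fast_config):
        triples = build_roi_triples(fast_config.device_geometry(), gel_depth=200.0)
        bg = BackgroundModel(mode="scalar", value=fast_config.noise.offset)
        ms = measure_device(fast_truth.stack, triples, bg)
        assert len(ms) == len(triples) == 6

    def test_determinism(self, fast_truth, fast_config):
        triples = build_roi_triples(fast_config.device_geometry(), gel_depth=200.0)
        bg = BackgroundModel(mode="scalar", value=fast_config.noise.offset)
        a = measurements_to_frame(measure_device(fast_truth.stack, triples, bg))
        b = measurements_to_frame(measure_device(fast_truth.stack, triples, bg))
        assert a.equals(b)

    def test_formula_identity_holds_in_output(self, fast_truth, fast_config):
        """Every record satisfies P_d = A_gel·slope/(w·ΔI) exactly (in cm/s)."""
        df = recover_once(fast_config, noise_free=True)
        lhs = df.Pd_cm_s
        rhs = df.A_gel_um2 * df.slope / (df.w_um * df.delta_I) * 1e-4
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_intensity_scale_invariance(self, fast_truth, fast_config):
        """Multiplying all intensities (and background) by k>0 leaves P_d unchanged."""
        triples = build_roi_triples(fast_config.device_geometry(), gel_depth=300.0)
        bg = BackgroundModel(mode="scalar", value=fast_config.noise.offset)
        base = measure_triple(fast_truth.stack, triples[0], bg)
        k = 3.7
        scaled_stack = ImageStack(
            fast_truth.stack.frames * k, pixel_size=2.0, frame_interval=30.0
        )
        bg_k = BackgroundModel(mode="scalar", value=fast_config.noise.offset * k)
        scaled = measure_triple(scaled_stack, triples[0], bg_k)
        assert scaled.P_d == pytest.approx(base.P_d, rel=1e-9)

    def test_failures_recorded_not_raised(self, fast_config):
        stack = ImageStack(np.full((6, 800, 300), 100.0), pixel_size=2.0, frame_interval=30.0)
        triples = build_roi_triples(fast_config.device_geometry(), gel_depth=200.0)
        ms = measure_device(stack, triples, BackgroundModel(mode="scalar", value=100.0))
        assert len(ms) == 6
        assert all(m.error for m in ms)  # lumen never fills

    def test_between_triple_scatter_small(self, fast_config):
        """Uniform true P_d: the six data points agree to a few per cent."""
        df = recover_once(fast_config, seed=11)
        cv = df.Pd_cm_s.std(ddof=1) / df.Pd_cm_s.mean()
        assert cv < 0.15

    def test_gel_depth_insensitivity(self):
        """Doubling the red-box depth leaves noise-free P_d within 5%.

        Holds once the control volume contains the diffusive front (the
        A_gel factor then compensates the dilution of the mean); a deep-gel
        single-channel device keeps both depths inside the gel.
        """
        cfg = SimulationConfig(
            duration=600.0, gel_half_width=1600.0, n_monolayers=1, n_gaps=1, lumen_width=60.0
        )
        a = recover_once(cfg, noise_free=True, gel_depth=400.0).Pd_cm_s.iloc[0]
        b = recover_once(cfg, noise_free=True, gel_depth=800.0).Pd_cm_s.iloc[0]
        assert abs(a / b - 1.0) < 0.05
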