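"""Unit tests for the forward-Euler simulator."""

import numpy as np
import pytest

from betadfc import (
    DEFAULT_PARAMS,
    DivergenceError,
    ModelState,
    NORMAL_COUPLING,
    PATHOLOGICAL_COUPLING,
    PopulationParams,
    SimulationConfig,
    SimulationResult,
    StimulationScheme,
    ConfigurationError,
    CouplingConfig,
    DelayBuffer,
    draw_external_inputs,
    feedback_signal,
    oscillation_index,
    route_stimulation,
    simulate,
    step,
)
from betadfc.simulator import _input_array

NOISELESS = CouplingConfig(5, 20, 2, 13, 1, cor_sd=0.0, str_sd=0.0, gpi_sd=0.0)


class TestExternalInputs:
    def test_zero_sd_returns_means_exactly(self):
        rng = np.random.default_rng(0)
        assert draw_external_inputs(rng, NOISELESS) == (27.0, 2.0, 20.0)

    def test_seeded_determinism(self):
        a = draw_external_inputs(np.random.default_rng(42), PATHOLOGICAL_COUPLING)
        b = draw_external_inputs(np.random.default_rng(42), PATHOLOGICAL_COUPLING)
        assert a == b

    def test_vectorised_draw_matches_per_step_draws(self):
        block = _input_array(np.random.default_rng(7), PATHOLOGICAL_COUPLING, 100)
        rng = np.random.default_rng(7)
        loop = np.array(
            [draw_external_inputs(rng, PATHOLOGICAL_COUPLING) for _ in range(100)]
        )
        assert np.array_equal(block, loop)

    def test_sample_mean_within_standard_error(self):
        n = 30000
        block = _input_array(np.random.default_rng(3), PATHOLOGICAL_COUPLING, n)
        se = 0.1 / np.sqrt(n)
        assert abs(block[:, 0].mean() - 27.0) < 3 * se
        assert abs(block[:, 1].mean() - 2.0) < 3 * se
        assert abs(block[:, 2].mean() - 20.0) < 3 * se


class TestStep:
    def test_zero_gain_system_stays_at_origin(self):
        params = {n: PopulationParams(0.0, p.x, p.r, p.y) for n, p in DEFAULT_PARAMS.items()}
        new = step(
            ModelState(), (27.0, 2.0, 20.0), (0.0, 0.0, 0.0), params,
            PATHOLOGICAL_COUPLING, 1e-4,
        )
        assert np.array_equal(new.to_array(), np.zeros(16))

    def test_one_step_from_rest(self):
        # from the origin v stays 0 and z_k = dt * (gain_k/x_k) * u_k
        dt = 1e-4
        coupling = NOISELESS
        new = step(
            ModelState(), (27.0, 2.0, 20.0), (0.0, 0.0, 0.0), DEFAULT_PARAMS,
            coupling, dt,
        )
        arr = new.to_array()
        assert np.array_equal(arr[0::2], np.zeros(8))  # potentials unchanged
        # at the origin every sigmoid sits at its midpoint r/2
        u = {"stn": 150.0, "gpe": 200.0, "ppn": 100.0}
        s, g, p = DEFAULT_PARAMS["stn"], DEFAULT_PARAMS["gpe"], DEFAULT_PARAMS["ppn"]
        expected_z = [
            dt * coupling.lambda1 * s.H / s.x * u["gpe"],
            dt * s.H / s.x * 27.0,
            dt * coupling.lambda5 * s.H / s.x * u["ppn"],
            dt * coupling.lambda2 * g.H / g.x * u["stn"],
            dt * coupling.lambda3 * g.H / g.x * u["gpe"],
            dt * g.H / g.x * 2.0,
            dt * p.H / p.x * 20.0,
            dt * coupling.lambda4 * p.H / p.x * u["stn"],
        ]
        assert arr[1::2] == pytest.approx(expected_z, rel=1e-12)

    def test_update_map_is_deterministic(self):
        inputs, offsets = (27.0, 2.0, 20.0), (0.1, 0.0, 0.0)
        one = step(ModelState(), inputs, offsets, DEFAULT_PARAMS, PATHOLOGICAL_COUPLING, 1e-4)
        two = step(one, inputs, offsets, DEFAULT_PARAMS, PATHOLOGICAL_COUPLING, 1e-4)
        again = step(
            step(ModelState(), inputs, offsets, DEFAULT_PARAMS, PATHOLOGICAL_COUPLING, 1e-4),
            inputs, offsets, DEFAULT_PARAMS, PATHOLOGICAL_COUPLING, 1e-4,
        )
        assert np.array_equal(two.to_array(), again.to_array())


class TestKernelAgreesWithReferenceStep:
    """The compiled loop and the plain-Python update are the same map."""

    def _python_trajectory(self, inputs, dt, scheme=None):
        n = inputs.shape[0]
        state = ModelState()
        traces = np.zeros((n, 3))
        w_tr = np.zeros(n)
        buf = DelayBuffer(max_lag_steps=n, dt=dt)
        from betadfc.model import compose_lfp

        for i in range(n):
            lfps = compose_lfp(state)
            traces[i] = lfps
            w = 0.0
            if scheme is not None:
                buf.push(lfps[("stn", "gpe", "ppn").index(scheme.source)])
                if i * dt >= scheme.onset:
                    w = feedback_signal(buf, buf.lagged(0), scheme, t=i * dt)
            w_tr[i] = w
            offsets = route_stimulation(scheme, w)
            state = step(state, tuple(inputs[i]), offsets, DEFAULT_PARAMS,
                         PATHOLOGICAL_COUPLING, dt)
        return traces, w_tr

    def test_unstimulated_short_run(self):
        dt, n = 1e-4, 200
        inputs = _input_array(np.random.default_rng(5), PATHOLOGICAL_COUPLING, n)
        res = simulate(
            SimulationConfig(T=n * dt, dt=dt, seed=5), coupling=PATHOLOGICAL_COUPLING
        )
        ref, _ = self._python_trajectory(inputs, dt)
        assert np.allclose(np.column_stack([res.v_stn, res.v_gpe, res.v_ppn]), ref,
                           rtol=1e-10, atol=1e-10)

    def test_stimulated_short_run_including_delay_path(self):
        dt, n = 1e-4, 400
        scheme = StimulationScheme("gpe", "ppn", K=-2.0, tau=0.005, onset=0.01)
        inputs = _input_array(np.random.default_rng(9), PATHOLOGICAL_COUPLING, n)
        res = simulate(
            SimulationConfig(T=n * dt, dt=dt, seed=9, scheme=scheme),
            coupling=PATHOLOGICAL_COUPLING,
        )
        ref, w_ref = self._python_trajectory(inputs, dt, scheme)
        assert np.allclose(np.column_stack([res.v_stn, res.v_gpe, res.v_ppn]), ref,
                           rtol=1e-9, atol=1e-9)
        assert np.allclose(res.w_trace, w_ref, rtol=1e-9, atol=1e-9)


class TestSimulate:
    def test_bitwise_seed_reproducibility(self):
        cfg = SimulationConfig(T=0.5, dt=1e-4, seed=11)
        a = simulate(cfg, coupling=PATHOLOGICAL_COUPLING)
        b = simulate(cfg, coupling=PATHOLOGICAL_COUPLING)
        for x, y in [(a.v_stn, b.v_stn), (a.v_gpe, b.v_gpe), (a.v_ppn, b.v_ppn),
                     (a.w_trace, b.w_trace)]:
            assert np.array_equal(x, y)

    def test_trace_shapes_and_time_grid(self, pathological_run):
        res = pathological_run
        assert res.t.size == res.v_stn.size == res.w_trace.size == 30000
        assert res.t[0] == 0.0
        assert res.t[1] == pytest.approx(1e-4)

    def test_unstimulated_run_has_zero_signal(self, pathological_run):
        assert np.array_equal(pathological_run.w_trace, np.zeros(30000))

    def test_signal_zero_before_onset(self):
        scheme = StimulationScheme("stn", "stn", K=0.4, tau=0.025, onset=1.0)
        res = simulate(
            SimulationConfig(seed=2, scheme=scheme), coupling=PATHOLOGICAL_COUPLING
        )
        onset_idx = int(round(1.0 / 1e-4))
        assert np.array_equal(res.w_trace[:onset_idx], np.zeros(onset_idx))
        assert np.any(res.w_trace[onset_idx:] != 0.0)

    def test_zero_gain_populations_stay_silent(self):
        params = {n: PopulationParams(0.0, p.x, p.r, p.y) for n, p in DEFAULT_PARAMS.items()}
        res = simulate(
            SimulationConfig(T=0.1, dt=1e-4, seed=0),
            params=params, coupling=PATHOLOGICAL_COUPLING,
        )
        assert np.array_equal(res.v_stn, np.zeros(1000))
        assert np.array_equal(res.v_gpe, np.zeros(1000))
        assert np.array_equal(res.v_ppn, np.zeros(1000))

    def test_zero_intensity_equals_no_stimulation(self):
        scheme = StimulationScheme("stn", "stn", K=0.0, tau=0.025, onset=1.0)
        with_scheme = simulate(
            SimulationConfig(seed=4, scheme=scheme), coupling=PATHOLOGICAL_COUPLING
        )
        without = simulate(SimulationConfig(seed=4), coupling=PATHOLOGICAL_COUPLING)
        assert np.array_equal(with_scheme.v_stn, without.v_stn)
        assert np.array_equal(with_scheme.w_trace, np.zeros(30000))

    def test_pathological_exceeds_normal_oscillation(self):
        path = simulate(SimulationConfig(seed=3), coupling=PATHOLOGICAL_COUPLING)
        norm = simulate(SimulationConfig(seed=3), coupling=NORMAL_COUPLING)
        for nucleus in ("stn", "gpe", "ppn"):
            oi_p = oscillation_index(path.lfp(nucleus), 1e-4)
            oi_n = oscillation_index(norm.lfp(nucleus), 1e-4)
            assert oi_n < 0.2 * oi_p

    def test_divergence_reports_step_index(self):
        # dt far beyond the Euler stability limit of the fastest channel
        with pytest.raises(DivergenceError) as err:
            simulate(SimulationConfig(T=30.0, dt=0.05, seed=0), coupling=PATHOLOGICAL_COUPLING)
        assert err.value.step_index >= 0

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(T=-1.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(T=1.0, dt=2.0)
        with pytest.raises(ConfigurationError):
            # delay longer than the pre-onset history
            SimulationConfig(scheme=StimulationScheme("stn", "stn", 1.0, tau=1.5, onset=1.0))
        with pytest.raises(ConfigurationError):
            simulate(SimulationConfig(), coupling=None)

    def test_external_inputs_override(self):
        n = 500
        inputs = np.tile([27.0, 2.0, 20.0], (n, 1))
        res = simulate(
            SimulationConfig(T=n * 1e-4, dt=1e-4, seed=0),
            coupling=PATHOLOGICAL_COUPLING, inputs=inputs,
        )
        noiseless = simulate(
            SimulationConfig(T=n * 1e-4, dt=1e-4, seed=0), coupling=NOISELESS
        )
        assert np.array_equal(res.v_stn, noiseless.v_stn)
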