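"""Connectivity/projection sampling moments, single-step dynamics oracles,
and the simulator's structural contracts."""

import numpy as np
import pytest

from mesovar.network import (
    Connectivity,
    NetworkParams,
    NetworkState,
    ParameterError,
    SpatialLayout,
    initial_state,
    sample_connectivity,
    sample_input_projection,
    sample_spatial_projection,
    simulate_trials,
    step,
    step_noise,
)
from mesovar.protocols import build_pulse_protocol


class TestParams:
    def test_dt_stability_bound_enforced(self):
        with pytest.raises(ParameterError):
            NetworkParams(n_neurons=10, tau=0.5, dt=0.3)

    @pytest.mark.parametrize("bad", [{"gain": -1.0}, {"gain": np.inf}, {"n_neurons": 0}])
    def test_invalid_params_rejected(self, bad):
        kwargs = {"n_neurons": 10} | bad
        with pytest.raises(ParameterError):
            NetworkParams(**kwargs)


class TestSampling:
    def test_zero_gain_gives_zero_matrix(self, rng):
        conn = sample_connectivity(NetworkParams(n_neurons=50, gain=0.0), rng)
        assert np.all(conn.matrix == 0)

    def test_connectivity_moments_match_g2_over_n(self, rng):
        n, g = 2000, 1.2
        conn = sample_connectivity(NetworkParams(n_neurons=n, gain=g), rng)
        # sample-moment oracle on the drawn matrix
        assert abs(conn.matrix.mean()) < 3 * g / n  # 3 sigma of the mean of n^2 entries
        assert conn.matrix.var() == pytest.approx(g**2 / n, rel=0.05)

    def test_zero_diagonal_flag(self, rng):
        p = NetworkParams(n_neurons=40, zero_diagonal=True)
        assert np.all(np.diag(sample_connectivity(p, rng).matrix) == 0)

    def test_half_gaussian_weights_mean(self, rng):
        # closed-form half-normal moment: E|N(0,1)| = sqrt(2/pi) ~ 0.7979
        p = NetworkParams(n_neurons=10**6)
        proj = sample_input_projection(p, fraction=1.0, sigma=1.0, rng=rng)
        w = proj.weights[0]
        assert np.all(w >= 0)
        assert w.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.005)

    def test_zero_sigma_gives_zero_weights(self, rng):
        proj = sample_input_projection(NetworkParams(n_neurons=100), 0.5, 0.0, rng)
        assert np.all(proj.weights == 0)

    def test_input_set_size_and_support(self, rng):
        p = NetworkParams(n_neurons=200)
        proj = sample_input_projection(p, fraction=0.25, sigma=2.0, rng=rng, n_channels=3)
        for k in range(3):
            assert proj.input_sets[k].size == 50
            outside = np.setdiff1d(np.arange(200), proj.input_sets[k])
            assert np.all(proj.weights[k, outside] == 0)

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ParameterError):
            sample_input_projection(NetworkParams(n_neurons=10), 0.0, 1.0, rng)


class TestSpatialProjection:
    def test_center_neuron_weight_is_one(self, rng):
        layout = SpatialLayout(positions=np.array([[0.0, 0.0], [3.0, 0.0]]), center=np.zeros(2))
        proj = sample_spatial_projection(layout, sigma=1.0, n_input=2, eta_scale=0.0, rng=rng)
        i_center = int(np.argmin(layout.distances))
        assert proj.weights[0, i_center] == pytest.approx(1.0)

    def test_half_width_distance_gives_half_weight(self, rng):
        # direct evaluation of the Gaussian falloff: w = 0.5 at d = sigma*sqrt(2 ln 2)
        sigma = 1.7
        d = sigma * np.sqrt(2 * np.log(2))
        layout = SpatialLayout(positions=np.array([[0.0, 0.0], [d, 0.0]]), center=np.zeros(2))
        proj = sample_spatial_projection(layout, sigma=sigma, n_input=2, eta_scale=0.0, rng=rng)
        assert proj.weights[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_equidistant_neurons_selected_uniformly(self, rng):
        # all distances equal -> every neuron equally likely to be the pick
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        layout = SpatialLayout(
            positions=np.column_stack([np.cos(ang), np.sin(ang)]), center=np.zeros(2)
        )
        counts = np.zeros(8)
        for _ in range(4000):
            proj = sample_spatial_projection(layout, 1.0, 1, 0.0, rng)
            counts[proj.input_sets[0][0]] += 1
        assert counts.min() > 4000 / 8 * 0.7

    def test_selection_favors_center(self, rng):
        layout = SpatialLayout.grid(11)
        picks = []
        for s in range(200):
            proj = sample_spatial_projection(layout, 2.0, 10, 0.0, np.random.default_rng(s))
            picks.append(layout.distances[proj.input_sets[0]].mean())
        assert np.mean(picks) < layout.distances.mean()

    def test_weights_clipped_nonnegative(self, rng):
        layout = SpatialLayout.grid(9)
        proj = sample_spatial_projection(layout, 0.5, 81, eta_scale=0.5, rng=rng)
        assert np.all(proj.weights >= 0)


class TestStepNoise:
    def test_zero_amplitude_decays_geometrically(self, rng):
        p = NetworkParams(n_neurons=4, noise_amp=0.0, noise_tau=0.5)
        h = np.ones(4)
        h1 = step_noise(h, p, rng)
        assert h1 == pytest.approx(np.exp(-p.dt / p.noise_tau) * h)

    def test_lag1_autocorrelation_matches_ar1(self):
        # AR(1) oracle: corr(H_t, H_{t+1}) = decay factor a
        p = NetworkParams(n_neurons=1, noise_amp=0.3, noise_tau=0.5)
        rng = np.random.default_rng(0)
        h = np.zeros(1)
        xs = np.empty(10**5)
        for i in range(xs.size):
            h = step_noise(h, p, rng)
            xs[i] = h[0]
        rho = np.corrcoef(xs[:-1], xs[1:])[0, 1]
        assert rho == pytest.approx(p.noise_decay, abs=0.02)

    def test_literal_exponent_mode(self, rng):
        p = NetworkParams(n_neurons=2, noise_tau=0.5, literal_noise_exponent=True)
        assert p.noise_decay == pytest.approx(np.exp(-0.5))


class TestStep:
    def test_uncoupled_undriven_decay(self, rng):
        # J=0, no drive: x decays by (1 - dt/tau) each step
        p = NetworkParams(n_neurons=5)
        conn = Connectivity(np.zeros((5, 5)))
        x0 = np.array([1.0, -2.0, 0.5, 3.0, -0.1])
        s = NetworkState(x=x0.copy(), h_wn=np.zeros(5))
        s = step(s, conn, None, None, p, rng)
        assert s.x == pytest.approx((1 - p.dt / p.tau) * x0)
        assert s.t == pytest.approx(p.dt)

    def test_single_neuron_converges_to_drive_fixed_point(self, rng):
        # analytic fixed point of tau*xdot = -x + c is x* = c
        from mesovar.network import InputProjection

        p = NetworkParams(n_neurons=1)
        conn = Connectivity(np.zeros((1, 1)))
        proj = InputProjection(
            weights=np.ones((1, 1)), input_sets=(np.array([0]),), sigma=np.array([1.0])
        )
        c = 0.7
        s = NetworkState(x=np.zeros(1), h_wn=np.zeros(1))
        for _ in range(400):
            s = step(s, conn, proj, np.array([c]), p, rng)
        assert s.x[0] == pytest.approx(c, abs=1e-6)

    def test_shape_mismatch_raises(self, rng):
        p = NetworkParams(n_neurons=3)
        conn = Connectivity(np.zeros((4, 4)))
        with pytest.raises(ParameterError):
            step(NetworkState(np.zeros(3), np.zeros(3)), conn, None, None, p, rng)

    def test_silent_vs_chaotic_regimes(self):
        # g < 1 decays to silence; g > 1 sustains irregular activity
        stds = {}
        for g in (0.8, 1.3):
            rng = np.random.default_rng(42)
            p = NetworkParams(n_neurons=500, gain=g)
            conn = sample_connectivity(p, rng)
            s = initial_state(p, rng)
            n_steps = int(200 * p.tau / p.dt)
            tail = []
            for i in range(n_steps):
                s = step(s, conn, None, None, p, rng)
                if i > n_steps // 2:
                    tail.append(s.x.copy())
            stds[g] = np.std(tail)
        assert stds[0.8] < 1e-3
        assert stds[1.3] > 0.05

    def test_bounded_activity_under_bounded_drive(self, rng):
        p = NetworkParams(n_neurons=80, gain=1.3, noise_amp=0.2)
        conn = sample_connectivity(p, rng)
        s = initial_state(p, rng)
        for _ in range(20000):
            s = step(s, conn, None, None, p, rng)
            assert np.all(np.isfinite(s.x))
        # tanh bounds the recurrent input, so activity stays order sqrt(N)*g/sqrt(N)
        assert np.max(np.abs(s.x)) < 10 * p.gain

    def test_euler_halving_consistency(self):
        # halving dt changes a 10-tau trajectory by < 5% relative L2
        rng = np.random.default_rng(0)
        p1 = NetworkParams(n_neurons=200, gain=1.3, dt=0.05)
        p2 = NetworkParams(n_neurons=200, gain=1.3, dt=0.025)
        conn = sample_connectivity(p1, rng)
        x0 = rng.standard_normal(200) * 0.5

        def trajectory(p, substeps):
            s = NetworkState(x=x0.copy(), h_wn=np.zeros(200))
            out = [x0.copy()]
            for _ in range(int(10 * p1.tau / p1.dt)):
                for _ in range(substeps):
                    s = step(s, conn, None, None, p, rng)
                out.append(s.x.copy())
            return np.array(out)

        t1, t2 = trajectory(p1, 1), trajectory(p2, 2)
        assert np.linalg.norm(t1 - t2) / np.linalg.norm(t1) < 0.05


class TestSimulateTrials:
    def _setup(self, seed=0, n=60, n_trials=5, amplitude=1.5):
        rng = np.random.default_rng(seed)
        p = NetworkParams(n_neurons=n, gain=1.3, noise_amp=0.05)
        conn = sample_connectivity(p, rng)
        proj = sample_input_projection(p, 0.3, 1.0, rng)
        prot = build_pulse_protocol(n_trials, amplitude, 1.0, (4.0, 6.0), rng)
        return conn, proj, prot, p, rng

    def test_trial_tensor_layout(self):
        conn, proj, prot, p, rng = self._setup()
        t = simulate_trials(conn, proj, prot, p, rng, pre_time=2.0, post_time=2.0)
        assert t.data.shape == (5, 60, 50)
        assert (t.onset_idx, t.offset_idx) == (20, 30)
        assert np.all(t.labels == 0)
        assert t.sample_rate == 10.0

    def test_zero_trial_protocol_gives_empty_tensor(self):
        conn, proj, _, p, rng = self._setup()
        prot = build_pulse_protocol(0, 1.0, 1.0, (4.0, 6.0), rng)
        t = simulate_trials(conn, proj, prot, p, rng)
        assert t.n_trials == 0
        assert t.data.shape[1] == 60

    def test_seed_determinism_bit_identical(self):
        runs = []
        for _ in range(2):
            conn, proj, prot, p, rng = self._setup(seed=5)
            runs.append(simulate_trials(conn, proj, prot, p, rng))
        assert np.array_equal(runs[0].data, runs[1].data)

    def test_stimulus_moves_input_neurons(self):
        conn, proj, prot, p, rng = self._setup(amplitude=6.0)
        t = simulate_trials(conn, proj, prot, p, rng)
        inset = proj.input_sets[0]
        pre = t.data[:, inset, t.onset_idx - 5 : t.onset_idx].mean()
        stim = t.data[:, inset, t.onset_idx + 2 : t.offset_idx].mean()
        assert stim > pre + 0.5

    def test_recording_stride_guard(self):
        conn, proj, prot, p, rng = self._setup()
        with pytest.raises(ParameterError):
            simulate_trials(conn, proj, prot, p, rng, sample_rate=100.0)

    def test_reset_mode_runs(self):
        conn, proj, prot, p, rng = self._setup()
        t = simulate_trials(conn, proj, prot, p, rng, reset_between_trials=True)
        assert t.n_trials == 5
        assert np.all(np.isfinite(t.data))
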