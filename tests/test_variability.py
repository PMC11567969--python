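"""Trial-variability statistics against hand-computed and closed-form oracles."""

import numpy as np
import pytest

from mesovar.network import TrialTensor
from mesovar.variability import (
    UndefinedVarianceError,
    compute_osi,
    fit_relaxation_constants,
    functional_connectivity,
    normalize_variability_trace,
    population_vector_correlation,
    preprocess_traces,
    responsive_counts,
    single_neuron_variance,
    sweep_and_fit,
    timepoint_variance,
    trial_variance,
    variability_summary,
)


def test_variability_summary_bundles_consistent_statistics(pulse_tensor):
    w = pulse_tensor.post_window(1.0)
    res = variability_summary(pulse_tensor, window=w)
    assert res.v_total == pytest.approx(trial_variance(pulse_tensor, window=w))
    assert res.v_trace.shape[0] == w[1] - w[0]
    assert res.per_neuron.shape[0] == pulse_tensor.n_neurons
    assert res.window == w


def make_tensor(data, labels=None, onset=0, offset=None, fs=10.0):
    data = np.asarray(data, dtype=float)
    offset = data.shape[2] if offset is None else offset
    labels = np.zeros(data.shape[0], dtype=int) if labels is None else np.asarray(labels)
    return TrialTensor(data=data, sample_rate=fs, labels=labels, onset_idx=onset, offset_idx=offset)


class TestPreprocess:
    def test_detrend_removes_planted_ramp(self, rng):
        # least-squares slope oracle on the output
        t = np.arange(200, dtype=float)
        trace = 0.3 * t + rng.normal(0, 0.5, 200)
        out = preprocess_traces(trace[None, :])[0]
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 1e-6

    def test_zscore_contract(self, rng):
        x = rng.normal(3.0, 2.0, size=(6, 120))
        out = preprocess_traces(x)
        assert np.abs(out.mean(axis=1)).max() < 1e-10
        assert out.std(axis=1) == pytest.approx(np.ones(6), abs=1e-10)

    def test_constant_trace_maps_to_zeros(self):
        out = preprocess_traces(np.full((2, 50), 7.0))
        assert np.all(out == 0)

    def test_tensor_roundtrip_preserves_metadata(self, pulse_tensor):
        out = preprocess_traces(pulse_tensor)
        assert out.onset_idx == pulse_tensor.onset_idx
        assert out.data.shape == pulse_tensor.data.shape


class TestTrialVariance:
    def test_identical_trials_give_zero(self):
        t = make_tensor(np.ones((4, 3, 5)))
        assert trial_variance(t) == 0.0

    def test_hand_worked_two_trial_example(self):
        # two trials, one neuron, one timepoint, values (1, 3):
        # Rbar = 2, V = (1/2) * ((1)^2 + (1)^2) / 2^2 = 0.25
        t = make_tensor(np.array([1.0, 3.0]).reshape(2, 1, 1))
        assert trial_variance(t) == pytest.approx(0.25)

    def test_scale_invariance(self, rng):
        data = rng.normal(1.0, 0.4, size=(5, 4, 6))
        t1, t2 = make_tensor(data), make_tensor(4.2 * data)
        assert trial_variance(t1) == pytest.approx(trial_variance(t2))

    def test_zero_mean_response_raises(self):
        data = np.stack([np.ones((2, 3)), -np.ones((2, 3))])
        with pytest.raises(UndefinedVarianceError):
            trial_variance(make_tensor(data))


class TestTimepointVariance:
    def test_identical_trials_zero_trace(self):
        v = timepoint_variance(make_tensor(np.ones((3, 2, 7))))
        assert np.all(v == 0)

    def test_time_constant_trials_constant_trace(self, rng):
        col = rng.normal(1.0, 0.5, size=(4, 3, 1))
        v = timepoint_variance(make_tensor(np.repeat(col, 6, axis=2)))
        assert v == pytest.approx(np.full(6, v[0]))

    def test_single_timepoint_equals_trial_variance(self, rng):
        data = rng.normal(1.0, 0.3, size=(5, 4, 9))
        t = make_tensor(data)
        v = timepoint_variance(t)
        for i in (0, 4, 8):
            assert v[i] == pytest.approx(trial_variance(t, window=(i, i + 1)))

    def test_zero_mean_timepoint_propagates_nan(self):
        data = np.ones((2, 1, 3))
        data[0, 0, 1], data[1, 0, 1] = 1.0, -1.0
        v = timepoint_variance(make_tensor(data))
        assert np.isnan(v[1]) and v[0] == 0.0


class TestNormalizeTrace:
    def test_baseline_mean_removed(self, rng):
        trace = rng.normal(2.0, 1.0, 50)
        out = normalize_variability_trace(trace, (0, 10))
        assert out[:10].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_sigma_is_identity_after_offset(self, rng):
        trace = rng.normal(0, 1, 30)
        out = normalize_variability_trace(trace, (0, 30), smoothing_sigma=0.0)
        assert out == pytest.approx(trace - trace.mean())

    def test_constant_trace_stays_constant_under_smoothing(self):
        # normalized-kernel convolution oracle: smoothing preserves constants
        out = normalize_variability_trace(np.full(40, 3.3), (0, 5), smoothing_sigma=2.5)
        assert out == pytest.approx(np.zeros(40), abs=1e-12)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_variability_trace(np.ones(10), (5, 5))


class TestSingleNeuronVariance:
    def test_reproducible_neuron_is_zero(self, rng):
        data = rng.normal(1, 0.3, size=(4, 3, 6))
        data[:, 0, :] = np.linspace(1, 2, 6)
        snv = single_neuron_variance(make_tensor(data))
        assert snv[0] == 0.0

    def test_single_neuron_tensor_matches_trial_variance(self, rng):
        data = rng.normal(1, 0.3, size=(5, 1, 8))
        t = make_tensor(data)
        assert single_neuron_variance(t)[0] == pytest.approx(trial_variance(t))

    def test_planted_reliable_subset_ranks_lowest(self, rng):
        data = rng.normal(1.0, 1.0, size=(10, 20, 6))
        data[:, :5, :] = 2.0 + rng.normal(0, 0.01, size=(10, 5, 6))
        snv = single_neuron_variance(make_tensor(data))
        assert set(np.argsort(snv)[:5]) == set(range(5))


class TestPopulationVectorCorrelation:
    def test_identical_trials_all_ones(self, rng):
        row = rng.normal(1, 1, size=(1, 6, 4))
        c, mean = population_vector_correlation(make_tensor(np.repeat(row, 3, axis=0)))
        assert mean == pytest.approx(1.0)

    def test_antiproportional_patterns_minus_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        data = np.stack([a[:, None], (-a + 5.0)[:, None]])  # two trials, 4 neurons, 1 frame
        c, mean = population_vector_correlation(make_tensor(data))
        assert c[0, 1] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self, rng):
        data = rng.normal(0, 1, size=(3, 10, 5))
        t = make_tensor(data)
        c, _ = population_vector_correlation(t, window=(1, 4))
        pv = data[:, :, 1:4].mean(axis=2)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = np.corrcoef(pv[i], pv[j])[0, 1]
                assert c[i, j] == pytest.approx(expected)

    def test_zero_variance_vector_flagged_nan(self, rng):
        data = rng.normal(0, 1, size=(3, 4, 2))
        data[1] = 2.0
        c, _ = population_vector_correlation(make_tensor(data))
        assert np.isnan(c[0, 1]) and np.isfinite(c[0, 2])


class TestFunctionalConnectivity:
    def test_duplicated_neuron_perfectly_coupled(self, rng):
        data = rng.normal(0, 1, size=(2, 3, 20))
        data[:, 1, :] = data[:, 0, :]
        fc = functional_connectivity(make_tensor(data))
        assert fc[0, 1] == pytest.approx(1.0)
        assert np.allclose(fc, fc.T, equal_nan=True)
        assert np.all(np.diag(fc) == 1.0)

    def test_independent_noise_near_zero(self, rng):
        data = rng.standard_normal((20, 2, 200))
        fc = functional_connectivity(make_tensor(data))
        assert abs(fc[0, 1]) < 0.05

    def test_constant_neuron_flagged(self, rng):
        data = rng.normal(0, 1, size=(2, 3, 10))
        data[:, 2, :] = 1.0
        fc = functional_connectivity(make_tensor(data))
        assert np.isnan(fc[0, 2])

    def test_short_window_rejected(self, rng):
        with pytest.raises(ValueError):
            functional_connectivity(make_tensor(rng.normal(size=(2, 2, 10))), window=(0, 2))


class TestResponsiveCounts:
    def test_all_zero_tensor_counts_zero(self):
        counts = responsive_counts(make_tensor(np.zeros((6, 4, 5))), max_trials=6)
        assert np.all(counts == 0)

    def test_hand_built_enumeration(self):
        # neuron 0 responsive in 3 trials, neuron 1 in 2, neuron 2 in 1
        data = np.zeros((3, 3, 4))
        data[:, 0, :] = 5.0
        data[:2, 1, :] = 5.0
        data[:1, 2, :] = 5.0
        counts = responsive_counts(make_tensor(data), threshold=1.96, max_trials=3)
        assert list(counts) == [3, 2, 1]

    def test_counts_non_increasing(self, rng):
        data = rng.normal(0, 2.0, size=(6, 30, 8))
        counts = responsive_counts(make_tensor(data), max_trials=6)
        assert np.all(np.diff(counts) <= 0)

    def test_quantile_rule_option(self, rng):
        data = rng.normal(0, 1, size=(4, 50, 6))
        counts = responsive_counts(make_tensor(data), max_trials=4, quantile=0.2)
        assert counts[0] >= counts[-1] >= 0


class TestRelaxationFit:
    def test_exact_exponential_recovery(self):
        t = np.arange(80) * 0.1
        trace = np.concatenate([0.5 + 1.0 * np.exp(-t[:40] / 2.0), 0.2 + 0.9 * (1 - np.exp(-t[:40] / 1.5))])
        fit = fit_relaxation_constants(trace, 0, 40, sample_rate=10.0)
        assert fit.tau_descent == pytest.approx(2.0, abs=1e-3)
        assert fit.tau_rise == pytest.approx(1.5, abs=1e-3)

    def test_noisy_exponential_recovery_within_15pct(self):
        # simulation-recovery oracle at SNR ~ 10
        taus = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.arange(60) * 0.1
            seg = 1.0 * np.exp(-t / 2.0) + rng.normal(0, 0.1, 60)
            trace = np.concatenate([seg, 0.5 + 0.5 * t[:10]])
            fit = fit_relaxation_constants(trace, 0, 60, sample_rate=10.0)
            taus.append(fit.tau_descent)
        assert np.median(taus) == pytest.approx(2.0, rel=0.15)

    def test_step_trace_gives_sub_sample_tau(self):
        trace = np.concatenate([np.ones(1), np.zeros(19), np.zeros(20)])
        fit = fit_relaxation_constants(trace, 0, 20, sample_rate=10.0)
        assert fit.tau_descent < 0.1

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            fit_relaxation_constants(np.ones(8), 0, 3, 10.0)


class TestSweepAndFit:
    def test_exact_exponential_perfect_fit(self):
        amps = np.array([1.0, 2.0, 3.0, 4.0])
        rows = [(a, float(np.exp(-2 * a)), 0) for a in amps]
        tab = sweep_and_fit(rows)
        assert tab.slope == pytest.approx(-2.0)
        assert tab.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        amps = np.repeat([1.0, 2.0, 3.0], 4)
        vs = np.exp(rng.normal(-amps, 0.3))
        rows = list(zip(amps, vs, np.zeros(12, dtype=int)))
        tab = sweep_and_fit(rows)
        x = np.column_stack([amps, np.ones_like(amps)])
        beta = np.linalg.lstsq(x, np.log(vs), rcond=None)[0]
        assert tab.slope == pytest.approx(beta[0])
        assert tab.intercept == pytest.approx(beta[1])

    def test_nonpositive_v_excluded_with_warning(self):
        rows = [(1.0, 0.5), (2.0, 0.0), (3.0, 0.2), (4.0, 0.1)]
        with pytest.warns(UserWarning):
            tab = sweep_and_fit(rows)
        assert len(tab.rows) == 3


class TestOSI:
    def _tensor(self, class_resp, n_per=3):
        # class_resp: K x N mean responses
        k, n = class_resp.shape
        labels = np.repeat(np.arange(k), n_per)
        data = np.stack([np.tile(class_resp[c][:, None], (1, 4)) for c in labels])
        return make_tensor(data, labels=labels)

    def test_pure_selective_neuron_is_one(self):
        resp = np.zeros((4, 1))
        resp[0, 0] = 2.0
        assert compute_osi(self._tensor(resp))[0] == pytest.approx(1.0)

    def test_flat_neuron_is_zero(self):
        resp = np.full((4, 1), 1.5)
        assert compute_osi(self._tensor(resp))[0] == pytest.approx(0.0)

    def test_hand_built_three_to_one_ratio(self):
        # r_pref=3, r_orth=1 -> OSI = (3-1)/(3+1) = 0.5
        resp = np.array([[3.0], [1.0]])
        assert compute_osi(self._tensor(resp))[0] == pytest.approx(0.5)

    def test_silent_neuron_flagged_nan(self):
        resp = np.zeros((2, 1))
        assert np.isnan(compute_osi(self._tensor(resp))[0])
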