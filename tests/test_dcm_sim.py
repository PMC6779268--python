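import numpy as np
import pytest
from scipy import signal, stats

from fraccum.dcm_sim import (
    ConfigurationError,
    DCMConfig,
    HemoParams,
    generate_pink_noise,
    load_hemo_priors,
    sample_hemo_params,
    sample_input_process,
    simulate_network,
    simulate_two_node_batch,
    two_node_adjacency,
)


class TestHemoParams:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            HemoParams(kappa=0.65, gamma=0.41, tau=0.98, alpha=1.2, e0=0.34)
        with pytest.raises(ConfigurationError):
            HemoParams(kappa=-1.0, gamma=0.41, tau=0.98, alpha=0.32, e0=0.34)

    def test_zero_variance_priors_return_means(self):
        priors = load_hemo_priors()
        degenerate = {k: dict(v, var=0.0) for k, v in priors.items()}
        draws = sample_hemo_params(np.random.default_rng(0), 3, degenerate)
        for h in draws:
            assert h.tau == priors["tau"]["mean"]
            assert h.kappa == priors["kappa"]["mean"]

    def test_seed_determinism(self):
        a = sample_hemo_params(np.random.default_rng(5), 4)
        b = sample_hemo_params(np.random.default_rng(5), 4)
        assert a == b

    def test_monte_carlo_mean_matches_prior(self):
        # truncation is mild for tau, so the sample mean tracks the prior mean
        priors = load_hemo_priors()
        draws = sample_hemo_params(np.random.default_rng(11), 10_000)
        taus = np.array([h.tau for h in draws])
        se = np.sqrt(priors["tau"]["var"] / taus.size)
        assert abs(taus.mean() - priors["tau"]["mean"]) < 3 * se

    def test_negative_prior_variance_rejected(self):
        priors = load_hemo_priors()
        priors["tau"] = dict(priors["tau"], var=-1.0)
        with pytest.raises(ConfigurationError):
            sample_hemo_params(np.random.default_rng(0), 2, priors)

    def test_draws_respect_domain(self):
        draws = sample_hemo_params(np.random.default_rng(3), 1000)
        for h in draws:
            assert 0 < h.alpha < 1
            assert 0 < h.e0 < 1
            assert h.tau > 0


class TestInputProcess:
    def test_zero_rates_from_off_state_all_zero(self):
        ts = sample_input_process(
            np.random.default_rng(0), fs=100, duration=5, magnitude=2.0,
            rate_on_off=0.0, rate_off_on=0.0,
        )
        assert np.all(ts.values == 0)

    def test_two_level_signal(self):
        m = 1.7
        ts = sample_input_process(
            np.random.default_rng(1), fs=100, duration=60, magnitude=m,
            rate_on_off=1.0, rate_off_on=1.0,
        )
        assert set(np.unique(ts.values)) <= {0.0, m}
        assert (ts.values == m).any()

    def test_mean_dwell_time(self):
        # symmetric 1/s switch rates -> exponential dwell with mean 1 s
        ts = sample_input_process(
            np.random.default_rng(2), fs=200, duration=600, magnitude=1.0,
            rate_on_off=1.0, rate_off_on=1.0,
        )
        on = ts.values > 0
        changes = np.flatnonzero(np.diff(on.astype(int)) != 0)
        dwells = np.diff(changes) / 200.0
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 1.0) < 3 * se

    def test_length(self):
        ts = sample_input_process(np.random.default_rng(3), fs=250, duration=4)
        assert len(ts) == 1000


class TestPinkNoise:
    def test_zero_variance_is_silent(self):
        ts = generate_pink_noise(np.random.default_rng(0), 1024, 0.0)
        assert np.all(ts.values == 0)

    def test_exact_variance(self):
        v = 2.31
        ts = generate_pink_noise(np.random.default_rng(1), 2**16, v)
        assert ts.values.var() == pytest.approx(v, rel=1e-2)
        assert abs(ts.values.mean()) < 1e-10

    def test_psd_slope_minus_one(self):
        ts = generate_pink_noise(np.random.default_rng(2), 2**16, 1.0)
        f, p = signal.welch(ts.values, nperseg=4096)
        band = (f > 0.01 * 0.5) & (f < 0.5)
        slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_pink_noise(np.random.default_rng(0), 8, 1.0)


class TestConfig:
    def test_positive_diagonal_rejected(self):
        with pytest.raises(ConfigurationError, match="diagonal"):
            DCMConfig(adjacency=np.array([[1.0, 0.0], [0.9, -1.0]]))

    def test_non_square_rejected(self):
        with pytest.raises(ConfigurationError):
            DCMConfig(adjacency=np.zeros((2, 3)))

    def test_paper_scale_sample_count(self):
        cfg = DCMConfig(adjacency=two_node_adjacency(0.9), fs=200.0, duration=600.0)
        assert cfg.n_steps == 120_000


class TestSimulateNetwork:
    @staticmethod
    def _quiet_config(duration=20.0):
        return DCMConfig(
            adjacency=two_node_adjacency(0.9),
            fs=200.0,
            duration=duration,
            input_magnitude=np.zeros(2),
            input_switch_rates=np.zeros((2, 2)),
        )

    def test_zero_input_settles_to_rest(self):
        result = simulate_network(self._quiet_config(), rng=np.random.default_rng(0))
        tail = result.bold[result.bold.shape[0] // 2 :]
        assert tail.var(axis=0).max() < 1e-10

    def test_sample_count_matches_duration(self):
        cfg = DCMConfig(adjacency=two_node_adjacency(0.9), fs=200.0, duration=30.0)
        result = simulate_network(cfg, rng=np.random.default_rng(1))
        assert result.bold.shape == (6000, 2)
        assert result.neuronal.shape == (6000, 2)

    def test_determinism_bit_identical(self):
        cfg = DCMConfig(adjacency=two_node_adjacency(0.9), fs=200.0, duration=10.0, seed=42)
        a = simulate_network(cfg)
        b = simulate_network(cfg)
        np.testing.assert_array_equal(a.bold, b.bold)
        np.testing.assert_array_equal(a.inputs, b.inputs)

    def test_impulse_propagates_downstream_with_delay(self):
        # node 0 gets a sustained input; node 1 only feels it through A
        cfg = DCMConfig(
            adjacency=two_node_adjacency(0.9),
            fs=200.0,
            duration=5.0,
            input_magnitude=np.array([1.0, 0.0]),
            input_switch_rates=np.array([[0.0, 1000.0], [0.0, 0.0]]),
        )
        result = simulate_network(cfg, rng=np.random.default_rng(2))
        z = result.neuronal
        t0 = np.argmax(z[:, 0] > 1e-4)
        t1 = np.argmax(z[:, 1] > 1e-4)
        assert z[:, 1].max() > 0.1
        assert t1 > t0

    def test_neuronal_linearity_in_input_magnitude(self):
        def run(mag):
            cfg = DCMConfig(
                adjacency=two_node_adjacency(0.9),
                fs=200.0,
                duration=10.0,
                input_magnitude=np.array([mag, 0.0]),
                input_switch_rates=np.zeros((2, 2)),
                seed=3,
            )
            cfg = DCMConfig(
                adjacency=cfg.adjacency, fs=cfg.fs, duration=cfg.duration,
                input_magnitude=cfg.input_magnitude,
                input_switch_rates=np.array([[0.0, 1000.0], [0.0, 0.0]]),
                seed=3,
            )
            return simulate_network(cfg).neuronal

        z1 = run(0.5)
        z2 = run(1.0)
        np.testing.assert_allclose(z2, 2 * z1, rtol=1e-9, atol=1e-12)

    def test_smaller_euler_step_agrees(self):
        # deterministic constant input: halving the step barely moves BOLD
        def run(fs):
            cfg = DCMConfig(
                adjacency=two_node_adjacency(0.9),
                fs=fs,
                duration=20.0,
                input_magnitude=np.array([1.0, 0.0]),
                input_switch_rates=np.array([[0.0, 1e9], [0.0, 0.0]]),
            )
            return simulate_network(cfg, rng=np.random.default_rng(0))

        coarse = run(200.0)
        fine = run(400.0)
        peak_coarse = coarse.bold[:, 1].max()
        peak_fine = fine.bold[:, 1].max()
        assert peak_coarse == pytest.approx(peak_fine, rel=0.02)


class TestBatch:
    def test_matches_config_shape(self):
        bu, bd = simulate_two_node_batch(
            np.random.default_rng(0), 4, 0.9, duration=10.0
        )
        assert bu.shape == (4, 2000)
        assert bd.shape == (4, 2000)

    def test_determinism(self):
        a = simulate_two_node_batch(np.random.default_rng(9), 3, 0.9, duration=10.0)
        b = simulate_two_node_batch(np.random.default_rng(9), 3, 0.9, duration=10.0)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_null_connection_node_exchangeability(self):
        # with no connection and i.i.d. node configs the per-node BOLD
        # variance summaries are exchangeable
        bu, bd = simulate_two_node_batch(
            np.random.default_rng(21), 40, 0.0, duration=30.0
        )
        v0 = bu.var(axis=1)
        v1 = bd.var(axis=1)
        p = stats.mannwhitneyu(v0, v1).pvalue
        assert p > 0.01

    def test_noisy_batch_finite(self):
        bu, bd = simulate_two_node_batch(
            np.random.default_rng(5), 4, 0.9, duration=10.0,
            noise_variance=np.array([5.0, 5.0]), noise_kind="pink",
        )
        assert np.isfinite(bu).all() and np.isfinite(bd).all()
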