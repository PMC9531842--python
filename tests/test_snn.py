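"""IF dynamics, rate coding, conversion fidelity, threshold exploration."""

import numpy as np
import pytest

import neorespire as nr
from neorespire.errors import ValidationError
from neorespire.network import Dense, Flatten, NetworkModel
from neorespire.snn import (
    IFNeuronState,
    MembraneDynamics,
    SNNConfig,
    SpikingNetwork,
    convert_to_snn,
    hidden_rates,
    if_step,
    membrane_potential,
    rate_encode,
    snn_infer,
    threshold_sweep,
)


def _random_relu_net(seed=0, hidden=16):
    """A 2-hidden-ReLU stack with weights sized to keep activations alive."""
    rng = np.random.default_rng(seed)
    model = NetworkModel(
        [Flatten(), Dense(hidden, activation="relu"), Dense(1, activation="sigmoid")],
        input_shape=(2, 1), seed=seed)
    model.layers[1].W[...] = rng.normal(scale=0.8, size=model.layers[1].W.shape)
    model.layers[1].b[...] = rng.normal(scale=0.2, size=hidden)
    model.layers[2].W[...] = rng.normal(scale=0.8, size=model.layers[2].W.shape)
    return model


class TestIFStep:
    def test_subthreshold_integration(self):
        s = IFNeuronState(v_m=0.0, v_th=1.0)
        s, spiked = if_step(s, 0.5 * 1 + 0.25 * 1)
        assert not spiked and s.v_m == pytest.approx(0.75)

    def test_spike_with_subtraction_reset(self):
        s = IFNeuronState(v_m=0.9, v_th=1.0)
        s, spiked = if_step(s, 0.2)
        assert spiked
        assert s.v_m == pytest.approx(0.1)
        assert s.spike_count == 1

    def test_zero_reset_mode_discards_residual(self):
        s, spiked = if_step(IFNeuronState(v_m=0.9, v_th=1.0), 0.2, reset="zero")
        assert spiked and s.v_m == 0.0

    def test_no_input_no_leak(self):
        s = IFNeuronState(v_m=0.4, v_th=1.0)
        s, spiked = if_step(s, 0.0)
        assert not spiked and s.v_m == 0.4

    @pytest.mark.parametrize("c,v_th,T", [(0.3, 1.0, 1000), (0.07, 1.0, 500),
                                          (0.5, 2.0, 400), (0.9, 1.3, 777)])
    def test_constant_drive_count_matches_floor_oracle(self, c, v_th, T):
        s = IFNeuronState(v_th=v_th)
        for _ in range(T):
            s, _ = if_step(s, c)
        assert abs(s.spike_count - np.floor(c * T / v_th)) <= 1


class TestMembranePotential:
    def test_no_spikes_stays_at_rest(self):
        dyn = MembraneDynamics(u0=-0.2)
        assert membrane_potential(dyn, w=2.0, t=10.0) == -0.2

    def test_delta_kernel_counts_past_spikes(self):
        dyn = MembraneDynamics(u0=0.0, a=1.0, spike_times=(1.0, 2.0, 3.0))
        assert membrane_potential(dyn, w=0.5, t=5.0) == pytest.approx(1.5)
        assert membrane_potential(dyn, w=0.5, t=1.5) == pytest.approx(0.5)

    def test_linear_in_weight(self):
        dyn = MembraneDynamics(u0=0.3, spike_times=(0.5, 1.5))
        u1 = membrane_potential(dyn, 0.4, 2.0) - 0.3
        u2 = membrane_potential(dyn, 0.8, 2.0) - 0.3
        assert u2 == pytest.approx(2 * u1)

    def test_exponential_kernel_decays(self):
        dyn = MembraneDynamics(u0=0.0, kernel=lambda s: np.exp(-s / 2.0),
                               spike_times=(0.0,))
        assert membrane_potential(dyn, 1.0, 4.0) == pytest.approx(np.exp(-2.0))


class TestRateEncode:
    def test_zero_intensity_zero_spikes(self):
        assert rate_encode(np.zeros(3), T=200, seed=0).sum() == 0

    def test_binomial_moments_at_half_rate(self):
        counts = [rate_encode(np.array([0.5]), T=1000, seed=s).sum() for s in range(40)]
        assert np.mean(counts) == pytest.approx(500, abs=4 * 15.8 / np.sqrt(40) + 2)
        assert np.std(counts) == pytest.approx(15.8, rel=0.5)

    def test_deterministic_mode_exact_and_seed_free(self):
        a = rate_encode(np.array([0.37]), T=1000, seed=1, deterministic=True)
        b = rate_encode(np.array([0.37]), T=1000, seed=99, deterministic=True)
        np.testing.assert_array_equal(a, b)
        assert a.sum() == 370

    def test_r_max_scales_expected_count(self):
        a = rate_encode(np.array([1.0]), T=1000, r_max=0.25, seed=0, deterministic=True)
        assert a.sum() == 250


class TestConversion:
    @pytest.fixture()
    def converted(self):
        model = _random_relu_net(seed=0)
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(200, 2))
        # label by the network's own decision boundary: a one-sided rate code
        # can only resolve boundaries in the positive-drive region
        y = (model.predict_proba(X) >= 0.5).astype(int)
        cfg = SNNConfig(T=2000, encoder="deterministic")
        return model, X, y, convert_to_snn(model, X, y, cfg=cfg, seed=2)

    def test_topology_isomorphic_to_source(self, converted):
        model, X, y, net = converted
        assert net.layer_sizes == [2, 16, 1]
        assert net.weights[0].shape == (2, 16)
        assert net.weights[1].shape == (16, 1)

    def test_canonical_model_neuron_counts(self, study):
        net = convert_to_snn(study.model, study.train_set.X, study.train_set.y,
                             cfg=SNNConfig(T=100), seed=0)
        assert net.layer_sizes == [2, 128, 200, 100, 1]

    def test_dead_model_rejected(self):
        model = _random_relu_net(seed=3)
        model.layers[1].W[...] = 0.0
        model.layers[1].b[...] = 0.0
        X = np.random.default_rng(0).uniform(0, 1, size=(50, 2))
        with pytest.raises(ValidationError, match="lambda"):
            convert_to_snn(model, X, cfg=SNNConfig(T=100))

    def test_hidden_rates_track_ann_activations(self, converted):
        model, X, y, net = converted
        Xe = X[:60]
        rates = hidden_rates(net, Xe, seed=5)
        ann_hidden = np.maximum(
            Xe @ model.layers[1].W + model.layers[1].b, 0.0)
        corr = np.corrcoef(rates[0].ravel(), ann_hidden.ravel())[0, 1]
        assert corr > 0.99

    def test_deterministic_record_bit_identical(self, converted):
        model, X, y, net = converted
        _, r1 = snn_infer(net, X[:10], seed=3)
        _, r2 = snn_infer(net, X[:10], seed=11)  # encoder ignores the seed
        for a, b in zip(r1.counts, r2.counts):
            np.testing.assert_array_equal(a, b)
        assert r1.routing_events == r2.routing_events

    def test_routing_events_conservation(self, converted):
        model, X, y, net = converted
        _, record = snn_infer(net, X[:20], seed=4)
        expected = sum(int(c @ f) for c, f in zip(record.counts, net.fan_out))
        assert record.routing_events == expected

    def test_agreement_with_calibration_labels(self, converted):
        # the decoder is fitted to the calibration labels, so the converted
        # network should reproduce them almost everywhere
        model, X, y, net = converted
        labels, _ = snn_infer(net, X, seed=6)
        assert np.mean(labels == y) >= 0.9

    def test_save_load_round_trip(self, tmp_path, converted):
        model, X, y, net = converted
        net.save(str(tmp_path / "snn"))
        back = SpikingNetwork.load(str(tmp_path / "snn"))
        l1, _ = snn_infer(net, X[:20], seed=7)
        l2, _ = snn_infer(back, X[:20], seed=7)
        np.testing.assert_array_equal(l1, l2)
        assert back.decision_rate == net.decision_rate


class TestThresholdSweep:
    @pytest.fixture()
    def sweep_setup(self):
        model = _random_relu_net(seed=8)
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, size=(400, 2))
        z = model.predict_proba(X)
        y = (z > np.median(z)).astype(int)
        net = convert_to_snn(model, X[:200], y[:200],
                             cfg=SNNConfig(T=400, encoder="deterministic"), seed=10)
        return net, X[200:], y[200:]

    def test_matrix_shape_and_spike_monotonicity(self, sweep_setup):
        net, X, y = sweep_setup
        sets = [(X[:50], y[:50]), (X, y)]
        res = threshold_sweep(net, sets, [1.0, 2.0, 5.0], seed=0)
        assert res["accuracy"].shape == (3, 2)
        assert res["total_spikes"].shape == (3, 2)
        # higher thresholds can only suppress firing
        assert np.all(np.diff(res["total_spikes"], axis=0) <= 0)

    def test_huge_threshold_degrades_to_majority_rate(self, sweep_setup):
        net, X, y = sweep_setup
        res = threshold_sweep(net, [(X, y)], [1e6], seed=0)
        majority = max(y.mean(), 1 - y.mean())
        calib_majority = net.majority_fallback
        expected = y.mean() if calib_majority == 1 else 1 - y.mean()
        assert res["accuracy"][0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(majority, abs=0.1)

    def test_empty_grid_rejected(self, sweep_setup):
        net, X, y = sweep_setup
        with pytest.raises(ValidationError):
            threshold_sweep(net, [(X, y)], [])


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [dict(T=0), dict(v_th=0.0), dict(r_max=0.0),
                                    dict(encoder="morse"), dict(reset="bounce")])
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValidationError):
            SNNConfig(**kw)

    def test_zero_T_inference_rejected(self, study):
        net = convert_to_snn(study.model, study.train_set.X[:50], study.train_set.y[:50],
                             cfg=SNNConfig(T=10), seed=0)
        with pytest.raises(ValidationError):
            snn_infer(net, study.test_set.X[:2], T=0)
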