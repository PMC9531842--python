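"""Rate-coded spiking conversion of the trained classifier.

Each hidden ReLU unit becomes an integrate-and-fire (IF) neuron without leak:

    v_m(t+1) = v_m(t) + sum_i w_i x_i(t) + bias

firing when v_m >= V_th with a reset-by-subtraction (v_m -= V_th), which
preserves the proportionality between a neuron's firing rate over T steps and
the ReLU activation it replaces. Biases become constant per-step input
currents. Per-layer weight normalization divides layer l's weights by
lambda_l, the maximum activation observed on a calibration batch (and
multiplies by lambda_{l-1}), keeping drives in the encodable [0, 1] range.

Inputs are standardized features, which can be negative; an affine map g
sends the calibrated input range into [0, 1] for rate encoding, and the
offset this introduces is folded into the first layer's bias currents.
Spike trains are Bernoulli with per-step probability g(x) * r_max (or evenly
spaced in deterministic mode). The single sigmoid output unit is decoded by
spike count: the decision rate is calibrated at the network's operating point
by maximizing accuracy on the calibration batch (the sigmoid logits of a
confident classifier are heavily right-skewed, so a fixed fraction of the
maximum rate sits far above the class boundary); if the operating point
silences the output entirely, the decoder degenerates to the calibration
majority class.

Raising V_th throttles every layer's firing, trading accuracy for spikes
(hence energy); ``threshold_sweep`` walks a V_th grid across evaluation sets
of different sizes and reports accuracy plus spike totals per cell.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from neorespire.errors import ValidationError
from neorespire.network import Conv1D, Dense, Dropout, Flatten, MaxPool1D, NetworkModel

__all__ = [
    "SNNConfig", "IFNeuronState", "MembraneDynamics", "SpikeRecord",
    "SpikingNetwork", "convert_to_snn", "if_step", "membrane_potential",
    "rate_encode", "snn_infer", "hidden_rates", "threshold_sweep",
]


@dataclass(frozen=True)
class SNNConfig:
    """Simulation horizon, threshold, encoder and reset choices."""

    T: int = 1000
    v_th: float = 1.0
    r_max: float = 1.0
    encoder: str = "bernoulli"      # or 'deterministic' (evenly spaced spikes)
    reset: str = "subtract"         # or 'zero'
    decision_fraction: float = 0.5  # of the calibrated max output rate
    calibration_subsample: int = 100

    def __post_init__(self):
        if self.T < 1:
            raise ValidationError("T must be >= 1")
        if self.v_th <= 0:
            raise ValidationError("V_th must be positive")
        if not (0 < self.r_max <= 1):
            raise ValidationError("r_max must be in (0, 1]")
        if self.encoder not in ("bernoulli", "deterministic"):
            raise ValidationError("encoder must be 'bernoulli' or 'deterministic'")
        if self.reset not in ("subtract", "zero"):
            raise ValidationError("reset must be 'subtract' or 'zero'")


# ---------------------------------------------------------------------------
# Single-neuron primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IFNeuronState:
    """One IF neuron: membrane potential, threshold, bias drive, spike tally."""

    v_m: float = 0.0
    v_th: float = 1.0
    bias_current: float = 0.0
    spike_count: int = 0

    def __post_init__(self):
        if self.v_th <= 0:
            raise ValidationError("V_th must be positive")
        if self.spike_count < 0:
            raise ValidationError("spike_count must be >= 0")


def if_step(state: IFNeuronState, weighted_input: float,
            reset: str = "subtract") -> tuple[IFNeuronState, bool]:
    """One synchronous step: integrate, compare to threshold, reset.

    Subtraction reset keeps the residual above-threshold charge, which is
    what makes spike rate proportional to drive; zero reset discards it.
    """
    v = state.v_m + weighted_input + state.bias_current
    if v >= state.v_th:
        v_next = v - state.v_th if reset == "subtract" else 0.0
        return replace(state, v_m=v_next, spike_count=state.spike_count + 1), True
    return replace(state, v_m=v), False


@dataclass
class MembraneDynamics:
    """Continuous-time membrane model u(t) = u0 + a * sum_i w K(t - t_i).

    ``kernel`` is the post-synaptic filter evaluated at elapsed time; None
    means the no-leak unit kernel (every past spike contributes w forever).
    An exponential kernel exp(-s/tau) gives a leaky variant.
    """

    u0: float = 0.0
    a: float = 1.0
    kernel: Callable[[np.ndarray], np.ndarray] | None = None
    spike_times: Sequence[float] = field(default_factory=tuple)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def membrane_potential(dyn: MembraneDynamics, w: float, t: float) -> float:
    """Potential at time t from the spike history (spikes at exactly t count)."""
    times = np.asarray(dyn.spike_times, dtype=float)
    past = times[times <= t]
    if past.size == 0:
        return dyn.u0
    contrib = np.ones_like(past) if dyn.kernel is None else dyn.kernel(t - past)
    return dyn.u0 + dyn.a * w * float(contrib.sum())


# ---------------------------------------------------------------------------
# Rate encoding
# ---------------------------------------------------------------------------

def rate_encode(p01: np.ndarray, T: int, r_max: float = 1.0, seed: int = 0,
                deterministic: bool = False) -> np.ndarray:
    """Spike trains (T, n) for per-input intensities already mapped to [0, 1].

    Bernoulli mode draws each step independently with probability
    clip(p, 0, 1) * r_max (expected count = p * r_max * T); deterministic
    mode places floor(p * r_max * T) evenly spaced spikes, seed-independent.
    """
    if T < 1:
        raise ValidationError("T must be >= 1")
    p = np.clip(np.asarray(p01, dtype=float), 0.0, 1.0) * r_max
    if deterministic:
        t = np.arange(1, T + 1)[:, None]
        return (np.floor(t * p) - np.floor((t - 1) * p)) >= 1.0
    rng = np.random.default_rng(seed)
    return rng.random((T,) + p.shape) < p


# ---------------------------------------------------------------------------
# Conversion
# ---------------------------------------------------------------------------

@dataclass
class SpikeRecord:
    """Per-neuron spike tallies by layer (layer 0 = input encoders) and the
    synaptic routing events they generated (spike count x fan-out)."""

    counts: list  # list of (n_l,) int arrays, aggregated over the batch
    routing_events: int
    n_inferences: int = 1
    T: int = 1

    @property
    def total_spikes(self) -> int:
        return int(sum(c.sum() for c in self.counts))


class SpikingNetwork:
    """Dense-equivalent layer graph of IF neurons mirroring the source model."""

    def __init__(self, weights, biases, cfg: SNNConfig, input_lo, input_hi,
                 lambdas, decision_rate: float = 0.0, majority_fallback: int = 0):
        self.weights = [np.asarray(W, dtype=float) for W in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]
        self.cfg = cfg
        self.input_lo = np.asarray(input_lo, dtype=float)
        self.input_hi = np.asarray(input_hi, dtype=float)
        self.lambdas = list(lambdas)
        self.decision_rate = decision_rate
        self.majority_fallback = majority_fallback
        self.layer_sizes = [self.weights[0].shape[0]] + [W.shape[1] for W in self.weights]
        # fan-out of a neuron = its count of nonzero outgoing synapses
        self.fan_out = [np.count_nonzero(W, axis=1) for W in self.weights]
        self.fan_out.append(np.zeros(self.layer_sizes[-1], dtype=int))
        self._calib = None  # optional (X, y) kept for decoder recalibration

    @property
    def n_neurons(self) -> int:
        return int(sum(self.layer_sizes))

    def encode_input(self, X: np.ndarray) -> np.ndarray:
        """Affine map of calibrated feature range into [0, 1] spike intensity."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = self.input_hi - self.input_lo
        return np.clip((X - self.input_lo) / span, 0.0, 1.0)

    def with_threshold(self, v_th: float) -> "SpikingNetwork":
        net = copy.copy(self)
        net.cfg = replace(self.cfg, v_th=v_th)
        return net

    def save(self, path_prefix: str) -> None:
        """Write ``<prefix>.json`` (topology + config) and ``<prefix>.npz``
        (weights, bias currents, calibration batch)."""
        import dataclasses as _dc
        import json as _json

        meta = {
            "cfg": _dc.asdict(self.cfg),
            "lambdas": self.lambdas,
            "decision_rate": self.decision_rate,
            "majority_fallback": self.majority_fallback,
            "layer_sizes": self.layer_sizes,
            "n_layers": len(self.weights),
            "has_calib": self._calib is not None,
            "has_calib_labels": self._calib is not None and self._calib[1] is not None,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            _json.dump(meta, fh, indent=1)
        arrays = {"input_lo": self.input_lo, "input_hi": self.input_hi}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        if self._calib is not None:
            arrays["calib_X"] = self._calib[0]
            if self._calib[1] is not None:
                arrays["calib_y"] = self._calib[1]
        np.savez(f"{path_prefix}.npz", **arrays)

    @classmethod
    def load(cls, path_prefix: str) -> "SpikingNetwork":
        import json as _json

        with open(f"{path_prefix}.json") as fh:
            meta = _json.load(fh)
        cfg = SNNConfig(**meta["cfg"])
        with np.load(f"{path_prefix}.npz") as data:
            weights = [data[f"W{i}"] for i in range(meta["n_layers"])]
            biases = [data[f"b{i}"] for i in range(meta["n_layers"])]
            net = cls(weights, biases, cfg, data["input_lo"], data["input_hi"],
                      meta["lambdas"], decision_rate=meta["decision_rate"],
                      majority_fallback=meta["majority_fallback"])
            if meta["has_calib"]:
                net._calib = (data["calib_X"],
                              data["calib_y"] if meta["has_calib_labels"] else None)
        return net


def _dense_equivalent(model: NetworkModel) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """Collapse the layer stack to dense (W, b, activation) triples.

    Kernel-1 convolutions become block-diagonal position-wise maps (the
    flatten order, position-major, matches the network's Flatten); pool-1
    pooling and dropout vanish at inference.
    """
    length, ch = model.input_shape
    triples = []
    for layer in model.layers:
        if isinstance(layer, Conv1D):
            if layer.kernel != 1:
                raise ValidationError("spiking conversion supports kernel-1 convolutions only")
            W = np.zeros((length * ch, length * layer.filters))
            for p in range(length):
                W[p * ch:(p + 1) * ch, p * layer.filters:(p + 1) * layer.filters] = layer.W[0]
            b = np.tile(layer.b, length)
            triples.append((W, b, layer.activation))
            ch = layer.filters
        elif isinstance(layer, MaxPool1D):
            if layer.pool != 1 or layer.stride != 1:
                raise ValidationError("spiking conversion supports pool-1 pooling only")
        elif isinstance(layer, (Flatten, Dropout)):
            continue
        elif isinstance(layer, Dense):
            triples.append((layer.W.copy(), layer.b.copy(), layer.activation))
        else:
            raise ValidationError(f"cannot convert layer kind {layer.kind!r}")
    for W, b, act in triples[:-1]:
        if act != "relu":
            raise ValidationError("hidden layers must be ReLU for rate-coded conversion")
    return triples


def _ann_layer_maxima(triples, X: np.ndarray) -> list[float]:
    """Max post-ReLU activation per layer (pre-activation clamped at 0 for the
    output head) over a calibration batch."""
    a = np.atleast_2d(X)
    maxima = []
    for W, b, act in triples:
        z = a @ W + b
        a = np.maximum(z, 0.0)  # output head rate tracks the positive part of its drive
        maxima.append(float(a.max()))
    return maxima


def _simulate(net: SpikingNetwork, X: np.ndarray, seed: int = 0,
              T: int | None = None, record_hidden: bool = False):
    """Synchronous time-stepped simulation, vectorized over the batch.

    Returns (output spike counts per sample, SpikeRecord, hidden per-sample
    counts or None).
    """
    cfg = net.cfg
    T = cfg.T if T is None else T
    if T < 1:
        raise ValidationError("T must be >= 1")
    P = net.encode_input(X) * cfg.r_max
    B = P.shape[0]
    rng = np.random.default_rng(seed)
    deterministic = cfg.encoder == "deterministic"

    v = [np.zeros((B, n)) for n in net.layer_sizes[1:]]
    counts = [np.zeros(n, dtype=np.int64) for n in net.layer_sizes]
    per_sample = [np.zeros((B, n), dtype=np.int64) for n in net.layer_sizes[1:]] \
        if record_hidden else None
    out_counts = np.zeros(B, dtype=np.int64)

    floor_prev = np.zeros_like(P)
    for t in range(T):
        if deterministic:
            floor_now = np.floor((t + 1) * P)
            s = (floor_now - floor_prev) >= 1.0
            floor_prev = floor_now
        else:
            s = rng.random(P.shape) < P
        s = s.astype(float)
        counts[0] += s.sum(axis=0).astype(np.int64)
        for l, (W, b) in enumerate(zip(net.weights, net.biases)):
            v[l] += s @ W + b
            spk = v[l] >= cfg.v_th
            if cfg.reset == "subtract":
                v[l] -= cfg.v_th * spk
            else:
                v[l][spk] = 0.0
            s = spk.astype(float)
            counts[l + 1] += spk.sum(axis=0).astype(np.int64)
            if record_hidden:
                per_sample[l] += spk
        out_counts += s[:, 0].astype(np.int64)

    routing = int(sum(int(c @ f) for c, f in zip(counts, net.fan_out)))
    record = SpikeRecord(counts=counts, routing_events=routing, n_inferences=B, T=T)
    return out_counts, record, per_sample


def _calibrate_decoder(net: SpikingNetwork, X: np.ndarray, y: np.ndarray | None,
                       seed: int = 0, T: int | None = None) -> None:
    """Fit the output-rate decision threshold at the current operating point.

    With calibration labels the threshold maximizing calibration accuracy is
    chosen from the midpoints between sorted observed rates (a silent output
    then degenerates to always predicting the calibration majority class);
    without labels the threshold is ``decision_fraction`` of the maximum
    observed rate.
    """
    cfg = net.cfg
    T = cfg.T if T is None else T
    n = min(len(np.atleast_2d(X)), cfg.calibration_subsample)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(np.atleast_2d(X)), size=n, replace=False)
    Xc = np.atleast_2d(X)[idx]
    out_counts, _, _ = _simulate(net, Xc, seed=seed + 1, T=T)
    rates = out_counts / T
    if y is None:
        net.decision_rate = cfg.decision_fraction * float(rates.max())
        return
    yc = np.asarray(y)[idx]
    net.majority_fallback = int(yc.mean() >= 0.5)
    r = np.sort(np.unique(rates))
    cands = np.concatenate([[0.0], (r[1:] + r[:-1]) / 2.0, [r[-1] + 1.0 / T]])
    acc = ((rates[:, None] >= cands[None, :]) == yc[:, None]).mean(axis=0)
    net.decision_rate = float(cands[int(np.argmax(acc))])


def convert_to_snn(model: NetworkModel, calibration_X: np.ndarray,
                   calibration_y: np.ndarray | None = None,
                   cfg: SNNConfig = SNNConfig(), seed: int = 0) -> SpikingNetwork:
    """Convert a trained model into a rate-coded IF network.

    ``calibration_X`` (standardized feature rows, e.g. the training split)
    fixes three data-driven pieces: the input encoding range, the per-layer
    weight-normalization factors lambda, and the output decoder threshold.
    A layer whose calibration activations are all zero is dead and cannot be
    normalized — this raises.
    """
    triples = _dense_equivalent(model)
    Xc = np.atleast_2d(np.asarray(calibration_X, dtype=float))
    lo = Xc.min(axis=0)
    hi = Xc.max(axis=0)
    span = hi - lo
    if np.any(span <= 0):
        raise ValidationError("calibration data has a constant feature; cannot encode")

    lambdas = _ann_layer_maxima(triples, Xc)
    for i, lam in enumerate(lambdas):
        if lam <= 0 and i < len(lambdas) - 1:
            raise ValidationError(f"layer {i} never activates on calibration data (lambda = 0)")
    if lambdas[-1] <= 0:
        lambdas[-1] = 1.0  # output never positive on calibration; decoder will fall back

    weights, biases = [], []
    lam_prev = 1.0  # encoded inputs already live in [0, 1]
    for i, (W, b, _act) in enumerate(triples):
        lam = lambdas[i]
        if i == 0:
            # fold the input affine map g(x) = (x - lo)/span into layer 0:
            # W x + b = (W * span) g(x) + (W lo + b)
            W = W * span[:, None]
            b = b + lo @ triples[0][0]
        weights.append(W * lam_prev / lam)
        biases.append(b / lam)
        lam_prev = lam

    net = SpikingNetwork(weights, biases, cfg, lo, hi, lambdas)
    net._calib = (Xc, None if calibration_y is None else np.asarray(calibration_y))
    _calibrate_decoder(net, Xc, net._calib[1], seed=seed)
    return net


# ---------------------------------------------------------------------------
# Inference and design-space exploration
# ---------------------------------------------------------------------------

def snn_infer(net: SpikingNetwork, X: np.ndarray, T: int | None = None,
              seed: int = 0, record_hidden: bool = False):
    """Simulate T steps and decode labels from output spike rates.

    Returns (labels, SpikeRecord) or (labels, SpikeRecord, hidden per-sample
    spike counts) when ``record_hidden``.
    """
    out_counts, record, hidden = _simulate(net, X, seed=seed, T=T,
                                           record_hidden=record_hidden)
    T_eff = record.T
    rates = out_counts / T_eff
    if net.decision_rate > 0:
        labels = (rates >= net.decision_rate).astype(int)
    else:
        labels = np.full(len(rates), net.majority_fallback, dtype=int)
    if record_hidden:
        return labels, record, hidden
    return labels, record


def hidden_rates(net: SpikingNetwork, X: np.ndarray, T: int | None = None,
                 seed: int = 0) -> list[np.ndarray]:
    """Per-sample firing rates of every non-input layer (counts / T)."""
    _, record, hidden = snn_infer(net, X, T=T, seed=seed, record_hidden=True)
    return [h / record.T for h in hidden]


def threshold_sweep(net: SpikingNetwork, eval_sets, v_th_grid, seed: int = 0,
                    T: int | None = None):
    """Accuracy / spike-count matrix over (V_th, evaluation set).

    ``eval_sets`` is a list of (X, y). For each threshold the output decoder
    is recalibrated on the network's stored calibration batch at that
    operating point (a high threshold silences the output; the decoder then
    degenerates to the calibration majority class). Returns a dict with
    'v_th', 'set_sizes', 'accuracy' (grid x sets), 'total_spikes'.
    """
    v_th_grid = list(v_th_grid)
    if not v_th_grid:
        raise ValidationError("V_th grid must be non-empty")
    if net._calib is None:
        raise ValidationError("network carries no calibration batch for decoder recalibration")
    acc = np.zeros((len(v_th_grid), len(eval_sets)))
    spikes = np.zeros((len(v_th_grid), len(eval_sets)), dtype=np.int64)
    sizes = [len(np.atleast_2d(X)) for X, _ in eval_sets]
    for i, v_th in enumerate(v_th_grid):
        sub = net.with_threshold(float(v_th))
        _calibrate_decoder(sub, net._calib[0], net._calib[1], seed=seed, T=T)
        for j, (X, y) in enumerate(eval_sets):
            labels, record = snn_infer(sub, X, T=T, seed=seed + 7919 * (i + 1) + j)
            acc[i, j] = float(np.mean(labels == np.asarray(y)))
            spikes[i, j] = record.total_spikes
    return {"v_th": [float(v) for v in v_th_grid], "set_sizes": sizes,
            "accuracy": acc, "total_spikes": spikes}
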