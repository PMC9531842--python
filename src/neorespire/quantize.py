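"""k-bit quantization of weights and activations, and model-size accounting.

The unit quantizer maps [0, 1] onto the 2^k-point lattice {i / (2^k - 1)}:

    Q(z) = round((2^k - 1) z) / (2^k - 1)

Weights pass through a tanh squash and a per-tensor affine map into [0, 1]
before quantizing,

    w_q = Q( tanh(w) / (2 max|tanh(w)|) + 1/2 ),

and activations are clipped to [0, 1] first, x_q = Q(clip(x, 0, 1)). A
mantissa quantizer with ``b`` integer bits left of the binary point,

    2^(b-k+1) clip(round(x 2^(k-b-1)), -2^(k-1), 2^(k-1) - 1),

covers fixed-point semantics. Rounding is half-away-from-zero everywhere so
ties are deterministic. Model size is parameter_count * k bits, which for the
canonical 46,129-parameter classifier gives 92,258 / 184,516 / 369,032 /
738,064 / 1,476,128 / 2,952,256 bits at k = 2 / 4 / 8 / 16 / 32 / 64.

Quantized inference dequantizes the stored lattice weights back to the signed
range by inverting the full weight map (affine inverse then artanh), so the
k -> 64 limit recovers the full-precision forward pass. Hidden ReLU
activations are quantized through the clip quantizer with an optional
per-layer scale calibrated on data (activations of a trained network exceed 1,
and an unscaled hard clip would not converge to the full-precision model);
the final sigmoid head stays in full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from neorespire.errors import ValidationError
from neorespire.network import Conv1D, Dense, NetworkModel


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Deterministic round-half-away-from-zero (np.round would round half to even)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass(frozen=True)
class QuantizationConfig:
    """k total bits per value; b integer bits for the mantissa quantizer."""

    k: int = 8
    b: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not (0 <= self.b < self.k):
            raise ValidationError("need 0 <= b < k")


def quantize_unit(z_r, k: int):
    """Quantize values in [0, 1] onto the 2^k-point lattice; idempotent,
    endpoints fixed. Out-of-range input is an error — clipping is the
    caller's job."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    z = np.asarray(z_r, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValidationError("unit quantizer input must lie in [0, 1]")
    levels = float(2**k - 1)
    out = _round_half_away(z * levels) / levels
    return float(out) if np.isscalar(z_r) else out


@dataclass
class QuantizedTensor:
    """Lattice values in [0, 1] plus the per-tensor normalizer max|tanh(w)|."""

    lattice: np.ndarray
    max_tanh: float
    k: int


def quantize_weights(w_r: np.ndarray, k: int) -> QuantizedTensor:
    """tanh-squash, affine-map to [0, 1], quantize; stores the normalizer."""
    t = np.tanh(np.asarray(w_r, dtype=float))
    max_tanh = float(np.max(np.abs(t)))
    if max_tanh == 0.0:
        raise ValidationError("cannot quantize an all-zero weight tensor")
    z = t / (2.0 * max_tanh) + 0.5
    # guard float round-off at the endpooints of the affine map
    z = np.clip(z, 0.0, 1.0)
    return QuantizedTensor(quantize_unit(z, k), max_tanh, k)


def dequantize_weights(q: QuantizedTensor) -> np.ndarray:
    """Invert the weight map: lattice -> tanh domain -> arctanh.

    The arctanh argument is clipped just inside (-1, 1); weights saturated in
    tanh (|w| > ~19) come back at the saturation boundary.
    """
    t = (q.lattice - 0.5) * 2.0 * q.max_tanh
    t = np.clip(t, -1.0 + 1e-16, 1.0 - 1e-16)
    return np.arctanh(t)


def quantize_activations(x_r, k: int):
    """x_q = Q(clip(x, 0, 1)): the clip bounds the activation, then the unit
    quantizer snaps it to the lattice."""
    x = np.clip(np.asarray(x_r, dtype=float), 0.0, 1.0)
    out = quantize_unit(x, k)
    return float(out) if np.isscalar(x_r) else out


def mantissa_quantize(x, k: int, b: int):
    """Fixed-point quantization with b integer bits: saturates at the signed
    k-bit range, resolution 2^(b-k+1)."""
    if b >= k:
        raise ValidationError("need b < k for mantissa quantization")
    x = np.asarray(x, dtype=float)
    scaled = _round_half_away(x * 2.0 ** (k - b - 1))
    clipped = np.clip(scaled, -(2.0 ** (k - 1)), 2.0 ** (k - 1) - 1)
    out = 2.0 ** (b - k + 1) * clipped
    return float(out) if np.isscalar(x) else out


def model_size_bits(model: NetworkModel, k: int) -> int:
    """Storage footprint: parameter count times bits per parameter."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    return model.parameter_count * k


# ---------------------------------------------------------------------------
# Quantized inference
# ---------------------------------------------------------------------------

@dataclass
class QuantizedModel:
    """A network with k-bit weights/biases and k-bit clipped activations.

    ``activation_scales[i]`` rescales layer i's ReLU output into [0, 1]
    before the clip quantizer (s * Q(clip(a / s, 0, 1))); scale 1.0 is the
    bare textbook quantizer. The sigmoid output head is not quantized.
    """

    base: NetworkModel
    k: int
    weight_tensors: dict = field(default_factory=dict)   # layer idx -> {"W": QuantizedTensor, ...}
    activation_scales: dict = field(default_factory=dict)  # layer idx -> float

    @property
    def model_size_bits(self) -> int:
        return model_size_bits(self.base, self.k)

    def forward(self, X: np.ndarray) -> np.ndarray:
        out = self.base._coerce_input(X)
        last = len(self.base.layers) - 1
        for i, layer in enumerate(self.base.layers):
            if i in self.weight_tensors:
                saved = {k: v.copy() for k, v in layer.params().items()}
                try:
                    for name, qt in self.weight_tensors[i].items():
                        getattr(layer, name)[...] = dequantize_weights(qt)
                    out = layer.forward(out, training=False)
                finally:
                    for name, v in saved.items():
                        getattr(layer, name)[...] = v
            else:
                out = layer.forward(out, training=False)
            if layer.activation == "relu" and i != last:
                s = self.activation_scales.get(i, 1.0)
                out = s * quantize_activations(out / s, self.k)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X).reshape(-1)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def manifest(self) -> dict:
        return {
            "k": self.k,
            "model_size_bits": self.model_size_bits,
            "normalizers": {
                str(i): {name: qt.max_tanh for name, qt in tensors.items()}
                for i, tensors in self.weight_tensors.items()
            },
            "activation_scales": {str(i): s for i, s in self.activation_scales.items()},
        }


def calibrate_activation_scales(model: NetworkModel, X: np.ndarray) -> dict:
    """Per-layer max ReLU activation on a calibration batch (quantizer range)."""
    acts = model.hidden_activations(X)
    scales = {}
    last = len(model.layers) - 1
    for i, layer in enumerate(model.layers):
        if layer.activation == "relu" and i != last:
            m = float(np.max(acts[i]))
            scales[i] = m if m > 0 else 1.0
    return scales


def quantize_model(model: NetworkModel, k: int, calibration_X: np.ndarray | None = None) -> QuantizedModel:
    """Post-training quantization of every parameterized layer.

    Biases are quantized like weights at the same k. When a calibration batch
    is given, per-layer activation scales are fitted from its ReLU maxima.
    """
    tensors = {}
    for i, layer in enumerate(model.layers):
        if isinstance(layer, (Conv1D, Dense)):
            tensors[i] = {name: quantize_weights(p, k) for name, p in layer.params().items()
                          if np.any(p != 0)}
    scales = calibrate_activation_scales(model, calibration_X) if calibration_X is not None else {}
    return QuantizedModel(base=model, k=k, weight_tensors=tensors, activation_scales=scales)
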