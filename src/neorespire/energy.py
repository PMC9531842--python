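"""Energy accounting: spike counting for the SNN, a parametric per-operation
model for conventional inference.

Spiking side, with neuromorphic-hardware constants (Loihi-class, OxRRAM
synapses): 23.6 pJ per spike (calibrated at 30 Hz spike frequency) and 3 pJ
per routing event, one event per downstream synapse a spike traverses:

    E = n_spikes * e_spike + n_routing * e_route

Conventional side, a layer-wise sum over multiply-accumulate operations and
parameter accesses at bit width k:

    E = sum_l ( macs_l * e_mac(k) + params_l * e_mem(k) )

The default coefficient tables scale as e_mac(k) = 12 pJ * (k/1)^2 (multiplier
energy grows quadratically in operand width) and e_mem(k) = 1 pJ * k (memory
movement grows linearly in word size), representative of memory-movement-
dominated inference on wearable-class microcontrollers. The absolute numbers
are parametric defaults — only orderings and ratios between models evaluated
under the same table are meaningful, and both tables are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from neorespire.errors import ValidationError
from neorespire.network import Conv1D, Dense, NetworkModel
from neorespire.snn import SpikeRecord


@dataclass(frozen=True)
class EnergyTable:
    """Per-event energies in pJ; e_mac/e_mem must be non-decreasing in k."""

    e_spike_pj: float = 23.6
    e_route_pj: float = 3.0
    e_mac_pj: dict = field(default_factory=lambda: {k: 12.0 * k**2 for k in (1, 2, 4, 8, 16, 32, 64)})
    e_mem_pj: dict = field(default_factory=lambda: {k: 1.0 * k for k in (1, 2, 4, 8, 16, 32, 64)})

    def __post_init__(self):
        if self.e_spike_pj < 0 or self.e_route_pj < 0:
            raise ValidationError("energies must be >= 0")
        for table in (self.e_mac_pj, self.e_mem_pj):
            ks = sorted(table)
            vals = [table[k] for k in ks]
            if any(v < 0 for v in vals):
                raise ValidationError("energies must be >= 0")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValidationError("e_mac/e_mem must be non-decreasing in k")

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyTable":
        return cls(
            e_spike_pj=float(d.get("e_spike_pj", 23.6)),
            e_route_pj=float(d.get("e_route_pj", 3.0)),
            e_mac_pj={int(k): float(v) for k, v in d["e_mac_pj"].items()} if "e_mac_pj" in d
            else cls().e_mac_pj,
            e_mem_pj={int(k): float(v) for k, v in d["e_mem_pj"].items()} if "e_mem_pj" in d
            else cls().e_mem_pj,
        )


@dataclass
class EnergyReport:
    """Total pJ with an additive breakdown by category (and layer for ANNs)."""

    model_id: str
    total_pj: float
    breakdown: dict

    def __post_init__(self):
        s = _breakdown_sum(self.breakdown)
        if not np.isclose(s, self.total_pj, rtol=1e-9, atol=1e-6):
            raise ValidationError("report total must equal breakdown sum")


def _breakdown_sum(breakdown: dict) -> float:
    total = 0.0
    for v in breakdown.values():
        total += _breakdown_sum(v) if isinstance(v, dict) else float(v)
    return total


def snn_energy(record: SpikeRecord, table: EnergyTable = EnergyTable(),
               model_id: str = "snn") -> EnergyReport:
    """Spike-count model: spikes burn e_spike, each traversed synapse e_route."""
    n_spikes = record.total_spikes
    spike_pj = n_spikes * table.e_spike_pj
    route_pj = record.routing_events * table.e_route_pj
    return EnergyReport(model_id, spike_pj + route_pj,
                        {"spike": spike_pj, "route": route_pj})


def layer_mac_counts(model: NetworkModel) -> dict:
    """Multiply-accumulates per inference derived from layer shapes."""
    length, ch = model.input_shape
    macs = {}
    for i, layer in enumerate(model.layers):
        if isinstance(layer, Conv1D):
            out_len = length - layer.kernel + 1
            macs[i] = out_len * layer.kernel * ch * layer.filters
            length, ch = out_len, layer.filters
        elif isinstance(layer, Dense):
            macs[i] = layer.W.shape[0] * layer.W.shape[1]
        elif hasattr(layer, "_lout"):
            length = layer._lout
    return macs


def ann_energy(model: NetworkModel, k_bits: int, table: EnergyTable = EnergyTable(),
               model_id: str | None = None) -> EnergyReport:
    """Layer-wise MAC + parameter-access energy at bit width k."""
    if k_bits not in table.e_mac_pj or k_bits not in table.e_mem_pj:
        raise ValidationError(f"no energy coefficients for k={k_bits}")
    e_mac, e_mem = table.e_mac_pj[k_bits], table.e_mem_pj[k_bits]
    macs = layer_mac_counts(model)
    breakdown = {}
    for i, layer in enumerate(model.layers):
        params = sum(p.size for p in layer.params().values())
        if i in macs or params:
            breakdown[f"layer{i}_{layer.kind}"] = {
                "mac": macs.get(i, 0) * e_mac,
                "mem": params * e_mem,
            }
    total = _breakdown_sum(breakdown)
    return EnergyReport(model_id or f"ann_k{k_bits}", total, breakdown)


def compare(reports: list[EnergyReport], accuracies: list[float],
            baseline_id: str | None = None) -> list[dict]:
    """Accuracy/energy tradeoff rows sorted by energy, with ratio-to-baseline.

    The baseline is the named report, or the most energy-hungry one.
    """
    if len(reports) != len(accuracies):
        raise ValidationError("need one accuracy per report")
    if baseline_id is None:
        base = max(r.total_pj for r in reports)
    else:
        matches = [r for r in reports if r.model_id == baseline_id]
        if not matches:
            raise ValidationError(f"no report named {baseline_id!r}")
        base = matches[0].total_pj
    rows = [
        {
            "model": r.model_id,
            "accuracy": float(a),
            "energy_pj": r.total_pj,
            "ratio_to_baseline": (base / r.total_pj) if r.total_pj > 0 else float("inf"),
        }
        for r, a in zip(reports, accuracies)
    ]
    rows.sort(key=lambda row: row["energy_pj"])
    return rows
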