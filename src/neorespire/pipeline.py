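"""Seven-stage pipeline orchestration.

simulate -> featurize -> train -> quantize -> convert -> sweep -> evaluate,
with every artifact written under one run directory and a manifest recording
the configuration hash and the per-stage seeds (all derived deterministically
from one master seed). Re-running with the same config and seed reproduces
metrics bit-for-bit in the deterministic encoder mode and to the same seeded
stream otherwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from neorespire import energy as energy_mod
from neorespire import features as feat_mod
from neorespire import metrics as metrics_mod
from neorespire import network as net_mod
from neorespire import quantize as quant_mod
from neorespire import snn as snn_mod
from neorespire import synthetic as synth_mod
from neorespire.errors import StageError, ValidationError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "featurize", "train", "quantize", "convert", "sweep", "evaluate")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    master_seed: int = 7
    duration_s: float = 600.0
    protocol: synth_mod.BreathingProtocol = field(default_factory=synth_mod.BreathingProtocol)
    rfid: synth_mod.RFIDConfig = field(default_factory=synth_mod.RFIDConfig)
    train: net_mod.TrainConfig = field(default_factory=net_mod.TrainConfig)
    snn: snn_mod.SNNConfig = field(default_factory=snn_mod.SNNConfig)
    energy_table: energy_mod.EnergyTable = field(default_factory=energy_mod.EnergyTable)
    quant_bits: tuple = (2, 4, 8, 16, 32, 64)
    sweep_v_th: tuple = (1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 4.0, 6.0, 10.0)
    sweep_sizes: tuple = (100, 500, 2000)
    sweep_T: int = 400
    test_fraction: float = 0.25

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.master_seed < 0:
            raise ValidationError("master_seed must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        subs = {
            "protocol": synth_mod.BreathingProtocol,
            "rfid": synth_mod.RFIDConfig,
            "train": net_mod.TrainConfig,
            "snn": snn_mod.SNNConfig,
        }
        for key, klass in subs.items():
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                d[key] = klass(**sub)
        if "energy_table" in d and isinstance(d["energy_table"], dict):
            d["energy_table"] = energy_mod.EnergyTable.from_dict(d["energy_table"])
        for key in ("quant_bits", "sweep_v_th", "sweep_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def stage_seeds(master_seed: int) -> dict:
    """One deterministic sub-seed per stage, all below 2^31."""
    rng = np.random.default_rng(master_seed)
    return {name: int(rng.integers(0, 2**31)) for name in STAGES}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a result dict and persists artifacts.

    A failing stage raises :class:`StageError` naming the stage; artifacts
    written by earlier stages remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.master_seed)
    manifest = {"config_hash": cfg.config_hash(), "seeds": seeds,
                "config": cfg.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    results: dict = {"out_dir": str(out), "seeds": seeds}

    def _run(stage, fn):
        logger.info("stage %s (seed %d)", stage, seeds[stage])
        try:
            return fn()
        except (ValidationError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(stage, str(exc)) from exc

    # 1. simulate ----------------------------------------------------------
    def _simulate():
        protocol = dataclasses.replace(cfg.protocol, total_duration=cfg.duration_s)
        timeline = synth_mod.generate_protocol(protocol, seed=seeds["simulate"])
        stream = synth_mod.simulate_interrogations(timeline, cfg.rfid, seed=seeds["simulate"])
        synth_mod.write_interrogations_csv(stream, out / "raw.csv")
        (out / "timeline.json").write_text(json.dumps(timeline.to_dict()))
        return timeline, stream

    timeline, stream = _run("simulate", _simulate)
    results["n_records"] = len(stream)

    # 2. featurize ---------------------------------------------------------
    def _featurize():
        ctx = feat_mod.RCSContext(p_tx_w=cfg.rfid.p_tx_w, g_reader=cfg.rfid.g_reader,
                                  r_m=cfg.rfid.nominal_r_m)
        frame = feat_mod.featurize_records(stream, timeline, ctx=ctx)
        feat_mod.write_feature_csvs(frame, out / "features.csv", out / "labels.csv")
        return frame

    frame = _run("featurize", _featurize)

    # 3. train -------------------------------------------------------------
    def _train():
        windows = feat_mod.build_windows(frame, timeline)
        train_set, test_set = feat_mod.clean_and_split(
            windows, test_fraction=cfg.test_fraction, seed=seeds["train"])
        tcfg = dataclasses.replace(cfg.train, seed=seeds["train"])
        model = net_mod.build_1dcnn(seed=seeds["train"])
        model, history = net_mod.train(model, train_set, None, tcfg)
        model.save(str(out / "model"))
        acc = float(np.mean(model.predict(test_set.X) == test_set.y))
        return model, train_set, test_set, history, acc

    model, train_set, test_set, history, cnn_acc = _run("train", _train)
    results["cnn_test_accuracy"] = cnn_acc
    results["epochs_run"] = len(history["train_loss"])

    # 4. quantize ----------------------------------------------------------
    def _quantize():
        rows = []
        qmodels = {}
        for k in cfg.quant_bits:
            qm = quant_mod.quantize_model(model, k, calibration_X=train_set.X)
            acc = float(np.mean(qm.predict(test_set.X) == test_set.y))
            rows.append({"k": k, "top1": acc, "model_size_bits": qm.model_size_bits})
            qmodels[k] = qm
        with open(out / "quantization.json", "w") as fh:
            json.dump(rows, fh, indent=1)
        return rows, qmodels

    quant_rows, qmodels = _run("quantize", _quantize)
    results["quantization"] = quant_rows

    # 5. convert -----------------------------------------------------------
    def _convert():
        net = snn_mod.convert_to_snn(model, train_set.X, train_set.y,
                                     cfg=cfg.snn, seed=seeds["convert"])
        labels, record = snn_mod.snn_infer(net, test_set.X, seed=seeds["convert"])
        acc = float(np.mean(labels == test_set.y))
        (out / "snn.json").write_text(json.dumps({
            "layer_sizes": net.layer_sizes, "lambdas": net.lambdas,
            "decision_rate": net.decision_rate, "v_th": net.cfg.v_th, "T": net.cfg.T,
        }, indent=1))
        return net, record, acc

    net, snn_record, snn_acc = _run("convert", _convert)
    results["snn_test_accuracy"] = snn_acc

    # 6. sweep -------------------------------------------------------------
    def _sweep():
        rng = np.random.default_rng(seeds["sweep"])
        eval_sets = []
        for size in cfg.sweep_sizes:
            idx = rng.choice(len(test_set.y), size=size, replace=True)
            eval_sets.append((test_set.X[idx], test_set.y[idx]))
        res = snn_mod.threshold_sweep(net, eval_sets, cfg.sweep_v_th,
                                      seed=seeds["sweep"], T=cfg.sweep_T)
        lines = ["v_th,set_size,accuracy,total_spikes"]
        for i, v in enumerate(res["v_th"]):
            for j, size in enumerate(res["set_sizes"]):
                lines.append(f"{v},{size},{res['accuracy'][i, j]},{res['total_spikes'][i, j]}")
        (out / "sweep.csv").write_text("\n".join(lines) + "\n")
        return res

    results["sweep"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in _run("sweep", _sweep).items()}

    # 7. evaluate ----------------------------------------------------------
    def _evaluate():
        table = cfg.energy_table
        n_test = len(test_set.y)
        reports = [energy_mod.ann_energy(model, 64, table, model_id="ann_full")]
        accs = [cnn_acc]
        for row in quant_rows:
            if row["k"] == 64:
                continue
            reports.append(energy_mod.ann_energy(model, row["k"], table,
                                                 model_id=f"ann_k{row['k']}"))
            accs.append(row["top1"])
        # per-inference spike energy: average the batch record over inferences
        batch_rep = energy_mod.snn_energy(snn_record, table, model_id="snn")
        n_inf = max(snn_record.n_inferences, 1)
        snn_rep = energy_mod.EnergyReport(
            "snn", batch_rep.total_pj / n_inf,
            {k: v / n_inf for k, v in batch_rep.breakdown.items()})
        reports.append(snn_rep)
        accs.append(snn_acc)
        tradeoff = energy_mod.compare(reports, accs, baseline_id="ann_full")

        c = metrics_mod.confusion(test_set.y, model.predict(test_set.X))
        report = metrics_mod.all_metrics(c, test_set.y, model.predict_proba(test_set.X))
        payload = {"cnn": report, "snn_accuracy": snn_acc, "tradeoff": tradeoff,
                   "n_test": n_test}
        (out / "metrics.json").write_text(json.dumps(payload, indent=1, default=str))
        lines = ["model,accuracy,energy_pj,ratio_to_baseline"]
        for row in tradeoff:
            lines.append(f"{row['model']},{row['accuracy']},{row['energy_pj']},{row['ratio_to_baseline']}")
        (out / "energy.csv").write_text("\n".join(lines) + "\n")
        return payload

    results["evaluate"] = _run("evaluate", _evaluate)
    return results
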