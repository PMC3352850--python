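"""Run configuration, network archives, spike/result logs.

A run is reproducible from its configuration plus a master seed: the seed
is split into independent child seeds for weight initialization, the
training trial stream, and each evaluation arm, so paired experiments
(e.g. the attention ablation) can share trial streams while differing
elsewhere.

Network archives are ``.npz`` files holding one array per connection and
per group membrane, plus a JSON header with the group parameters and a
content checksum for integrity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .lif import Connection, Network, NeuronGroupParams
from .plasticity import PlasticityConfig, RewardSchedule
from .training import DEFAULT_RENORM_INTERVALS, TrainingSchedule

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "save_network",
    "load_network",
    "spike_log_frame",
    "derive_seeds",
]

_FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to rebuild, train and evaluate a network."""

    seed: int = 0
    unsupervised_epochs: int = 1
    supervised_epochs: int = 2
    presentations_per_epoch: int = 400
    eta0_unsupervised: float = 0.005
    eta0_supervised: float = 0.1
    eta0_per_layer: dict = field(
        default_factory=lambda: {"S2-shape-ex": 0.005, "S2-where-ex": 0.002})
    renorm_intervals: dict = field(default_factory=lambda: dict(DEFAULT_RENORM_INTERVALS))
    speed: int = 10
    plasticity: dict = field(default_factory=dict)   # PlasticityConfig overrides
    rewards: dict = field(default_factory=dict)      # RewardSchedule overrides
    noise_levels: list = field(default_factory=list)
    n_per_level: int = 100
    output_dir: str = "results"

    def plasticity_config(self) -> PlasticityConfig:
        return PlasticityConfig(**self.plasticity)

    def reward_schedule(self) -> RewardSchedule:
        return RewardSchedule(**self.rewards)

    def schedule(self, epochs: int, supervised: bool = True) -> TrainingSchedule:
        return TrainingSchedule(
            presentations_per_epoch=self.presentations_per_epoch,
            epochs=epochs,
            eta0_unsupervised=self.eta0_unsupervised,
            eta0_supervised=self.eta0_supervised,
            eta0_per_layer=dict(self.eta0_per_layer),
            renorm_intervals=dict(self.renorm_intervals),
            speed=self.speed,
            plasticity=self.plasticity_config(),
            rewards=self.reward_schedule(),
        )


def derive_seeds(master: int, n: int = 4) -> list[int]:
    """Independent child seeds (below 2**31) from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = RunConfig().__dict__.keys()
    unknown = set(data) - set(known)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def _network_payload(net: Network) -> dict:
    header = {
        "version": _FORMAT_VERSION,
        "retina": net.retina_name,
        "testing": net.testing,
        "groups": {
            name: {
                "grid": list(net.grids[name]),
                "params": (net.params[name].__dict__ if name in net.params else None),
            }
            for name in net.sizes
        },
        "connections": [
            {"name": c.name, "source": c.source, "target": c.target,
             "plastic": c.plastic, "supervised": c.supervised,
             "delay": c.delay, "multiplier": c.multiplier,
             "test_only": c.test_only}
            for c in net.connections
        ],
    }
    arrays = {f"weights/{c.name}": c.weights for c in net.connections}
    arrays.update({f"membrane/{name}": net.state[name].membrane for name in net.sizes})
    return {"header": header, "arrays": arrays}


def _checksum(arrays: dict) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def save_network(net: Network, path) -> None:
    """Archive weights, membranes and parameters; lossless round trip."""
    payload = _network_payload(net)
    header = payload["header"]
    header["checksum"] = _checksum(payload["arrays"])
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **payload["arrays"])


def load_network(path) -> Network:
    """Rebuild a network from an archive, verifying its checksum."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported archive version {header.get('version')}")
        arrays = {k: data[k] for k in data.files if k != "__header__"}
    if _checksum(arrays) != header["checksum"]:
        raise ValueError("archive checksum mismatch: file corrupted or tampered")
    net = Network(retina_name=header["retina"])
    for name, g in header["groups"].items():
        params = NeuronGroupParams(**g["params"]) if g["params"] else None
        net.add_group(name, tuple(g["grid"]), params)
    for c in header["connections"]:
        net.connect(Connection(
            c["source"], c["target"], arrays[f"weights/{c['name']}"],
            plastic=c["plastic"], supervised=c["supervised"],
            delay=c["delay"], multiplier=c["multiplier"],
            test_only=c.get("test_only", False), name=c["name"]))
    net.finalize()
    net.testing = header["testing"]
    for name in net.sizes:
        net.state[name].membrane[:] = arrays[f"membrane/{name}"]
    return net


def spike_log_frame(record):
    """Spike record as a tidy (tick, group, neuron_index) DataFrame."""
    import pandas as pd

    return pd.DataFrame(record.to_rows(), columns=["tick", "group", "neuron_index"])
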