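"""Training protocol: concurrent unsupervised / value-gated burst-STDP.

One *presentation* is a single letter traversing the noiseless retina along
a random trajectory.  While it runs, the lower plastic projections
(C1-max -> S2-shape, S1-inst/S1-del -> S2-where) potentiate online at every
postsynaptic spike; the supervised projections (S2 -> CLA pools, shape ->
attention) only *accumulate* their burst-STDP changes.  At the end of the
presentation an external supervisor compares each classifier layer's
winning pool with the trial's label and applies the accumulated change
scaled by the annealed reward (correct) or punishment (wrong) constant.
Attention connections are gated differently: they are updated, always with
the reward sign, only on presentations that contain the target letter.

Each plastic layer is renormalized ("sleep") at its own fixed interval of
simulation ticks, and :func:`consolidate` finishes a training run by a
final renormalization, thresholding every plastic weight to {0, 1} and
severing the train-only winner-take-all interneurons.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .architecture import PLASTIC_LAYERS, validate_hardware
from .environment import StimulusTrial, make_training_trial, render_frame
from .lif import Network
from .plasticity import (
    PlasticityConfig,
    RewardSchedule,
    binarize_weights,
    burst_stdp_update,
    make_traces,
    update_burst_traces,
    value_gated_rate,
)

__all__ = [
    "TrainingSchedule",
    "RewardEvent",
    "TrainingLog",
    "judge_response",
    "pool_sums",
    "train",
    "train_unsupervised",
    "train_value_gated",
    "train_protocol",
    "consolidate",
]

_LETTER_INDEX = {"T": 0, "L": 1, "J": 2}

#: Renormalization ("sleep") interval per plastic layer, in ticks, within
#: the 500-2500 band; the feature layers sleep most often (their
#: potentiation is densest), the value-gated classifier layers least.
DEFAULT_RENORM_INTERVALS = {
    "S2-shape-ex": 500,
    "CLA-shape": 2500,
    "S2-where-ex": 500,
    "CLA-where": 2500,
    "Attention": 2500,
}

#: Per-layer unsupervised rates.  The motion feature layer learns from
#: long-lasting presence coincidences and needs a lower rate than the
#: shape feature layer to keep its weights from racing to the cap between
#: sleeps (which would let early winners hijack every movement primitive).
DEFAULT_ETA_PER_LAYER = {
    "S2-shape-ex": 0.005,
    "S2-where-ex": 0.002,
}


@dataclass(frozen=True)
class TrainingSchedule:
    """How long and how aggressively to train.

    ``presentations_per_epoch`` defaults to 400 single-object traversals
    (50 per trajectory on average); ``anneal_horizon`` is the number of
    presentations over which the reward/punishment constants interpolate
    from their start to their end values (defaults to the whole run).
    """

    presentations_per_epoch: int = 400
    epochs: int = 1
    eta0_unsupervised: float = 0.005
    eta0_supervised: float = 0.1
    eta0_per_layer: dict = field(default_factory=lambda: dict(DEFAULT_ETA_PER_LAYER))
    speed: int = 10
    renorm_intervals: dict = field(default_factory=lambda: dict(DEFAULT_RENORM_INTERVALS))
    anneal_horizon: Optional[int] = None
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    rewards: RewardSchedule = field(default_factory=RewardSchedule)

    def __post_init__(self) -> None:
        if self.presentations_per_epoch < 1 and self.epochs > 0:
            raise ValueError("schedule needs at least one presentation")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")

    @property
    def total_presentations(self) -> int:
        return self.presentations_per_epoch * self.epochs

    @property
    def horizon(self) -> int:
        return self.anneal_horizon or max(1, self.total_presentations)


@dataclass(frozen=True)
class RewardEvent:
    """Outcome of judging one classifier layer on one presentation."""

    trial_id: int
    group: str
    winning_pool: int
    correct: bool


class TrainingLog:
    """Per-presentation summaries (winners, correctness, modulation)."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)


def pool_sums(counts: np.ndarray, n_pools: int) -> np.ndarray:
    """Total spikes per pool for a (n_pools x pool_size) classifier layer."""
    return counts.reshape(n_pools, -1).sum(axis=1)


def judge_response(counts: np.ndarray, n_pools: int, true_pool: int,
                   trial_id: int = 0, group: str = "") -> Optional[RewardEvent]:
    """Winning pool = argmax of summed spikes; a tie yields no event."""
    sums = pool_sums(counts, n_pools)
    peak = sums.max()
    winners = np.flatnonzero(sums == peak)
    if peak == 0 or winners.size != 1:
        return None
    win = int(winners[0])
    return RewardEvent(trial_id, group, win, win == true_pool)


def _renormalize_layer(net: Network, layer: str) -> None:
    """Joint per-neuron rescale across every plastic input of ``layer``."""
    conns = [net.connection(n) for n in PLASTIC_LAYERS[layer]]
    stacked = np.vstack([c.weights for c in conns])
    peaks = stacked.max(axis=0)
    safe = np.where(peaks > 0.0, peaks, 1.0)
    for c in conns:
        c.weights = c.weights / safe


def train(net: Network, schedule: TrainingSchedule, rng: np.random.Generator,
          unsupervised: bool = True, supervised: bool = True,
          log: Optional[TrainingLog] = None) -> Network:
    """Run the full training protocol in place on ``net``."""
    net.testing = False
    cfg = schedule.plasticity
    unsup = [c for c in net.connections if c.plastic and not c.supervised]
    sup = [c for c in net.connections if c.supervised]
    trace_groups = sorted({c.source for c in unsup + sup})
    traces = {g: make_traces(net.sizes[g]) for g in trace_groups}
    tick_count = 0

    for p_idx in range(schedule.total_presentations):
        trial = make_training_trial(rng, speed=schedule.speed)
        letter, traj = trial.objects[0]
        net.reset_state()
        for g in trace_groups:
            traces[g][:] = 0.0
        elig = {c.name: np.zeros_like(c.weights) for c in sup}
        shape_counts = np.zeros(net.sizes["CLA-shape"], dtype=int)
        where_counts = np.zeros(net.sizes["CLA-where"], dtype=int)

        for t in range(trial.duration):
            fired = net.tick(render_frame(trial, t))
            for g in trace_groups:
                traces[g] = update_burst_traces(traces[g], fired[g], cfg)
            if unsupervised:
                for c in unsup:
                    post = fired[c.target]
                    if post.any():
                        rate = schedule.eta0_per_layer.get(
                            c.target, schedule.eta0_unsupervised)
                        c.weights = burst_stdp_update(
                            c.weights, traces[c.source], post, rate, cfg)
            if supervised:
                for c in sup:
                    post = fired[c.target]
                    if post.any():
                        elig[c.name] += np.outer(traces[c.source], post.astype(float))
            shape_counts += fired["CLA-shape"]
            where_counts += fired["CLA-where"]
            tick_count += 1
            for layer, interval in schedule.renorm_intervals.items():
                if interval and tick_count % interval == 0:
                    _renormalize_layer(net, layer)

        if supervised:
            progress = p_idx / schedule.horizon
            row = {"presentation": p_idx, "letter": letter, "trajectory": traj}
            ev_shape = judge_response(shape_counts, 3, _LETTER_INDEX[letter],
                                      p_idx, "CLA-shape")
            ev_where = judge_response(where_counts, 8, traj, p_idx, "CLA-where")
            for ev, conn_name, n_pools in (
                    (ev_shape, "S2-shape-ex->CLA-shape", 3),
                    (ev_where, "S2-where-ex->CLA-where", 8)):
                if ev is None:
                    continue
                rate = value_gated_rate(schedule.eta0_supervised, ev.correct,
                                        progress, schedule.rewards)
                c = net.connection(conn_name)
                # the reward system acts on the winning pool: its eligible
                # synapses are potentiated when it is the correct pool and
                # depressed when it is the wrong one; other pools' synapses
                # are untouched by this trial
                pool_size = c.weights.shape[1] // n_pools
                cols = slice(ev.winning_pool * pool_size,
                             (ev.winning_pool + 1) * pool_size)
                c.weights[:, cols] = np.clip(
                    c.weights[:, cols] + rate * elig[conn_name][:, cols],
                    cfg.weight_lower, cfg.weight_upper)
                row[f"{ev.group}_win"] = ev.winning_pool
                row[f"{ev.group}_correct"] = ev.correct
                row[f"{ev.group}_rate"] = rate
            if letter == "T":
                # attention plasticity is gated on target presence and is
                # always rewarded (there is no wrong answer to punish: the
                # supervisor only marks "the target is here")
                rate = value_gated_rate(schedule.eta0_supervised, True,
                                        progress, schedule.rewards)
                c = net.connection("S2-shape-ex->Attention")
                c.weights = np.clip(c.weights + rate * elig[c.name],
                                    cfg.weight_lower, cfg.weight_upper)
            if log is not None:
                log.rows.append(row)

    return net


def train_unsupervised(net: Network, schedule: TrainingSchedule,
                       rng: np.random.Generator) -> Network:
    """Unsupervised phase only (feature layers; classifiers untouched)."""
    return train(net, schedule, rng, unsupervised=True, supervised=False)


def train_protocol(net: Network, rng: np.random.Generator,
                   unsupervised_epochs: int = 1, supervised_epochs: int = 2,
                   schedule: Optional[TrainingSchedule] = None,
                   log: Optional[TrainingLog] = None) -> Network:
    """The canonical staged protocol, ending with consolidation.

    First the feature layers self-organize on their own (unsupervised
    burst-STDP under the training-time winner-take-all), then value-gated
    learning shapes the classifier pools and attention while unsupervised
    refinement continues underneath.  One "training epoch" of the shipped
    experiments is one such pass.
    """
    schedule = schedule or TrainingSchedule()
    if unsupervised_epochs:
        train(net, replace(schedule, epochs=unsupervised_epochs), rng,
              unsupervised=True, supervised=False)
    if supervised_epochs:
        train(net, replace(schedule, epochs=supervised_epochs), rng,
              unsupervised=True, supervised=True, log=log)
    return consolidate(net, schedule.plasticity)


def train_value_gated(net: Network, schedule: TrainingSchedule,
                      rng: np.random.Generator,
                      log: Optional[TrainingLog] = None) -> Network:
    """Concurrent unsupervised + value-gated training (the default protocol)."""
    return train(net, schedule, rng, unsupervised=True, supervised=True, log=log)


def consolidate(net: Network, cfg: Optional[PlasticityConfig] = None) -> Network:
    """Final renormalization + binarization; switch the network to test mode.

    All plastic weights end in {0, 1}, train-only groups are severed, and a
    hardware-compatibility report is attached as ``net.hardware_report``.
    Idempotent.
    """
    cfg = cfg or PlasticityConfig()
    for layer in PLASTIC_LAYERS:
        _renormalize_layer(net, layer)
    for c in net.connections:
        if c.plastic:
            c.weights = binarize_weights(c.weights, cfg.binarize_threshold)
    net.testing = True
    net.hardware_report = validate_hardware(net)
    return net
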