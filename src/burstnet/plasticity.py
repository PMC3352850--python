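"""Burst-STDP learning: traces, value gating, renormalization, binarization.

The learning rule keeps one non-negative "burstiness" trace per presynaptic
neuron -- a leaky memory of its recent spiking.  Each trace is incremented
by a fixed amount on every spike and decremented by a fixed amount on every
tick (clamped at 0), so bursts accumulate a large trace while sparse spikes
do not.  Whenever a postsynaptic neuron spikes, every incoming plastic
weight is potentiated proportionally to its presynaptic trace::

    b  <-  max(0, b + increment * spike - decay)       (every tick)
    dw  =  eta * b_pre                                 (per post spike)

Unsupervised learning uses only this potentiation side; depression would be
redundant because homeostatic renormalization -- a periodic linear rescale
of every neuron's incoming weights so the strongest equals 1 -- erodes any
weight that is not regularly re-potentiated.  Supervised (value-gated)
learning multiplies the same accumulated change by a signed modulation
delivered by an external supervisor: positive for correct responses,
negative for wrong ones, both annealed over the course of training.
Weights live in [0, 1.5] while learning and are thresholded to {0, 1}
before testing, matching the binary synapses of the target hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityConfig",
    "RewardSchedule",
    "make_traces",
    "update_burst_traces",
    "burst_stdp_update",
    "value_gated_rate",
    "renormalize_incoming",
    "binarize_weights",
]


@dataclass(frozen=True)
class PlasticityConfig:
    """Constants of the burst-STDP rule.

    ``trace_increment`` (0.4) and ``trace_decay`` (0.05) are the per-spike
    increment and per-tick decrement of the burstiness trace;
    ``weight_upper`` (1.5) and ``weight_lower`` (0) bound synaptic strength
    during training; ``binarize_threshold`` separates on- from off-synapses
    at consolidation (after renormalization the strongest incoming weight
    is exactly 1, so any mid-range value works); ``base_rate`` is the
    unsupervised learning rate eta0.
    """

    trace_increment: float = 0.4
    trace_decay: float = 0.05
    base_rate: float = 0.1
    weight_lower: float = 0.0
    weight_upper: float = 1.5
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (self.trace_increment > self.trace_decay > 0):
            raise ValueError("need trace_increment > trace_decay > 0")
        if not (self.weight_lower < self.binarize_threshold < self.weight_upper):
            raise ValueError("binarize_threshold must sit between the weight bounds")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")


@dataclass(frozen=True)
class RewardSchedule:
    """Annealed reward/punishment constants for value-gated learning.

    The modulation starts at ``reward_start`` (0.5) for correct responses
    and ``punish_start`` (-0.1) for wrong ones, and interpolates linearly
    over training to ``reward_end`` (0.1) and ``punish_end`` (0): early
    trials reshape connectivity aggressively, late trials only refine it.
    """

    reward_start: float = 0.5
    reward_end: float = 0.1
    punish_start: float = -0.1
    punish_end: float = 0.0

    def __post_init__(self) -> None:
        if self.reward_start <= 0 or self.reward_end <= 0:
            raise ValueError("reward constants must stay positive")
        if self.punish_start > 0 or self.punish_end > 0:
            raise ValueError("punishment constants must be non-positive")


def make_traces(n: int) -> np.ndarray:
    """Fresh all-zero burst-trace array for ``n`` presynaptic neurons."""
    return np.zeros(n)


def update_burst_traces(traces, pre_spikes, cfg: PlasticityConfig) -> np.ndarray:
    """One tick of the trace recurrence, elementwise.

    The spike increment and the decay are applied together in a single
    update: ``b' = max(0, b + increment * spike - decay)``.
    """
    traces = np.asarray(traces, dtype=float)
    s = np.asarray(pre_spikes).astype(float)
    return np.maximum(0.0, traces + cfg.trace_increment * s - cfg.trace_decay)


def burst_stdp_update(weights, traces, post_spikes, rate, cfg: PlasticityConfig) -> np.ndarray:
    """Apply ``dw = rate * b_pre`` to every synapse onto a spiking target.

    ``weights`` is ``(n_pre, n_post)``; columns of non-spiking targets are
    untouched.  The result is clamped to ``[weight_lower, weight_upper]``.
    A negative ``rate`` (value-gated punishment) depresses instead.
    """
    weights = np.asarray(weights, dtype=float)
    post = np.asarray(post_spikes).astype(float)
    delta = rate * np.outer(np.asarray(traces, dtype=float), post)
    return np.clip(weights + delta, cfg.weight_lower, cfg.weight_upper)


def value_gated_rate(eta0: float, reward_correct: bool, progress: float,
                     schedule: RewardSchedule) -> float:
    """Signed learning rate ``eta0 * v(reward, progress)``.

    ``progress`` is the fraction of completed training presentations in
    [0, 1]; ``v`` interpolates the schedule's start constants to its end
    constants linearly in ``progress``.
    """
    progress = float(np.clip(progress, 0.0, 1.0))
    if reward_correct:
        v = schedule.reward_start + progress * (schedule.reward_end - schedule.reward_start)
    else:
        v = schedule.punish_start + progress * (schedule.punish_end - schedule.punish_start)
    return eta0 * v


def renormalize_incoming(weights) -> np.ndarray:
    """Linearly rescale one neuron's incoming weights so the max is 1.

    Preserves ordering and pairwise ratios; an all-zero vector is returned
    unchanged (no division).  Idempotent.
    """
    w = np.asarray(weights, dtype=float)
    peak = w.max() if w.size else 0.0
    if peak <= 0.0:
        return w.copy()
    return w / peak


def renormalize_columns(weights) -> np.ndarray:
    """Renormalize a whole ``(n_pre, n_post)`` matrix per postsynaptic neuron."""
    w = np.asarray(weights, dtype=float)
    peaks = w.max(axis=0, keepdims=True)
    safe = np.where(peaks > 0.0, peaks, 1.0)
    return w / safe


def binarize_weights(weights, threshold: float) -> np.ndarray:
    """Threshold weights to {0, 1}; ``w >= threshold`` becomes 1."""
    w = np.asarray(weights, dtype=float)
    return (w >= threshold).astype(float)
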