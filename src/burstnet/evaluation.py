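"""Experiment battery: recognition accuracy, noise sweeps, attention ablation.

Outcome accounting follows the last-response rule: the network's decision
on a trial is its *last* motor spike before the object leaves the retina; a
trial with no motor spike at all is a No Decision.

The motion-detection task asks "which way is the object moving?"
irrespective of what it is, for all three letters -- including the
distractor, whose motor output the decision module deliberately silences.
It is therefore read from the trajectory-classifier (CLA-where) pools:
the decision is the pool with the most spikes integrated over the trial.
The full-task and two-object experiments use the motor layer of the
complete network with its catch/avoid/ignore semantics.

:func:`direction_network` is also provided: a configuration with the
letter-semantics channels severed whose motor output reports the
anticipated arrival placement for any letter.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .architecture import build_network, sever_attention
from .environment import (
    SINGLE_OBJECT_MIX,
    TARGET_AVOID_MIX,
    TWO_OBJECT_MIX,
    StimulusTrial,
    expected_response,
    inject_noise,
    make_trial,
    render_frame,
)
from .lif import Network
from .training import TrainingSchedule, pool_sums, train_protocol

__all__ = [
    "TrialOutcome",
    "TrialResult",
    "SweepResult",
    "run_trial",
    "classify_outcome",
    "classify_direction",
    "direction_network",
    "shape_recognition_experiment",
    "noise_sweep",
    "attention_ablation_experiment",
    "train_default_network",
]

CORRECT = "Correct"
INCORRECT = "Incorrect"
NO_DECISION = "NoDecision"

_LETTER_INDEX = {"T": 0, "L": 1, "J": 2}


@dataclass(frozen=True)
class TrialOutcome:
    outcome: str
    final_motor: Optional[int] = None
    decision_tick: Optional[int] = None


@dataclass
class TrialResult:
    """What one simulated trial leaves behind for scoring."""

    trial: StimulusTrial
    motor_spikes: list  # (tick, motor index) pairs, time-ordered
    cla_shape_counts: np.ndarray
    cla_where_counts: np.ndarray


def run_trial(net: Network, trial: StimulusTrial,
              rng: Optional[np.random.Generator] = None) -> TrialResult:
    """Simulate one full stimulus traversal and collect the readout layers."""
    if trial.noise_p > 0 and rng is None:
        raise ValueError("noisy trials need an RNG")
    net.reset_state()
    motor: list[tuple[int, int]] = []
    shape_counts = np.zeros(net.sizes["CLA-shape"], dtype=int)
    where_counts = np.zeros(net.sizes["CLA-where"], dtype=int)
    for t in range(trial.duration):
        frame = render_frame(trial, t)
        if trial.noise_p > 0:
            frame = inject_noise(frame, trial.noise_p, rng)
        fired = net.tick(frame)
        shape_counts += fired["CLA-shape"]
        where_counts += fired["CLA-where"]
        for idx in np.flatnonzero(fired["Motor"]):
            motor.append((t, int(idx)))
    return TrialResult(trial, motor, shape_counts, where_counts)


def classify_outcome(motor_spikes: Sequence, trial: StimulusTrial) -> TrialOutcome:
    """Score the motor log by the last-response rule.

    The final decision is the motor neuron spiking at the last active tick
    (two different motor neurons on that tick count as an incorrect,
    ambiguous response).  For a distractor-only trial any motor response is
    wrong and silence is a No Decision -- the experiment convention decides
    whether that counts as correct.
    """
    expected = expected_response(trial).expected_motor_index
    if not motor_spikes:
        return TrialOutcome(NO_DECISION)
    last_tick = motor_spikes[-1][0]
    finals = sorted({idx for t, idx in motor_spikes if t == last_tick})
    if len(finals) > 1:
        return TrialOutcome(INCORRECT, final_motor=finals[0], decision_tick=last_tick)
    final = finals[0]
    if expected is not None and final == expected:
        return TrialOutcome(CORRECT, final_motor=final, decision_tick=last_tick)
    return TrialOutcome(INCORRECT, final_motor=final, decision_tick=last_tick)


def classify_direction(where_counts: np.ndarray, trial: StimulusTrial) -> TrialOutcome:
    """Score the motion task from the trajectory-classifier pools.

    The decision is the pool with the most spikes integrated over the
    whole trial; no spikes at all, or an exact tie, is a No Decision.
    """
    sums = pool_sums(where_counts, 8)
    peak = sums.max()
    winners = np.flatnonzero(sums == peak)
    if peak == 0 or winners.size != 1:
        return TrialOutcome(NO_DECISION)
    win = int(winners[0])
    true_traj = trial.objects[0][1]
    return TrialOutcome(CORRECT if win == true_traj else INCORRECT, final_motor=win)


def direction_network(net: Network) -> Network:
    """Copy of ``net`` with the object-semantics channels disconnected.

    Severs the outgoing weights of Shape-inh (the catch/avoid/ignore
    vetoes) and Obstacle (the avoidance placement channel), leaving motor
    output driven by Target + Shape-decision alone: a pure
    direction-anticipation readout.
    """
    out = copy.deepcopy(net)
    for c in out.connections:
        if c.source in ("Shape-inh", "Obstacle"):
            c.weights = np.zeros_like(c.weights)
    return out


@dataclass
class SweepResult:
    """Outcome fractions per noise level (they partition each level's trials)."""

    task: str
    levels: np.ndarray
    correct: np.ndarray
    incorrect: np.ndarray
    no_decision: np.ndarray
    n_per_level: int
    seed: Optional[int] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "noise": self.levels, "correct": self.correct,
            "incorrect": self.incorrect, "no_decision": self.no_decision,
            "n": self.n_per_level,
        })

    def plot(self, ax=None, title=None):
        """Stacked correct / incorrect / no-decision fractions vs. noise."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = 100 * self.levels
        ax.stackplot(x, self.correct, self.incorrect, self.no_decision,
                     labels=("Correct", "Incorrect", "No Decision"),
                     colors=("tab:green", "tab:red", "tab:gray"), alpha=0.8)
        ax.set_xlabel("noise (% pixels flipped per tick)")
        ax.set_ylabel("fraction of trials")
        ax.set_ylim(0, 1)
        ax.legend(loc="center left")
        ax.set_title(title or self.task)
        return ax


_TASK_MIX = {
    "motion_only": SINGLE_OBJECT_MIX,
    "single_object": TARGET_AVOID_MIX,
    "two_object": TWO_OBJECT_MIX,
}


def _score_trial(task: str, result: TrialResult) -> str:
    if task == "motion_only":
        return classify_direction(result.cla_where_counts, result.trial).outcome
    out = classify_outcome(result.motor_spikes, result.trial)
    if expected_response(result.trial).expected_motor_index is None:
        # distractor-only: silence is the correct behaviour
        return CORRECT if out.outcome == NO_DECISION else INCORRECT
    return out.outcome


def noise_sweep(net: Network, task: str, levels: Sequence[float],
                n_per_level: int, rng: np.random.Generator,
                speed: int = 10) -> SweepResult:
    """Classify ``n_per_level`` random trials of ``task`` at each noise level."""
    if task not in _TASK_MIX:
        raise ValueError(f"unknown task {task!r}")
    mix = _TASK_MIX[task]
    runner = net
    levels = np.asarray(list(levels), dtype=float)
    frac = {CORRECT: [], INCORRECT: [], NO_DECISION: []}
    for p in levels:
        tally = {CORRECT: 0, INCORRECT: 0, NO_DECISION: 0}
        for _ in range(n_per_level):
            trial = make_trial(rng, mix, noise_p=float(p), speed=speed)
            result = run_trial(runner, trial, rng)
            tally[_score_trial(task, result)] += 1
        for k in tally:
            frac[k].append(tally[k] / n_per_level)
    return SweepResult(task, levels, np.array(frac[CORRECT]),
                       np.array(frac[INCORRECT]), np.array(frac[NO_DECISION]),
                       n_per_level)


def shape_recognition_experiment(seeds: Sequence[int] = (0, 1, 2, 3),
                                 n_per_letter: int = 100,
                                 schedule: Optional[TrainingSchedule] = None
                                 ) -> dict:
    """Per-letter recognition accuracy after a single training epoch.

    Trains one network per seed (distinct random weight initializations and
    trial streams), consolidates, then presents each letter ``n_per_letter``
    times on random noiseless trajectories; a presentation is correct when
    the winning CLA-shape pool matches the letter.  Returns per-letter
    accuracies per seed plus means and standard errors across seeds.
    """
    schedule = schedule or TrainingSchedule()
    acc = np.zeros((len(seeds), 3))
    for si, seed in enumerate(seeds):
        net = build_network(rng_seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        train_protocol(net, rng, schedule=schedule)
        test_rng = np.random.default_rng(seed + 20_000)
        for li, letter in enumerate("TLJ"):
            hits = 0
            for _ in range(n_per_letter):
                traj = int(test_rng.integers(8))
                trial = StimulusTrial([(letter, traj)], noise_p=0.0,
                                      speed=schedule.speed)
                result = run_trial(net, trial)
                sums = pool_sums(result.cla_shape_counts, 3)
                winners = np.flatnonzero(sums == sums.max())
                if sums.max() > 0 and winners.size == 1 and winners[0] == li:
                    hits += 1
            acc[si, li] = hits / n_per_letter
    return {
        "per_seed": acc,
        "mean": acc.mean(axis=0),
        "sem": acc.std(axis=0, ddof=1) / np.sqrt(len(seeds)) if len(seeds) > 1
               else np.zeros(3),
        "letters": ("T", "L", "J"),
    }


def attention_ablation_experiment(net: Network, levels: Sequence[float],
                                  n_per_level: int, seed: int) -> dict:
    """Two-object sweep on the intact network vs. the attention-severed copy.

    Both arms see identical trial streams (paired seeds); the severed arm
    is a deep copy with every outgoing attention connection zeroed.
    """
    severed = sever_attention(copy.deepcopy(net))
    intact_sweep = noise_sweep(net, "two_object", levels, n_per_level,
                               np.random.default_rng(seed))
    severed_sweep = noise_sweep(severed, "two_object", levels, n_per_level,
                                np.random.default_rng(seed))
    return {"intact": intact_sweep, "severed": severed_sweep}


def train_default_network(seed: int = 0, unsupervised_epochs: int = 1,
                          supervised_epochs: int = 2,
                          schedule: Optional[TrainingSchedule] = None) -> Network:
    """Build, run the staged training protocol, and consolidate."""
    net = build_network(rng_seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    return train_protocol(net, rng, unsupervised_epochs, supervised_epochs,
                          schedule=schedule)
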