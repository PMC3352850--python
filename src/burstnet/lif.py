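"""Discrete-time simulation engine for hardware-constrained LIF neurons.

The neuron model mirrors a digital neurosynaptic core: integer firing
threshold ``T``, linear (constant) membrane leak ``L``, one multiplicative
synaptic weighting value per input sign (``S+`` for excitatory inputs,
``S-`` for inhibitory ones), a membrane potential clamped at 0 from below,
reset-to-0 on spiking, and a fixed 1 ms tick.  Every spike emitted at tick
``t`` is integrated by its postsynaptic targets at tick ``t+1`` (one-cycle
propagation delay); the only longer delay in the network is the explicit
delay line feeding the delayed motion detectors.

Membrane update convention
--------------------------
At each tick a neuron receives the weighted excitatory drive ``x`` and
inhibitory drive ``y`` produced by the previous tick's spikes.  The firing
test is applied to the integrated membrane *before* the leak is taken out::

    fired  =  (M + x - y) > T
    M'     =  0                      if fired
              max(0, M + x - y - L)  otherwise

i.e. the leak only erodes potential that is carried to the next tick.  The
threshold comparison is strict.  This ordering is what makes the shipped
architecture table self-consistent: several groups (the training-time
winner-take-all interneurons, the retinal presence detectors, the motor
coincidence units) are parameterised with ``L`` close to or above ``S+``
and can only ever fire if the leak is excluded from the firing test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "EXCITATORY",
    "INHIBITORY",
    "NeuronGroupParams",
    "LayerState",
    "Connection",
    "Network",
    "SpikeRecord",
    "membrane_step",
    "propagate",
]

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"

#: Parameter ranges of the target neuromorphic core (used again by the
#: hardware-compatibility report in :mod:`burstnet.architecture`).
THRESHOLD_RANGE = (1, 256)
LEAK_RANGE = (-256, 255)
MULTIPLIER_RANGE = (-256, 255)


@dataclass(frozen=True)
class NeuronGroupParams:
    """Per-group LIF parameters, one row of the architecture table.

    Parameters
    ----------
    threshold :
        Firing threshold ``T`` (membrane units), in [1, 256].
    leak :
        Linear per-tick membrane decrement ``L``, in [0, 255].
    s_plus, s_minus :
        Multiplier applied to each weighted excitatory / inhibitory input
        spike, in [0, 255].
    axon_type :
        ``"excitatory"`` or ``"inhibitory"`` -- the sign this group's output
        spikes carry everywhere downstream.
    train_only :
        Group participates only while learning; its outputs are severed in
        the consolidated (test-time) network.
    """

    threshold: int
    leak: int
    s_plus: int
    s_minus: int
    axon_type: str = EXCITATORY
    train_only: bool = False

    def __post_init__(self) -> None:
        if not (THRESHOLD_RANGE[0] <= self.threshold <= THRESHOLD_RANGE[1]):
            raise ValueError(f"threshold {self.threshold} outside {THRESHOLD_RANGE}")
        if not (0 <= self.leak <= 255):
            raise ValueError(f"leak {self.leak} outside [0, 255]")
        for name, v in (("s_plus", self.s_plus), ("s_minus", self.s_minus)):
            if not (0 <= v <= 255):
                raise ValueError(f"{name} {v} outside [0, 255]")
        if self.axon_type not in (EXCITATORY, INHIBITORY):
            raise ValueError(f"unknown axon type {self.axon_type!r}")


def membrane_step(M, x, y, params: NeuronGroupParams):
    """One membrane update for a vector of neurons sharing parameters.

    ``x`` and ``y`` are the weighted excitatory / inhibitory drives already
    multiplied by ``S+`` / ``S-``.  Returns ``(M', fired)``.
    """
    M = np.asarray(M, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("weighted inputs must be non-negative")
    drive = M + x - y
    fired = drive > params.threshold
    M_next = np.where(fired, 0.0, np.maximum(0.0, drive - params.leak))
    return M_next, fired


def propagate(spikes, weights):
    """Weighted input delivered to a target group by one spike vector.

    The result is, by the engine's contract, applied to the targets at the
    *next* tick.  ``weights`` has shape ``(n_source, n_target)``.
    """
    spikes = np.asarray(spikes)
    weights = np.asarray(weights, dtype=float)
    if spikes.shape[0] != weights.shape[0]:
        raise ValueError(
            f"spike vector length {spikes.shape[0]} does not match "
            f"weight matrix rows {weights.shape[0]}"
        )
    return spikes.astype(float) @ weights


@dataclass
class LayerState:
    """Mutable per-group state: membrane potentials and last spikes."""

    membrane: np.ndarray
    fired: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "LayerState":
        return cls(membrane=np.zeros(n), fired=np.zeros(n, dtype=bool))


@dataclass
class Connection:
    """A weighted projection between two neuron groups.

    ``weights`` is dense ``(n_source, n_target)``; real-valued in
    ``[0, 1.5]`` for plastic connections during training, binary otherwise.
    ``multiplier`` overrides the target's ``S+``/``S-`` for this projection
    (the hardware's spare per-neuron synapse-value slot); ``None`` means use
    the target group's default.  ``delay`` is in ticks and is at least 1.
    """

    source: str
    target: str
    weights: np.ndarray
    plastic: bool = False
    supervised: bool = False
    delay: int = 1
    multiplier: Optional[int] = None
    test_only: bool = False  # engaged only after learning (top-down feedback)
    name: str = ""

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("delay must be >= 1 tick")
        if self.supervised and not self.plastic:
            raise ValueError("supervised connections must be plastic")
        if not self.name:
            self.name = f"{self.source}->{self.target}"


class SpikeRecord:
    """Tick-indexed spike log for a simulated interval."""

    def __init__(self) -> None:
        self._events: list[tuple[int, str, np.ndarray]] = []

    def append(self, tick: int, group: str, fired: np.ndarray) -> None:
        idx = np.flatnonzero(fired)
        if idx.size:
            self._events.append((tick, group, idx))

    def counts(self, group: str, n: int, window=None) -> np.ndarray:
        """Total spikes per neuron of ``group`` (optionally within ``[t0, t1)``)."""
        out = np.zeros(n, dtype=int)
        for t, g, idx in self._events:
            if g != group:
                continue
            if window is not None and not (window[0] <= t < window[1]):
                continue
            np.add.at(out, idx, 1)
        return out

    def spike_times(self, group: str):
        """List of ``(tick, neuron_index)`` pairs for ``group``."""
        out = []
        for t, g, idx in self._events:
            if g == group:
                out.extend((t, int(i)) for i in idx)
        return out

    def to_rows(self):
        """Rows ``(tick, group, neuron_index)`` for tabular export."""
        for t, g, idx in self._events:
            for i in idx:
                yield t, g, int(i)


class Network:
    """A collection of neuron groups and connections stepped one tick at a time.

    The retina group is an input clamp: its neurons spike on every tick
    their pixel is 1 and perform no integration.
    """

    def __init__(self, retina_name: str = "Retina") -> None:
        self.retina_name = retina_name
        self.params: dict[str, NeuronGroupParams] = {}
        self.sizes: dict[str, int] = {}
        self.grids: dict[str, tuple[int, int]] = {}
        self.connections: list[Connection] = []
        self.state: dict[str, LayerState] = {}
        self.testing: bool = False  # severs train-only groups when True
        self.t: int = 0
        self._history: dict[str, np.ndarray] = {}
        self._hist_len: int = 2
        self._incoming: dict[str, list[Connection]] = {}

    # -- construction -----------------------------------------------------

    def add_group(self, name: str, grid: tuple[int, int], params: Optional[NeuronGroupParams]) -> None:
        if name in self.sizes:
            raise ValueError(f"duplicate group {name!r}")
        self.grids[name] = tuple(grid)
        self.sizes[name] = int(grid[0] * grid[1])
        if params is not None:
            self.params[name] = params
        elif name != self.retina_name:
            raise ValueError("only the retina may omit neuron parameters")

    def connect(self, conn: Connection) -> None:
        for end in (conn.source, conn.target):
            if end not in self.sizes:
                raise KeyError(f"unknown group {end!r}")
        expect = (self.sizes[conn.source], self.sizes[conn.target])
        if conn.weights.shape != expect:
            raise ValueError(
                f"{conn.name}: weight shape {conn.weights.shape} != {expect}"
            )
        self.connections.append(conn)

    def finalize(self) -> None:
        """Allocate state and spike-history buffers; call after wiring."""
        self._hist_len = max([c.delay for c in self.connections], default=1) + 1
        for name, n in self.sizes.items():
            self.state[name] = LayerState.zeros(n)
            self._history[name] = np.zeros((self._hist_len, n), dtype=bool)
        self._incoming = {name: [] for name in self.sizes}
        for c in self.connections:
            self._incoming[c.target].append(c)
        self.t = 0

    # -- runtime ----------------------------------------------------------

    def reset_state(self) -> None:
        """Zero membranes and spike history (a fresh stimulus presentation)."""
        for name in self.sizes:
            self.state[name].membrane[:] = 0.0
            self.state[name].fired[:] = False
            self._history[name][:] = False
        self.t = 0

    def connection(self, name: str) -> Connection:
        for c in self.connections:
            if c.name == name:
                return c
        raise KeyError(name)

    def past_spikes(self, group: str, delay: int) -> np.ndarray:
        """Spike vector of ``group`` emitted ``delay`` ticks before now."""
        if delay >= self._hist_len or delay > self.t:
            return np.zeros(self.sizes[group], dtype=bool)
        return self._history[group][(self.t + 1 - delay) % self._hist_len]

    def _group_severed(self, name: str) -> bool:
        p = self.params.get(name)
        return self.testing and p is not None and p.train_only

    def tick(self, frame: np.ndarray, record: Optional[SpikeRecord] = None) -> dict[str, np.ndarray]:
        """Advance the whole network by one 1 ms tick.

        ``frame`` is the 10x10 (or retina-shaped) binary image for this
        tick.  Every group consumes the inputs produced by spikes of
        previous ticks, applies the membrane update, and queues its own
        spikes for the next tick.  Deterministic given state and frame.
        """
        frame = np.asarray(frame)
        if frame.size != self.sizes[self.retina_name]:
            raise ValueError("frame does not match retina size")
        fired_now: dict[str, np.ndarray] = {}
        fired_now[self.retina_name] = frame.ravel().astype(bool)

        for name in self.sizes:
            if name == self.retina_name:
                continue
            if self._group_severed(name):
                fired_now[name] = np.zeros(self.sizes[name], dtype=bool)
                continue
            p = self.params[name]
            drive = self.state[name].membrane.copy()
            for c in self._incoming[name]:
                if self._group_severed(c.source):
                    continue
                if c.test_only and not self.testing:
                    continue
                src_spikes = self.past_spikes(c.source, c.delay)
                if not src_spikes.any():
                    continue
                contrib = src_spikes.astype(float) @ c.weights
                src_p = self.params.get(c.source)
                src_sign = src_p.axon_type if src_p is not None else EXCITATORY
                if src_sign == EXCITATORY:
                    mult = p.s_plus if c.multiplier is None else c.multiplier
                    drive += mult * contrib
                else:
                    mult = p.s_minus if c.multiplier is None else c.multiplier
                    drive -= mult * contrib
            # inline membrane update (same rule as membrane_step, without
            # per-call input validation: the engine only produces
            # non-negative weighted drives)
            fired = drive > p.threshold
            st = self.state[name]
            st.membrane = np.where(fired, 0.0,
                                   np.maximum(0.0, drive - p.leak))
            st.fired = fired
            fired_now[name] = fired

        self.t += 1
        slot = self.t % self._hist_len
        for name, fired in fired_now.items():
            self._history[name][slot] = fired
            if record is not None:
                record.append(self.t, name, fired)
        return fired_now
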