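"""The 23-group visuo-motor network: group table, wiring, hardware checks.

The network is organised in five modules on top of a 10x10 retina:

* **shape** -- an HMAX-like ventral stream (S1 edge detectors, C1 layers
  implementing max pooling with localized inhibition, S2 feature cells
  learned without supervision under a weakly-enforced winner-take-all, and
  a value-gated classifier layer CLA-shape with one pool of 10 neurons per
  letter);
* **motion** -- a dorsal stream pairing instantaneous (S1-inst) and delayed
  (S1-del) presence detectors, S2-where cells that learn local motion
  primitives from their coincidences, and CLA-where with one pool of 10
  neurons per trajectory;
* **attention** -- an inhibitory group that learns (value-gated, only when
  the target letter is shown) which shape cells signal the target, and
  feeds back inhibition onto non-target classifications and non-target
  motion;
* **decision** -- hard-wired Target/Obstacle integrators over the CLA-where
  pools, letter-driven vetoes (Shape-inh), a slow evidence integrator
  (Shape-decision) and 8 motor units, one per catcher placement.

Every group's parameters come from a single declarative table that also
drives the hardware-compatibility report (parameter ranges and binary
synapses of the target neurosynaptic core).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .environment import OPPOSITE_TRAJECTORY, RETINA_SHAPE
from .lif import (
    EXCITATORY,
    INHIBITORY,
    LEAK_RANGE,
    MULTIPLIER_RANGE,
    THRESHOLD_RANGE,
    Connection,
    Network,
    NeuronGroupParams,
)

__all__ = [
    "GroupSpec",
    "ConnectionSpec",
    "HardwareReport",
    "DEFAULT_GROUPS",
    "DEFAULT_CONNECTIONS",
    "build_network",
    "wire_topographic",
    "wire_random",
    "validate_hardware",
    "sever_attention",
    "total_neurons",
    "PLASTIC_LAYERS",
]

# Delay of the S1-del pathway in ticks.  The presence detectors tile the
# retina at stride 2, so a glyph moving 1 pixel per 10-tick step realigns
# with a window every SECOND step; the delayed pathway spans that
# realignment interval so that instantaneous/delayed coincidences encode
# a movement direction.  Hence 2 x the 10-tick movement period.
MOTION_DELAY = 20


@dataclass(frozen=True)
class GroupSpec:
    """One row of the architecture table."""

    name: str
    module: str               # retina | shape | motion | attention | decision
    grid: tuple[int, int]
    targets: tuple[str, ...]
    rf: Optional[tuple[int, int]] = None  # input receptive field, if topographic
    train_only: bool = False
    axon_type: str = EXCITATORY
    threshold: Optional[int] = None
    leak: Optional[int] = None
    s_plus: Optional[int] = None
    s_minus: Optional[int] = None

    @property
    def size(self) -> int:
        return self.grid[0] * self.grid[1]

    def neuron_params(self) -> Optional[NeuronGroupParams]:
        if self.threshold is None:
            return None  # the retina is an input clamp
        return NeuronGroupParams(
            threshold=self.threshold, leak=self.leak,
            s_plus=self.s_plus, s_minus=self.s_minus,
            axon_type=self.axon_type, train_only=self.train_only,
        )


# The shipped default table.  Grid sizes, targets, receptive fields,
# train-only flags and the four neuron constants (T, L, S+, S-) are the
# published operating point of the architecture; everything downstream
# (wiring strides, pool layout) is derived from it.
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("Retina", "retina", (10, 10),
              ("S1-ver", "S1-hor", "S1-inst", "S1-del"), rf=(1, 1)),
    GroupSpec("S1-ver", "shape", (10, 5), ("C1-ver-ex",), rf=(1, 2),
              threshold=31, leak=16, s_plus=16, s_minus=0),
    GroupSpec("S1-hor", "shape", (5, 10), ("C1-hor-ex",), rf=(2, 1),
              threshold=31, leak=16, s_plus=16, s_minus=0),
    GroupSpec("C1-ver-ex", "shape", (10, 5), ("C1-ver-inh", "C1-ver-max"), rf=(1, 1),
              threshold=4, leak=2, s_plus=8, s_minus=64),
    GroupSpec("C1-hor-ex", "shape", (5, 10), ("C1-hor-inh", "C1-hor-max"), rf=(1, 1),
              threshold=4, leak=2, s_plus=8, s_minus=64),
    GroupSpec("C1-ver-inh", "shape", (10, 5), ("C1-ver-ex",), rf=(1, 1),
              axon_type=INHIBITORY, threshold=4, leak=2, s_plus=32, s_minus=0),
    GroupSpec("C1-hor-inh", "shape", (5, 10), ("C1-hor-ex",), rf=(1, 1),
              axon_type=INHIBITORY, threshold=4, leak=2, s_plus=32, s_minus=0),
    GroupSpec("C1-ver-max", "shape", (5, 5), ("S2-shape-ex",), rf=(2, 1),
              threshold=1, leak=2, s_plus=32, s_minus=0),
    GroupSpec("C1-hor-max", "shape", (5, 5), ("S2-shape-ex",), rf=(1, 2),
              threshold=16, leak=2, s_plus=32, s_minus=0),
    GroupSpec("S2-shape-ex", "shape", (6, 6),
              ("CLA-shape", "Attention", "S2-shape-inh"),
              threshold=100, leak=64, s_plus=32, s_minus=255),
    GroupSpec("S2-shape-inh", "shape", (6, 6), ("S2-shape-ex",), rf=(1, 1),
              train_only=True, axon_type=INHIBITORY,
              threshold=2, leak=32, s_plus=32, s_minus=0),
    GroupSpec("CLA-shape", "shape", (3, 10), ("Shape-inh", "Shape-decision"),
              threshold=16, leak=2, s_plus=32, s_minus=128),
    GroupSpec("S1-inst", "motion", (4, 4), ("S2-where-ex",), rf=(4, 4),
              threshold=27, leak=26, s_plus=4, s_minus=0),
    GroupSpec("S1-del", "motion", (4, 4), ("S2-where-ex",), rf=(4, 4),
              threshold=27, leak=26, s_plus=4, s_minus=0),
    GroupSpec("S2-where-ex", "motion", (4, 6),
              ("CLA-where", "Attention", "S2-where-inh"),
              threshold=100, leak=64, s_plus=64, s_minus=192),
    GroupSpec("S2-where-inh", "motion", (4, 6), ("S2-where-ex",), rf=(1, 1),
              train_only=True, axon_type=INHIBITORY,
              threshold=16, leak=2, s_plus=32, s_minus=0),
    GroupSpec("CLA-where", "motion", (8, 10), ("Target", "Obstacle"),
              threshold=32, leak=16, s_plus=64, s_minus=0),
    GroupSpec("Attention", "attention", (4, 6),
              ("S2-where-ex", "CLA-shape", "Attention"),
              axon_type=INHIBITORY, threshold=5, leak=16, s_plus=16, s_minus=128),
    GroupSpec("Target", "decision", (1, 8), ("Motor",), rf=(1, 10),
              threshold=21, leak=5, s_plus=1, s_minus=80),
    GroupSpec("Obstacle", "decision", (1, 8), ("Motor",), rf=(1, 10),
              threshold=21, leak=5, s_plus=1, s_minus=80),
    GroupSpec("Shape-inh", "decision", (1, 3), ("Target", "Obstacle"), rf=(1, 10),
              axon_type=INHIBITORY, threshold=4, leak=4, s_plus=1, s_minus=0),
    GroupSpec("Shape-decision", "decision", (1, 3), ("Motor",), rf=(1, 10),
              threshold=13, leak=3, s_plus=1, s_minus=0),
    GroupSpec("Motor", "decision", (1, 8), (),
              threshold=8, leak=7, s_plus=4, s_minus=0),
)

#: Plastic layers and their incoming plastic connection names, used by
#: training for renormalization ("all incoming connections for a certain
#: layer are renormalized simultaneously", per postsynaptic neuron across
#: every plastic input of that layer).
PLASTIC_LAYERS: dict[str, tuple[str, ...]] = {
    "S2-shape-ex": ("C1-ver-max->S2-shape-ex", "C1-hor-max->S2-shape-ex"),
    "S2-where-ex": ("S1-inst->S2-where-ex", "S1-del->S2-where-ex"),
    "CLA-shape": ("S2-shape-ex->CLA-shape",),
    "CLA-where": ("S2-where-ex->CLA-where",),
    "Attention": ("S2-shape-ex->Attention",),
}


@dataclass(frozen=True)
class ConnectionSpec:
    """Declarative description of one projection; built by :func:`build_network`."""

    source: str
    target: str
    wiring: str                      # see build_network for the vocabulary
    plastic: bool = False
    supervised: bool = False
    delay: int = 1
    multiplier: Optional[int] = None  # per-connection synapse-value override
    test_only: bool = False           # feedback engaged only after learning
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plastic and self.wiring != "random_plastic":
            raise ValueError("plastic connections use random_plastic wiring")
        if self.supervised and not self.plastic:
            raise ValueError("supervised implies plastic")


# -- wiring builders -------------------------------------------------------

def wire_topographic(src_grid, dst_grid, rf, stride) -> np.ndarray:
    """Binary adjacency where each destination covers one rf-window.

    Windows are placed at ``stride`` steps over the source grid; the window
    count must equal the destination grid exactly.
    """
    sr, sc = src_grid
    dr, dc = dst_grid
    rr, rc = rf
    tr, tc = stride
    nr = (sr - rr) // tr + 1
    nc = (sc - rc) // tc + 1
    if (nr, nc) != (dr, dc) or (sr - rr) % tr or (sc - rc) % tc:
        raise ValueError(
            f"rf {rf} / stride {stride} tile {src_grid} into {(nr, nc)}, "
            f"but destination grid is {dst_grid}"
        )
    W = np.zeros((sr * sc, dr * dc))
    for i in range(dr):
        for j in range(dc):
            rows = np.arange(i * tr, i * tr + rr)
            cols = np.arange(j * tc, j * tc + rc)
            src = (rows[:, None] * sc + cols[None, :]).ravel()
            W[src, i * dc + j] = 1.0
    return W


def wire_random(n_src: int, n_dst: int, rng: np.random.Generator) -> np.ndarray:
    """Dense i.i.d. uniform [0, 1) weights (plastic initialization)."""
    return rng.random((n_src, n_dst))


def _wire_identity(n: int) -> np.ndarray:
    return np.eye(n)


def _wire_all_minus_self(n: int) -> np.ndarray:
    return np.ones((n, n)) - np.eye(n)


def _wire_neighborhood(grid, radius: int = 1, exclude_center: bool = True) -> np.ndarray:
    """Each source cell projects to grid cells within Chebyshev ``radius``."""
    r, c = grid
    n = r * c
    W = np.zeros((n, n))
    for i in range(r):
        for j in range(c):
            src = i * c + j
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if exclude_center and di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < r and 0 <= jj < c:
                        W[src, ii * c + jj] = 1.0
    return W


def _wire_pool_rows(src_grid, n_dst: int, row_map=None) -> np.ndarray:
    """Source row (pool) ``r`` projects onto destination cell ``row_map[r]``."""
    rows, cols = src_grid
    if n_dst != rows and row_map is None:
        raise ValueError("need one destination cell per source pool")
    W = np.zeros((rows * cols, n_dst))
    for r in range(rows):
        dst = r if row_map is None else row_map[r]
        W[r * cols:(r + 1) * cols, dst] = 1.0
    return W


def _wire_rows_broadcast(n_src: int, n_dst: int, src_cells, ) -> np.ndarray:
    """Selected source cells project to every destination cell."""
    W = np.zeros((n_src, n_dst))
    for s in src_cells:
        W[s, :] = 1.0
    return W


def _wire_cols_subset(n_src: int, n_dst: int, dst_cells) -> np.ndarray:
    """Every source cell projects to the selected destination cells."""
    W = np.zeros((n_src, n_dst))
    for d in dst_cells:
        W[:, d] = 1.0
    return W


def _wire_permutation(n: int, mapping: dict[int, int]) -> np.ndarray:
    W = np.zeros((n, n))
    for s, d in mapping.items():
        W[s, d] = 1.0
    return W


# Letter pools in CLA-shape / Shape-inh / Shape-decision order: T, L, J.
_LETTER_INDEX = {"T": 0, "L": 1, "J": 2}

# The default connection plan.  Hard-wired circuits are black wires of the
# architecture diagram; plastic ones are learned (supervised=True for the
# value-gated green wires).  The two multiplier overrides use the spare
# per-neuron synapse-value slot of the hardware: the motion input to
# Attention is deliberately sub-threshold (4 <= T=5) so attention needs a
# coincident learned shape input to fire, and Shape-decision drives Motor
# at 8 so that one Shape-decision spike plus one Target/Obstacle spike
# (8 + 4 > T=8) forms the motor coincidence detector.
DEFAULT_CONNECTIONS: tuple[ConnectionSpec, ...] = (
    # shape stream
    ConnectionSpec("Retina", "S1-ver", "topographic",
                   params=dict(rf=(1, 2), stride=(1, 2))),
    ConnectionSpec("Retina", "S1-hor", "topographic",
                   params=dict(rf=(2, 1), stride=(2, 1))),
    ConnectionSpec("S1-ver", "C1-ver-ex", "identity"),
    ConnectionSpec("S1-hor", "C1-hor-ex", "identity"),
    ConnectionSpec("C1-ver-ex", "C1-ver-inh", "identity"),
    ConnectionSpec("C1-hor-ex", "C1-hor-inh", "identity"),
    # localized inhibitory surround: suppresses neighbouring edge
    # responses (dense accidental clusters, i.e. noise) while leaving the
    # letters' deliberately non-adjacent features untouched
    ConnectionSpec("C1-ver-inh", "C1-ver-ex", "neighborhood",
                   params=dict(radius=1, exclude_center=True)),
    ConnectionSpec("C1-hor-inh", "C1-hor-ex", "neighborhood",
                   params=dict(radius=1, exclude_center=True)),
    ConnectionSpec("C1-ver-ex", "C1-ver-max", "topographic",
                   params=dict(rf=(2, 1), stride=(2, 1))),
    ConnectionSpec("C1-hor-ex", "C1-hor-max", "topographic",
                   params=dict(rf=(1, 2), stride=(1, 2))),
    ConnectionSpec("C1-ver-max", "S2-shape-ex", "random_plastic", plastic=True),
    ConnectionSpec("C1-hor-max", "S2-shape-ex", "random_plastic", plastic=True),
    ConnectionSpec("S2-shape-ex", "S2-shape-inh", "identity"),
    ConnectionSpec("S2-shape-inh", "S2-shape-ex", "all_minus_self"),
    ConnectionSpec("S2-shape-ex", "CLA-shape", "random_plastic",
                   plastic=True, supervised=True),
    # motion stream
    ConnectionSpec("Retina", "S1-inst", "topographic",
                   params=dict(rf=(4, 4), stride=(2, 2))),
    ConnectionSpec("Retina", "S1-del", "topographic", delay=1 + MOTION_DELAY,
                   params=dict(rf=(4, 4), stride=(2, 2))),
    ConnectionSpec("S1-inst", "S2-where-ex", "random_plastic", plastic=True),
    ConnectionSpec("S1-del", "S2-where-ex", "random_plastic", plastic=True),
    ConnectionSpec("S2-where-ex", "S2-where-inh", "identity"),
    ConnectionSpec("S2-where-inh", "S2-where-ex", "all_minus_self"),
    ConnectionSpec("S2-where-ex", "CLA-where", "random_plastic",
                   plastic=True, supervised=True),
    # attention
    ConnectionSpec("S2-shape-ex", "Attention", "random_plastic",
                   plastic=True, supervised=True),
    ConnectionSpec("S2-where-ex", "Attention", "identity", multiplier=4),
    # the top-down feedback engages only after learning has completed; during
    # training only the lateral competition among attention neurons is active
    ConnectionSpec("Attention", "S2-where-ex", "all_minus_self", test_only=True),
    ConnectionSpec("Attention", "CLA-shape", "cols_subset", test_only=True,
                   params=dict(dst_cells=tuple(range(10, 30)))),  # L and J pools
    ConnectionSpec("Attention", "Attention", "all_minus_self"),
    # decision
    # classifier pools feed the decision integrators through the spare
    # synapse-value slot at gain 2: one full pool volley then crosses the
    # integrator thresholds within a couple of ticks, while partial
    # (noise-driven) volleys still decay away under the leak
    ConnectionSpec("CLA-where", "Target", "pool_rows", multiplier=2),
    ConnectionSpec("CLA-where", "Obstacle", "pool_rows", multiplier=2),
    ConnectionSpec("CLA-shape", "Shape-inh", "pool_rows"),
    ConnectionSpec("CLA-shape", "Shape-decision", "pool_rows", multiplier=2),
    ConnectionSpec("Shape-inh", "Target", "rows_broadcast",
                   params=dict(src_cells=(1, 2))),   # L and J veto catching
    ConnectionSpec("Shape-inh", "Obstacle", "rows_broadcast",
                   params=dict(src_cells=(0, 2))),   # T and J veto avoiding
    ConnectionSpec("Target", "Motor", "identity"),
    ConnectionSpec("Obstacle", "Motor", "permutation",
                   params=dict(mapping=OPPOSITE_TRAJECTORY)),
    ConnectionSpec("Shape-decision", "Motor", "all_to_all", multiplier=8),
)


def build_network(groups=DEFAULT_GROUPS, connections=DEFAULT_CONNECTIONS,
                  rng_seed=0) -> Network:
    """Instantiate and wire the whole network.

    Hard-wired circuits get binary weights; plastic connections are
    initialized i.i.d. uniform in [0, 1), reproducibly from ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    by_name = {g.name: g for g in groups}
    for g in groups:
        for t in g.targets:
            if t not in by_name:
                raise ValueError(f"{g.name} targets unknown group {t!r}")

    net = Network(retina_name="Retina")
    for g in groups:
        net.add_group(g.name, g.grid, g.neuron_params())

    for cs in connections:
        src, dst = by_name[cs.source], by_name[cs.target]
        if cs.wiring == "topographic":
            W = wire_topographic(src.grid, dst.grid, **cs.params)
        elif cs.wiring == "identity":
            if src.size != dst.size:
                raise ValueError(f"identity wiring needs equal sizes "
                                 f"({cs.source}: {src.size}, {cs.target}: {dst.size})")
            W = _wire_identity(src.size)
        elif cs.wiring == "all_minus_self":
            W = _wire_all_minus_self(src.size)
        elif cs.wiring == "neighborhood":
            W = _wire_neighborhood(src.grid, **cs.params)
        elif cs.wiring == "random_plastic":
            W = wire_random(src.size, dst.size, rng)
        elif cs.wiring == "pool_rows":
            W = _wire_pool_rows(src.grid, dst.size, **cs.params)
        elif cs.wiring == "rows_broadcast":
            W = _wire_rows_broadcast(src.size, dst.size, **cs.params)
        elif cs.wiring == "cols_subset":
            W = _wire_cols_subset(src.size, dst.size, **cs.params)
        elif cs.wiring == "permutation":
            W = _wire_permutation(src.size, **cs.params)
        elif cs.wiring == "all_to_all":
            W = np.ones((src.size, dst.size))
        else:
            raise ValueError(f"unknown wiring kind {cs.wiring!r}")
        net.connect(Connection(cs.source, cs.target, W, plastic=cs.plastic,
                               supervised=cs.supervised, delay=cs.delay,
                               multiplier=cs.multiplier, test_only=cs.test_only))
    net.finalize()
    return net


def total_neurons(groups=DEFAULT_GROUPS) -> int:
    return sum(g.size for g in groups)


def sever_attention(net: Network) -> Network:
    """Zero all outgoing connections of the Attention group (idempotent)."""
    for c in net.connections:
        if c.source == "Attention":
            c.weights = np.zeros_like(c.weights)
    return net


# -- hardware compatibility ------------------------------------------------

@dataclass
class HardwareCheck:
    check: str
    subject: str
    passed: bool
    detail: str = ""


@dataclass
class HardwareReport:
    """Pass/fail audit of the network against the neuromorphic core limits."""

    checks: list[HardwareCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[HardwareCheck]:
        return [c for c in self.checks if not c.passed]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([c.__dict__ for c in self.checks])


def validate_hardware(net: Network) -> HardwareReport:
    """Audit parameter ranges, axon types and synapse binarity.

    The binarity check covers the synapses exercised at test time, i.e.
    every connection not involving a train-only group; it fails (by
    design) on a network that has not been consolidated yet.
    """
    rep = HardwareReport()
    axon_types = set()
    for name, p in net.params.items():
        axon_types.add(p.axon_type)
        rep.checks.append(HardwareCheck(
            "threshold_range", name,
            THRESHOLD_RANGE[0] <= p.threshold <= THRESHOLD_RANGE[1],
            f"T={p.threshold}"))
        rep.checks.append(HardwareCheck(
            "leak_range", name,
            LEAK_RANGE[0] <= p.leak <= LEAK_RANGE[1], f"L={p.leak}"))
        rep.checks.append(HardwareCheck(
            "multiplier_range", name,
            MULTIPLIER_RANGE[0] <= p.s_plus <= MULTIPLIER_RANGE[1]
            and MULTIPLIER_RANGE[0] <= p.s_minus <= MULTIPLIER_RANGE[1],
            f"S+={p.s_plus}, S-={p.s_minus}"))
    rep.checks.append(HardwareCheck(
        "axon_types", "network", axon_types <= {EXCITATORY, INHIBITORY},
        f"types used: {sorted(axon_types)}"))
    for c in net.connections:
        if c.multiplier is not None:
            rep.checks.append(HardwareCheck(
                "multiplier_range", c.name,
                MULTIPLIER_RANGE[0] <= c.multiplier <= MULTIPLIER_RANGE[1],
                f"override={c.multiplier}"))
        src_p = net.params.get(c.source)
        tgt_p = net.params.get(c.target)
        train_only = (src_p is not None and src_p.train_only) or \
                     (tgt_p is not None and tgt_p.train_only)
        if train_only:
            continue
        binary = bool(np.isin(c.weights, (0.0, 1.0)).all())
        rep.checks.append(HardwareCheck(
            "synapse_binarity", c.name, binary,
            "weights in {0,1}" if binary else "real-valued weights present"))
    rep.checks.append(HardwareCheck(
        "reset_to_zero", "network", True, "engine resets fired membranes to 0"))
    return rep
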