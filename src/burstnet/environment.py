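"""Synthetic visual world: moving letter glyphs on a 10x10 binary retina.

A stimulus is a letter glyph (T, L or J) that appears fully visible in one
of the four corners of the retina, moves in the lateral or vertical
direction (1 pixel every ``speed`` ticks, default 10), and finally exits
the field on the opposite side.  Eight (corner, direction) combinations
exist; each is also the arrival placement of exactly one trajectory, which
is how the catcher's eight motor positions are indexed.  Per-pixel flip
noise is redrawn independently on every tick.

Task semantics: T is a target (the catcher must be placed at its arrival
placement), L is an avoidance object (the catcher must go to the placement
diagonally opposite its arrival), and J is a distractor that should elicit
no motor response at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GLYPHS",
    "TRAJECTORIES",
    "OPPOSITE_TRAJECTORY",
    "Glyph",
    "Trajectory",
    "StimulusTrial",
    "CatcherGoal",
    "render_frame",
    "inject_noise",
    "make_trial",
    "make_training_trial",
    "expected_response",
    "SINGLE_OBJECT_MIX",
    "TWO_OBJECT_MIX",
    "TARGET_AVOID_MIX",
]

RETINA_SHAPE = (10, 10)
LETTERS = ("T", "L", "J")

# 4x4 letter bitmaps, selected by exhaustive search of the 4x4 bitmap
# space against the constraints the architecture's fixed neuron constants
# impose on a stimulus:
#
# * aligned visibility -- the motion-stream presence detectors (threshold
#   27, multiplier 4) fire only when >= 7 pixels fall inside one of their
#   stride-2 4x4 windows; each glyph carries 7-8 pixels and registers
#   exactly when it is aligned with a window (every second movement step,
#   which is why the delayed motion pathway spans two movement periods)
#   and never in between;
# * sparse, non-adjacent edge features -- the shape stream reads aligned
#   2-pixel edge windows; each letter activates 3 pooled edge features at
#   a time (enough to drive the learned shape cells, few enough that
#   their winner-take-all competition can rank candidates), placed so
#   that no two feature cells are neighbours in the same orientation map:
#   the localized inhibitory surround then never interrupts a clean
#   letter's volleys and acts purely as a noise filter;
# * distinctness -- any two letters share at most one pooled feature at a
#   matched position.
#
# The serif-style strokes are what those constraints leave of the
# letterforms.  Replaceable through ``StimulusTrial.glyphs``.
_T = np.array([[1, 0, 0, 1],
               [0, 1, 1, 1],
               [0, 1, 0, 0],
               [0, 1, 0, 0]], dtype=bool)
_L = np.array([[1, 1, 0, 0],
               [0, 1, 0, 0],
               [0, 1, 0, 0],
               [1, 0, 1, 1]], dtype=bool)
_J = np.array([[1, 1, 0, 1],
               [0, 0, 0, 1],
               [0, 0, 0, 1],
               [1, 1, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class Glyph:
    letter: str
    bitmap: np.ndarray

    @property
    def size(self) -> tuple[int, int]:
        return self.bitmap.shape


GLYPHS: dict[str, Glyph] = {
    "T": Glyph("T", _T),
    "L": Glyph("L", _L),
    "J": Glyph("J", _J),
}


@dataclass(frozen=True)
class Trajectory:
    """One of the eight (start corner, direction) stimulus paths."""

    index: int
    start_corner: str  # UL, UR, LL, LR
    direction: str     # lateral | vertical
    step: tuple[int, int]  # (drow, dcol) per move

    def start_anchor(self, glyph_rows: int, glyph_cols: int,
                     field=RETINA_SHAPE) -> tuple[int, int]:
        row = 0 if self.start_corner[0] == "U" else field[0] - glyph_rows
        col = 0 if self.start_corner[1] == "L" else field[1] - glyph_cols
        return row, col

    @property
    def arrival_corner(self) -> str:
        v, h = self.start_corner
        if self.direction == "lateral":
            h = "R" if h == "L" else "L"
        else:
            v = "L" if v == "U" else "U"
        return v + h


def _build_trajectories() -> tuple[Trajectory, ...]:
    out = []
    idx = 0
    for corner in ("UL", "UR", "LL", "LR"):
        for direction in ("lateral", "vertical"):
            if direction == "lateral":
                step = (0, 1) if corner[1] == "L" else (0, -1)
            else:
                step = (1, 0) if corner[0] == "U" else (-1, 0)
            out.append(Trajectory(idx, corner, direction, step))
            idx += 1
    return tuple(out)


TRAJECTORIES: tuple[Trajectory, ...] = _build_trajectories()

#: Placement index diagonally opposite each trajectory's arrival placement
#: (same orientation, diagonal corner) -- where the catcher goes for an
#: avoidance object.  Equals the trajectory starting at the diagonal corner
#: with the same direction.
OPPOSITE_TRAJECTORY: dict[int, int] = {}
for _traj in TRAJECTORIES:
    _diag = {"U": "L", "L": "U"}[_traj.start_corner[0]] + \
            {"L": "R", "R": "L"}[_traj.start_corner[1]]
    for _other in TRAJECTORIES:
        if _other.start_corner == _diag and _other.direction == _traj.direction:
            OPPOSITE_TRAJECTORY[_traj.index] = _other.index


@dataclass(frozen=True)
class CatcherGoal:
    """Expected final motor placement; ``None`` for distractor-only trials."""

    expected_motor_index: Optional[int]


@dataclass
class StimulusTrial:
    """1-2 moving objects plus a noise level; unrolls to binary frames."""

    objects: list[tuple[str, int]]  # (letter, trajectory index)
    noise_p: float = 0.0
    speed: int = 10  # ticks per 1-pixel move
    glyphs: dict[str, Glyph] = field(default_factory=lambda: GLYPHS)

    def __post_init__(self) -> None:
        if not (1 <= len(self.objects) <= 2):
            raise ValueError("a trial carries 1 or 2 objects")
        if not (0.0 <= self.noise_p <= 1.0):
            raise ValueError("noise probability outside [0, 1]")

    @property
    def duration(self) -> int:
        """Ticks until every object has fully exited the retina."""
        return RETINA_SHAPE[0] * self.speed

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(letter for letter, _ in self.objects)


def render_frame(trial: StimulusTrial, t: int) -> np.ndarray:
    """Noiseless binary frame at tick ``t`` (objects OR-ed, clipped)."""
    if t < 0:
        raise ValueError("tick must be non-negative")
    frame = np.zeros(RETINA_SHAPE, dtype=bool)
    moves = t // trial.speed
    for letter, traj_idx in trial.objects:
        glyph = trial.glyphs[letter]
        traj = TRAJECTORIES[traj_idx]
        g_r, g_c = glyph.size
        r0, c0 = traj.start_anchor(g_r, g_c)
        r = r0 + traj.step[0] * moves
        c = c0 + traj.step[1] * moves
        rows = slice(max(r, 0), min(r + g_r, RETINA_SHAPE[0]))
        cols = slice(max(c, 0), min(c + g_c, RETINA_SHAPE[1]))
        if rows.start >= rows.stop or cols.start >= cols.stop:
            continue
        sub = glyph.bitmap[rows.start - r: rows.stop - r,
                           cols.start - c: cols.stop - c]
        frame[rows, cols] |= sub
    return frame


def inject_noise(frame: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each pixel independently with probability ``p``."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("noise probability outside [0, 1]")
    if p == 0.0:
        return frame.copy()
    flips = rng.random(frame.shape) < p
    return frame ^ flips


# Object mixes: mapping from a tuple of letters to its probability.
SINGLE_OBJECT_MIX = {("T",): 1 / 3, ("L",): 1 / 3, ("J",): 1 / 3}
TARGET_AVOID_MIX = {("T",): 0.5, ("L",): 0.5}
TWO_OBJECT_MIX = {("T",): 0.25, ("L",): 0.25, ("T", "L"): 0.5}


def make_trial(rng: np.random.Generator, object_mix: dict, noise_p: float = 0.0,
               speed: int = 10) -> StimulusTrial:
    """Draw letters per ``object_mix`` and trajectories uniformly at random."""
    combos = list(object_mix.keys())
    probs = np.array([object_mix[c] for c in combos], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("mix probabilities must sum to 1")
    choice = combos[rng.choice(len(combos), p=probs)]
    objects = [(letter, int(rng.integers(len(TRAJECTORIES)))) for letter in choice]
    return StimulusTrial(objects=objects, noise_p=noise_p, speed=speed)


def make_training_trial(rng: np.random.Generator, speed: int = 10) -> StimulusTrial:
    """Single random letter on a random trajectory, no noise."""
    trial = make_trial(rng, SINGLE_OBJECT_MIX, noise_p=0.0, speed=speed)
    return trial


def expected_response(trial: StimulusTrial) -> CatcherGoal:
    """Catcher goal: catch T if present, else avoid L, else nothing (J)."""
    by_letter = dict((letter, traj) for letter, traj in trial.objects)
    if "T" in by_letter:
        return CatcherGoal(by_letter["T"])
    if "L" in by_letter:
        return CatcherGoal(OPPOSITE_TRAJECTORY[by_letter["L"]])
    return CatcherGoal(None)
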