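"""The synthetic visual world: letters, trajectories, noise, catcher goals.

Renders a letter T traversing the top edge of the 10x10 retina, shows the
effect of 8% pixel-flip noise, and prints the expected catcher placement
for each kind of trial.
"""
import numpy as np

from burstnet.environment import (
    GLYPHS,
    TRAJECTORIES,
    StimulusTrial,
    expected_response,
    inject_noise,
    render_frame,
)


def show(frame):
    print("\n".join("".join("#" if v else "." for v in row) for row in frame))


print("letter bitmaps (stylized single-pixel strokes):")
for letter, glyph in GLYPHS.items():
    print(f"\n{letter}:")
    show(glyph.bitmap)

trial = StimulusTrial([("T", 0)])  # upper-left corner, moving right
print(f"\nT on trajectory 0 ({TRAJECTORIES[0].start_corner} "
      f"{TRAJECTORIES[0].direction}); frames at ticks 0, 30, 60:")
for t in (0, 30, 60):
    print(f"\ntick {t}:")
    show(render_frame(trial, t))

rng = np.random.default_rng(0)
noisy = inject_noise(render_frame(trial, 30), 0.08, rng)
print("\nthe same tick-30 frame with 8% per-pixel flip noise:")
show(noisy)
print(f"({int((noisy ^ render_frame(trial, 30)).sum())} pixels flipped; "
      "on average 8 of 100 flip at this level)")

print("\nexpected catcher placements:")
for objects in ([("T", 0)], [("L", 0)], [("J", 0)], [("T", 2), ("L", 5)]):
    goal = expected_response(StimulusTrial(objects)).expected_motor_index
    label = "+".join(f"{l}@{tr}" for l, tr in objects)
    where = ("none (distractor: stay put)" if goal is None else
             f"placement {goal} ({TRAJECTORIES[goal].arrival_corner} "
             f"{TRAJECTORIES[goal].direction})")
    print(f"  {label:12s} -> {where}")
print("\nT is caught at its own arrival; L is avoided at the diagonally "
      "opposite placement; J should elicit no motor response.")
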