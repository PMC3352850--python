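"""Noise tolerance of the motion-direction readout.

Trains the default network (full-length protocol; takes a minute or two),
then classifies the movement direction of 40 random letters per noise
level as pixel-flip noise rises, printing the Correct / Incorrect /
No-Decision fractions.
"""
import numpy as np

import burstnet as bn
from burstnet.evaluation import noise_sweep

print("training the default network...")
net = bn.train_default_network(seed=0)

sweep = noise_sweep(net, "motion_only", [0.0, 0.05, 0.1, 0.2, 0.33], 40,
                    np.random.default_rng(99))
print("\nper-pixel  correct  incorrect  no-decision")
for lvl, c, i, nd in zip(sweep.levels, sweep.correct, sweep.incorrect,
                         sweep.no_decision):
    print(f"  {lvl:5.0%}    {c:6.2f}    {i:6.2f}     {nd:6.2f}")
print("\nEach trial's decision is the trajectory pool with the most spikes")
print("integrated over the traversal; noise is redrawn independently every")
print("millisecond tick, so the integration window does the filtering.")
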