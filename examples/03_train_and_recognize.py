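"""Train the network and watch it classify moving letters.

Runs a shortened version of the staged protocol (a 120-presentation
unsupervised phase, then 240 value-gated presentations -- the shipped
default uses 400 and 800), consolidates to binary synapses, and prints
the classifier pools' votes for a few test presentations.
"""
import numpy as np

import burstnet as bn
from burstnet.environment import StimulusTrial, TRAJECTORIES
from burstnet.evaluation import run_trial
from burstnet.training import TrainingSchedule, pool_sums, train_protocol

schedule = TrainingSchedule(presentations_per_epoch=120)
net = bn.build_network(rng_seed=0)
rng = np.random.default_rng(10_000)
print("training (unsupervised feature phase, then value-gated phase)...")
train_protocol(net, rng, unsupervised_epochs=1, supervised_epochs=2,
               schedule=schedule)
print(f"consolidated; hardware report passed: {net.hardware_report.passed}\n")

rng = np.random.default_rng(7)
hits = 0
rows = []
for i in range(12):
    letter = "TLJ"[i % 3]
    traj = int(rng.integers(8))
    res = run_trial(net, StimulusTrial([(letter, traj)]))
    sums = pool_sums(res.cla_shape_counts, 3)
    guess = "TLJ"[sums.argmax()] if sums.max() > 0 else "?"
    hits += guess == letter
    rows.append(f"  {letter} moving {TRAJECTORIES[traj].start_corner}-"
                f"{TRAJECTORIES[traj].direction:8s} pools T/L/J = "
                f"{sums.tolist()} -> {guess}")
print("letter-classifier pool votes (spikes summed over each trial):")
print("\n".join(rows))
print(f"\n{hits}/12 correct.  Each pool's vote counts the spikes of its 10")
print("neurons; the winning pool is the network's letter classification.")
print("(The shipped full-length protocol is more accurate; see README.)")
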