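"""Single-neuron dynamics: integration, linear leak, reset, one-cycle delay.

Builds a three-stage chain (retina pixel -> relay A -> relay B) and steps
it tick by tick, printing who spikes when.  The spike raster shows the
hardware contract: a spike emitted at tick t reaches its target at t+1,
a firing membrane resets to exactly 0, and with no input the membrane
drains linearly to its floor at 0.
"""
import numpy as np

from burstnet.lif import Connection, Network, NeuronGroupParams, membrane_step

# one relay neuron: threshold 1, no leak, strong input multiplier
relay = NeuronGroupParams(threshold=1, leak=0, s_plus=8, s_minus=0)

net = Network(retina_name="R")
net.add_group("R", (1, 1), None)
net.add_group("A", (1, 1), relay)
net.add_group("B", (1, 1), relay)
net.connect(Connection("R", "A", np.eye(1)))
net.connect(Connection("A", "B", np.eye(1)))
net.finalize()

print("tick | pixel  A  B")
for t, pixel in enumerate([1, 0, 0, 0, 1, 0, 0], start=1):
    fired = net.tick(np.full((1, 1), pixel))
    print(f"{t:4d} |   {pixel}    {int(fired['A'][0])}  {int(fired['B'][0])}")
print("\nEach stage lags its input by exactly one tick (the one-cycle "
      "propagation delay of the neurosynaptic core).")

# the leak is linear (a constant decrement), not proportional
p = NeuronGroupParams(threshold=100, leak=8, s_plus=1, s_minus=0)
M = 30.0
trace = [M]
while M > 0:
    M, _ = membrane_step(M, 0.0, 0.0, p)
    trace.append(float(M))
print(f"\nmembrane decay from 30 with leak 8: {trace}")
print("A fixed amount per tick, clamped at 0 -- not an exponential decay.")
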