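"""A single region's intrinsic rhythm.

One node of the model is a three-population oscillator: the excitatory
population excites itself and both inhibitory populations; subtractive
inhibition raises the excitatory threshold while divisive inhibition
scales down its gain.  With the default parameters this produces a
sustained beta-band oscillation.
"""

import numpy as np

import neuromass as nm

# a 1-region "network": no external connections at all
conn = nm.Connectome(S=np.zeros((1, 1)), L=np.zeros((1, 1)),
                     W=np.zeros((1, 1)), D=np.zeros((1, 1)))
params = nm.PopulationParams()

res = nm.simulate(conn, params, nm.EngineConfig(t_end=1000.0, initial_state=0.1),
                  snapshot_interval=1.0)
E = np.array(res.series.E).ravel()

tail = E[-400:]  # last 400 ms, transient discarded
centered = tail - tail.mean()
cycles = int(np.sum((centered[:-1] < 0) & (centered[1:] >= 0)))
print(f"E range over the last 400 ms : [{tail.min():.3f}, {tail.max():.3f}]")
print(f"oscillation frequency        : {cycles / 0.4:.1f} Hz")
print(f"refractory ceiling k_e       : {params.k_e:.4f}")
# The activity stays inside (0, k_e): the refractory constant caps the
# fraction of the population that can fire, and the rhythm arises from the
# delayed push-pull between excitation and the two kinds of inhibition.
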