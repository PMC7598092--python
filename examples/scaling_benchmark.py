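"""Cost scaling with network size.

The coupling term dominates: every region sums over its afferent
connections at each of the four solver stages, so the work per step grows
quadratically with the region count.  The benchmark counts the actual
multiply-adds (deterministic, hardware-independent) and reports wall time
only as a side note.
"""

import neuromass as nm
from neuromass.bench import scaling_exponent

df = nm.benchmark_scaling(
    sizes=[25, 50, 100, 200],
    p=1.0,                 # full connectivity: n(n-1) terms per evaluation
    plasticity_on=False,
    biological_time=20.0,  # ms; the counts per step are what matters
    seed=0,
)
print(df[["n", "edges_expected", "rhs_evals", "coupling_macs"]].to_string(index=False))
print(f"\nlog-log slope of coupling multiply-adds vs n: "
      f"{scaling_exponent(df, 'coupling_macs'):.3f}  (quadratic = 2)")
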