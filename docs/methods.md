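# Methods

## Model

Each brain region is a neural mass: three coupled firing-rate variables
`E`, `Is`, `Id` (excitatory, subtractive-inhibitory, divisive-inhibitory),
dimensionless in [0, k_j). Subtractive inhibition shifts the population
input–output function toward higher inputs; divisive inhibition divides its
gain, lowering both the midpoint slope (`a_j/(1+a)/4`) and the supremum
`k_j(a) = σ(a_j θ_j/(1+a))`, where σ is the logistic function. The
constant-offset term in `F_j` makes `F_j(0,0,a) = 0`, so the origin is an
equilibrium in the absence of external drive — a property the test suite
asserts exactly.

The refractory constants `k_e`, `k_i` are evaluated once at parameter
construction with zero divisive modulation and then treated as constants of
the dynamics. Because the defining formula does depend on the divisive
input, the alternative reading is kept available behind the
`dynamic_k` flag (recompute `k_e` from the instantaneous `w₃·Id` at every
evaluation); the static variant is the default and the validated one.

Inter-region coupling enters only the excitatory equation, as
`Σ_j W_ij E_j(t − del_ij)`: row *i* of `W` lists region *i*'s afferents.
`W` is directed. Tractography gives symmetric streamline counts, but
plasticity breaks the symmetry immediately, so each ordered pair is an
independent connection throughout.

### Parameters

The model's sources specify the structural constants (weight scale 0.1,
propagation speed 7 m/s, step 1 ms, chunk and plasticity cadence 10 steps,
snapshot interval 50 s, connection probability 0.2) but not the node-level
constants. The package defaults are therefore its own calibration, chosen
so that a single isolated node shows sustained bounded oscillation rather
than a fixed point:

| parameter | default | meaning |
|---|---|---|
| τ_e, τ_i | 5 ms, 10 ms | population response timescales |
| a_e = a_i | 1 | sigmoid gain |
| θ_e = θ_i | 4 | sigmoid threshold |
| w₁…w₇ | 16, 10, 1, 8, 2, 0.5, 0.5 | E→E, Is⊣E, Id⊣E, E→Is, E→Id, Is⊣Id, Id⊣Id |
| P_e, P_s, P_d | 1.0, 0.5, 0.5 | external drives |
| c | 0.01 | Hebbian learning rate |

With these values a single node oscillates at ≈22.5 Hz with amplitude
E ∈ [0.03, 0.44] (see `examples/single_node_oscillation.py`); weaker
recurrent weights (e.g. w₁ ≈ 2) put the node in a stable-focus regime that
decays to a low-activity fixed point, which was verified numerically during
calibration. All defaults are overridable per run.

## Synthetic connectome

The generator emulates DTI-derived matrices: each directed pair (i, j) is
connected with probability p (default 0.2, the approximate fraction of
inter-region connections present in the brain; n defaults to 82 regions).
Connected pairs draw a streamline count from `1 + Geometric(1/49)`
(minimum 2, mean 50) — a right-skewed integer law whose log-weights
`0.1·ln S` span ≈0.07–0.6, the range typical of log-scaled tractography
weights — and a fiber length uniform in 20–150 mm, giving delays of
2.9–21.4 ms at 7 m/s. What the generator does **not** emulate: spatial
embedding (no distance-dependent connection probability), hemispheric or
modular structure, symmetric streamline counts, or heavy-tailed hub degree
distributions. Tests passing on this family therefore demonstrate the
correctness of the numerics and the plasticity bookkeeping, not the
biological realism of any particular connectome; imaging-derived matrices
can be supplied as CSV/TSV files.

The expected edge count of the family is `7n + p·n(n−1)` (seven internal
connections per region plus the expected directed external connections).

## Numerics

**Stepper.** Bogacki–Shampine explicit Runge–Kutta (2,3): four stages,
third-order solution, embedded second-order estimate, first-same-as-last.
The step is fixed at 1 ms — the temporal resolution the model is specified
at — so the error estimate is logged (warning above 1e-3) but never
controls the step. Measured global-error convergence order on a smooth
problem is ≈3.1.

**Delayed lookups.** Node states and derivatives are kept in a circular
buffer; delayed values are interpolated with piecewise cubic Hermite
polynomials (the continuous extension matching the pair's order), exact at
stored nodes and exact on cubic solutions. Delays are used at full floating
precision, not rounded to step multiples. Pre-history (t ≤ 0) is the
constant initial state. Delays shorter than one step would need
extrapolation inside the current step; they are clamped up to one step with
a logged warning. The buffer holds `max(10, ⌈max delay/step⌉ + 4)` entries
— the historical 10-step ring, automatically enlarged because conduction
delays at 7 m/s routinely exceed 10 ms. Memory is therefore O(capacity),
independent of simulated duration.

**Chunking.** The stepper runs in chunks of 10 steps; at chunk boundaries
plasticity fires (when the global step index is a multiple of
`update_every`) and snapshots are recorded. With plasticity off, chunked
and monolithic full-history integration agree to ≈1e-16 (asserted < 1e-9
against an independent naive reference integrator).

**Weight updates and the FSAL stage.** Weights are piecewise constant
between plasticity updates. After an update the cached first stage and the
newest buffered derivative are recomputed with the new weights: the state
is continuous across the boundary but the right-limit derivative belongs to
the new weight configuration, and the dense output of the following
interval should reflect it. This refresh is counted as plasticity work in
the instrumentation, keeping solver-stage counts identical between
plasticity-on and plasticity-off runs.

**Exact coupling contract.** The vectorised coupling drive accumulates
column by column, so each region's afferent sum is performed in exactly the
per-element loop order; the vectorised and scalar forms agree bit for bit
(and Fortran-ordered storage, used for speed in the engine, provably does
not change a bit). This makes the production path and the testable contract
the same code.

**Precision.** Double precision throughout; the weight increments
(c·E·ΔE ≈ 1e-6 per update at the defaults) are far below single-precision
resolution of O(1) weights, which rules out a single-precision variant.

**Divergence.** Any |activity| above 1e6 (or a non-finite stage) aborts the
run with a timestamped error after flushing pending snapshots.

## Plasticity

The external rule `ΔW_ij = c · E_j(t − del_ij) · (E_i(t) − E_i(t − step))`
uses the presynaptic activity *as it arrives* (conduction-delayed) and the
postsynaptic change over the last solver step, both read from the history
buffer. Design choices where the formulation was genuinely open:

- **Index convention.** The coupling term fixes row = target; the rule is
  applied with pre = delayed source `E_j`, post = target `E_i`, and
  normalization runs over each row (a region's incoming weights), matching
  synaptic-scaling biology.
- **Non-negativity** by clipping at zero: excitatory inter-region weights
  cannot change sign. A clipped-to-zero connection joins the "never
  update zero weights" set; with the default learning rate this does not
  occur, and the sparsity pattern is invariant in all tested regimes.
- **c = 0 is a strict no-op** — no update *and* no normalization — so a
  zero-learning-rate run is bitwise identical to a plasticity-off run. The
  first active update normalizes incoming sums to 1; thereafter
  normalization is idempotent.
- **Internal rule** uses the wiring table (w₁: E→E, w₂: Is→E, w₃: Id→E,
  w₄: E→Is, w₅: E→Id, w₆: Is→Id, w₇: Id→Id) with the same pre/post form.
  The plastic subset of each node's internal weights is renormalized to
  conserve its pre-update *sum* (per-node conservation, not per-population
  — the simplest scheme that keeps total internal drive fixed).
- **Oja's rule** (`ΔW = c·post·(pre − post·W)`) is included as a rule
  plugin for external weights only; it is exercised by a smoke test but
  not validated against a reference.

## Recording

Snapshots (activities, external weight matrix, internal weights, run
metadata including config hash and seed) are taken at multiples of the
snapshot interval, always including t = 0, either in memory or streamed to
HDF5 with one group per snapshot. Dataset timestamps are disabled so
deterministic runs produce byte-identical files; the snapshot count
attribute is rewritten after every append, so truncated or partial files
are detected on read and reported with the last valid snapshot. CSV export
produces one long-format activity table plus per-snapshot weight matrices.

## Benchmarking

Wall time depends on hardware, so the scaling harness reports deterministic
operation counters: solver-stage evaluations, coupling multiply-adds (one
per existing afferent connection per stage evaluation), and plasticity
update counts. At full connectivity the coupling count per evaluation is
exactly n(n−1); the measured log–log slope of total coupling work versus n
is ≈2.0, the O(n²) regime that dominates large networks. Task-share
profiles are expressed as counter shares for the same reason.

## Problem sizes used in validation

The test suite and the acceptance script use desk-scale versions of the
study conditions: the chunked-vs-monolithic comparison runs 3 regions for
1000 steps (the naive full-history oracle is O(steps²) in lookups); the
plasticity reference comparison 3 regions for 100 steps; the scaling
measurement n ∈ {50, 100, 200} at 20 ms each (counts per step, not
duration, carry the signal); and the end-to-end determinism check the full
82-region network for 100 s of biological time, executed twice. Longer
horizons change none of the asserted properties: memory is bounded by the
ring buffer and the snapshot count, and the integrator state advances
identically chunk by chunk.

## Known limitations

- Fixed-step integration only; no adaptive step or event location.
- No spatial structure within regions (single mass per region) and no
  structural plasticity (connections are never created or deleted beyond
  clipping).
- The plasticity cadence must align with chunk boundaries (updates fire at
  chunk boundaries whose step index is a multiple of `update_every`; the
  defaults, 10 and 10, align).
- Single-threaded core; parallelism is offered across runs (subjects), not
  within one network.
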