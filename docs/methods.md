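# Methods

## Model

The dynamical core is a four-level logical model on a signed directed
network. Node levels are qualitative severities/activations 0–3. Each edge
`(j → i)` has a perception threshold `τ ∈ {1,2,3}` — the minimum source
level at which the target perceives the interaction — and an integer weight
`w ≥ 1`. The perceived input of node `i` is the signed weighted sum over
perceived in-edges; the node moves one level toward the sign of that sum per
iteration (gradual ±1 kinetics; the model never jumps levels). Ties
(`s = 0`) hold the current level by default; a `decay` option steps toward
baseline instead, modeling passive relaxation. The exogenous stressor has no
regulators and keeps its level unless clamped by an exposure schedule.

Assumptions worth stating explicitly:

* **Synchronous default.** All nodes update simultaneously, making the
  update a deterministic total function; dynamical predecessors are then
  well defined, which the snapshot-consistency constraint and the
  persistence test rely on. An asynchronous scheme (one uniformly chosen
  non-quiescent node per step, seeded) is provided for fidelity to the
  classical formalism but is excluded from the constraint machinery.
* **Additive arbitration.** Conflicts among perceived regulators are
  resolved purely by the weighted sum; context specificity enters through
  the fitted per-edge thresholds and weights, not through extra logic rules.
* **Weight domain {1, 2} by default** — the smallest domain that can express
  "one regulator outweighs another"; configurable.
* Because every threshold is ≥ 1, the all-zero state is a fixed point of
  *every* program under either tie rule. This anchors the idealized control
  when all behavioral constructs are severity-polarity.

## Profiles and departures

Instrument totals are range-normalized into four equal-width bins,
`level = min(3, ⌊4·(raw − min)/(max − min)⌋)`, with configurable per-
instrument bounds. Constructs scored as *function* (higher = better) are
reversed at ingest (`3 − level`) so the model operates uniformly on
severity; the reversal is an involution and never enters the engine. Model
fit is the Manhattan distance between predicted and observed levels on the
observed constructs, normalized by the maximum misalignment (3 per
construct, per subject): 9 constructs give a per-subject denominator of 27
and a 6-subject group denominator of 162.

## The constraint satisfaction fit

Unknowns: one `(τ, w)` pair per edge, plus the full state of every subject
and of the idealized control. Constraints:

* the control's behavioral targets extend to an **exact fixed point** (a
  stable resting state); its imputed molecular levels are the minimum-total-
  activation completion (ties broken lexicographically), which makes the
  control reference deterministic;
* each subject's full state satisfies the configured consistency mode. The
  default, `has_predecessor`, demands the state be reachable in one step
  from some predecessor — the weakest reading under which a cross-sectional
  snapshot is dynamically admissible without being stable. `fixed_point`
  (used by the persistence test) demands self-reproduction;
  `on_attractor_path` is vacuous under synchronous update and retained only
  for the asynchronous scheme.

The objective is the aggregate normalized departure. Subjects decouple once
the program is fixed, so the search is a branch-and-bound over programs with
per-subject optimizations inside.

Search strategies, chosen automatically by problem size:

* **Exhaustive** over all programs when the space is below a cap (default
  100 000); used by the verification tests, it returns the exact optimum,
  the full set of tied optimal programs and the count of feasible programs.
* **Backtracking with propagation.** Only parameters of edges feeding
  *observed* nodes can change the departure. Under predecessor consistency
  the per-subject optimum is computed exactly by variable elimination:
  for each observed node, a cost table over its local predecessor levels is
  built per parameter combo, private variables are minimized out, and the
  residual tables over the (small) shared-variable space are summed and
  minimized. The program search branches over per-node parameter combos,
  best-first, pruned by admissible per-node and suffix lower bounds; the
  departure budget escalates 0, 1, 2, … so the first feasible budget is the
  optimum. When the shared space or a combo table would be unmanageable the
  search falls back to a grouped depth-first search with exact per-subject
  branch-and-bound, and beyond that to local search.
* **Local search** (full-scale networks): seeded first-improvement hill
  climbing over the departure-relevant edge parameters with random restarts;
  per-subject imputation above ~16 coupled variables uses coordinate descent
  (an upper bound on the true optimum). Local-search results are therefore
  heuristic: feasibility claims are "found/not found", not proofs, and the
  fixed-point completion search is bounded by an expansion budget at >20
  nodes. All stochastic steps derive from the configured seed.

Degenerate optima are expected (hidden nodes are weakly constrained by a
single cross-section). All tied optimal imputations are retained up to a cap
(default 1000) per subject — pooled across up to 10 tied optimal programs,
since the degeneracy class spans programs — and summarized by the per-node
modal level with its agreement fraction; downstream statistics use the modal
state.

## Persistence test

Rerunning the fit with `fixed_point` consistency and a departure budget of 0
asks whether *any* program in the domain lets every subject's observations
extend to a self-reproducing state while the control also rests. Exhaustive
mode makes infeasibility a proof over the configured domain. A practical
observation: mid-level (1–2) observations with forced non-zero drive from
fully perceived (level-3) regulators are what typically make persistence
infeasible; all-low or all-saturated profiles are easy to stabilize.

## Group statistics

Per molecular marker, the subjects' imputed levels are compared to the
control's imputed level by a two-sided one-sample t-test (`scipy`), with
Benjamini–Hochberg step-up correction across markers
(`statsmodels multipletests(method="fdr_bh")`) at q = 0.05. Four-level data
with n = 6 make zero-variance samples likely; the degenerate cases are
explicit: all values equal to the reference → t = 0, p = 1; a unanimous
shift → p set to 0 with a `degenerate` flag and a warning, since the
statistic is undefined but the direction is systematic. Significant rows are
labeled up/down by the sign of mean − control.

## Synthetic study bundles

The generator emulates the shape of the motivating study so every stage is
testable with known ground truth:

* **Network**: molecular + behavioral nodes are placed on one random
  Hamiltonian cycle (guaranteeing the no-source/no-sink closure by
  construction rather than by rejection, which would be hopeless at 273
  edges), one stressor with out-edges only, and uniformly random extra edges
  to the target count. The full-scale preset (29 + 9 + 1 nodes, 273 edges)
  has density 273/1482 ≈ 18.4% by construction. Inhibitor fraction defaults
  to 0.3 (a modeling choice; exposed in config). Stressor
  out-edges are always activating — an exogenous insult that only inhibits
  already-resting targets would produce no response at all.
* **Evidence counts**: a discretized lognormal (median 9, σ = 1.6 on the log
  scale, floored at 1), giving visible mass at a single citation and a tail
  beyond 125 — the qualitative support profile of large text-mined networks.
* **Subjects**: the network rests at the control fixed point (all severity
  constructs; the all-zero anchor above guarantees validity for any planted
  program), the stressor is clamped at level 3 for 4 steps and released, and
  each subject is a snapshot at a uniformly drawn time in a window (default
  steps 2–8, inside or shortly after the transient). Observation noise, when
  enabled, is post-hoc ±1 level jitter on the behavioral slice only — the
  planted dynamics stay exact. Defaults for the recovery experiments: 10
  nodes (6 molecular, 3 behavioral, stressor), 16 edges (≈18% density,
  matching the full-scale density at small scale), 6 subjects, noiseless.

What the generator does **not** emulate: the real 273-edge topology, real
instrument score distributions, inter-subject heterogeneity in exposure
(all subjects share one trajectory and differ only in snapshot time), and
measurement error beyond single-level jitter. Passing the recovery suite
therefore shows the machinery is correct and well calibrated on in-model
data, not that the biological conclusions of any particular study transfer.

## Verification experiments

* Engine and predecessor sets: exact agreement with a naive dict-based
  oracle on 500 random (network ≤ 6 nodes, program, state) triples.
* Fitter: identical optimal departure, optimal-program set and
  feasible-program count versus full enumeration over programs ×
  completions on 50 random toys (≤ 5 edges, ≤ 4 hidden nodes, τ ∈ {1,2},
  w ∈ {1,2}).
* Recovery: on 20 noiseless planted bundles the fit reaches departure 0
  (guaranteed: the planted program is in the search space) and the planted
  hidden level is covered by the retained optimal imputations on ≥ 90% of
  hidden node-subject pairs. Coverage (rather than modal equality) is the
  right recovery notion here because the optimum class is genuinely
  degenerate under snapshot data; modal agreement is reported alongside and
  is much lower (~35%), quantifying that degeneracy.
* Persistence discrimination: bundles whose snapshots sit on a planted
  point attractor are always feasible (the planted program witnesses it);
  transient snapshots whose attractor differs on observed nodes are
  infeasible in roughly 60% of random instances — and the verdict matches
  full enumeration exactly — while the remainder admit a different
  stabilizing program. Discrimination, not a universal verdict, is the
  tested property.
* FDR: under the global null the mean flagged fraction stays below q = 0.05
  (95% CI over 200 simulated studies).

Problem sizes throughout (10-node bundles, 5-node persistence instances,
50 toys) were chosen so each verification runs in seconds to a couple of
minutes on one CPU while keeping the enumeration oracles exact.

## Known limitations

* The update scheme, tie behavior, weight domain and per-edge (versus
  per-source) thresholds are modeling choices; results should be read as
  conditional on them. Sensitivity can be probed by re-running with the
  `decay` tie rule, wider `w_domain`, or the asynchronous engine.
* `feasible_count` semantics differ by mode: exact census in exhaustive
  mode; number of optima found (capped) under backtracking; absent under
  local search.
* Persistence infeasibility is a proof only in exhaustive mode and only
  over the configured (τ, w) domain.
* SIF export drops citation counts (format limitation); the edge-CSV round
  trip is lossless.
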