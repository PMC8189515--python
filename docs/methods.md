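# Methods

## Model

The contagion is a dosage-threshold process with three states per node
(S susceptible, I adopter, R rejector; R absorbing) on an undirected
multilayer graph whose nodes carry a 1-based layer index (layer 1 =
staff). Time advances in micro-steps; an epoch is N micro-steps.

Per micro-step:

1. A listener is drawn uniformly from all N nodes (a Poisson-style
   activation scheme: R nodes keep listening and speaking; they simply
   confer zero doses).
2. A speaker is drawn uniformly from the listener's neighbors, pooled
   over all layers. A listener with no neighbors receives a zero dose
   and the step proceeds — the memory still advances and the removal
   check still applies.
3. The dose is 0 if the speaker is not in I. Otherwise it is drawn from
   N(dose_mean, dose_sd) truncated at 0 — unless the hierarchy override
   is active and the speaker's layer exceeds the listener's, in which
   case the dose equals the listener's own threshold d\*.
4. The dose is appended to the listener's length-T ring buffer (oldest
   evicted) and D = sum of the buffer is recomputed from the buffer
   each step (T is small; this avoids accumulating float error in a
   running sum).
5. If the listener is S and D ≥ d\*, it becomes I. Else if it is I and
   D < d\*, it becomes R with probability r. The two conditions are
   exhaustive and exclusive.

**Switch condition D ≥ d\* (not strict >).** The override dose equals
the listener's threshold while seed memories start zero-filled, so a
guaranteed immediate switch — the defining property of the override —
requires the inclusive comparison. The removal condition stays strict
(D < d\*), keeping the pair exhaustive.

**Truncation by resampling.** Thresholds are N(1, 0.5) redrawn until
strictly positive (realized mean ≈ 1.028, sd ≈ 0.483 — the tests check
against the exact truncated-normal moments); doses are redrawn until
non-negative. Resampling preserves the distribution shape where
clipping would put point mass at the bound.

**Dose scale.** The dose parameters are fixed at 0.5 and 0.25 of the
*nominal* threshold mean 1.0, not of the realized (truncated) mean.
This keeps the dose distribution identical across realizations; the
baseline reproductions below are only consistent with this reading.

**Memory window.** Exactly the last T = 5 doses are summed. A T+1-dose
window is numerically excluded by the baseline reproductions (it
roughly triples the single-seed peak).

### Parameters

| name | default | units | meaning |
|---|---|---|---|
| `T` | 5 | interactions | memory window length |
| `r` | 0.2 | probability/activation | removal rate, chosen as 1/T |
| `threshold_mean`, `threshold_sd` | 1.0, 0.5 | dose units | d\* distribution (truncated > 0) |
| `dose_mean`, `dose_sd` | 0.5, 0.25 | dose units | infected-speaker dose (truncated ≥ 0) |
| `manager_override` | True | – | False = flat-network ablation |
| `si_mode` | False | – | True forces r = 0 (SI consensus process) |
| `max_micro_steps` | 10⁶ | steps | ≈ 1000 epochs at N = 1000 |

With r > 0 the only absorbing macro-state is I = 0, except in degenerate
parameterizations (e.g. zero-variance doses above every threshold, where
an all-I configuration can no longer lose members — the exact-chain test
exercises this corner). The engine stops when the configuration is
frozen (I = 0, or S = 0 with r = 0); because frozen trajectories are
exactly constant, runs with `early_stop_on_extinction=False` are
extended analytically to the step budget rather than simulated.

### Random numbers and paired comparisons

Each run derives six independent child streams from
`SeedSequence(master_seed)`: seeding, thresholds, listener, speaker,
dose, removal. Exactly one variate per stream is consumed every
micro-step whether or not it is used (doses are pre-sampled truncated
normals), so two graphs on the same node set simulated from the same
master seed receive identical thresholds and identical attempted
transmission pathways. All paired contrasts (hierarchical vs flat,
removal-rate grids, manager-topology cells) reuse one list of master
seeds; `run_ensemble` rejects duplicate master seeds because they would
silently break this pairing.

The numba kernel and the pure-Python step function implement the same
update and are asserted trajectory-identical in the tests; the Python
path additionally records per-transition event logs.

## Synthetic hierarchies

The staff layer is a random geometric graph: n points uniform on the
unit square, edge iff Euclidean distance ≤ r = sqrt(k/(nπ)) (inclusive
boundary, no wraparound). The nominal k overstates the realized mean
degree because discs are clipped at the square's boundary; exactly,
E[deg] = (n−1)(πr² − 8r³/3 + r⁴/2) ≈ 18.65 at k = 20, n = 1000. The
radius formula, not the realized degree, is the specification, so the
generator keeps it and the tests assert the boundary-corrected value.
Disconnected draws (rare at k = 20) are regenerated with successive
seeds.

The base layer is partitioned into c = round(0.06 n) fluid communities
(networkx `asyn_fluidc`; connectivity required; mean community size is
exactly n/c). One layer-2 manager per community connects down to every
member; manager–manager wiring is one of: isolated (none), full
(complete), Erdős–Rényi(p), RGG (same radius formula with n = c), or
Barabási–Albert with attachment m = round(k/2) (note BA on c = 60 nodes
with m = 10 realizes ⟨k⟩ ≈ 16.7, the standard finite-size shortfall).

**System-size convention.** In the synthetic construction the staff
count N is the system-size constant: the manager layer (0.06 N nodes)
rides on top of it. Seed budgets quoted as 0.015 N therefore mean
round(0.015 · N_staff) = 15 nodes at N = 1000, and peak-adoption
fractions for the hierarchy are normalized by N_staff (a peak of 583
adopters among 1060 nodes counts as 0.583). Both conventions were
cross-checked against the published comparison grid: the staff-size
normalization matches every cell to within ~0.01, the total-size one
leaves a systematic 6% deficit. Empirical-network experiments use the
total node count (there the published N = 1942 includes all layers).

## Empirical networks and fixtures

`org_io` reads node lists (`node_id,level`) and edge lists
(`source,target[,weight]`) as CSV; undirected, deduplicated; edges with
endpoints missing from the node list are errors. Weighted co-working
records are thresholded with a strict rule (weight > threshold, e.g.
"more than 370 hours"), and `threshold_for_target_degree` scans the
unique weights for the cutoff that best matches a requested mean degree.
Layer statistics (mean closeness, degree, local clustering, per layer
and total) are computed on the full multilayer graph — per-layer
subgraphs of an administrative hierarchy are disconnected, which would
make closeness ill-defined; on disconnected inputs the component-size
normalized closeness is used and flagged.

Because the original organizational edge lists cannot be redistributed,
two programmatic fixtures emulate their topologies:

* **Line-Org style**: department cliques (sizes 2 + Poisson around the
  requested mean) on the base layer; one manager per department; sibling
  managers under a common parent form cliques; a single apex. Every
  non-apex node has exactly one upward edge (tree property).
* **Project style**: the same manager tree, but intra-layer edges from
  per-layer Erdős–Rényi models whose target mean degree grows as
  hub_skew^(min(layer,3)−1), scaled so the whole-graph mean degree hits
  `k_avg`. This reproduces the qualitative signature of a co-working
  network — degree concentrated in the lower management layers, low
  staff clustering — not any particular organization's microstructure.
  Tiny upper layers are capped at complete (n−1) degree, so their mean
  degree need not keep increasing.

What fixture-based tests show: that the *contrast* between a modular
administrative topology (clustering ≈ 0.98) and a centralized co-working
topology (clustering ≈ 0.04) has the expected effect on spreading
(the centralized network's best seeding configuration beats the modular
network's best). They do not validate numbers tied to the specific
empirical networks; the CSV readers accept those files wherever they are
available.

## Seed selection

Strategies: uniform random within a level; highest total degree;
VoteRank order (networkx implementation; an independent brute-force
reimplementation of the voting iteration serves as the test oracle);
onion-decomposition layer (iterative minimum-degree peeling, a
refinement of the k-core number). Rankings are computed on the full
multilayer graph and filtered to the requested level afterwards —
inter-layer edges are precisely what make managers influential, so
ranking within induced subgraphs would discard the signal. `level="all"`
drops the filter. Ties break by higher degree then lower node id, so
deterministic strategies are reproducible without randomness; if
VoteRank elects fewer nodes than requested on a level, the degree
ranking fills the remainder.

## Ensembles, pools and problem sizes

Replicates select seeds afresh per run (seeding stream) and are
aggregated into means, standard errors and per-epoch mean trajectories;
post-freeze tails are padded exactly before averaging. Survival curves
average the per-run normalized curve I(t)/I_max over all replicates,
alive or extinct (unconditional averaging).

Synthetic ensembles regenerate the network over a pool of independent
draws (default 25, round-robin assignment of replicates), so reported
means average over graph realizations as well as dynamical noise.
Reproduction runs in `scripts/acceptance.py` use 2000/1000 replicates
for the two baseline cells and 800/400 for minimal/community-seeded
hierarchy cells: single-seed peak distributions are heavy-tailed (most
runs die at the seed; a few spread widely), so minimal-seed cells need
more replicates for a stable mean. These sizes put Monte-Carlo standard
errors in the 0.001–0.005 range, well inside the ~±0.02 reproduction
band, at a few minutes of single-core runtime.

## Known limitations

* The dosage memory is a strict sliding window; no decay kernels,
  re-susceptibility, S→R transitions, or edge-weighted doses.
* The Project-style fixture is a statistical emulation; degree
  *distributions* within layers are binomial, not the heavy-tailed
  empirical ones.
* Closeness on Table-style statistics assumes the full multilayer graph;
  no per-layer-subgraph variant is exposed.
* VoteRank is computed globally; a per-layer variant is not implemented.
* Manager RGG wiring reuses the unit-square radius formula at n = c,
  where boundary clipping is substantial (realized ⟨k⟩ ≈ 14.5 at a
  nominal 20 for c = 60); this mirrors the construction it emulates.
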