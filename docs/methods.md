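# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `boolpath`. It states no empirical result that the test
suite does not itself compute.

## Boolean model of a pathway

A prior-knowledge network (PKN) is a directed graph over gene symbols
with edge signs +1 (activation) or −1 (inhibition). Preparation
normalizes gene names (uppercase, stripped), drops self-loops (under
synchronous OR-of-AND dynamics a self-loop admits degenerate
self-sustaining rules), and collapses duplicate edges keeping the
first-seen sign.

Each node with in-degree ≥ 1 carries a rule in OR-of-AND form over its
regulators; an inhibiting regulator enters clauses negated. The rule
space for k regulators is every nonempty set of nonempty AND-clauses:
2^(2^k−1)−1 rules (1, 7, 127 for k = 1, 2, 3). Clause sets are stored
as given — no absorption-law reduction — so this count is exact and rule
identity is clause-set identity. Logically equivalent rules with
different clause sets are deliberately distinct: the ERS size semantics
count syntactic candidates.

**In-degree truncation.** Nodes with more than 3 network regulators
keep the 3 whose binarized profiles have the highest absolute Pearson
correlation with the target's binarized profile across all
(layer, sample) states where both are measured; ties break
alphabetically, and regulators with no measurement overlap score 0.

**Dynamics.** All nodes update simultaneously (synchronous scheme);
in-degree-0 nodes hold their state and act as inputs. A trajectory is
deterministic and enters a fixed point or limit cycle within 2^n steps.
Steady-state node values are *attractor averages*, computed exactly by
cycle detection (iterate until a state repeats, average over the cycle)
rather than by a fixed simulation horizon; at a fixed point this is the
point itself. The windowed `steady_state(trajectory, window)` variant
(defaults: 100 steps, window 20) is provided for trajectory-level use;
its value equals the attractor average whenever the window spans whole
periods, which is why internal fitness and scoring use the exact
cycle-average route.

## Data model and binarization

Each omics layer is a genes × samples matrix of nonnegative log-scale
abundances. On load, rows whose median raw value is 0 are discarded;
`log2p1` applies log2(x+1) and `log2rpm` applies log2(RPM+1) — the
pseudocount keeps zero counts finite and the matrix nonnegative, a
deliberate deviation from plain log2(RPM) which is undefined at 0.

Binarization thresholds each gene per layer at the midpoint of its
observed (min, max); values strictly above threshold are 1. The
midpoint is invariant to additive shifts of a gene's values, fitting
log-scale data; constant genes fall to 0. A per-gene median threshold
would be the natural alternative; midpoint was chosen because with
well-separated condition means it lands between the classes regardless
of replicate imbalance.

Fold-changes are differences of condition means on the log scale.
Variability is the coefficient of variation (sample sd, n−1, divided by
mean) over the union of the contrast's samples, 0 for constant,
zero-mean, or unmeasured genes. CV rather than plain sd is used because
the permutation null resamples (FC, CV) pairs.

## Rule inference

**Objective.** For each (layer, sample) binarized state, the model is
initialized at that state (genes unmeasured in the layer start at 0),
run to its attractor, and a node's error is |attractor average −
observed bit|, averaged over the states in which the node was measured.
Unmeasured observations are never fabricated and never scored
(mask-aware fitness). Layers are integrated by concatenating their
(layer, sample) states as independent constraints.

**Genetic algorithm.** Generational GA over rule assignments
(one index per rule-bearing node): tournament selection (size 3),
uniform per-node crossover (probability 0.6 per mating, 0.5 per node),
mutation resampling one random node's rule (probability 0.3 per
offspring), 1 elite, population 24, 50 generations, fully seeded.
Elitism makes best fitness non-increasing; the search stops early at
fitness 0. These are pathway-scale defaults chosen so a 10–30-node
pathway converges in seconds; all are in `GAConfig`.

**Local search and the ERS.** Around the GA incumbent, each node's full
rule space (≤ 127) is evaluated exhaustively with all other nodes held
at their incumbent rules; the node's equivalent rule set is every rule
achieving its minimal error, with ties exact to 12 decimals so |ERS| is
reproducible across platforms. The incumbent is refined to the first
minimal-error rule in enumeration order (deterministic). Holding other
nodes fixed makes the search node-local and deterministic; co-optimizing
neighbourhoods was rejected as it makes |ERS| depend on search order.

## Perturbation scoring

**Importance.** I_g = mean over sampled rule assignments (default 10
uniform per-node draws from the ERSs, seeded) of
Σ_{states} Σ_{j≠g} |O_j − Z_j|, where O and Z are attractor averages
with g clamped to 0 / 1 throughout the simulation (clamping applies
from t = 0 and overrides the rule). The perturbed node is excluded from
the sum so I_g measures influence *on the rest of the network*; a sink
node scores exactly 0. Including the node itself would add a constant
offset per state and blur that reading.

**Modulation.** M_g = I_g · E_g · Σ_d |FC_{C,d,g}| · CV_{d,g}, with
E_g the number of layers measuring the gene. Absolute fold-change makes
up- and down-regulation both count; unmeasured layers contribute 0. The
combination is isolated in `node_modulation` so an alternative weighting
is a one-function change. M_p sums M_g over pathway nodes.

**Permutation null.** Each of 1000 replicates keeps the pathway's true
I_g and E_g and redraws, per gene and layer, a (|FC|, CV) pair uniformly
with replacement from the pool of all genes measured in that layer
(same contrast). Pairs are drawn jointly to preserve the empirical
FC–CV dependence. z = (M_p − null mean)/null sd; p = 1 − Φ(z),
one-sided upper tail. A point-mass null (sd below 1e−12 relative) falls
back to p = 0.5 at the null value, else 0/1 by sign — the relative
tolerance matters because a degenerate pool still leaves float jitter
of order 1e−16 in the replicate sums. BH adjustment is applied per
contrast across pathways (via statsmodels).

This null is *competitive*: it asks whether the pathway's genes carry
more fold-change-weighted signal than a random draw from the dataset.
It assumes (FC, CV) pairs are exchangeable across genes independently of
the importance weights. Two consequences worth knowing:

- a dataset containing only the pathway's own genes couples the
  observed score to its own pool and under-disperses z — pools should
  span a dataset much larger than any one pathway, which is how the
  tool is meant to be run;
- systematic correlation between importance and expression level (CV on
  the log scale falls with the mean) biases z; residual over-dispersion
  of order 10–15% from pathway-composition fluctuation persists even in
  well-behaved synthetic nulls and shrinks with pathway size. The
  calibration test therefore runs at KEGG-like pathway size (20 nodes).

## Synthetic worlds

The generator emulates the intended setting: a signed network with
known OR-of-AND rules, observed through D omics layers under matched
conditions. Conditions are induced by clamping the input nodes
(in-degree 0), the way stimuli enter signaling PKNs; each condition's
attractor average a ∈ [0,1] maps to a mean log2 abundance 4 + 4a (so
the binarization midpoint separates the extremes), observed with
additive Gaussian noise (default sd 0.5, a typical replicate spread on
the log2 scale) and floored at 0. Default 3 replicates per condition
(the usual LC–MS design size). Per-layer gene dropout emulates the
partial overlap of real omics layers. `generate_pathway_collection`
builds many disjoint pathways sharing one sample set — the realistic
regime for the permutation pool. Null worlds give both conditions one
*random* shared input pattern; the all-off pattern was rejected because
it parks every high-importance input node at the high-CV low state,
which no real null comparison would do.

Not emulated: mass-spectrometry intensity error models, peptide-level
structure, batch effects, library-size variation, inter-gene
correlation beyond the network dynamics. A green test on these fixtures
establishes algorithmic correctness — rule-space combinatorics, oracle
equivalence, recovery, calibration machinery — not robustness to real
measurement artifacts.

**Identifiability of recovery fixtures.** "True rule ∈ ERS" is only a
statement about the algorithm when the observations encode the truth.
Two generator outcomes break that: limit-cycle attractors (a fractional
cycle average binarizes to an arbitrary bit) and genes constant at the
high state in every condition (midpoint thresholding sends constant
genes to 0). `generate_recovery_world` resamples network and rules
jointly until all condition attractors are binary fixed points and no
gene is constant-high, making the noiseless dataset binarize back to
the truth exactly. On unconditioned worlds, recovery necessarily drops —
that is data loss at the binarization step, not search failure.

## Numerical and degenerate-input conventions

- Attractor detection is exact (state-repeat), not horizon-based;
  `max_steps` defaults to 2^n + 1 and is never hit in practice.
- ERS ties: error equality after rounding to 12 decimals.
- CV guards: zero mean → 0; single sample → 0 (sd undefined).
- Empty resampling pool (a layer with no measured genes) is an error.
- Importance seeds, GA seeds and permutation seeds are all fanned out
  from one global seed by CRC32 of a stage:pathway label, kept < 2^31,
  so every stage is independently reproducible.
- Graphml sign vocabulary: attribute `signal` or `interaction` with
  {a, activation, +} / {i, inhibition, −}; unknown values warn and
  default to activation. KGML: activation/expression → +1,
  inhibition/repression → −1; group entries expand to members; compound
  entries collapse to direct gene–gene edges with multiplied signs (an
  interpretation choice — KGML does not define gene-level semantics for
  compound-mediated links).

## Known limitations

- Binarization discards within-condition dose information; graded
  responses are invisible to the fitted rules.
- The permutation null's exchangeability assumption is approximate
  (see above); p-values are best read comparatively across pathways.
- Rule spaces stop at in-degree 3; denser regulation is truncated by
  correlation, which can discard true regulators when profiles are
  collinear.
- The synchronous update scheme is a modeling choice; asynchronous
  attractors can differ.
- No alias/identifier resolution: inputs are assumed pre-mapped to a
  single gene-symbol namespace.
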