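# Methods

This note records the model this package implements, the numerical and design
choices made where the formalism leaves room, and what the test networks do
and do not establish.

## Model and assumptions

A network is a finite set of units, each with a finite alphabet (≥ 2 states),
a current joint state, and a complete interventional transition probability
function p(ū | do(u)). Units are assumed conditionally independent given the
preceding joint state, so the joint TPM is the product of per-unit tables;
the factored form is the primary in-memory representation, and every
downstream quantity (conditioning, repertoires, partitioned probabilities) is
computed on single-unit factors and recombined by product. This both matches
the independence assumption and keeps all marginalizations exact.

State spaces are enumerated little-endian (unit 0 varies fastest). This
ordering is fixed across memory, JSON/YAML, and TSV formats so that
serialized tables round-trip bit-exactly.

Binary networks can be specified as logistic (noisy threshold) units: unit i
turns ON with probability 1/(1+exp(−k Σⱼ w_{j,i} u_j)) with u_j ∈ {−1, +1},
incoming weights summing to 1 per unit, and slope k > 0 controlling
determinism. The −1/+1 alphabet maps to state indices 0/1; case-coded labels
(`Abcdef` = first unit ON) are the display convention. The core analysis is
alphabet-agnostic; only the logistic builder is binary-specific.

## Conditioning on the background

For a candidate system S, the units W = U∖S are background conditions:

* effect side: the background is clamped at its current state, `p_e(s̄|s) =
  p(s̄|s, w)`;
* cause side: each unit factor is a mixture over prior background states w̄
  weighted by the posterior probability of w̄ given the current universe
  state under a uniform prior over prior universe states.

A current state with zero probability under every prior state makes the
cause mixture undefined; this is raised as an error rather than silently
renormalized, because the analysis of causes of an impossible state has no
interpretation. Note that near-deterministic logistic networks can make a
state *numerically* unreachable (probabilities underflow to 0); the error
message names the state.

## Intrinsic information and tie handling

Intrinsic information is selectivity × informativeness with log base 2
("ibits") throughout; `0·log(·)` is defined as 0. Non-maximal states may have
negative ii; the maximum is ≥ 0 and equals 0 exactly when the constrained
repertoire is at chance, in which case the side selects no state and the
system is flagged powerless.

States tied for maximal ii (within tolerance) are resolved by the larger φ
on that side — each tied state is scored at its side's own
normalized-minimum partition — then by the smallest state index. The same
two-stage rule (φ first, deterministic encoding second) applies to purview
states. Ties are resolved identically on every run; no randomness exists
anywhere in the pipeline.

## Partition searches

System partitions divide S into k ≥ 2 parts with a direction label per part
(inputs, outputs, or both severed); the induced severed-connection set
{(target, source)} fully determines the partitioned TPM, so distinct
labelings with identical cut-sets are deduplicated before scoring (a pure
optimization: a property test confirms the deduplicated search selects the
same φ_s as scoring every labeling). The normalization used during the MIP
search is the closed form Σᵢ|S⁽ⁱ⁾||X⁽ⁱ⁾|, which equals the cut-pair count.
Ties on the normalized value select the largest unnormalized φ_s, then the
lowest lexicographic part encoding. A single-unit system gets the one
complete cut: its own input noised (normalization 1); this is what lets an
isolated self-looping unit count as a minimal complex.

Mechanism–purview pairs use disintegrating partitions: joint partitions of
(M, Z) into ≥ 2 parts with empty sub-parts allowed and no part pairing the
whole mechanism with a non-empty purview part. The normalizer is the number
of mechanism→purview unit pairs the partition severs, |M||Z| − Σᵢ|M⁽ⁱ⁾||Z⁽ⁱ⁾|,
mirroring the system-level pairwise-connection count; it is ≥ 1 for every
valid partition.

**Exact zero shortcut.** Before enumerating disintegrations, the search
checks whether a valid partition exists that severs no *actual* dependency
(dependencies are read numerically off the factored TPM: does the factor of
unit v vary along unit u's axis?). If the dependency graph over M ⊔ Z lets
the elements be grouped into ≥ 2 blocks with every dependency inside a block
(and no block pairing all of M with purview units), the partitioned product
equals the intact product exactly, so φ = 0 at normalized value 0 — a
guaranteed minimum. The shortcut is one-directional (it never declares a
positive φ) and is property-tested against the full enumeration. It makes
reducible mechanism–purview pairs — the overwhelming majority in sparse
networks — essentially free, which is what keeps a 6-unit unfold in seconds
without any approximate search.

Two numerical conventions: probability comparisons use absolute tolerance
1e-10 (configurable); log-ratios below that tolerance are treated as exactly
0, so a partition that changes nothing yields φ = 0.0, not 1e-16. The
positive-part operator clamps partitions that *increase* the selected
state's probability.

## Distinctions, congruence, relations

A mechanism's maximal purview on each side is the φ-argmax over all
non-empty Z ⊆ S (ties: larger purview, then lexicographic). A mechanism
whose maximal ii over a purview is 0 specifies no state there and gets φ = 0
for that purview; a mechanism whose state is impossible under every prior
purview state is causeless (φ_c = 0), not an error. Distinctions require
φ_d = min(φ_c, φ_e) > 0 *and* congruence: purview states must be sub-states
of the system's maximal cause/effect states, compared as (unit, state)
tuples.

Relations are computed over (unit, state) tuple sets, so congruence is
built into every intersection and union. Faces are counted per *selection*
(cause, effect, or both, per distinction — up to 3^|d|), because identical
purview substates chosen from different distinctions still bind them; a
single distinction admits only the {cause, effect} self-relation face.
φ_r distributes each distinction's φ_d uniformly over its unique purview
units and scales the weakest such density by the joint purview size, so
φ_r ≤ min φ_d always. Subset enumeration is pruned by downward closure
(restricting a face to fewer distinctions keeps its intersection non-empty);
the pruned and exhaustive enumerations are property-tested equal. A
configurable cap (default 20 distinctions) guards the exponential subset
space.

Φ is the plain sum Σφ_d + Σφ_r over the assembled structure; it is stored
alongside the per-component ledger so serialized structures can be re-summed
exactly. Φ-folds are sub-structures: a distinction plus the relations bound
to it, or the union of such folds over a unit subset.

## Complexes and condensation

The first complex is the φ_s-argmax over all non-empty subsets (everything
else as background); condensation repeats the scan on the remaining units,
with extracted units still serving as background conditions. Because the
background of a candidate is always the rest of the universe at its current
state, subset scores are cached across rounds. Ties: mutually disjoint tied
candidates are extracted simultaneously; if tied candidates overlap, the
next φ level with a unique (or disjoint) candidate is used; residual
ambiguity prefers the larger system, then lexicographic order. The subset
scan is capped at 8 units by default (it is O(2ⁿ) subsets × partition
enumeration) with an explicit error beyond.

## Test networks: what they show and what they do not

The fixture families reproduce architecture classes: the directed copy
cycle, a deterministic feed-forward counter (exact truth tables, driven by a
frozen background input unit), disconnected copy pairs, weakly chained
modules, a degenerate hub (bottleneck), a seed-fixed specialized lattice,
random column-normalized logistic networks, and random DAG-topology networks
(roots fall back on self-loops so every unit's incoming weights sum to 1).
Only the cycle and the feed-forward family carry literature-reported values;
the lattice, bottleneck, modular, and excitatory/inhibitory fixtures are
qualitative stand-ins whose exact connection weights are this package's own
choices, and no published φ values are asserted for them.

The counter fixture deserves one caveat: with its internal units restricted
to edges A→B and A→C (plus self-loops), the internal dynamics under a held
input advance through a 4-state cycle, not an 8-state one — a 3-unit system
whose next state depends only on (A, input) cannot visit 8 states. The
fixture preserves the properties that matter for the analysis (deterministic,
functionally driven, not strongly connected, hence φ_s = 0 and no multi-unit
complex).

All benchmark computations run on ≤ 6-unit networks; property suites use
2–5 unit random networks with fixed seed grids (e.g. 100 seeds for the
conditioning and repertoire oracles, 100 for the MIP-search equivalence, 50
random DAGs for reducibility). These sizes exercise every code path
exhaustively (the searches are exact), but say nothing about the *tractable*
scale of larger systems: the subset scan, partition enumerations, and
relation lattice are all exponential, which is intrinsic to the method, not
to this implementation.

## Known limitations

* No macro-unit grain search: candidates are unit subsets at the given
  grain only.
* No approximate or heuristic MIP search; the package is for exact analysis
  of small systems (≤ ~8 units).
* Analytic relation-count formulas are not implemented; relations are
  enumerated (with pruning) up to the distinction cap.
* "Content" sub-structures (clusters of highly interrelated distinctions)
  have no formal criterion and are not implemented; distinction and
  compound folds are.
* φ_d is *not* always bounded by the mechanism's ii at the same purview
  state: the unconstrained and partitioned reference distributions differ,
  and the normalized MIP can land slightly below the unconstrained
  reference (≈1% excess observed on random 3-unit networks). The package
  implements the defining equations literally rather than enforcing the
  folk bound.
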