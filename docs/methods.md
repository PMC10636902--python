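# Methods

## The model

A molecule is a set of N atoms with Cartesian coordinates (Å), element
symbols and an undirected bond graph. The continuous symmetry measure with
respect to a cyclic point group G — C_n generated by a proper rotation by
2π/n, or S_n generated by an improper rotation (S_1 = C_s reflection,
S_2 = C_i inversion; improper n must be 1 or even, since an odd S_n is not
closed as written) — is

    S(G) = 100 · M(G) / D,   D = Σ_k |Q_k − Q_0|²,

with Q_0 the unweighted geometric center (no mass weighting anywhere) and
M(G) the minimal summed squared displacement to a T-invariant structure.
The minimum runs over the operation axis and over atom permutations π that

1. map atoms within their graph equivalence class,
2. preserve the bond graph (π(i)–π(j) bonded iff i–j bonded), and
3. have cycle lengths in {1, n}, plus 2 when G is S_n or C_2.

For fixed (π, T) the minimizing T-invariant structure is the orbit average
P_k = (1/g) Σ_{i=0..g−1} T^{−i} Q_{π^i(k)} (g = group order; the
quadratic problem is separable per orbit and the average is its closed-form
solution), and M equals the cycle-averaged objective
(1/2g) Σ_{i=1..g} Σ_k |T^i Q_k − Q_{π^i(k)}|². Both identities are
verified numerically in the test suite to 1e-9.

S is translation-, rotation- and scale-invariant, lies in [0, 100] for
admissible permutations, and is 0 iff the structure is exactly symmetric.

### Single-operation surrogate

Approximate engines optimize the i = 1 term only,

    M̂ = c · Σ_k |T Q_k − Q_{π(k)}|²,

because it is the quantity a distance-matrix assignment can minimize. The
normalization c is chosen as 1/4 for groups of order two (C_2, C_s, C_i)
and 1/2 otherwise. With this convention M̂ coincides with the full
objective M whenever g = 2 and π is an involution, which makes the
lower/upper bounds of `csm_bounds` directly comparable with the reported
measure: a literal 1/2 normalization would double M̂ for order-2 groups
(the i = 2 term of the cycle average vanishes for an involution, it does
not repeat the i = 1 term) and the bound bracket would fail by a factor of
two. For n > 2 the i = 1 term is a representative summand of the cycle
average and 1/2 is the natural weight.

When an unconstrained assignment returns a permutation whose cycle
structure is not admissible for G, the full objective is not meaningful;
the result is flagged `cycle_valid=False` and S is reported from M̂. For
admissible permutations S is always reported from the full objective, and
the record carries both values.

## Algorithms

**Equivalence classes.** Iterative neighbour-colour refinement starting
from element symbols, refining by the sorted multiset of neighbour colours
to a fixpoint (≤ N rounds). Any bond-preserving, element-preserving
permutation automatically preserves these classes, so using them to
restrict candidates and to mask the distance matrix loses no admissible
permutation. Note that refinement cannot split a uniform-degree
single-element graph (e.g. any fullerene cage is one class regardless of
its actual symmetry).

**Exact enumeration.** Depth-first search over partial permutations with
per-atom candidate sets. After each assignment the candidates of every
unassigned atom are filtered through the bond biconditional; chains of the
permutation are tracked and a chain reaching the maximal allowed cycle
length is closed by forced assignment. The branching atom is always one
with a minimal number of remaining options (ties to the lowest index), and
candidates are visited in index order, so the stream is deterministic.
Every emitted permutation is re-verified post hoc. A node cap (default
10⁷) guards runaway searches. For each permutation the optimal axis of the
full objective is found analytically (below); the global (π, axis) minimum
is returned. The identity permutation is always admissible (all cycles of
length 1), so the exact measure is always defined; it is non-trivial
because T itself has fixed order n.

**Optimal axis.** For a rotation by angle a about unit axis m, the
axis-dependent part of the objective assembles into −(mᵀ C m + b·m) with
C built from the symmetric parts of Σ Q_k Q_{π^i(k)}ᵀ and b from
Σ Q_k × Q_{π^i(k)} (one term per group power for the full objective, the
i = 1 term alone for the surrogate). Maximizing a quadratic-plus-linear
form on the unit sphere is solved by the secular equation in the eigenbasis
of C (bisection-free Brent solve on the monotone branch above the top
eigenvalue, with the degenerate "hard case" handled explicitly), followed
by a guarded BFGS polish of all candidate stationary points. The contract
is oracle-matching: tests require the result to be within 1e-8 of a
10,000-direction grid search plus local refinement. C_i has no axis and
returns the (0, 0, 1) convention; reported axes are sign-canonicalized
(first component of magnitude > 1e-8 made positive).

**Permutation–direction iterations.** Alternate (axis → distance matrix →
assignment) and (permutation → optimal axis). The distance matrix is
A_ij = |T Q_i − Q_j|² with cross-class entries masked to +∞. Assignment is
either greedy (globally smallest remaining entry, ties by lowest row then
column, rows/columns eliminated after each pick) or the Hungarian optimum
(scipy's linear_sum_assignment). Each Hungarian step and each axis step is
optimal for its subproblem, so the objective trajectory is non-increasing;
a greedy step that would worsen the objective is rejected and terminates
the iteration at the previous iterate, preserving monotonicity. Stopping:
permutation repeat, improvement < 1e-10, or 50 iterations.

**Start directions.** The educated guesses fit a best line and best plane
(SVD) through the equivalence-class centroids and emit the line direction,
the plane normal and two perpendicular complements of each. Outliers are
removed by iteratively dropping the centroid with the largest fit residual
while it exceeds twice the median residual, capped at 20% of centroids
(the rule degrades gracefully: an outlier with extreme leverage can tilt
the fit enough to hide itself, as any non-robust residual rule must).
With fewer than two distinct centroids the coordinate axes are used. The
Fibonacci multistart adds the lattice u_k = (x, r cos θ, r sin θ),
θ = π(√5+1)k, x = 1 − 2k/(M−1), r = √(1−x²), default M = 100, and reduces
deterministically (minimum objective, ties to the earliest start).

**Approximate structure-preserving engine.** The same iteration, but the
assignment step runs the exact enumeration engine in best-first mode:
candidate values π(i) = j are visited in ascending A_ij and a partial
permutation is abandoned once its partial cost reaches the best complete
cost. A global time limit (default 300 s) and node cap (default 2·10⁶)
bound the search; truncation is reported via `complete=False`. The final
axis is re-polished for the full objective. Results are always
cycle-valid, so S is reported from the full objective; consequently this
engine can never report below the exact engine on the same input.

**Bounds.** The Fibonacci+Hungarian minimum of M̂ is a lower estimate (the
Hungarian minimum at any axis is ≤ the structure-preserving minimum at
that axis; with a dense enough lattice some start is near the optimal
axis), and the structure-preserving engine an upper bound. For C_s/C_i,
where M̂ = M on involutions, the pair brackets the exact S; for n > 2 the
lower value bounds the surrogate only and is labelled `tight=False`. The
lower estimate is heuristic in the axis dimension; the bracket is verified
empirically on every test fixture rather than guaranteed.

**Dispatch.** `algorithm="auto"` tries the exact engine for molecules of
≤ 300 atoms under a 10⁶-node enumeration cap and falls back to the
Hungarian iteration — so a 60-atom cage with 32 admissible permutations is
still solved exactly, while a 2,000-atom framework goes straight to the
assignment engine. The CCM scans {C_s, C_i} by default (chirality usually
stems from missing reflection symmetry, so S(C_s) most often achieves the
minimum); additional improper groups can be requested.

## Synthetic fixtures

The generator module emulates the benchmark families at desk scale: exact
C_n rings and prisms (macrocycle-like), the truncated icosahedron (the C60
cage: 60 vertices from the cyclic permutations of (0, ±1, ±3φ),
(±1, ±(2+φ), ±2φ), (±2, ±(1+2φ), ±φ), scaled to a 1.4 Å edge, 90 bonds,
3-regular, one equivalence class, exactly 32 structure-preserving
involutions), a two-element bonded pair (mirror-symmetric, not
inversion-symmetric; its S(C_i) is exactly 100), a Frucht-graph cage in
the tests (cubic with trivial automorphism group — the desk-scale analogue
of a topologically asymmetric fullerene), and a four-element chiral toy
whose only admissible permutation is the identity, making its CCM a
closed-form planarity defect. Distortion adds seeded i.i.d. Gaussian noise
per coordinate. All generators are pure functions of their arguments.

What the fixtures do not emulate: realistic force-field geometries,
conformational (rather than Gaussian) distortion modes, hydrogen-bond
networks, and crystal periodicity. Passing tests demonstrate algorithmic
correctness (oracle equivalence, bound brackets, limiting values), not
chemical accuracy on any particular real dataset.

## Numerical choices and problem sizes

* Bond perception: Cordero covalent radii, slack 0.4 Å (common heuristic;
  required for XYZ input, which carries no connectivity).
* Convergence: Δ objective < 1e-10 or permutation repeat, ≤ 50 iterations.
* Degenerate inputs: all-coincident atoms raise (D = 0, S undefined);
  bond-free molecules report structure preservation as not applicable.
* Tests exercise exhaustive oracles at N ≤ 6 atoms (all 720 permutations,
  grid+refined axes), 20 seeded molecules for the brute-force comparison
  and 20 for the bound bracket, and 1,000 random matrices for the
  Hungarian-vs-greedy dominance check; these sizes keep the default suite
  around two minutes while covering every engine code path. The C60 cage
  (60 atoms) is the largest structure enumerated exactly in the suite.

## Known limitations

* Only cyclic generators C_n and S_n are measured; composite groups
  (D_n, T, O, I) are out of scope.
* The exact engine's feasibility depends on the bond graph's automorphism
  structure, not only on atom count; the node cap is the real guard.
* Fibonacci multistart cost grows linearly in the lattice size; beyond
  ~100 directions the accuracy gain is usually marginal.
* Cross-class masking assumes the colour-refined classes are the right
  exchange groups; for single-element uniform-degree graphs (fullerenes)
  the mask is vacuous by construction, which is intended.
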