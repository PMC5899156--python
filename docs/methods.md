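# Methods

## Objective and equivalence

The detector partitions an undirected binary loop-free graph by minimizing
clique conductance. Each maximal clique σ (size ω(σ)) charges ω(σ) for
every one of its vertex pairs split by a cut, so a cut through a large
clique is penalized by both the clique's size and the number of its
internal edges severed. The balancing volume is the clique degree
d_c(v) = Σ_{σ∋v} ω(σ)(ω(σ)−1), summed over the cluster.

Both functionals equal their ordinary weighted-graph counterparts on the
induced clique graph G_c with weights π_c(u,v) = Σ_{σ∋u,v} ω(σ): the cut
identity is the quadratic form zᵀL_c z with z the cluster indicator, and
the volume identity follows from the degree matrix. The implementation
keeps π_c, cuts and volumes as exact integers and verifies both identities
in tests (exact equality, no tolerance); floating point enters only at the
conductance division.

Two readings of the volume exist: the size-mass form Σ_σ ω(σ)|σ∩A| and the
weighted-volume form above. They differ (triangle, A one vertex: 3 vs 6),
and only the weighted form satisfies the cut/volume identities and hence
the Cheeger machinery, so `clique_vol` is the weighted form; the size-mass
reading remains available as `membership_volume` for inspection.

Similarly, the m-term conductance sum at m = 2 counts the same cut twice
(both terms coincide), while the guarantee is stated for the single-term
Cheeger ratio h(A) = cut/min(vol, vol̄). The package exposes both:
`partition_conductance` is the m-term sum, and the sweep, brute-force and
bound-verification code work with the Cheeger ratio.

## Pipeline

1. **Maximal cliques** — Bron–Kerbosch with pivoting (pivot = vertex of
   P∪X with most neighbours in P), the outer level iterating a degeneracy
   ordering; worst-case O(3^(n/3)), which is tight (complete tripartite
   graphs with parts of 3 attain it). Isolated vertices are emitted as
   1-cliques so every vertex is covered; they contribute no pairs to G_c.
2. **Induced clique graph** — integer accumulation of π_c over clique
   pairs; construction verifies that the support of π_c equals the original
   edge set (every edge lies in a maximal clique of size ≥ 2, so π_c ≥ 2 on
   edges).
3. **Spectral stage** — symmetric normalized Laplacian
   ℒ_c = I − D_c^(−1/2) W_c D_c^(−1/2); dense `scipy.linalg.eigh` up to
   n = 2000, shift-invert Lanczos above. For m = 2: vertices sorted by
   descending g = D_c^(−1/2)x₂ (ties broken by ascending index for
   determinism), Cheeger ratio of every proper prefix evaluated
   incrementally, minimizing prefix returned. The result is insensitive to
   the eigenvector's sign because prefixes of the reversed order are
   complements of suffixes and h(A) = h(Ā). For m > 2: rows of the n×m
   eigenvector matrix unit-normalized and clustered with k-means
   (k-means++, 20 restarts, best inertia, labels canonicalized by first
   appearance).

Degenerate inputs: vertices with zero clique degree (isolated in G) make
D_c^(−1/2) undefined, so they are removed before the spectral stage and
appended afterwards as singleton communities with a warning. m = 2 on a
disconnected graph short-circuits to a component split with φ̂ = 0 (the
conductance optimum); m > 2 on disconnected graphs proceeds normally (the
zero eigenvalue's multiplicity spans the components). Degenerate
partitions (a part with zero volume on both sides) raise rather than
return infinities, so optimization code fails loudly.

## Bipartition guarantee

For connected graphs the expanded Cheeger chain
2φ* ≥ λ₂ ≥ φ̂²/2 ≥ φ*²/2 links the exhaustive optimum φ*, the sweep result
φ̂ (which by construction is the minimum prefix ratio α), and λ₂ of ℒ_c,
giving φ* ≤ φ̂ ≤ 2√φ*. The verification suite checks every inequality with
slack 1e−8 on random geometric graphs: n points uniform in [0,1]^100,
complete graph weighted by negative Euclidean distance, binarized by
keeping the ⌊ρ·n(n−1)/2⌋ shortest pairs (threshold ties broken by
lexicographic pair order; in practice exact ties do not occur but the
tie-break keeps runs bit-reproducible). Draws are not forced connected;
disconnected draws keep φ* = φ̂ = λ₂ = 0 and satisfy the chain with
equality. The exhaustive search enumerates the 2^(n−1)−1 proper subsets
containing vertex 0 in vectorized chunks and refuses n above a default cap
of 20; the test suite runs n ∈ {12, 14, 16} with 20 trials at each
ρ ∈ {0.2, 0.4, 0.6, 0.8}, which finishes in seconds while exercising the
same bound the larger offline sweeps would.

## Benchmark generators

The generators define the evaluation conditions and are first-class,
tested code.

**GN**: 128 vertices, 4 planted communities of 32, degree exactly 16 per
vertex with z_out inter-community connections (z_out ∈ [0, 16]). Wiring is
by stub matching: each vertex gets 16 − z_out intra-community and z_out
inter-community stubs, paired uniformly at random avoiding self and multi
edges, with unmatched remainders reshuffled up to 100 times and then
dropped (logged; in practice at most a stub or two per realization). For
half-integer z_out = k + ½, half of each community's vertices get k
inter-community stubs and half k + 1; other fractional values are
randomized per vertex with matching expectation. The count-based wiring
(rather than independent Bernoulli edges) matters at the recovery
threshold: Bernoulli degree fluctuations create vertices with genuinely
ambiguous neighbourhoods and depress mean NMI by a few percent near
z_out = 6–7, whereas with fixed counts recovery is essentially perfect up
to z_out = 7 — the behaviour the benchmark is defined to exhibit.

**LFR-style**: n = 500 vertices in m = 10 communities by default; degrees
from a discrete truncated power law (exponent γ = 2 on [20, 80], sampled
by inverse CDF on integer support), community sizes likewise (β = 1.1 on
[30, 100]), nudged by ±1 steps within bounds to sum exactly to n and
re-drawn (up to 100 times) until the largest size can host the largest
internal degree. Vertices are assigned by the homeless/kick-out loop: each
homeless vertex joins a random community whose size exceeds the vertex's
internal degree ⌊(1−μ)k⌉; joining a full community kicks out a random
member. The capacity test uses the internal degree rather than the total
degree because a vertex of degree 80 could otherwise be unplaceable
whenever no size draw exceeds 80, which the parameter constraints
k_min < s_min, k_max < s_max are clearly not meant to allow. Stubs are
split round-half-up into internal/external (with per-community parity
fix-ups that move one stub outward — or drop it when μ = 0, so that μ = 0
yields strictly intra-community graphs — and a +1 degree bump on one
vertex when the drawn degree total is odd) and paired like the GN stubs,
external pairs additionally rejected within a community. Realized degrees
can fall a stub short of target at extreme μ; bounds [k_min, k_max] are
never exceeded.

These generators emulate planted community structure with controlled
mixing; they do not emulate degree correlations, clustering beyond what
cliques induce, overlapping communities, or weighted/directed edges, so
benchmark results say nothing about those regimes.

**NMI** uses natural logarithms (the normalized ratio is base-invariant)
with arithmetic-mean-entropy normalization; the 0/0 case of two trivial
one-cluster partitions is defined as 1 (they are identical) and logged.
Arguments are put in a canonical order before computation so symmetry
holds to the last bit.

## Problem sizes and defaults

Test and acceptance runs use desk-scale sizes chosen to exercise every
claim while keeping a full run in tens of seconds: benchmark curves at 50
(GN) and 20 (LFR) realizations per grid point, bound verification at
n ∈ {12, 14, 16} × 4 densities × 20 trials, oracle suites at 100–200
random graphs with n ≤ 12 (where 2ⁿ enumeration is itself instant). The
method's complexity — O(3^(n/3)) enumeration plus O(n³) eigensolve — makes
it unsuitable for large networks regardless of these choices; a few
thousand vertices of sparse real data is the practical ceiling.

## Known limitations

- The method is defined on binary graphs; weighted input is binarized by
  `simplify` (weights discarded, documented in the loader).
- k-means (m > 2) carries no optimality guarantee; only the m = 2 sweep
  does.
- The m > 2 path depends on the seed through k-means initialization;
  results on well-separated inputs are seed-stable, near-degenerate inputs
  may not be.
- Exhaustive verification is limited to n ≈ 20 by its 2^(n−1) cost; the
  guarantee itself is proved, the suite only spot-checks the
  implementation against it.
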