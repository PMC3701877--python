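# Methods

This note records the models, conventions and design choices behind
aviannet's analyses, what the synthetic generator does and does not
emulate, and the known limitations — including one substantive
discrepancy between the packaged connection table and the statistics
historically reported for it.

## The data model

A connectome is an ordered list of region labels plus a dense 0/1
adjacency matrix, `A[i, j] = 1` iff a directed connection exists from
region *i* to region *j* (row = source everywhere in the package). Graphs
are simple: no self-loops, no multi-edges, no hemispheric distinction.
The packaged pigeon fixture is parsed from a frozen transcription of the
published connection table (`src/aviannet/data/pigeon_table2.txt`; the
typographic irregularities of the source and their resolutions are listed
in `transcription_notes.md` alongside). The transcription gate — 52
regions, 344 arcs, no self-loops, no isolated region — is enforced by the
test suite, together with spot checks (BO is a pure source of out-degree
6; AD, AI, NCL form a complete directed triangle).

## Metric conventions

**Clustering.** Fagiolo's directed clustering handles reciprocal arcs
exactly through the correction term $2d^{\leftrightarrow}_i$; no
pre-symmetrization. Nodes with a vanishing denominator (total degree < 2,
or all partners reciprocal) contribute 0 to the network mean rather than
being dropped — the binary-toolbox convention, and the one that
reproduces the published γ = 0.3647 on the fixture.

**Path length.** Unweighted BFS over directed arcs; λ is the mean over
ordered pairs *i* ≠ *j* with finite distance. The fixture is not strongly
connected (e.g. the olfactory bulb BO and the interstitial nucleus IHA
receive nothing; the globus pallidus GP sends nothing), so 200 of the
2652 ordered pairs are unreachable; they are excluded from the mean and
their count is always reported.

**Small-world nulls.** Both indices use 200 null samples (the reference
protocol). The degree-sequence null (σ_io) uses Maslov–Sneppen two-arc
swaps (`a→b, c→d ⇒ a→d, c→b`), rejecting self-loops and duplicates, with
20 attempted swaps per arc: measured null means on 52-node graphs are
stationary from ~5 swaps/arc, so 20 gives comfortable margin; the value
is configurable. The classical null ("same n and average node degree k")
is an Erdős–Rényi *digraph* matching the average **total** (in+out)
degree, i.e. with 2m arcs: this is the only reading that reproduces the
reported null values (γ_r ≈ 0.259 = 2m/(n(n−1)), λ_r ≈ 1.763) — a
directed ER graph with m arcs has Fagiolo clustering ≈ m/(n(n−1)) ≈ 0.13
instead. `er_random(n, m)` itself keeps exact-m semantics; the doubling
is applied only inside the small-world ER normalization.

**Assortativity.** The edge-wise formula with pooled moments,
x = source out-degree, y = target in-degree:
r = (⟨xy⟩ − ⟨(x+y)/2⟩²) / (⟨(x²+y²)/2⟩ − ⟨(x+y)/2⟩²). Degenerate graphs
with zero pooled variance (e.g. a directed cycle) raise rather than
returning a value.

**Motifs.** Structural-motif semantics: one count per node subset whose
induced digraph is weakly connected. Isomorphism classes are canonical
ids assigned by the lexicographically minimal adjacency bit-encoding over
all node permutations — 13 classes at size 3 and 199 at size 4, both
verified by construction. Classification is a table lookup over all 2⁶ or
2¹² induced codes, making full 4-node censuses of 52-node graphs fast
enough to run against 200 rewired nulls in seconds. z-scores with a zero
null standard deviation are flagged (NaN) rather than inflated.

**Modularity.** Directed Leicht–Newman Q with m = arc count and 1/m
normalization. Printed formulations that define A_ij as "from j to i" are
the transpose of our convention; Q is identical under transposition with
in/out swapped (asserted by test), so the package-wide row = source
orientation is used uniformly. The optimizer is a directed Louvain:
randomized-order single-node moves on the modularity gain
ΔQ = (w_{v→C} + w_{C→v})/m − (k^{out}_v K^{in}_C + k^{in}_v K^{out}_C)/m²,
followed by community aggregation, iterated to a local optimum, with 100
independent restarts by default (best Q kept; never below the all-in-one
partition, whose Q is identically 0). On the fixture this finds
Q = 0.312 with five modules — above both the historically reported
machine optimum (0.2796, two modules) and the hand-tuned five-module
value (0.3020) — with recursive within-module optimization giving child
Q values of 0.132 and 0.203 for the two large modules (reported values:
0.1309 and 0.1932). Q for any user-supplied partition can be evaluated
from a `region,module[,submodule]` CSV.

**Participation.** Directed generalization averaging the squared
module-shares of incoming and outgoing arcs. A node with zero in-degree
(or out-degree) has that half treated as fully concentrated (squared-share
sum = 1): absent connectivity cannot be spread. This keeps P ∈ [0, 1] and
makes P = 0 under a single-module partition.

**Hubs.** Betweenness is the ratio-sum over ordered pairs (unreachable
pairs contribute zero), computed by Brandes' algorithm and cross-checked
against exhaustive path enumeration in tests. Rank boundaries include
ties. The 0.35 connector threshold is exposed as a parameter.

**k-core.** Peeling on total degree recomputed on the shrinking
subgraph; sub-shell (i, j) is the j-th sweep at threshold i. A threshold-0
pre-pass removes isolated nodes (core level 0). The erosion level is the
smallest i whose i-core is empty — on the fixture the 10-core is the
innermost non-empty core and erosion occurs at i = 11.

**Rich club.** φ(k) = E_k/(N_k(N_k−1)) over the top-k total-degree nodes
with directed E_k; equal-degree ties are ordered greedily to maximize the
internal-arc contribution at each rank. Some formulations put 2E_k over
the same denominator; any constant factor cancels in the normalization
φ/φ_rand (same ranking procedure applied to every rewired null), so club
membership is robust to the convention. The club is the largest top set
whose every prefix rank k ≥ 2 has φ_norm > 1.

**Knotty centrality.** KC(S) is internal arc density times the subset's
share of total betweenness. The original search heuristic is not public;
the default here is exhaustive enumeration over all subsets of the top-12
betweenness nodes (≤ 2¹² evaluations) followed by greedy single-node
add/remove refinement over all nodes — verifiable, and exact over its
pool. On the fixture it returns {AD, AI, NCL, MD}, matching the reported
knotty center.

## The synthetic generator

`planted_partition` is a directed stochastic block model: each ordered
pair receives an arc independently with p_in (within module), p_out
(between), and optionally p_mid (between sibling child-modules inside a
parent, for two-level structure). `planted_hubs` overlays designated hub
nodes with extra cross-module in- and out-arcs (probability `hub_boost`).
Defaults (n = 52, modules 16/14/9/7/6, p_in = 0.35, p_out = 0.04) mimic
the fixture's size and density (~0.13). For the two-level recovery
experiment, p_mid must be high enough that sibling children cohere at the
top level of the Q landscape; the tested regime (p_in = 0.5,
p_mid = 0.25, p_out = 0.02) plants a genuinely hierarchical world.

What the generator does *not* emulate: reciprocity structure (real
connectomes have far more reciprocal pairs than an SBM at equal density),
degree heterogeneity beyond the hub overlay, and any spatial embedding.
A green recovery test therefore establishes that the optimizer/classifier
finds planted block/hub structure at realistic size and density — not
that it would resolve every anatomical nuance of a real connectome.

## Reproducibility

Every stochastic routine takes a seed; ensemble sample *i* draws its
stream from `(seed, i)`, so results are independent of evaluation order
and bit-reproducible. The full default battery on the fixture runs in
well under a minute on one CPU.

## Known discrepancy: direction-sensitive statistics of the printed table

Two published values are not reproducible from the printed connection
table under any standard convention: λ = 2.3961 (we compute 2.4878, also
confirmed by networkx and igraph) and r = −0.1143 (we compute −0.1269
from the printed formula). Every direction-*insensitive* statistic
reproduces essentially exactly — γ (invariant under reversing
non-reciprocal arcs), the motif totals 2328 and 22,114 (dependent only on
the undirected skeleton), and the complete k-core structure (total-degree
peeling) — while every direction-*sensitive* one is off, including the
path-length z-score versus rewired nulls (7.9 here vs 2.84 reported).
The parsimonious explanation is that the matrix actually analysed
differed from the printed table in a small number of arc directions.
Searches over all single and paired direction flips found no combination
reconciling both λ and r, so no principled correction exists; the package
ships the table exactly as printed and reports what it implies. The
derived index σ_io ≈ 1.32 (reported: 1.4004) inherits this discrepancy;
the corresponding acceptance tests are intentionally left failing as a
record.

## Limitations

- Binary connectivity only: no weights, tracer-strength grading, or
  spatial information.
- The modularity optimizer is stochastic and returns a lower bound on the
  optimum; module membership on glassy landscapes can vary across seeds
  even when Q barely moves.
- Motif analysis stops at size 4; functional (non-induced) motif counting
  is out of scope.
- The rewiring null conditions on the exact degree sequence but not on
  reciprocity, which real connectomes over-express; z-scores against it
  partly reflect that excess.
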