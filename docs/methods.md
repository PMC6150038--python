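# Methods

## Canonical labeling from resolving sets

A simple graph Γ = (V, E) with |V| = n is canonized in four steps:

1. **Twin partition.** Vertices u, v are *parity nodes* (twins) when their
   neighborhoods coincide outside the pair: undirected,
   N(u)∖{v} = N(v)∖{u}; directed, equal in- and out-degrees together with
   N⁺(u)∖{v} = N⁺(v)∖{u} and N⁻(u)∖{v} = N⁻(v)∖{u}. This is an equivalence
   relation; the partition is built by testing all O(n²) pairs and
   union-find, with transitivity verified in the test suite rather than
   assumed.
2. **Advanced metric dimension.** With one representative per class
   (V_S), enumerate subsets of V_S of cardinality 0, 1, 2, … and keep every
   subset of the first cardinality that resolves V_S — i.e. gives the
   representatives pairwise-distinct metric representations. The search is
   exhaustive by design and exponential in the dimension; a configurable
   cap (default 5 × 10⁶ subset tests) raises an explicit resource error
   rather than running away.
3. **Induced orderings.** Each ordered basis W sorts the parity *classes*
   by the metric representation of their representative, compared
   coordinate-by-coordinate with smaller distances first; class members are
   then listed contiguously in ascending vertex id.
4. **Lexicographic leader.** Over every minimum advanced resolving set and
   every ordering of it, permute the adjacency matrix by the induced vertex
   order and keep the row-major minimum (0 before 1). The winning matrix is
   serialized as `n:<d|u>:<bits>` — n² row-major bits for digraphs, the
   n(n−1)/2 upper-triangle bits for undirected graphs.

Equal labels characterize isomorphism. Soundness rests on two facts checked
directly by tests: a swap of any twin pair inside any vertex ordering leaves
the permuted matrix bit-identical (so the within-class order and the choice
of representative are immaterial), and the class-representative keys never
tie across classes (W resolves them), so the full ordering is determined by
isomorphism-invariant data up to twin swaps.

Two conventions deserve a note:

* **Classes, not vertices, are the sort unit.** Sorting individual vertices
  by their own representations looks equivalent but is not: a twin of a
  basis vertex gets a representation of its own (its distance to its twin
  replaces the twin's 0), which can collide with the representation of a
  vertex from a *different* class; breaking such a tie by vertex id would
  destroy isomorphism invariance. Class-keyed sorting cannot tie across
  classes and is provably invariant.
* **The label is canonical, not globally minimal.** The leader is taken
  over basis-induced orderings only, a strict subset of all n!
  permutations, so the label generally differs from the brute-force
  minimum adjacency matrix. Completeness is what matters and is tested
  exhaustively: on all 2⁶ labeled graphs on 4 vertices and all 2¹⁰ on 5,
  labels coincide exactly with the 11 and 34 isomorphism classes.

Distances are BFS shortest-path lengths; unreachable pairs hold the
sentinel n (any finite distance is ≤ n − 1), which keeps representations
well-defined and invariant on disconnected inputs. For directed graphs each
representation coordinate is the ordered pair (d(v, w), d(w, v)) — more
discriminating than one-way distances, hence smaller dimensions on sparse
digraphs, and equally invariant. With a single twin class (complete graphs)
the empty set is a valid advanced basis: dimension 0, identity-ordered
classes, and the twin-swap theorem covers the rest.

## Subgraph census (ESU)

Connected induced k-vertex subgraphs are enumerated by growing each
subgraph from its minimum-id root, extending only with neighbors of id
greater than the root that are not already adjacent to the partial
subgraph; every subgraph is visited exactly once (checked against a
brute-force subset oracle). Directed subgraphs use weak connectivity, the
standard motif-tool convention, and occurrences are *induced* (all edges
among the chosen vertices). Canonical labels of the induced patterns are
cached by their raw adjacency bitmask — at most 2^(k(k−1)) patterns — so
canonization cost is paid per pattern, not per occurrence. The size guard
defaults to k ≤ 5.

## Null model and significance

Randomized networks are produced by edge switching: pick two distinct
edges (a,b), (c,d) uniformly, rewire to (a,d), (c,b), reject if the move
would create a self-loop or duplicate edge. Directed moves exchange heads
only, preserving every vertex's in- and out-degree exactly; undirected
moves randomly orient the two picked edges first so that both pairings of
the four endpoints are reachable. The swap budget counts *successful*
swaps — default 10·|E| per member, the standard mixing prescription — with
an attempt cap (100× budget) so rigid graphs such as the directed 3-cycle,
which admits no legal swap, still terminate (the member is returned
unchanged with a `capped` flag). Mutual-edge (antiparallel-pair) counts are
not separately conserved; the plain switch is the model. Member i of an
ensemble uses seed + i, making ensembles reproducible and trivially
parallelizable.

Per pattern the report gives the real count, ensemble mean and population
standard deviation, z = (real − mean)/sd, the empirical p-value (plain
fraction of members with count ≥ real; legitimately 0 when no member
reaches the real count), and the upper-tail normal p-value at z. Both
p-values are reported because the empirical fraction saturates at 0 for
strong motifs while the normal tail stays informative; when sd = 0 the
z-based fields are reported missing rather than infinite.

Patterns: the FFL (x→y, y→z, x→z) and bi-fan (x→z, x→w, y→z, y→w) are
counted through the full ESU + canonization path, their target labels
computed at startup from edge lists so they track any labeling-convention
change. The single input module has variable size and is counted by a
direct scan: a regulator qualifies when at least `min_targets` (default 10,
i.e. module size > 10 nodes) of its targets have it as their *sole*
regulator; one count per qualifying regulator.

## Synthetic regulatory networks

The generator plants motif instances on disjoint reserved vertex blocks
that receive no background edges, so every planted instance is an induced
occurrence and real counts are lower-bounded by construction — enrichment
tests cannot be flaky in the planted direction. Defaults: 200 genes, 30
FFLs, 10 bi-fans, Erdős–Rényi directed background at density 0.03 among the
unreserved vertices (~280 edges total, mean degree ≈ 2.8, a realistic
sparsity for curated transcription-factor/target maps). What the generator
does *not* emulate: scale-free out-degree hubs, autoregulation (self-loops
are excluded by the graph model), overlap between motif instances, and
dense overlapping regulons; a significant planted motif here demonstrates
the pipeline's correctness, not biological discovery.

End-to-end validation runs the full pipeline on the planted network versus
a density-matched unplanted digraph with a 100-member ensemble — large
enough that the empirical p-value resolves 0.01 steps, small enough for a
desk-scale test run; the same machinery accepts the conventional
1000-member ensemble unchanged.

## Numerical and interface choices

* Vertices are dense integers 0..n−1 internally; string names exist only
  in edge-list TSV I/O (tab-separated pairs, `#` comments, optional
  `source\ttarget` header, first-appearance id assignment).
* Ordering tie-breaks: within a parity class, ascending vertex id
  (immaterial to the matrix); among equal-cardinality bases and their
  orderings, plain lexicographic enumeration with duplicate induced
  permutations skipped.
* Degenerate inputs: the empty target set and singleton graphs are
  resolved by the empty set; n = 0 and edgeless graphs are legal
  everywhere except edge switching, which requires ≥ 2 edges.
* CLI exit codes: 0 success/isomorphic, 1 non-isomorphic, 2 usage error,
  3 resource cap.

## Known limitations

* The basis search is exponential in ν(Γ); graphs that are both twin-free
  and high-dimensional (large stars minus a perfect matching, say) hit the
  work cap by design. The cap errs loudly, never silently truncates.
* No automorphism-group output, and no hardening against
  adversarial families (e.g. Miyazaki-style constructions) beyond what the
  resolving-set scheme naturally provides.
* `is_isomorphic` canonizes both inputs; for many pairwise comparisons,
  canonize once and compare labels.
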